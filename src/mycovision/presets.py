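"""Reference calibrations for the synthetic scene families.

Real micrographs always need their own calibration (that is what the
parameter sweep is for); these presets are the parameter sets obtained by
calibrating each quantification function against its synthetic reference
scene (seed 0 of the corresponding generator) and are what the tests, the
examples and the accuracy-evaluation suites use.

The reasoning behind each value:

* spore scenes — inverted spores sit near 0.8, inverted background near
  0.15 with sigma-0.05 noise, so ``b1=0.5 / b2=0.35`` leaves > 3 sigma of
  headroom on both sides; the area gate [40, 3000] brackets the planted
  ellipse areas (~70-450 px^2) while excluding dust specks (< 10 px^2);
  ``elongation_max=0.7`` passes spores (planted elongation <= 0.4) and
  rejects thin bars (~0.95);
* mycelium scenes — after background subtraction the branch interior sits
  near 0.4-0.55 and the flattened background near 0, so ``b1=0.35 /
  b2=0.2``; ``gaussian_radius=15`` is ~5x the branch width, wide enough
  to treat branches as "detail"; ``min_hyphae=12`` deletes noise specks
  and prunes thinning spurs but is far below the shortest planted branch;
* trap scenes — inverted traps ~0.8, inverted hyphae ~0.45, so
  ``b1=0.6 / b2=0.5`` keeps single hyphae entirely out of the weak mask;
  the area gate [250, 20000] excludes any hypha fragment and the
  elongation gate excludes straight runs.
"""

from __future__ import annotations

from .core import CalibrationParams

__all__ = ["spore_scene_params", "mycelium_scene_params", "trap_scene_params"]


def spore_scene_params(scale: float = 1.0) -> CalibrationParams:
    """Calibration for the synthetic spore scenes (both polarities)."""
    return CalibrationParams(
        b1=0.5,
        b2=0.35,
        min_area=40,
        max_area=3000,
        elongation_max=0.7,
        gaussian_radius=0.0,
        min_hyphae=0,
        scale=scale,
    )


def mycelium_scene_params(scale: float = 1.0) -> CalibrationParams:
    """Calibration for the synthetic mycelium scenes."""
    return CalibrationParams(
        b1=0.35,
        b2=0.2,
        min_area=0,
        max_area=10_000_000,
        elongation_max=1.0,
        gaussian_radius=15.0,
        min_hyphae=12,
        scale=scale,
    )


def trap_scene_params(scale: float = 1.0) -> CalibrationParams:
    """Calibration for the synthetic trap scenes."""
    return CalibrationParams(
        b1=0.6,
        b2=0.5,
        min_area=250,
        max_area=20_000,
        elongation_max=0.7,
        gaussian_radius=0.0,
        min_hyphae=0,
        scale=scale,
    )
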