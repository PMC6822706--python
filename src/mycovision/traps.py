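"""Counting of nematode-trap structures.

Adhesive-network traps appear as dense, compact clusters clearly distinct
from ordinary hyphae.  Detection is purely morphological — the same
invert / hysteresis / size-and-elongation gating used for spore counting,
run with trap-scale parameters: a large ``min_area`` excludes single
hyphal strands and the elongation gate excludes long straight hyphal runs.
Trap counting is therefore a named entry point over the shared component
pipeline, kept separate for workflow clarity (its calibrations differ).
"""

from __future__ import annotations

import numpy as np

from .core import CalibrationParams
from .spores import SporeCountResult, count_spores

__all__ = ["count_traps"]


def count_traps(
    img: np.ndarray, params: CalibrationParams, image_name: str = ""
) -> SporeCountResult:
    """Count trap structures in a brightfield image.

    Identical pipeline to :func:`mycovision.spores.count_spores` (shared
    implementation); only the calibrated parameter ranges differ, so
    ``count_traps(img, p) == count_spores(img, p)`` for any image and
    parameters.
    """
    return count_spores(img, params, image_name=image_name)
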