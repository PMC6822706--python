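"""Spore / conidia counting and per-spore morphometry.

Counting assumes the brightfield convention — spores darker than a bright
transparent background — so the image is inverted before thresholding.
Morphometry assumes the fluorescence convention (calcofluor-stained spores,
bright on dark) and skips the inversion.  Both share the same segmentation:
hysteresis binarization followed by closed-interval area and elongation
gates that reject dust specks (too small) and hyphal fragments (too
elongated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    CalibrationParams,
    ComponentRecord,
    as_gray,
    filter_components,
    hysteresis_binarize,
    invert,
    label_and_measure,
)

__all__ = [
    "SporeCountResult",
    "SporeMeasurement",
    "SporeMorphologyRecord",
    "count_spores",
    "measure_spores",
    "droplet_to_dish",
    "percent_error",
]


@dataclass(frozen=True)
class SporeCountResult:
    """Count of detected spores in one image plus the surviving components.

    ``detection_mask`` holds the pixels of the kept components (used for
    overlay rendering); ``n_spores == len(kept_components)``.
    """

    image_name: str
    n_spores: int
    kept_components: Tuple[ComponentRecord, ...]
    detection_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class SporeMeasurement:
    """Morphometry of a single spore, in physical units (scale applied)."""

    spore_id: int
    area: float
    length: float
    width: float
    circularity: float


@dataclass(frozen=True)
class SporeMorphologyRecord:
    """Per-spore morphometry for one image (long format, one row per spore)."""

    image_name: str
    spores: Tuple[SporeMeasurement, ...]
    detection_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image": self.image_name,
                    "spore_id": s.spore_id,
                    "area": s.area,
                    "length": s.length,
                    "width": s.width,
                    "circularity": s.circularity,
                }
                for s in self.spores
            ],
            columns=["image", "spore_id", "area", "length", "width", "circularity"],
        )


def _segment(img: np.ndarray, params: CalibrationParams, do_invert: bool):
    work = invert(img) if do_invert else as_gray(img)
    binary = hysteresis_binarize(work, params.b1, params.b2)
    records = label_and_measure(binary)
    kept = filter_components(records, params)
    mask = np.zeros(binary.shape, dtype=bool)
    if kept:
        from skimage.measure import label as _label

        labels = _label(binary, connectivity=2)
        keep_ids = np.zeros(labels.max() + 1, dtype=bool)
        for r in kept:
            keep_ids[r.label] = True
        mask = keep_ids[labels]
    return kept, mask


def count_spores(
    img: np.ndarray, params: CalibrationParams, image_name: str = ""
) -> SporeCountResult:
    """Count spores/conidia in a brightfield image (dark on bright).

    Pipeline: invert -> hysteresis binarize (b1, b2) -> label and measure
    -> area/elongation filter -> count.  Touching spores merge into one
    component and are counted once (no declumping).
    """
    kept, mask = _segment(img, params, do_invert=True)
    return SporeCountResult(
        image_name=image_name,
        n_spores=len(kept),
        kept_components=tuple(kept),
        detection_mask=mask,
    )


def measure_spores(
    img: np.ndarray, params: CalibrationParams, image_name: str = ""
) -> SporeMorphologyRecord:
    """Measure per-spore morphometry in a fluorescence image (bright on dark).

    Same segmentation as :func:`count_spores` but without inversion.
    Length/width are the best-fit-ellipse major/minor axes times
    ``params.scale`` (microns per pixel); area is pixel area times
    ``scale**2``; circularity is unitless.
    """
    kept, mask = _segment(img, params, do_invert=False)
    s = params.scale
    spores = tuple(
        SporeMeasurement(
            spore_id=i + 1,
            area=r.area_px * s * s,
            length=r.major_axis_px * s,
            width=r.minor_axis_px * s,
            circularity=r.circularity,
        )
        for i, r in enumerate(kept)
    )
    return SporeMorphologyRecord(image_name=image_name, spores=spores, detection_mask=mask)


def droplet_to_dish(n_droplet: int, droplet_volume: float, suspension_volume: float) -> int:
    """Extrapolate a droplet count to the whole suspension.

    A count of ``n_droplet`` spores in an imaged droplet of
    ``droplet_volume`` (e.g. 5 ul) taken from a suspension of
    ``suspension_volume`` (e.g. 1000 ul, the full dish harvest) scales to
    ``n_droplet * suspension_volume / droplet_volume``, rounded to the
    nearest integer.
    """
    if droplet_volume <= 0 or suspension_volume <= 0:
        raise ValueError("volumes must be positive")
    return int(round(n_droplet * suspension_volume / droplet_volume))


def percent_error(n_auto: int, n_manual: int) -> float:
    """Signed percent error of an automated count against a manual count.

    ``100 * (n_auto - n_manual) / n_manual``: positive when the automated
    pipeline detects more spores than the manual count, negative when it
    misses spores.
    """
    if n_manual == 0:
        raise ValueError("manual count must be positive")
    return 100.0 * (n_auto - n_manual) / n_manual
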