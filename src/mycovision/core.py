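"""Shared low-level image operations and the calibration-parameter model.

Images are plain numpy arrays: grayscale images are 2-D float arrays with
intensities in [0, 1], binary images are 2-D boolean arrays.  Every
quantification pipeline in the package is a composition of the pure
functions in this module.

Conventions fixed here (and relied on everywhere else):

* 8-connectivity for component labeling and for the hysteresis flood fill,
  so that one-pixel-wide diagonal hyphae stay connected;
* strict inequalities for both binarization thresholds (a pixel must be
  *greater than* ``b1`` / ``b2``);
* Crofton perimeter estimates (contour-length, not boundary-pixel count),
  which keep the circularity of rasterized disks near 1;
* elongation defined as ``1 - minor/major`` best-fit-ellipse axis ratio,
  bounded in [0, 1] with 0 for a circle;
* Gaussian blurs use ``sigma = radius / 2`` with the kernel truncated at
  ``radius`` (so ``radius`` is the half-width of the kernel support), and
  reflected boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "CalibrationParams",
    "ComponentRecord",
    "as_gray",
    "as_binary",
    "invert",
    "gaussian_background_subtract",
    "hysteresis_binarize",
    "dilate_3x3",
    "thin_skeleton",
    "clean_skeleton",
    "subtract_mask",
    "label_and_measure",
    "filter_components",
    "circularity",
    "elongation",
]

# 3x3 all-ones structuring element == 8-connectivity
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CalibrationParams:
    """User-tunable parameters shared by all quantification functions.

    Parameters
    ----------
    b1 : float
        Strong binarization threshold in [0, 1].  Pixels strictly above
        ``b1`` are foreground seeds.
    b2 : float
        Weak (hysteresis) threshold in [0, 1], ``b2 <= b1``.  Pixels
        strictly above ``b2`` that are 8-connected to a seed become
        foreground too.
    min_area, max_area : int
        Closed-interval component-area gate, in pixels.
    elongation_max : float
        Maximum allowed elongation (``1 - minor/major`` axis) for
        spore/trap components; filters out long thin hyphal fragments.
    gaussian_radius : float
        Radius (pixels) of the Gaussian kernel used for background
        estimation in the mycelium pipeline.
    min_hyphae : int
        Skeleton-cleaning threshold (pixels): connected skeleton
        components smaller than this are deleted and terminal branches
        shorter than this are pruned.
    scale : float
        Physical pixel size in microns per pixel; 1.0 keeps all outputs
        in pixel units.
    """

    b1: float = 0.5
    b2: float = 0.3
    min_area: int = 10
    max_area: int = 10_000_000
    elongation_max: float = 1.0
    gaussian_radius: float = 0.0
    min_hyphae: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b2 <= self.b1 <= 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 <= b2 <= b1 <= 1, got b1={self.b1}, b2={self.b2}"
            )
        if not (0 <= self.min_area <= self.max_area):
            raise ValueError(
                f"areas must satisfy 0 <= min_area <= max_area, got "
                f"min_area={self.min_area}, max_area={self.max_area}"
            )
        if not (0.0 <= self.elongation_max <= 1.0):
            raise ValueError(f"elongation_max must be in [0, 1], got {self.elongation_max}")
        if self.gaussian_radius < 0:
            raise ValueError(f"gaussian_radius must be >= 0, got {self.gaussian_radius}")
        if self.min_hyphae < 0:
            raise ValueError(f"min_hyphae must be >= 0, got {self.min_hyphae}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    def replace(self, **kwargs) -> "CalibrationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ComponentRecord:
    """Measurements of one segmented connected component, in pixel units.

    ``major_axis_px`` / ``minor_axis_px`` are the axes of the ellipse with
    the same normalized second central moments as the pixel set (the
    best-fit ellipse); ``elongation = 1 - minor/major``; ``circularity =
    2 sqrt(pi * area) / perimeter`` (equal-area-disk perimeter over actual
    perimeter, 1 for a disk).
    """

    label: int
    area_px: float
    perimeter_px: float
    major_axis_px: float
    minor_axis_px: float
    elongation: float
    circularity: float
    centroid: Tuple[float, float]


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and return a grayscale image (2-D float in [0, 1])."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale image, got shape {a.shape}")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ValueError("grayscale intensities must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def as_binary(img: np.ndarray) -> np.ndarray:
    """Validate and return a binary image (2-D bool)."""
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D binary image, got shape {a.shape}")
    if a.dtype != bool:
        u = np.unique(a)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError("binary image must contain only 0/1 values")
        a = a.astype(bool)
    return a


def invert(img: np.ndarray) -> np.ndarray:
    """Complement intensities: every pixel p becomes 1 - p.

    Used so that dark brightfield spores become bright objects before
    thresholding.  Involutive: ``invert(invert(x)) == x``.
    """
    return 1.0 - as_gray(img)


def _gaussian_blur(img: np.ndarray, radius: float) -> np.ndarray:
    # sigma = radius/2, kernel truncated at `radius` pixels, reflect borders
    sigma = radius / 2.0
    return ndi.gaussian_filter(img, sigma=sigma, truncate=2.0, mode="reflect")


def gaussian_background_subtract(img: np.ndarray, radius: float) -> np.ndarray:
    """Subtract a Gaussian-blurred background estimate from the image.

    The blur (kernel radius ``radius`` px, ``sigma = radius/2``) estimates
    the smoothly varying background — uneven illumination, dye gradients —
    which is subtracted from the original; the result is clipped to
    [0, 1].  Thin bright structures survive because the blur spreads their
    mass over the kernel support.  ``radius = 0`` returns an all-zero
    image (the image minus itself).
    """
    a = as_gray(img)
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return np.zeros_like(a)
    return np.clip(a - _gaussian_blur(a, radius), 0.0, 1.0)


def hysteresis_binarize(img: np.ndarray, b1: float, b2: float) -> np.ndarray:
    """Double-threshold (hysteresis) binarization.

    Foreground = pixels strictly above ``b1``, plus pixels strictly above
    ``b2`` that are connected to such a seed through pixels above ``b2``
    (8-connectivity).  Requires ``0 <= b2 <= b1 <= 1``.
    """
    a = as_gray(img)
    if not (0.0 <= b2 <= b1 <= 1.0):
        raise ValueError(f"thresholds must satisfy 0 <= b2 <= b1 <= 1, got b1={b1}, b2={b2}")
    strong = a > b1
    weak = a > b2
    labels, n = ndi.label(weak, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(weak)
    seeded = np.zeros(n + 1, dtype=bool)
    seeded[np.unique(labels[strong])] = True
    seeded[0] = False
    return seeded[labels]


def dilate_3x3(img: np.ndarray) -> np.ndarray:
    """Binary dilation with a 3x3 box: closes one-pixel gaps in hyphae."""
    return ndi.binary_dilation(as_binary(img), structure=_STRUCT8)


def thin_skeleton(img: np.ndarray) -> np.ndarray:
    """Reduce foreground to a 1-pixel-wide, topology-preserving skeleton.

    Uses iterative morphological thinning (Guo–Hall class), which
    preserves connected components and holes and leaves already-thin
    lines essentially unchanged.
    """
    return morphology.thin(as_binary(img))


def _neighbor_count(sk: np.ndarray) -> np.ndarray:
    """Number of 8-neighbors that are skeleton pixels, for each pixel."""
    return ndi.convolve(sk.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]],
                                                      dtype=np.uint8), mode="constant")


_NBR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _prune_terminal_branches(sk: np.ndarray, min_hyphae: int) -> bool:
    """One pruning pass; mutates ``sk`` in place, returns True if changed.

    Walks from each endpoint (degree-1 pixel) along degree-2 pixels until
    a junction (degree >= 3).  If the walked branch is shorter than
    ``min_hyphae`` pixels it is deleted, the junction pixel kept.  A
    component that is a bare path (endpoint to endpoint, no junction) is
    left for the component-size filter.
    """
    h, w = sk.shape
    deg = _neighbor_count(sk)
    endpoints = np.argwhere(sk & (deg == 1))
    changed = False
    for r0, c0 in endpoints:
        if not sk[r0, c0]:
            continue  # removed by an earlier walk this pass
        path = [(int(r0), int(c0))]
        prev = None
        cur = (int(r0), int(c0))
        hit_junction = False
        while len(path) <= min_hyphae:
            nbrs = []
            for dr, dc in _NBR_OFFSETS:
                r, c = cur[0] + dr, cur[1] + dc
                if 0 <= r < h and 0 <= c < w and sk[r, c] and (r, c) != prev:
                    nbrs.append((r, c))
            if len(nbrs) == 0:
                break  # isolated path end
            if len(nbrs) > 1:
                hit_junction = True  # cur is adjacent to a junction region
                break
            nxt = nbrs[0]
            # is nxt itself a junction?
            ndeg = sum(
                1
                for dr, dc in _NBR_OFFSETS
                if 0 <= nxt[0] + dr < h and 0 <= nxt[1] + dc < w and sk[nxt[0] + dr, nxt[1] + dc]
            )
            if ndeg >= 3:
                hit_junction = True
                break
            prev, cur = cur, nxt
            path.append(cur)
        if hit_junction and len(path) < min_hyphae:
            for r, c in path:
                sk[r, c] = False
            changed = True
    return changed


def clean_skeleton(skel: np.ndarray, min_hyphae: int) -> np.ndarray:
    """Delete small skeleton components and prune short terminal branches.

    Connected components (8-connectivity) with fewer than ``min_hyphae``
    pixels are removed, and terminal branches shorter than ``min_hyphae``
    pixels are pruned back to their junction, iterating to a fixed point
    (so the operation is idempotent).  ``min_hyphae = 0`` is the identity.
    """
    sk = as_binary(skel).copy()
    if min_hyphae <= 0:
        return sk
    while True:
        before = sk.sum()
        # remove components with strictly fewer than min_hyphae pixels
        sk = morphology.remove_small_objects(sk, max_size=min_hyphae - 1, connectivity=2)
        sk = np.ascontiguousarray(sk)
        _prune_terminal_branches(sk, min_hyphae)
        if sk.sum() == before:
            return sk


def subtract_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove masked pixels: output = img AND (NOT mask).

    Used to delete known nuisance structure such as well edges.
    """
    a = as_binary(img)
    m = as_binary(mask)
    if a.shape != m.shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {a.shape}")
    return a & ~m


def circularity(area: float, perimeter: float) -> float:
    """Circularity ``2 sqrt(pi A) / P``: equal-area-disk perimeter over
    actual perimeter.  Exactly 1 for an ideal disk (A = pi r^2,
    P = 2 pi r); 0 is returned for a degenerate zero perimeter."""
    if perimeter <= 0:
        return 0.0
    return 2.0 * math.sqrt(math.pi * area) / perimeter


def elongation(major_axis: float, minor_axis: float) -> float:
    """Elongation ``1 - minor/major``: 0 for a circle, -> 1 for a line."""
    if major_axis <= 0:
        return 0.0
    return 1.0 - minor_axis / major_axis


def label_and_measure(img: np.ndarray) -> List[ComponentRecord]:
    """Label connected components (8-connectivity) and measure each one.

    Per component: pixel-count area, Crofton perimeter, best-fit-ellipse
    major/minor axes (moment ellipse), elongation, circularity and
    centroid, all in pixel units.  Physical units are obtained downstream
    by multiplying lengths by the pixel scale and areas by its square.
    """
    a = as_binary(img)
    labels = measure.label(a, connectivity=2)
    records: List[ComponentRecord] = []
    for p in measure.regionprops(labels):
        major = float(p.axis_major_length)
        minor = float(p.axis_minor_length)
        perim = float(p.perimeter_crofton)
        area = float(p.area)
        records.append(
            ComponentRecord(
                label=int(p.label),
                area_px=area,
                perimeter_px=perim,
                major_axis_px=major,
                minor_axis_px=minor,
                elongation=elongation(major, minor),
                circularity=circularity(area, perim),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return records


def filter_components(
    records: Sequence[ComponentRecord], params: CalibrationParams
) -> List[ComponentRecord]:
    """Keep components passing the closed-interval morphology gates.

    A record survives iff ``min_area <= area_px <= max_area`` and
    ``elongation <= elongation_max`` (values exactly at a bound are
    admissible, matching slider semantics).  Order is preserved;
    idempotent.
    """
    return [
        r
        for r in records
        if params.min_area <= r.area_px <= params.max_area
        and r.elongation <= params.elongation_max
    ]
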