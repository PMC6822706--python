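"""Image/config I/O, batch execution and the three-output contract.

A batch run takes a folder of homogeneous images plus one calibration and
produces three things in the output directory:

1. ``parameters.txt`` — a ``key=value`` dump of the calibration applied;
2. a results table (CSV by default, TSV on request) whose first column is
   the image name;
3. one overlay PNG per input image showing the detected features over the
   original (spores/traps in blue; for mycelium the graph in green, hull
   outline in blue, tips in yellow).

Images are processed in lexicographic filename order (which also defines
time-series order); per-image failures are logged and recorded as error
rows without stopping the batch.  Batch output is a pure function of the
image bytes and the configuration: reruns are byte-identical.
"""

from __future__ import annotations

import itertools
import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .core import CalibrationParams, as_binary
from .mycelium import analyze_mycelium_image
from .spores import count_spores, measure_spores
from .traps import count_traps
from .validation import evaluate_pairs

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_image",
    "read_mask",
    "write_config",
    "read_config",
    "run_batch",
    "run_validation",
    "sweep_calibration",
    "render_overlay",
]

logger = logging.getLogger("mycovision")

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")

FUNCTIONS = ("count-spores", "spore-morphology", "mycelium", "traps")


class ConfigError(ValueError):
    """Invalid run configuration or malformed parameter file."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run (one folder, one calibration)."""

    function: str
    input_dir: Path
    output_dir: Path
    params: CalibrationParams
    mask_path: Optional[Path] = None
    table_name: str = "results.csv"
    time_series: bool = False  # mycelium only: add a timepoint column

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise ConfigError(
                f"unknown function {self.function!r}; expected one of {FUNCTIONS}"
            )


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG image as a grayscale float array in [0, 1].

    Integer images are rescaled by the dtype maximum (255 for 8-bit,
    65535 for 16-bit); float images are assumed already normalized and
    are clipped to [0, 1].  RGB(A) images are converted to gray as the
    plain average of the R, G, B channels.
    """
    path = Path(path)
    try:
        a = iio.imread(path)
    except Exception as exc:  # unreadable / unsupported
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if a.ndim not in (2, 3):
        raise IOError(f"unsupported image dimensionality {a.shape} in {path}")
    if a.ndim == 3 and a.shape[2] not in (3, 4):
        raise IOError(f"unsupported channel layout {a.shape} in {path}")
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(float) / np.iinfo(a.dtype).max
    else:
        a = np.clip(a.astype(float), 0.0, 1.0)
    if a.ndim == 3:
        a = a[:, :, :3].mean(axis=2)
    return a


def read_mask(path) -> np.ndarray:
    """Read a mask image: nonzero / bright pixels (> 0.5) are masked."""
    return read_image(path) > 0.5


_CONFIG_KEYS = tuple(f.name for f in dc_fields(CalibrationParams))
_INT_KEYS = ("min_area", "max_area", "min_hyphae")


def write_config(params: CalibrationParams, path) -> None:
    """Write the calibration as plain-text ``key=value`` lines."""
    lines = ["# calibration parameters"]
    for key in _CONFIG_KEYS:
        lines.append(f"{key}={getattr(params, key)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> CalibrationParams:
    """Parse a ``key=value`` calibration file (``#`` comments ignored).

    Every parameter key must be present exactly; unknown keys or
    malformed lines raise :class:`ConfigError` naming the line.
    """
    values: Dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: malformed line {raw!r} (expected key=value)")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in values:
            raise ConfigError(f"{path}:{lineno}: duplicate parameter {key!r}")
        try:
            values[key] = int(value) if key in _INT_KEYS else float(value)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: invalid value for {key!r}: {value!r}") from exc
    missing = [k for k in _CONFIG_KEYS if k not in values]
    if missing:
        raise ConfigError(f"{path}: missing parameter(s): {', '.join(missing)}")
    return CalibrationParams(**values)


# ---------------------------------------------------------------------------
# overlays


def _to_rgb(img: np.ndarray) -> np.ndarray:
    base = np.clip(np.asarray(img, dtype=float), 0, 1)
    return np.stack([base, base, base], axis=2)


_BLUE = (0.1, 0.3, 1.0)
_GREEN = (0.1, 0.9, 0.2)
_YELLOW = (1.0, 0.9, 0.1)


def _paint(rgb: np.ndarray, mask: np.ndarray, color) -> None:
    for ch in range(3):
        rgb[:, :, ch][mask] = color[ch]


def render_overlay(img: np.ndarray, result) -> np.ndarray:
    """Render detected features over the original image as an RGB array.

    Spore/trap results paint the kept components blue; mycelium results
    paint graph edges green, the convex hull outline blue and tips as
    yellow dots.
    """
    rgb = _to_rgb(img)
    h, w = rgb.shape[:2]
    if hasattr(result, "detection_mask") and result.detection_mask is not None:
        _paint(rgb, result.detection_mask, _BLUE)
        return rgb
    graph, metrics = result  # (MycelialGraph, MyceliumMetrics)
    edge_mask = np.zeros((h, w), dtype=bool)
    for e in graph.edges:
        p = np.rint(e.path).astype(int)
        edge_mask[np.clip(p[:, 0], 0, h - 1), np.clip(p[:, 1], 0, w - 1)] = True
    hull_mask = np.zeros((h, w), dtype=bool)
    verts = list(metrics.hull_vertices)
    for (r0, c0), (r1, c1) in zip(verts, verts[1:] + verts[:1]):
        rr, cc = skdraw.line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        hull_mask[np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)] = True
    deg = graph.degrees()
    tip_mask = np.zeros((h, w), dtype=bool)
    for n in graph.nodes:
        if deg[n.id] == 1:
            rr, cc = skdraw.disk((n.row, n.col), 3, shape=(h, w))
            tip_mask[rr, cc] = True
    _paint(rgb, hull_mask, _BLUE)
    _paint(rgb, edge_mask, _GREEN)
    _paint(rgb, tip_mask, _YELLOW)
    return rgb


def _save_overlay(rgb: np.ndarray, path: Path) -> None:
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# batch execution


def _list_images(folder: Path) -> List[Path]:
    return sorted(
        p for p in Path(folder).iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Run one quantification function over every image in a folder.

    Writes ``parameters.txt``, the results table and one overlay per
    image into ``config.output_dir`` and returns the table.  Every input
    image contributes exactly one block of rows (success or an error
    row); failures are logged to stderr and ``run.log``.
    """
    images = _list_images(config.input_dir)
    if not images:
        raise ConfigError(f"no readable images found in {config.input_dir}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler(sys.stderr))
    log_file = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(log_file)
    logger.setLevel(logging.INFO)

    mask = read_mask(config.mask_path) if config.mask_path else None
    params = config.params
    write_config(params, out / "parameters.txt")

    rows: List[dict] = []
    try:
        for t, path in enumerate(images):
            name = path.name
            try:
                img = read_image(path)
                if config.function in ("count-spores", "traps"):
                    fn = count_spores if config.function == "count-spores" else count_traps
                    res = fn(img, params, image_name=name)
                    col = "n_spores" if config.function == "count-spores" else "n_traps"
                    rows.append({"image": name, col: res.n_spores, "error": ""})
                    logger.info("%s: %d components kept", name, res.n_spores)
                elif config.function == "spore-morphology":
                    res = measure_spores(img, params, image_name=name)
                    frame = res.to_frame()
                    if frame.empty:
                        rows.append({"image": name, "spore_id": 0, "error": ""})
                    else:
                        for rec in frame.to_dict("records"):
                            rec["error"] = ""
                            rows.append(rec)
                    logger.info("%s: %d spores measured", name, len(res.spores))
                else:  # mycelium
                    res = analyze_mycelium_image(img, params, mask=mask)
                    graph, metrics = res
                    row = {
                        "image": name,
                        "total_length": metrics.total_length,
                        "n_tips": metrics.n_tips,
                        "n_edges": metrics.n_edges,
                        "hull_area": metrics.hull_area,
                        "error": "",
                    }
                    if config.time_series:
                        row = {"image": name, "timepoint": t, **{k: v for k, v in row.items() if k != "image"}}
                    rows.append(row)
                    logger.info(
                        "%s: length=%.1f tips=%d edges=%d", name,
                        metrics.total_length, metrics.n_tips, metrics.n_edges,
                    )
                _save_overlay(render_overlay(img, res), out / f"{path.stem}_overlay.png")
            except Exception as exc:
                logger.error("%s: %s", name, exc)
                rows.append({"image": name, "error": str(exc)})
    finally:
        logger.removeHandler(log_file)
        log_file.close()

    table = pd.DataFrame(rows)
    cols = ["image"] + [c for c in table.columns if c != "image"]
    table = table[cols]
    sep = "\t" if config.table_name.endswith(".tsv") else ","
    table.to_csv(out / config.table_name, sep=sep, index=False)
    return table


def run_validation(pred_dir, truth_dir, output_csv=None) -> pd.DataFrame:
    """Pixelwise accuracy of predicted masks against ground-truth masks.

    Pairs files by sorted order (names must correspond); returns the
    per-image precision/recall/F/MCC table with a trailing Average row
    and optionally writes it to ``output_csv``.
    """
    preds = _list_images(Path(pred_dir))
    truths = _list_images(Path(truth_dir))
    if not preds or len(preds) != len(truths):
        raise ConfigError(
            f"prediction/truth folders must hold the same number of images "
            f"({len(preds)} vs {len(truths)})"
        )
    pairs = [(read_image(p) > 0.5, read_image(t) > 0.5) for p, t in zip(preds, truths)]
    df = evaluate_pairs(pairs, names=[p.name for p in preds])
    if output_csv is not None:
        df.to_csv(output_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# calibration sweep


def sweep_calibration(
    image,
    function: str,
    grid: Dict[str, Sequence],
    base_params: Optional[CalibrationParams] = None,
    output_dir=None,
) -> pd.DataFrame:
    """Evaluate a calibration grid on one image (the "Test" workflow).

    ``grid`` maps parameter names to candidate values; every point of the
    Cartesian product is applied to the image with the selected function
    and summarized by its headline metric (component count for
    spores/traps/morphology, total length for mycelium).  One overlay per
    grid point is written when ``output_dir`` is given, replacing an
    interactive slider-and-preview calibration.  Invalid parameter
    combinations (e.g. b2 > b1) are recorded with a NaN metric.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("parameter grid must be non-empty")
    unknown = [k for k in grid if k not in _CONFIG_KEYS]
    if unknown:
        raise ConfigError(f"unknown grid parameter(s): {unknown}")
    if function not in FUNCTIONS:
        raise ConfigError(f"unknown function {function!r}")
    img = read_image(image) if isinstance(image, (str, Path)) else np.asarray(image)
    base = base_params or CalibrationParams()
    keys = sorted(grid)
    rows = []
    metric_name = "total_length" if function == "mycelium" else "n_detected"
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        point = dict(zip(keys, combo))
        row = dict(point)
        try:
            p = base.replace(**point)
            if function == "mycelium":
                res = analyze_mycelium_image(img, p)
                row[metric_name] = res[1].total_length
            elif function == "spore-morphology":
                res = measure_spores(img, p)
                row[metric_name] = len(res.spores)
            else:
                fn = count_spores if function == "count-spores" else count_traps
                res = fn(img, p)
                row[metric_name] = res.n_spores
            if output_dir is not None:
                Path(output_dir).mkdir(parents=True, exist_ok=True)
                tag = "_".join(f"{k}{v}" for k, v in point.items())
                _save_overlay(render_overlay(img, res), Path(output_dir) / f"sweep_{i:03d}_{tag}.png")
        except ValueError as exc:
            row[metric_name] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if output_dir is not None:
        df.to_csv(Path(output_dir) / "sweep.csv", index=False)
    return df
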