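"""Synthetic micrograph generator with exact planted ground truth.

Every quantification pipeline in the package can be exercised without
microscope data: each generator returns a :class:`PlantedScene` holding
the rendered image, the exact rasterized ground-truth mask, the list of
planted objects, and (for mycelium scenes) the generative tree as a
:class:`~mycovision.mycelium.MycelialGraph` whose tips and lengths serve
as the recovery oracle.

The scenes emulate the four acquisition conventions the pipelines expect:

* brightfield spore droplets — dark ellipses on a bright background, with
  optional distractors (thin dark bars mimicking hyphal fragments, tiny
  dots mimicking dust);
* calcofluor-stained spores — the same geometry, bright on dark;
* stained growing mycelium — a random planar tree of smooth curvy
  branches, dilated to a fixed width, bright on dark, with a
  low-frequency illumination gradient and shot-like Gaussian noise;
* trap cultures — dense compact clusters of overlapping rings (adhesive
  networks) over sparse thin hyphae, dark on bright.

All randomness flows through one ``numpy.random.default_rng`` stream per
scene, seeded explicitly: identical seed + parameters reproduce the scene
bit for bit.  What the generator does *not* emulate: optics (PSF, depth
of field), aerial 3-D structure, nematodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.morphology import disk as _disk

from .mycelium import GraphEdge, GraphNode, MycelialGraph

__all__ = [
    "PlantedObject",
    "PlantedScene",
    "SceneGenerationError",
    "generate_spore_scene",
    "generate_mycelium_scene",
    "generate_trap_scene",
    "generate_growth_series",
]

DEFAULT_SHAPE = (1024, 1024)


class SceneGenerationError(RuntimeError):
    """Raised when a feasible scene cannot be packed."""


@dataclass(frozen=True)
class PlantedObject:
    """Descriptor of one planted object.

    ``kind`` is one of ``spore``, ``bar``, ``dust``, ``hypha``, ``trap``,
    ``branch``.  ``axes`` are semi-axes for ellipse-like objects;
    ``path`` is the centerline polyline for curvilinear ones.
    """

    kind: str
    center: Tuple[float, float]
    axes: Tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    path: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class PlantedScene:
    """A rendered synthetic image plus its exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    objects: Tuple[PlantedObject, ...]
    rng_seed: int
    planted_graph: Optional[MycelialGraph] = None

    @property
    def n_planted(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for o in self.objects:
            counts[o.kind] = counts.get(o.kind, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# spore scenes


def generate_spore_scene(
    n_spores: int = 25,
    axis_range: Tuple[float, float] = (6.0, 12.0),
    elongation_range: Tuple[float, float] = (0.0, 0.4),
    polarity: str = "dark_on_bright",
    noise_sigma: float = 0.05,
    n_distractors: int = 0,
    seed: int = 0,
    shape: Tuple[int, int] = DEFAULT_SHAPE,
) -> PlantedScene:
    """Plant non-overlapping ellipses ("spores") plus optional distractors.

    Spores sample a major semi-axis from ``axis_range`` and an elongation
    (1 - minor/major) from ``elongation_range``; distractors alternate
    between thin elongated bars (hyphal fragments, rejected by the
    elongation gate) and tiny dots (dust, rejected by the area gate).
    ``polarity`` selects brightfield (``dark_on_bright``, background 0.85
    / objects ~0.2) or fluorescence (``bright_on_dark``, background 0.08
    / objects ~0.8) rendering.  Placement is rejection-sampled to keep
    objects non-touching; an infeasibly dense request raises
    :class:`SceneGenerationError`.
    """
    if polarity not in ("dark_on_bright", "bright_on_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)

    a_lo, a_hi = axis_range
    mean_area = math.pi * ((a_lo + a_hi) / 2) ** 2
    if n_spores * mean_area > 0.3 * h * w:
        raise SceneGenerationError(
            f"{n_spores} spores of mean area {mean_area:.0f} px^2 exceed 30% of the image"
        )

    margin = a_hi + 4
    placed: List[Tuple[float, float, float]] = []  # (r, c, bounding radius)

    def place(radius: float, tries: int = 400) -> Tuple[float, float]:
        for _ in range(tries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 > (radius + prad + 4) ** 2
                   for pr, pc, prad in placed):
                placed.append((r, c, radius))
                return r, c
        raise SceneGenerationError("could not place object without overlap")

    objects: List[PlantedObject] = []
    truth = np.zeros(shape, dtype=bool)
    fg = np.zeros(shape, dtype=float)
    bg, obj_level = (0.85, 0.2) if polarity == "dark_on_bright" else (0.08, 0.8)

    for _ in range(n_spores):
        a = rng.uniform(a_lo, a_hi)
        e = rng.uniform(*elongation_range)
        b = a * (1.0 - e)
        theta = rng.uniform(0, math.pi)
        r0, c0 = place(a)
        rr, cc = skdraw.ellipse(r0, c0, a, b, shape=shape, rotation=theta)
        truth[rr, cc] = True
        fg[rr, cc] = obj_level + rng.uniform(-0.04, 0.04)
        objects.append(PlantedObject("spore", (r0, c0), (a, b), theta))

    for i in range(n_distractors):
        if i % 2 == 0:  # thin bar: long and narrow, high elongation
            length = rng.uniform(40, 80)
            half_w = 1.5
            theta = rng.uniform(0, math.pi)
            r0, c0 = place(length / 2)
            dr, dc = math.sin(theta), math.cos(theta)
            # rectangle corners
            pr = np.array([-dc, dc]) * half_w
            pc = np.array([dr, -dr]) * half_w
            ends = [(-length / 2), (length / 2)]
            rows = [r0 + ends[0] * dr + pr[0], r0 + ends[0] * dr + pr[1],
                    r0 + ends[1] * dr + pr[1], r0 + ends[1] * dr + pr[0]]
            cols = [c0 + ends[0] * dc + pc[0], c0 + ends[0] * dc + pc[1],
                    c0 + ends[1] * dc + pc[1], c0 + ends[1] * dc + pc[0]]
            rr, cc = skdraw.polygon(rows, cols, shape=shape)
            kind = "bar"
            axes = (length / 2, half_w)
        else:  # dust dot: sub-min-area speck
            rad = rng.uniform(1.0, 1.6)
            r0, c0 = place(rad)
            rr, cc = skdraw.disk((r0, c0), rad, shape=shape)
            kind = "dust"
            axes = (rad, rad)
            theta = 0.0
        truth[rr, cc] = True
        fg[rr, cc] = obj_level + rng.uniform(-0.04, 0.04)
        objects.append(PlantedObject(kind, (r0, c0), axes, theta))

    img = np.full(shape, bg)
    img[truth] = fg[truth]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return PlantedScene(image=img, truth_mask=truth, objects=tuple(objects), rng_seed=seed)


# ---------------------------------------------------------------------------
# mycelium scenes


@dataclass
class _Branch:
    points: List[Tuple[float, float]]
    parent: int  # branch index, -1 for the root branch
    parent_vertex: int  # vertex index on the parent where this branch starts


def _grow_tree(
    rng: np.random.Generator,
    n_branches: int,
    branch_length_range: Tuple[float, float],
    branch_width: int,
    shape: Tuple[int, int],
    step: float = 2.0,
    curliness: float = 0.08,
) -> List[_Branch]:
    """Grow a planar random tree of smooth polyline branches.

    Each branch is a constant-step polyline with small angular jitter;
    children spawn at interior vertices of existing branches at a sampled
    branching angle.  Every drawn branch claims an exclusion corridor of
    ``3 * branch_width + 2`` pixels around its centerline; a candidate
    path is truncated where it enters another branch's corridor (its
    parent's corridor is exempt until the child has left the spawn
    neighborhood) and resampled if it becomes too short.  The planted
    tree is therefore planar with wide clearances, so its topology
    survives rendering, dilation, thinning and moderate noise.
    """
    h, w = shape
    margin = 2 * branch_width + 6
    l_lo, l_hi = branch_length_range
    corr = 3 * branch_width + 2
    # corridor ownership: -1 free, else index of the first claiming branch
    occupancy = np.full(shape, -1, dtype=np.int32)
    corridor = _disk(corr)
    escape_r2 = float((2 * corr) ** 2)

    branches: List[_Branch] = []

    def stamp(points: Sequence[Tuple[float, float]], branch_id: int) -> None:
        mask = np.zeros(shape, dtype=bool)
        pts = np.rint(np.asarray(points)).astype(int)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(r0, c0, r1, c1)
            mask[rr, cc] = True
        grown = ndi.binary_dilation(mask, structure=corridor)
        occupancy[grown & (occupancy == -1)] = branch_id

    def propose(
        start: Tuple[float, float], heading: float, parent_id: int
    ) -> Optional[List[Tuple[float, float]]]:
        length = rng.uniform(l_lo, l_hi)
        n_steps = max(2, int(round(length / step)))
        pts = [start]
        r, c = start
        th = heading
        escaped = False
        for _ in range(n_steps):
            th += rng.normal(0.0, curliness)
            r += step * math.sin(th)
            c += step * math.cos(th)
            if not (margin <= r < h - margin and margin <= c < w - margin):
                break
            if (r - start[0]) ** 2 + (c - start[1]) ** 2 > escape_r2:
                escaped = True
            owner = occupancy[int(round(r)), int(round(c))]
            if owner != -1 and (escaped or owner != parent_id):
                break
            pts.append((r, c))
        if (len(pts) - 1) * step < l_lo * 0.6:
            return None  # too short after truncation
        return pts

    # root branch
    for _ in range(60):
        start = (rng.uniform(0.3 * h, 0.7 * h), rng.uniform(0.3 * w, 0.7 * w))
        pts = propose(start, rng.uniform(0, 2 * math.pi), parent_id=-2)
        if pts is not None:
            branches.append(_Branch(pts, -1, 0))
            stamp(pts, 0)
            break
    if not branches:
        raise SceneGenerationError("could not seed the root branch")

    # junctions stay >= 24 px away from branch ends so terminal hyphal
    # segments are long enough to survive skeleton pruning downstream
    end_gap = int(math.ceil(24.0 / step))
    attempts = 0
    while len(branches) < n_branches and attempts < 60 * n_branches:
        attempts += 1
        pi = int(rng.integers(0, len(branches)))
        parent = branches[pi]
        if len(parent.points) < 2 * end_gap + 4:
            continue
        vi = int(rng.integers(end_gap, len(parent.points) - end_gap))
        p0, p1 = parent.points[vi - 1], parent.points[vi]
        local_heading = math.atan2(p1[0] - p0[0], p1[1] - p0[1])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        heading = local_heading + sign * rng.uniform(0.5, 1.1)
        pts = propose(parent.points[vi], heading, parent_id=pi)
        if pts is None:
            continue
        branches.append(_Branch(pts, pi, vi))
        stamp(pts[1:], len(branches) - 1)
    return branches


def _tree_to_graph(branches: Sequence[_Branch]) -> MycelialGraph:
    """Exact generative graph: nodes at branch ends and spawn junctions."""
    splits: List[set] = [set([0, len(b.points) - 1]) for b in branches]
    for b in branches:
        if b.parent >= 0:
            splits[b.parent].add(b.parent_vertex)

    node_of: Dict[Tuple[float, float], int] = {}
    nodes: List[GraphNode] = []

    def node_id(pt: Tuple[float, float]) -> int:
        if pt not in node_of:
            node_of[pt] = len(nodes)
            nodes.append(GraphNode(len(nodes), float(pt[0]), float(pt[1])))
        return node_of[pt]

    edges: List[GraphEdge] = []
    for bi, b in enumerate(branches):
        idx = sorted(splits[bi])
        for i0, i1 in zip(idx[:-1], idx[1:]):
            seg = np.asarray(b.points[i0 : i1 + 1], dtype=float)
            length = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
            edges.append(GraphEdge(node_id(b.points[i0]), node_id(b.points[i1]), seg, length))
    return MycelialGraph(nodes=tuple(nodes), edges=tuple(edges))


def _render_mycelium(
    branches: Sequence[_Branch],
    shape: Tuple[int, int],
    branch_width: int,
    gradient_amplitude: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    h, w = shape
    centerline = np.zeros(shape, dtype=bool)
    for b in branches:
        pts = np.rint(np.asarray(b.points)).astype(int)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(r0, c0, r1, c1)
            centerline[rr, cc] = True
    truth = ndi.binary_dilation(centerline, structure=_disk(branch_width // 2))

    rows, cols = np.mgrid[0:h, 0:w]
    img = np.full(shape, 0.05)
    if gradient_amplitude > 0:  # low-frequency uneven illumination
        fr, fc = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * math.pi)
        g = 0.5 + 0.5 * np.sin(2 * math.pi * (fr * rows / h + fc * cols / w) + phase)
        img = img + gradient_amplitude * g
    # along-branch intensity variation (uneven dye uptake)
    phase2 = rng.uniform(0, 2 * math.pi)
    var = 0.08 * np.sin(2 * math.pi * (rows + cols) / 64.0 + phase2)
    img[truth] = 0.72 + var[truth]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(img, 0.0, 1.0), truth


def generate_mycelium_scene(
    n_branches: int = 10,
    branch_length_range: Tuple[float, float] = (60.0, 160.0),
    branch_width: int = 3,
    gradient_amplitude: float = 0.1,
    noise_sigma: float = 0.05,
    seed: int = 0,
    shape: Tuple[int, int] = DEFAULT_SHAPE,
) -> PlantedScene:
    """Render a planted mycelial tree, bright on dark.

    The generative model is a random planar tree grown from a root point:
    each branch is a smooth constant-step polyline, children spawn at
    interior vertices at sampled branching angles, and branches keep a
    clearance of about three drawn widths from one another so the planted
    topology is recoverable after dilation, thinning and moderate noise.  The image is
    the centerline tree dilated to ``branch_width`` (odd), with slight
    along-branch intensity variation, a low-frequency illumination
    gradient of the given amplitude, and additive Gaussian noise.

    ``planted_graph`` records the exact tree (nodes, centerline paths,
    Euclidean lengths); its tip count and total length are the recovery
    oracle for the imaging pipeline.
    """
    if branch_width < 1 or branch_width % 2 == 0:
        raise ValueError("branch_width must be a positive odd integer")
    if noise_sigma < 0 or gradient_amplitude < 0:
        raise ValueError("noise_sigma and gradient_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    branches = _grow_tree(rng, n_branches, branch_length_range, branch_width, shape)
    graph = _tree_to_graph(branches)
    img, truth = _render_mycelium(
        branches, shape, branch_width, gradient_amplitude, noise_sigma, rng
    )
    objects = tuple(
        PlantedObject("branch", b.points[0], path=np.asarray(b.points)) for b in branches
    )
    return PlantedScene(
        image=img, truth_mask=truth, objects=objects, rng_seed=seed, planted_graph=graph
    )


def generate_growth_series(
    n_frames: int = 5,
    growth_per_frame: int = 2,
    branch_length_range: Tuple[float, float] = (60.0, 160.0),
    branch_width: int = 3,
    gradient_amplitude: float = 0.1,
    noise_sigma: float = 0.03,
    seed: int = 0,
    shape: Tuple[int, int] = DEFAULT_SHAPE,
) -> List[PlantedScene]:
    """Nested growing-tree series: frame k extends frame k-1's tree.

    One tree of ``n_frames * growth_per_frame`` branches is grown once;
    frame k (0-based) renders its first ``(k + 1) * growth_per_frame``
    branches, so every frame's planted structure is a supergraph of the
    previous frame's and planted total length strictly increases.  Noise
    is drawn independently per frame from a seed-derived stream.
    """
    if n_frames < 1 or growth_per_frame < 1:
        raise ValueError("n_frames and growth_per_frame must be >= 1")
    if branch_width < 1 or branch_width % 2 == 0:
        raise ValueError("branch_width must be a positive odd integer")
    rng = np.random.default_rng(seed)
    total = n_frames * growth_per_frame
    branches = _grow_tree(rng, total, branch_length_range, branch_width, shape)
    scenes: List[PlantedScene] = []
    for k in range(n_frames):
        sub = branches[: min((k + 1) * growth_per_frame, len(branches))]
        frame_rng = np.random.default_rng([seed, k])
        img, truth = _render_mycelium(
            sub, shape, branch_width, gradient_amplitude, noise_sigma, frame_rng
        )
        scenes.append(
            PlantedScene(
                image=img,
                truth_mask=truth,
                objects=tuple(
                    PlantedObject("branch", b.points[0], path=np.asarray(b.points)) for b in sub
                ),
                rng_seed=seed,
                planted_graph=_tree_to_graph(sub),
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# trap scenes


def generate_trap_scene(
    n_traps: int = 10,
    background_hyphae: int = 12,
    noise_sigma: float = 0.03,
    seed: int = 0,
    shape: Tuple[int, int] = DEFAULT_SHAPE,
) -> PlantedScene:
    """Dense ring-cluster "traps" over sparse thin hyphae, dark on bright.

    Each trap is a connected cluster of 6-10 overlapping annuli whose
    centers sit about one ring-radius from the trap center (so every ring
    passes near it and the union is connected): a compact, low-elongation
    blob with area far above a single hypha cross-section, emulating the
    adhesive networks of nematode-trapping fungi.  Hyphae are rendered as
    faint thin polylines that stay above the weak threshold of a
    trap-scale calibration, so only the planted clusters are counted.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    bg = 0.85
    img = np.full(shape, bg)
    truth = np.zeros(shape, dtype=bool)
    objects: List[PlantedObject] = []

    # sparse background hyphae: gentle random walks spanning the frame
    hypha_mask = np.zeros(shape, dtype=bool)
    for _ in range(background_hyphae):
        r = rng.uniform(10, h - 10)
        c = rng.uniform(10, w - 10)
        th = rng.uniform(0, 2 * math.pi)
        pts = [(r, c)]
        for _ in range(400):
            th += rng.normal(0.0, 0.1)
            r += 2.5 * math.sin(th)
            c += 2.5 * math.cos(th)
            if not (2 <= r < h - 2 and 2 <= c < w - 2):
                break
            pts.append((r, c))
        ip = np.rint(np.asarray(pts)).astype(int)
        for (r0, c0), (r1, c1) in zip(ip[:-1], ip[1:]):
            rr, cc = skdraw.line(r0, c0, r1, c1)
            hypha_mask[rr, cc] = True
        objects.append(PlantedObject("hypha", pts[0], path=np.asarray(pts)))
    hypha_mask = ndi.binary_dilation(hypha_mask, structure=_disk(1))
    img[hypha_mask] = 0.55
    truth |= hypha_mask

    # trap clusters, non-overlapping
    centers: List[Tuple[float, float]] = []
    cluster_extent = 30.0
    for _ in range(n_traps):
        ok = False
        for _ in range(400):
            r0 = rng.uniform(cluster_extent + 5, h - cluster_extent - 5)
            c0 = rng.uniform(cluster_extent + 5, w - cluster_extent - 5)
            if all((r0 - pr) ** 2 + (c0 - pc) ** 2 > (2.2 * cluster_extent) ** 2
                   for pr, pc in centers):
                ok = True
                break
        if not ok:
            raise SceneGenerationError("could not place trap cluster without overlap")
        centers.append((r0, c0))
        cluster = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(6, 11))):
            ring_r = rng.uniform(6.0, 9.0)
            # ring center one radius away: the ring passes near the trap
            # center, keeping the cluster union connected
            ang = rng.uniform(0, 2 * math.pi)
            d = ring_r + rng.uniform(-1.0, 1.0)
            rc = (r0 + d * math.sin(ang), c0 + d * math.cos(ang))
            rr, cc = skdraw.disk(rc, ring_r + 1.5, shape=shape)
            outer = np.zeros(shape, dtype=bool)
            outer[rr, cc] = True
            rr, cc = skdraw.disk(rc, max(ring_r - 1.5, 1.0), shape=shape)
            outer[rr, cc] = False
            cluster |= outer
        img[cluster] = 0.2 + rng.uniform(-0.03, 0.03)
        truth |= cluster
        objects.append(PlantedObject("trap", (r0, c0), (cluster_extent, cluster_extent)))

    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return PlantedScene(image=img, truth_mask=truth, objects=tuple(objects), rng_seed=seed)
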