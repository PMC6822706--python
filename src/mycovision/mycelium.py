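"""Mycelium characterization: skeleton -> mathematical graph -> metrics.

A cleaned, 1-pixel-wide skeleton of the mycelium is converted into a graph
in which nodes are hyphal tips (degree 1) and junctions (degree >= 3) and
edges are the hyphal segments connecting them, each carrying its pixel
path.  From the graph we compute the measures used to describe mycelial
growth:

* total length — the sum of all edge lengths (orthogonal steps count 1,
  diagonal steps sqrt(2), so diagonal hyphae are not overestimated);
* number of hyphal tips — nodes connected to exactly one edge (isolated
  degree-0 nodes, e.g. a germinating spore reduced to a dot, are not
  tips);
* area covered — the convex hull of the node coordinates (shoelace area).

The full image pipeline (``analyze_mycelium_image``) is: Gaussian
background subtraction, hysteresis binarization, 3x3 dilation (closes
out-of-focus gaps), thinning, deletion/pruning of small skeleton pieces,
optional mask subtraction, then graph extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .core import (
    CalibrationParams,
    as_binary,
    as_gray,
    clean_skeleton,
    dilate_3x3,
    gaussian_background_subtract,
    hysteresis_binarize,
    subtract_mask,
    thin_skeleton,
    _neighbor_count,
    _STRUCT8,
    _NBR_OFFSETS,
)

__all__ = [
    "GraphNode",
    "GraphEdge",
    "MycelialGraph",
    "MyceliumMetrics",
    "skeleton_to_graph",
    "graph_metrics",
    "mycelium_binary",
    "analyze_mycelium_image",
    "analyze_time_series",
    "polyline_length",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class GraphNode:
    """A hyphal tip or junction, at (row, col) pixel coordinates.

    Junction clusters (adjacent degree->=3 skeleton pixels) are merged into
    one node at their centroid, so coordinates may be fractional.
    """

    id: int
    row: float
    col: float


@dataclass(frozen=True)
class GraphEdge:
    """A hyphal segment between nodes ``u`` and ``v`` (u == v: self-loop).

    ``path`` is the ordered pixel polyline; ``length_px`` its step length.
    """

    u: int
    v: int
    path: np.ndarray = field(repr=False, compare=False)
    length_px: float = 0.0


@dataclass(frozen=True)
class MycelialGraph:
    """Graph representation of a mycelium skeleton."""

    nodes: Tuple[GraphNode, ...]
    edges: Tuple[GraphEdge, ...]

    def degrees(self) -> Dict[int, int]:
        """Edge-incidence count per node (self-loops count twice)."""
        deg = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    @property
    def n_tips(self) -> int:
        return sum(1 for d in self.degrees().values() if d == 1)

    def node_coords(self) -> np.ndarray:
        return np.array([(n.row, n.col) for n in self.nodes], dtype=float).reshape(-1, 2)

    def total_length_px(self) -> float:
        return float(sum(e.length_px for e in self.edges))

    def to_networkx(self):
        """Export as a networkx MultiGraph (edge attr ``length_px``)."""
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, row=n.row, col=n.col)
        for e in self.edges:
            g.add_edge(e.u, e.v, length_px=e.length_px)
        return g


@dataclass(frozen=True)
class MyceliumMetrics:
    """Scalar mycelial measures (physical units if a scale was applied)."""

    total_length: float
    n_tips: int
    n_edges: int
    hull_area: float
    hull_vertices: Tuple[Tuple[float, float], ...] = ()


def polyline_length(path: np.ndarray) -> float:
    """Length of a pixel path: 1 per orthogonal step, sqrt(2) per diagonal."""
    p = np.asarray(path, dtype=float)
    if len(p) < 2:
        return 0.0
    steps = np.abs(np.diff(p, axis=0))
    diag = (steps[:, 0] > 0) & (steps[:, 1] > 0)
    return float(np.sum(np.where(diag, _SQRT2, 1.0)))


def skeleton_to_graph(skel: np.ndarray) -> MycelialGraph:
    """Convert a thinned skeleton into a node/edge graph.

    Skeleton pixels with a number of 8-neighbors different from 2 become
    node pixels: degree-1 pixels are tips, degree->=3 pixels are junction
    pixels (adjacent junction pixels merge into one node at their
    centroid), degree-0 pixels are isolated nodes.  Maximal chains of
    degree-2 pixels between node pixels become edges carrying their pixel
    path; a closed loop containing no node pixel becomes a single node
    with a self-loop edge.

    The input must be 1-pixel wide (output of :func:`thin_skeleton`);
    thick blobs produce an undefined graph structure.
    """
    sk = as_binary(skel)
    h, w = sk.shape
    if not sk.any():
        return MycelialGraph(nodes=(), edges=())
    deg = _neighbor_count(sk)

    junction_mask = sk & (deg >= 3)
    tip_mask = sk & (deg == 1)
    isolated_mask = sk & (deg == 0)

    pixel_node: Dict[Tuple[int, int], int] = {}
    nodes: List[GraphNode] = []

    jl, nj = ndi.label(junction_mask, structure=_STRUCT8)
    for lab in range(1, nj + 1):
        coords = np.argwhere(jl == lab)
        nid = len(nodes)
        nodes.append(GraphNode(nid, float(coords[:, 0].mean()), float(coords[:, 1].mean())))
        for r, c in coords:
            pixel_node[(int(r), int(c))] = nid
    for mask in (tip_mask, isolated_mask):
        for r, c in np.argwhere(mask):
            nid = len(nodes)
            nodes.append(GraphNode(nid, float(r), float(c)))
            pixel_node[(int(r), int(c))] = nid

    edges: List[GraphEdge] = []
    visited = np.zeros_like(sk)  # consumed degree-2 chain pixels
    direct: set = set()  # dedupe zero-interior edges between adjacent node pixels

    def neighbors(p):
        r0, c0 = p
        for dr, dc in _NBR_OFFSETS:
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w and sk[r, c]:
                yield (r, c)

    node_pixels = sorted(pixel_node.keys())
    for p in node_pixels:
        for q in neighbors(p):
            if q in pixel_node:
                if pixel_node[q] == pixel_node[p]:
                    continue  # same junction cluster
                key = (min(p, q), max(p, q))
                if key in direct:
                    continue
                direct.add(key)
                path = np.array([p, q])
                edges.append(
                    GraphEdge(pixel_node[p], pixel_node[q], path, polyline_length(path))
                )
            elif not visited[q]:
                # trace a degree-2 chain until the next node pixel
                path = [p, q]
                visited[q] = True
                prev, cur = p, q
                while True:
                    nxts = [n for n in neighbors(cur) if n != prev]
                    # on staircases prev may be 8-adjacent to the successor;
                    # drop candidates already in the path
                    nxts = [n for n in nxts if not visited[n] or n in pixel_node]
                    if not nxts:
                        break  # dead end (shouldn't happen on clean skeletons)
                    nxt = nxts[0]
                    path.append(nxt)
                    if nxt in pixel_node:
                        break
                    visited[nxt] = True
                    prev, cur = cur, nxt
                end = path[-1]
                if end in pixel_node:
                    arr = np.array(path)
                    edges.append(
                        GraphEdge(pixel_node[p], pixel_node[end], arr, polyline_length(arr))
                    )

    # leftover degree-2 pixels form pure cycles: one node + self-loop each
    leftover = sk & (deg == 2) & ~visited.astype(bool)
    ll, nl = ndi.label(leftover, structure=_STRUCT8)
    for lab in range(1, nl + 1):
        coords = [tuple(int(x) for x in rc) for rc in np.argwhere(ll == lab)]
        start = coords[0]
        nid = len(nodes)
        nodes.append(GraphNode(nid, float(start[0]), float(start[1])))
        nbrs = [n for n in neighbors(start) if ll[n] == lab]
        path = [start]
        if nbrs:
            prev, cur = start, nbrs[0]
            path.append(cur)
            while cur != start:
                step = [n for n in neighbors(cur) if n != prev and ll[n] == lab or n == start]
                step = [n for n in step if n != prev]
                if not step:
                    break
                prev, cur = cur, step[0]
                path.append(cur)
        arr = np.array(path)
        edges.append(GraphEdge(nid, nid, arr, polyline_length(arr)))

    return MycelialGraph(nodes=tuple(nodes), edges=tuple(edges))


def _hull(coords: np.ndarray) -> Tuple[float, Tuple[Tuple[float, float], ...]]:
    """Convex-hull area of node coordinates (0 for < 3 non-collinear)."""
    if len(coords) < 3:
        return 0.0, ()
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return 0.0, ()  # collinear or otherwise degenerate
    verts = tuple((float(r), float(c)) for r, c in coords[hull.vertices])
    return float(hull.volume), verts  # 2-D "volume" is the polygon area


def graph_metrics(g: MycelialGraph, scale: float = 1.0) -> MyceliumMetrics:
    """Compute the mycelial measures from a graph.

    ``total_length`` = sum of edge lengths x scale; ``n_tips`` = number of
    degree-1 nodes; ``hull_area`` = convex-hull (shoelace) area of the
    node coordinates x scale^2, 0 when fewer than 3 non-collinear nodes.
    """
    area, verts = _hull(g.node_coords())
    return MyceliumMetrics(
        total_length=g.total_length_px() * scale,
        n_tips=g.n_tips,
        n_edges=len(g.edges),
        hull_area=area * scale * scale,
        hull_vertices=verts,
    )


def mycelium_binary(
    img: np.ndarray,
    params: CalibrationParams,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Segmentation stage of the mycelium pipeline (binary image).

    Gaussian background subtraction, hysteresis binarization, removal of
    components smaller than ``min_hyphae`` pixels, optional mask
    subtraction.  This pre-skeleton binary is the image compared against
    ground truth in segmentation-accuracy evaluation.
    """
    from skimage.morphology import remove_small_objects

    flat = gaussian_background_subtract(img, params.gaussian_radius)
    binary = hysteresis_binarize(flat, params.b1, params.b2)
    if params.min_hyphae > 0:
        binary = remove_small_objects(binary, max_size=params.min_hyphae - 1, connectivity=2)
    if mask is not None:
        binary = subtract_mask(binary, mask)
    return binary


def analyze_mycelium_image(
    img: np.ndarray,
    params: CalibrationParams,
    mask: Optional[np.ndarray] = None,
) -> Tuple[MycelialGraph, MyceliumMetrics]:
    """Full mycelium pipeline for one fluorescence image (bright on dark).

    Background subtraction (radius ``gaussian_radius``), hysteresis
    binarization, 3x3 dilation, thinning, skeleton cleaning
    (``min_hyphae``), optional mask subtraction, graph extraction and
    metrics (scaled by ``params.scale``).
    """
    a = as_gray(img)
    if mask is not None:
        mask = as_binary(mask)
        if mask.shape != a.shape:
            raise ValueError(f"mask shape {mask.shape} does not match image {a.shape}")
    flat = gaussian_background_subtract(a, params.gaussian_radius)
    binary = hysteresis_binarize(flat, params.b1, params.b2)
    binary = dilate_3x3(binary)
    skel = thin_skeleton(binary)
    skel = clean_skeleton(skel, params.min_hyphae)
    if mask is not None:
        skel = subtract_mask(skel, mask)
    graph = skeleton_to_graph(skel)
    return graph, graph_metrics(graph, scale=params.scale)


def analyze_time_series(
    imgs: Sequence[np.ndarray],
    params: CalibrationParams,
    mask: Optional[np.ndarray] = None,
) -> List[Tuple[int, MyceliumMetrics]]:
    """Apply the mycelium pipeline to an ordered series of frames.

    All frames must share a shape; identical parameters are applied to
    every frame, and metrics are returned as (timepoint, metrics) in
    input order (timepoints are the 0-based frame indices).
    """
    imgs = list(imgs)
    if not imgs:
        return []
    shape = np.asarray(imgs[0]).shape
    for i, im in enumerate(imgs):
        if np.asarray(im).shape != shape:
            raise ValueError(f"frame {i} shape {np.asarray(im).shape} != {shape}")
    out: List[Tuple[int, MyceliumMetrics]] = []
    for t, im in enumerate(imgs):
        _, metrics = analyze_mycelium_image(im, params, mask=mask)
        out.append((t, metrics))
    return out
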