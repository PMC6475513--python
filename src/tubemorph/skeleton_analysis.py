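"""Skeletonization and topology analysis of the vessel mask.

The binary vessel mask is reduced to a one-pixel-wide medial skeleton by
iterative morphological thinning (hit-and-miss transform with the standard
eight rotated template pairs, iterated to a fixpoint).  Thinning is
homotopic: it never changes the number of 8-connected components.

Topology is then read off the skeleton raster:

* *endpoints* — skeleton pixels with exactly one 8-neighbour;
* *junction pixels* — pixels from which >= 3 distinct branches leave.  The
  branch count of a pixel is the number of circular runs of foreground in
  its 8-neighbour ring, so two neighbours that are themselves 8-adjacent
  count as a single branch (this excludes spurious corner configurations);
* *spur pruning* — endpoint-terminated ramifications shorter than the spur
  length are deleted (up to, but not including, the junction pixel),
  iterated to a fixpoint.  ``spur_length = 0`` disables pruning entirely;
* *junction merging* — junction pixels closer than the merge distance are
  single-linkage clustered and replaced by their rounded centroid.
  ``merge_distance = 0`` disables merging;
* *classification* — a merged junction of degree 3 is a *branching* point;
  degree >= 4 is a *crossing* point (two vessels overlapping in the 2-D
  projection).  The degree of a merged junction is the number of distinct
  skeleton branches leaving the cluster's dilated footprint (dilation
  radius = merge_distance / 2, shrunk if it would swallow every branch).

Geodesic skeleton length sums 1 per orthogonal and sqrt(2) per diagonal
8-neighbour adjacency, each adjacency counted once; ``pixel_count`` mode
simply counts skeleton pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .detect import STRUCT8
from .preprocess import ParameterError

logger = logging.getLogger(__name__)

#: circular order of the 8-neighbour offsets (N, NE, E, SE, S, SW, W, NW)
RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _thinning_templates() -> list[np.ndarray]:
    """The eight 3x3 template pairs (1=fg required, 0=bg required, 2=any)."""
    edge = np.array([[0, 0, 0], [2, 1, 2], [1, 1, 1]])
    corner = np.array([[2, 0, 0], [1, 1, 0], [2, 1, 2]])
    out = []
    for base in (edge, corner):
        t = base
        for _ in range(4):
            out.append(t.copy())
            t = np.rot90(t)
    return out


_TEMPLATES = _thinning_templates()


@dataclass
class AnalysisParams:
    """Tunable parameters of the skeleton-analysis stage.

    spur_length: ramifications shorter than this many pixels (geodesic,
        measured from the endpoint up to and including the step onto the
        junction) are pruned; 0 disables pruning.  Default 15 (whole-mount
        presets); in vitro tube formation uses 30.
    merge_distance: junction pixels within this Euclidean distance are
        merged; 0 disables merging.  Default 10.
    """

    spur_length: float = 15.0
    merge_distance: float = 10.0
    length_mode: str = "geodesic"
    remove_free_segments: bool = True

    def __post_init__(self) -> None:
        self.spur_length = float(self.spur_length)
        self.merge_distance = float(self.merge_distance)
        if self.spur_length < 0 or self.merge_distance < 0:
            raise ParameterError("spur_length and merge_distance must be >= 0")
        if self.length_mode not in ("geodesic", "pixel_count"):
            raise ParameterError(f"unknown length_mode {self.length_mode!r}")


@dataclass
class Skeleton:
    """One-pixel-wide skeleton raster (8-connected)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    def to_graph(self) -> nx.Graph:
        """Skeleton as a graph: nodes = endpoint/junction pixels, edges =
        branches with geodesic length attribute ``length``."""
        return _skeleton_graph(self.pixels)


@dataclass(frozen=True)
class JunctionPoint:
    row: int
    col: int
    degree: int
    kind: str = ""  # "branching" | "crossing" once classified


@dataclass
class JunctionSet:
    points: list[JunctionPoint]
    merge_radius: float

    @property
    def n_branching(self) -> int:
        return sum(1 for p in self.points if p.kind == "branching")

    @property
    def n_crossing(self) -> int:
        return sum(1 for p in self.points if p.kind == "crossing")


@dataclass
class MorphometricsRecord:
    """Per-image morphometric read-outs, in pixel and physical units."""

    filename: str
    vessel_area_px2: float
    skeleton_length_px: float
    mean_width_px: float  # area / length; NaN when length is 0
    n_branch_points: int
    n_crossing_points: int
    threshold_used: float = float("nan")
    pixel_size_um: float | None = None

    def as_dict(self) -> dict:
        s = self.pixel_size_um
        return {
            "filename": self.filename,
            "vessel_area_px2": self.vessel_area_px2,
            "skeleton_length_px": self.skeleton_length_px,
            "mean_width_px": self.mean_width_px,
            "n_branch_points": self.n_branch_points,
            "n_crossing_points": self.n_crossing_points,
            "threshold_used": self.threshold_used,
            "vessel_area_um2": self.vessel_area_px2 * s * s if s else float("nan"),
            "skeleton_length_um": self.skeleton_length_px * s if s else float("nan"),
            "mean_width_um": self.mean_width_px * s if s else float("nan"),
            "pixel_size_um": s if s else float("nan"),
        }


# ---------------------------------------------------------------------------
# thinning

def skeletonize(mask: np.ndarray) -> Skeleton:
    """Iterative hit-and-miss thinning to a 1-px-wide homotopic skeleton.

    The eight template pairs are applied sequentially within each pass;
    passes repeat until no pixel changes.  An empty mask yields an empty
    skeleton.
    """
    m = np.asarray(mask, dtype=bool).copy()
    if not m.any():
        logger.info("skeletonize: empty mask")
        return Skeleton(m)
    while True:
        changed = False
        for t in _TEMPLATES:
            hit = ndimage.binary_hit_or_miss(
                m, structure1=(t == 1), structure2=(t == 0)
            )
            if hit.any():
                m &= ~hit
                changed = True
        if not changed:
            break
    _remove_staircase_residues(m)
    return Skeleton(m)


def _remove_staircase_residues(m: np.ndarray) -> None:
    """Delete remaining simple pixels the template pass cannot reach.

    Template thinning can leave corner pixels whose neighbours form a single
    connected arc of the 8-ring (e.g. tiny triangles at blunt tube ends).
    Such a pixel is not an endpoint, and removing it provably preserves
    connectivity, so the skeleton is not thin until they are gone.  Deleted
    sequentially in raster order until stable (in place).
    """
    while True:
        runs = branch_count(m)
        ncnt = neighbour_count(m)
        cand = np.argwhere(m & (runs == 1) & (ncnt >= 2))
        if len(cand) == 0:
            return
        deleted = False
        for r, c in cand:
            # re-check against the current state (sequential deletion)
            ring = [
                m[r + dr, c + dc]
                if 0 <= r + dr < m.shape[0] and 0 <= c + dc < m.shape[1]
                else False
                for dr, dc in RING
            ]
            n_runs = sum(
                1 for i in range(8) if ring[i] and not ring[(i + 1) % 8]
            )
            if sum(ring) >= 2 and n_runs == 1:
                m[r, c] = False
                deleted = True
        if not deleted:
            return


# ---------------------------------------------------------------------------
# raster topology

def neighbour_count(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbours of each pixel within the skeleton."""
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(np.int8), kernel, mode="constant").astype(int)


def branch_count(skel: np.ndarray) -> np.ndarray:
    """Distinct branches leaving each pixel: circular foreground runs of the
    8-neighbour ring (adjacent neighbours collapse into one run)."""
    skel = np.asarray(skel, bool)
    padded = np.pad(skel, 1)
    ring = np.stack(
        [padded[1 + dr : 1 + dr + skel.shape[0], 1 + dc : 1 + dc + skel.shape[1]]
         for dr, dc in RING]
    )
    nxt = np.roll(ring, -1, axis=0)
    return (ring & ~nxt).sum(axis=0)


def find_endpoints(skel: Skeleton | np.ndarray) -> list[tuple[int, int]]:
    """Skeleton pixels with exactly one 8-neighbour."""
    px = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    pts = np.argwhere(px & (neighbour_count(px) == 1))
    return [tuple(p) for p in pts]


def find_branchpoints(skel: Skeleton | np.ndarray) -> list[tuple[int, int]]:
    """Raw junction pixels: >= 3 distinct branches leave the pixel."""
    px = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    pts = np.argwhere(px & (branch_count(px) >= 3))
    return [tuple(p) for p in pts]


def _neighbours(px: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    H, W = px.shape
    out = []
    for dr, dc in RING:
        rr, cc = r + dr, c + dc
        if 0 <= rr < H and 0 <= cc < W and px[rr, cc]:
            out.append((rr, cc))
    return out


def _step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _trace_spur(px: np.ndarray, runs: np.ndarray, start: tuple[int, int]):
    """Walk from endpoint ``start`` to the first junction pixel or the other
    end.  Returns (path pixels excluding any junction, geodesic length
    including the step onto the junction, kind in {'junction', 'free'})."""
    path = [start]
    visited = {start}
    length = 0.0
    cur = start
    while True:
        nbrs = [n for n in _neighbours(px, *cur) if n not in visited]
        if not nbrs:
            return path, length, "free"
        # a junction neighbour ends the spur (prefer it over diagonal
        # shortcuts onto a neighbouring arm)
        jn = [n for n in nbrs if runs[n] >= 3]
        if jn:
            return path, length + _step(cur, jn[0]), "junction"
        nxt = nbrs[0]  # deterministic tie-break: first in ring order
        length += _step(cur, nxt)
        if len([n for n in _neighbours(px, *nxt) if n != cur]) > 1:
            return path, length, "junction"
        path.append(nxt)
        visited.add(nxt)
        cur = nxt


def prune_spurs(
    skel: Skeleton,
    spur_length: float,
    remove_free_segments: bool = True,
) -> Skeleton:
    """Remove endpoint-terminated ramifications shorter than ``spur_length``.

    All qualifying spurs found in a pass are deleted together (up to, not
    including, their junction pixel); passes repeat until no spur qualifies.
    ``spur_length = 0`` is an exact no-op.  Isolated free segments shorter
    than ``spur_length`` are removed entirely when ``remove_free_segments``.
    """
    if spur_length <= 0:
        return Skeleton(skel.pixels.copy())
    px = skel.pixels.copy()
    while True:
        runs = branch_count(px)
        to_delete: set[tuple[int, int]] = set()
        for ep in find_endpoints(px):
            if ep in to_delete:
                continue
            path, length, kind = _trace_spur(px, runs, ep)
            if kind == "junction" and length < spur_length:
                to_delete.update(path)
            elif kind == "free" and remove_free_segments and length < spur_length:
                to_delete.update(path)
        if not to_delete:
            return Skeleton(px)
        for p in to_delete:
            px[p] = False
        # deleting arms can expose corner residues at former junctions;
        # remove them so the next pass sees a thin skeleton
        _remove_staircase_residues(px)


# ---------------------------------------------------------------------------
# junctions

def merge_branchpoints(
    raw: list[tuple[int, int]],
    merge_distance: float,
    skel: Skeleton | np.ndarray | None = None,
) -> JunctionSet:
    """Single-linkage merge of junction pixels within ``merge_distance``.

    Each cluster is replaced by the rounded arithmetic mean of its member
    coordinates.  ``merge_distance = 0`` keeps every raw pixel.  When the
    skeleton is given, merged degrees are computed from it (else from the
    cluster size alone they would be meaningless, so degree 3 is assumed).
    """
    if merge_distance < 0:
        raise ParameterError("merge_distance must be >= 0")
    px = None
    if skel is not None:
        px = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    pts = np.asarray(raw, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return JunctionSet([], merge_distance)
    if merge_distance == 0:
        clusters = [[i] for i in range(len(pts))]
    else:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(merge_distance, output_type="ndarray")
        parent = list(range(len(pts)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[rb] = ra
        groups: dict[int, list[int]] = {}
        for i in range(len(pts)):
            groups.setdefault(find(i), []).append(i)
        clusters = sorted(groups.values(), key=lambda g: tuple(pts[g[0]]))
    points = []
    for members in clusters:
        centroid = pts[members].mean(axis=0)
        r, c = int(np.round(centroid[0])), int(np.round(centroid[1]))
        if px is not None:
            deg = _cluster_degree(px, pts[members].astype(int), merge_distance / 2.0)
        else:
            deg = 3
        points.append(JunctionPoint(r, c, deg))
    return JunctionSet(points, merge_distance)


def _cluster_degree(
    px: np.ndarray, members: np.ndarray, radius: float
) -> int:
    """Distinct skeleton branches leaving the cluster's dilated footprint.

    The footprint is every skeleton pixel within ``radius`` of a member
    pixel; the degree is the number of 8-connected components of the
    remaining skeleton that touch the footprint.  If the radius swallows
    every branch the radius is halved until a degree >= 3 emerges (at
    radius < 1 the maximum member branch count is used).
    """
    runs = branch_count(px)
    while True:
        if radius < 1.0:
            return int(max(runs[r, c] for r, c in members))
        dist = np.full(px.shape, np.inf)
        coords = np.argwhere(px)
        tree = cKDTree(members)
        d, _ = tree.query(coords)
        dist[tuple(coords.T)] = d
        footprint = px & (dist <= radius)
        rest = px & ~footprint
        labels, n = ndimage.label(rest, structure=STRUCT8)
        grown = ndimage.binary_dilation(footprint, structure=STRUCT8)
        touching = np.unique(labels[grown & rest])
        deg = int(len(touching[touching > 0]))
        if deg >= 3:
            return deg
        radius /= 2.0


def classify_junctions(skel: Skeleton, junctions: JunctionSet) -> JunctionSet:
    """Label each merged junction: degree 3 -> branching, >= 4 -> crossing."""
    out = []
    for p in junctions.points:
        if p.degree < 3:
            raise ValueError(
                f"junction at ({p.row},{p.col}) has degree {p.degree} < 3"
            )
        kind = "branching" if p.degree == 3 else "crossing"
        out.append(JunctionPoint(p.row, p.col, p.degree, kind))
    return JunctionSet(out, junctions.merge_radius)


# ---------------------------------------------------------------------------
# measurements

def skeleton_length(skel: Skeleton | np.ndarray, mode: str = "geodesic") -> float:
    """Total skeleton length in pixels.

    ``geodesic``: 1 per orthogonal, sqrt(2) per diagonal 8-adjacency, each
    adjacency counted once.  ``pixel_count``: number of skeleton pixels.
    """
    px = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    if mode == "pixel_count":
        return float(px.sum())
    if mode != "geodesic":
        raise ParameterError(f"unknown length mode {mode!r}")
    length = 0.0
    length += float(np.sum(px[:, :-1] & px[:, 1:]))
    length += float(np.sum(px[:-1, :] & px[1:, :]))
    length += math.sqrt(2.0) * float(np.sum(px[:-1, :-1] & px[1:, 1:]))
    length += math.sqrt(2.0) * float(np.sum(px[:-1, 1:] & px[1:, :-1]))
    return length


def compute_morphometrics(
    mask: np.ndarray,
    skel: Skeleton,
    junctions: JunctionSet,
    pixel_size_um: float | None = None,
    filename: str = "",
    threshold_used: float = float("nan"),
    length_mode: str = "geodesic",
) -> MorphometricsRecord:
    """The four morphometric read-outs for one image.

    area = mask foreground pixel count; length per :func:`skeleton_length`;
    mean width = area / length (NaN for an empty skeleton); branch and
    crossing counts from the classified junction set.
    """
    area = float(np.asarray(mask, bool).sum())
    length = skeleton_length(skel, length_mode)
    width = area / length if length > 0 else float("nan")
    return MorphometricsRecord(
        filename=filename,
        vessel_area_px2=area,
        skeleton_length_px=length,
        mean_width_px=width,
        n_branch_points=junctions.n_branching,
        n_crossing_points=junctions.n_crossing,
        threshold_used=threshold_used,
        pixel_size_um=pixel_size_um,
    )


def analyse_mask(
    mask: np.ndarray,
    params: AnalysisParams,
    pixel_size_um: float | None = None,
    filename: str = "",
    threshold_used: float = float("nan"),
) -> tuple[MorphometricsRecord, Skeleton, JunctionSet]:
    """Full tube-analysis stage: thin, prune, merge, classify, measure."""
    skel = skeletonize(mask)
    skel = prune_spurs(skel, params.spur_length, params.remove_free_segments)
    raw = find_branchpoints(skel)
    junctions = merge_branchpoints(raw, params.merge_distance, skel)
    junctions = classify_junctions(skel, junctions)
    record = compute_morphometrics(
        mask, skel, junctions, pixel_size_um, filename, threshold_used,
        params.length_mode,
    )
    return record, skel, junctions


# ---------------------------------------------------------------------------
# graph view

def _skeleton_graph(px: np.ndarray) -> nx.MultiGraph:
    g = nx.MultiGraph()
    runs = branch_count(px)
    ncount = neighbour_count(px)
    nodes = {tuple(p) for p in np.argwhere(px & ((ncount == 1) | (runs >= 3)))}
    # isolated pixels and pure cycles have no endpoint/junction: anchor one px
    labels, n = ndimage.label(px, structure=STRUCT8)
    for i in range(1, n + 1):
        comp = np.argwhere(labels == i)
        if not any(tuple(p) in nodes for p in comp):
            nodes.add(tuple(comp[0]))
    for node in nodes:
        g.add_node(node, kind="junction" if runs[node] >= 3 else "endpoint")
    visited_edges: set[frozenset] = set()
    for node in sorted(nodes):
        for nb in _neighbours(px, *node):
            # walk this branch until the next node
            path = [node, nb]
            length = _step(node, nb)
            seen = {node, nb}
            cur = nb
            while cur not in nodes:
                options = [
                    q for q in _neighbours(px, *cur)
                    if q not in seen or (q in nodes and q != path[-2])
                ]
                if not options:
                    break
                # the true continuation is not 8-adjacent to the pixel
                # before last (that would be a diagonal shortcut between
                # arms); fall back for genuine corners
                prev2 = path[-2]
                straight = [
                    q for q in options
                    if max(abs(q[0] - prev2[0]), abs(q[1] - prev2[1])) > 1
                ]
                pool = straight or options
                node_opts = [q for q in pool if q in nodes]
                nxt = node_opts[0] if node_opts else pool[0]
                length += _step(cur, nxt)
                path.append(nxt)
                seen.add(nxt)
                cur = nxt
            key = frozenset(path)
            if key in visited_edges:
                continue
            if cur == node:
                # a cycle traced in both directions may differ only by
                # corner pixels; keep a single representative
                dup = any(
                    len(key & other) / len(key | other) > 0.8
                    for other in visited_edges
                    if node in other
                )
                if dup:
                    continue
            visited_edges.add(key)
            if cur in nodes:
                g.add_edge(node, cur, length=length, path=path)
    return g
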