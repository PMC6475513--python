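"""Synthetic vascular networks with exact ground-truth morphometrics.

The generator grows branching, self-avoiding random walks ("vessels") on a
2-D canvas, optionally injects explicit vessel crossings, and rasterises the
result as a bright-on-dark fluorescence-like image with controllable
degradations (vignetting, heterogeneous staining along tubes, additive
noise).  Because every branch and crossing event is recorded at generation
time — and the geometry is validated to be free of *accidental* contacts —
the true total centerline length, vessel area and junction counts are known
exactly, which makes the full measurement chain testable end to end.

Geometry model
--------------
Each vessel is a polyline of fixed step length with Gaussian heading noise
and a constant width drawn per vessel.  A branching event spawns a child
walker at the parent's current position; the event only counts as a true
branch point if all three arms grow long enough to survive spur pruning
(otherwise the child is erased and the event discarded).  Self-avoidance is
enforced during growth by a forbidden-zone grid (no new centerline point may
come closer than a clearance distance to previously laid vessels) and
checked again after generation by exact pairwise centerline distances; a
network that still contains an accidental near-contact is regenerated from
a derived seed.  Consequently any junction in the rasterised mask
corresponds to exactly one recorded event.

Rendering
---------
Tubes are flat-topped intensity plateaus (peak signal 0.8 over the
background) blurred by a Gaussian optical PSF, so the profile crosses half
maximum exactly at the true tube boundary and thresholding the clean render
halfway up the profile recovers the true area up to discretisation.  Degradations are
applied in order: vignetting (an additive radial illumination field
``a * (1 - rho^2)``, brightest at the image centre and zero at the
corners, so image intensity decreases towards the edges), staining
heterogeneity (a smooth multiplicative modulation along each tube's axis),
then additive Gaussian sensor noise; the result is clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import GrayImage
from .skeleton_analysis import MorphometricsRecord

#: minimum centerline clearance (px) enforced between unrelated vessels
CLEARANCE = 17.0
#: radius (px) around a legitimate contact point that is exempt from
#: the clearance check (covers the junction neighbourhood)
CONTACT_EXEMPT = 40.0
#: tube peak signal over background
PEAK = 0.8
#: walker-id offset for injected crossing vessels in the forbidden grid
_X_ID = 100000


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the network growth process."""

    image_size: int = 256
    n_seed_points: int = 6
    branch_probability: float = 0.15
    step_length: float = 10.0
    max_steps: int = 60
    turn_angle_std: float = 0.2
    width_mean: float = 10.0
    width_std: float = 1.5
    n_crossings: int = 0
    margin: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")


@dataclass
class Polyline:
    points: np.ndarray            # (n, 2) float, (row, col)
    width: float

    @property
    def length(self) -> float:
        return float(np.sqrt(np.diff(self.points, axis=0) ** 2
                             @ np.ones(2)).sum())


@dataclass
class GroundTruth:
    """Exact geometry and derived truth values of one synthetic network."""

    spec: NetworkSpec
    polylines: list[Polyline]
    branch_points: list[tuple[float, float]]
    crossing_points: list[tuple[float, float]]
    #: (index_a, index_b, contact point) pairs allowed to touch
    contacts: list[tuple[int, int, tuple[float, float]]] = field(
        default_factory=list
    )

    @property
    def true_total_length(self) -> float:
        return sum(p.length for p in self.polylines)

    @property
    def true_branch_count(self) -> int:
        return len(self.branch_points)

    @property
    def true_crossing_count(self) -> int:
        return len(self.crossing_points)

    def rasterize(self) -> np.ndarray:
        """Hard rasterised union: pixel foreground iff within width/2 of a
        centerline.  This defines the ground-truth vessel area."""
        size = self.spec.image_size
        mask = np.zeros((size, size), bool)
        for poly in self.polylines:
            d, _, sl = _polyline_distance(poly, size, poly.width / 2.0 + 1.0)
            mask[sl] |= d <= poly.width / 2.0
        return mask

    @property
    def true_area(self) -> float:
        return float(self.rasterize().sum())


def _dense_samples(points: np.ndarray, spacing: float = 2.0):
    """Resample a polyline at roughly uniform spacing; returns (pts, arcs)."""
    pts = [points[0]]
    arcs = [0.0]
    arc = 0.0
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        if seg == 0:
            continue
        n = max(int(math.ceil(seg / spacing)), 1)
        for i in range(1, n + 1):
            t = i / n
            pts.append(a + t * (b - a))
            arcs.append(arc + t * seg)
        arc += seg
    return np.asarray(pts), np.asarray(arcs)


def _polyline_distance(poly: Polyline, size: int, pad: float):
    """Distance map to the polyline centerline on its padded bounding box.

    Returns ``(distance, arc_of_nearest, slice)`` restricted to the box.
    """
    pts, arcs = _dense_samples(poly.points, spacing=0.7)
    r0 = max(int(pts[:, 0].min() - pad - 2), 0)
    r1 = min(int(pts[:, 0].max() + pad + 3), size)
    c0 = max(int(pts[:, 1].min() - pad - 2), 0)
    c1 = min(int(pts[:, 1].max() + pad + 3), size)
    sl = (slice(r0, r1), slice(c0, c1))
    box = np.zeros((r1 - r0, c1 - c0), bool)
    arc_img = np.zeros_like(box, dtype=float)
    rr = np.clip(np.round(pts[:, 0]).astype(int) - r0, 0, box.shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int) - c0, 0, box.shape[1] - 1)
    box[rr, cc] = True
    arc_img[rr, cc] = arcs  # last write wins; adjacent arcs are near-equal
    d, (iy, ix) = ndimage.distance_transform_edt(~box, return_indices=True)
    return d, arc_img[iy, ix], sl


class _ForbiddenGrid:
    """Occupancy grid of zones too close to already-laid centerlines.

    Each zone pixel stores the id (1-based) of the walker that stamped it,
    so a freshly spawned child can be exempted from its parent's zone only.
    """

    def __init__(self, size: int) -> None:
        self.size = size
        self.grid = np.zeros((size, size), dtype=np.int32)

    def stamp_segment(self, a: np.ndarray, b: np.ndarray, wid: int) -> None:
        lo = np.floor(np.minimum(a, b) - CLEARANCE).astype(int)
        hi = np.ceil(np.maximum(a, b) + CLEARANCE).astype(int) + 1
        lo = np.clip(lo, 0, self.size)
        hi = np.clip(hi, 0, self.size)
        yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
        d = _point_segment_distance(yy, xx, a, b)
        patch = self.grid[lo[0]:hi[0], lo[1]:hi[1]]
        patch[d <= CLEARANCE] = wid + 1

    def blocked(self, a: np.ndarray, b: np.ndarray,
                allow: int | None = None) -> bool:
        for t in np.linspace(0.0, 1.0, 9):
            p = a + t * (b - a)
            r, c = int(round(p[0])), int(round(p[1]))
            if 0 <= r < self.size and 0 <= c < self.size:
                v = self.grid[r, c]
                if v and (allow is None or v != allow + 1):
                    return True
        return False


def _point_segment_distance(yy, xx, a, b):
    d = b - a
    L2 = float(d @ d)
    if L2 == 0:
        return np.sqrt((yy - a[0]) ** 2 + (xx - a[1]) ** 2)
    t = np.clip(((yy - a[0]) * d[0] + (xx - a[1]) * d[1]) / L2, 0.0, 1.0)
    return np.sqrt((yy - a[0] - t * d[0]) ** 2 + (xx - a[1] - t * d[1]) ** 2)


@dataclass
class _Walker:
    pts: list
    width: float
    parent: int | None            # walker index of the parent, if any
    events: list = field(default_factory=list)  # (step, (r, c), child_widx)
    dead: bool = False


#: a connected family must exceed this many px^2 so it survives the default
#: 1%-of-image small-region removal on a 256 px canvas with margin
_MIN_FAMILY_AREA = 1000.0


def _grow_network(spec: NetworkSpec, rng: np.random.Generator):
    """One growth attempt.

    Returns ``(polylines, branch_points, crossing_points, contacts)``.
    """
    size = spec.image_size
    lo, hi = spec.margin, size - 1 - spec.margin
    grid = _ForbiddenGrid(size)

    def draw_width() -> float:
        return float(np.clip(rng.normal(spec.width_mean, spec.width_std),
                             spec.width_mean - 2 * spec.width_std,
                             spec.width_mean + 2 * spec.width_std))

    # --- injected crossings: two straight vessels through a common centre
    cross_polys: list[Polyline] = []
    cross_contacts: list[tuple[int, int, tuple[float, float]]] = []
    crossing_points: list[tuple[float, float]] = []
    for _ in range(spec.n_crossings):
        for _attempt in range(100):
            centre = rng.uniform(lo + 48, hi - 48, size=2)
            theta = rng.uniform(0, math.pi)
            arm = 45.0
            pls = []
            for k, ang in enumerate(
                (theta, theta + math.pi / 2 + rng.normal(0, 0.15))
            ):
                u = np.array([math.sin(ang), math.cos(ang)])
                p0, p1 = centre - arm * u, centre + arm * u
                if grid.blocked(p0, p1, allow=_X_ID + len(cross_polys) + k
                                if k else None):
                    pls = []
                    break
                pls.append(np.stack([p0, centre, p1]))
            if not pls:
                continue
            idx0 = len(cross_polys)
            for k, pts in enumerate(pls):
                cross_polys.append(Polyline(pts, draw_width()))
                for a, b in zip(pts[:-1], pts[1:]):
                    grid.stamp_segment(a, b, _X_ID + idx0 + k)
            cross_contacts.append((idx0, idx0 + 1, tuple(centre)))
            crossing_points.append(tuple(centre))
            break

    # --- branching random walks, breadth-first over a walker queue
    queue: list[tuple[np.ndarray, float, float, int | None]] = []
    for _ in range(spec.n_seed_points):
        for _attempt in range(30):
            pos = rng.uniform(lo, hi, size=2)
            if not grid.grid[int(round(pos[0])), int(round(pos[1]))]:
                queue.append((pos, rng.uniform(0, 2 * math.pi),
                              draw_width(), None))
                break

    walkers: list[_Walker] = []
    qi = 0
    while qi < len(queue):
        pos, ang, width, parent = queue[qi]
        me = qi
        qi += 1
        w = _Walker(pts=[pos.copy()], width=width, parent=parent)
        walkers.append(w)
        pending: list[tuple[np.ndarray, np.ndarray]] = []
        last_branch_step = -10
        if parent is not None:
            ppts = walkers[parent].pts
            parent_segments = [
                (np.asarray(a), np.asarray(b))
                for a, b in zip(ppts[:-1], ppts[1:])
                if min(np.linalg.norm(np.asarray(a) - pos),
                       np.linalg.norm(np.asarray(b) - pos)) < 80
            ] or [(pos.copy(), pos.copy())]
        for step in range(spec.max_steps):
            immune = step < 3 and parent is not None
            base = ang + rng.normal(0.0, spec.turn_angle_std)
            placed = False
            # symmetric fan search around the intended heading, reflecting
            # off the canvas walls, so walkers bend around obstacles
            for delta in (0.0, 0.45, -0.45, 0.9, -0.9, 1.35, -1.35):
                trial_ang = base + delta
                for _reflect in range(2):
                    u = np.array([math.sin(trial_ang), math.cos(trial_ang)])
                    cand = pos + spec.step_length * u
                    if not lo <= cand[0] <= hi:
                        trial_ang = -trial_ang
                        continue
                    if not lo <= cand[1] <= hi:
                        trial_ang = math.pi - trial_ang
                        continue
                    break
                u = np.array([math.sin(trial_ang), math.cos(trial_ang)])
                cand = pos + spec.step_length * u
                in_bounds = lo <= cand[0] <= hi and lo <= cand[1] <= hi
                if not in_bounds:
                    continue
                # never curl into the walker's own not-yet-stamped tail
                own = any(
                    _point_segment_distance(
                        np.array([cand[0]]), np.array([cand[1]]), a, b
                    )[0] < width + 4.0
                    for a, b in pending[:-2]
                )
                if own:
                    continue
                if immune:
                    # exempt only the parent's zone, but force divergence
                    # from the parent centerline so the child tube becomes
                    # a visible branch rather than hugging the parent
                    dpar = min(
                        float(_point_segment_distance(
                            np.array([cand[0]]), np.array([cand[1]]), a, b
                        )[0])
                        for a, b in parent_segments
                    )
                    if (dpar >= 0.5 * spec.step_length * (step + 1)
                            and not grid.blocked(pos, cand, allow=parent)):
                        placed = True
                        break
                elif not grid.blocked(pos, cand):
                    placed = True
                    break
            if not placed:
                break
            ang = trial_ang
            pending.append((pos.copy(), cand.copy()))
            if len(pending) > 3:
                grid.stamp_segment(*pending.pop(0), me)
            pos = cand
            w.pts.append(pos.copy())
            if (rng.random() < spec.branch_probability
                    and step >= 4
                    and step - last_branch_step > 3
                    and step < spec.max_steps - 4):
                side = 1 if rng.random() < 0.5 else -1
                child_ang = ang + side * rng.uniform(0.7, 1.1)
                queue.append((pos.copy(), child_ang, draw_width(), me))
                w.events.append((step, (float(pos[0]), float(pos[1])),
                                 len(queue) - 1))
                last_branch_step = step
        for seg in pending:
            grid.stamp_segment(*seg, me)

    # --- cleanup pass 1: erase walkers that produced (almost) no geometry.
    # A child shorter than 6 points cannot produce a branch arm that
    # reliably survives spur pruning once the part hidden inside the parent
    # tube and the skeleton end-shortening are accounted for, so it is
    # erased (with its descendants) and the branch event discarded.
    for i, w in enumerate(walkers):
        if (len(w.pts) < 6 and w.parent is not None) or len(w.pts) < 2:
            w.dead = True
    changed = True
    while changed:
        changed = False
        for w in walkers:
            if not w.dead and w.parent is not None and walkers[w.parent].dead:
                w.dead = True
                changed = True
    for w in walkers:
        w.events = [e for e in w.events if not walkers[e[2]].dead]

    # --- cleanup pass 2: trim trailing stubs after the last branch event so
    # every remaining junction's third arm decisively survives spur pruning
    for w in walkers:
        if w.dead or not w.events:
            continue
        s_last = w.events[-1][0]
        tail_steps = (len(w.pts) - 1) - (s_last + 1)
        if 1 <= tail_steps <= 3:
            w.pts = w.pts[: s_last + 2]
            tail_steps = 0
        if tail_steps < 4:
            # the parent now ends at the spawn point, so the "junction" is
            # geometrically just a bend into the child: not a branch point
            w.events = w.events[:-1]

    # --- cleanup pass 3: drop families too small to survive small-region
    # removal under the default settings
    def root(i: int) -> int:
        while walkers[i].parent is not None and not walkers[walkers[i].parent].dead:
            i = walkers[i].parent
        return i

    fam_area: dict[int, float] = {}
    for i, w in enumerate(walkers):
        if w.dead:
            continue
        r = root(i)
        length = float(
            np.sqrt((np.diff(np.asarray(w.pts), axis=0) ** 2).sum(axis=1)).sum()
        ) if len(w.pts) > 1 else 0.0
        fam_area[r] = fam_area.get(r, 0.0) + length * w.width
    for i, w in enumerate(walkers):
        if not w.dead and fam_area.get(root(i), 0.0) < _MIN_FAMILY_AREA:
            w.dead = True
    for w in walkers:
        w.events = [e for e in w.events if not walkers[e[2]].dead]

    # --- assemble
    polylines = list(cross_polys)
    contacts = list(cross_contacts)
    branch_points: list[tuple[float, float]] = []
    poly_index: dict[int, int] = {}
    for i, w in enumerate(walkers):
        if w.dead:
            continue
        poly_index[i] = len(polylines)
        polylines.append(Polyline(np.asarray(w.pts), w.width))
    for i, w in enumerate(walkers):
        if w.dead:
            continue
        if w.parent is not None and w.parent in poly_index:
            contacts.append((poly_index[w.parent], poly_index[i],
                             (float(w.pts[0][0]), float(w.pts[0][1]))))
        for _step, at, _child in w.events:
            branch_points.append(at)
    return polylines, branch_points, crossing_points, contacts


def _validate(polylines: list[Polyline],
              contacts: list[tuple[int, int, tuple[float, float]]]) -> bool:
    """Exact pairwise clearance check of the final geometry."""
    dense = [_dense_samples(p.points) for p in polylines]
    contact_map: dict[tuple[int, int], list[np.ndarray]] = {}
    for a, b, pt in contacts:
        key = (min(a, b), max(a, b))
        contact_map.setdefault(key, []).append(np.asarray(pt))
    n = len(polylines)
    for i in range(n):
        pts_i, arcs_i = dense[i]
        # self-check: far-apart arc positions must stay separated
        d2 = np.sqrt(((pts_i[:, None, :] - pts_i[None, :, :]) ** 2).sum(-1))
        arcgap = np.abs(arcs_i[:, None] - arcs_i[None, :])
        if np.any((arcgap > CONTACT_EXEMPT) & (d2 < polylines[i].width + 4)):
            return False
        for j in range(i + 1, n):
            pts_j, _ = dense[j]
            d = np.sqrt(((pts_i[:, None, :] - pts_j[None, :, :]) ** 2).sum(-1))
            limit = min((polylines[i].width + polylines[j].width) / 2 + 4,
                        CLEARANCE)
            bad = d < limit
            for pt in contact_map.get((i, j), []):
                near_i = np.linalg.norm(pts_i - pt, axis=1) < CONTACT_EXEMPT
                near_j = np.linalg.norm(pts_j - pt, axis=1) < CONTACT_EXEMPT
                far_i = np.linalg.norm(pts_i - pt, axis=1) < CONTACT_EXEMPT + 30
                far_j = np.linalg.norm(pts_j - pt, axis=1) < CONTACT_EXEMPT + 30
                bad &= ~(near_i[:, None] & far_j[None, :])
                bad &= ~(far_i[:, None] & near_j[None, :])
            if bad.any():
                return False
    return True


def generate_network(spec: NetworkSpec) -> GroundTruth:
    """Grow a network for ``spec``; deterministic for a fixed seed.

    Regenerates from derived seeds until the exact clearance validation
    passes, so recorded events are the only junctions in the geometry.
    """
    for attempt in range(25):
        rng = np.random.default_rng((spec.seed + 99991 * attempt) % 2**31)
        grown = _grow_network(spec, rng)
        polylines, branches, crossings, contacts = grown
        if not polylines:
            continue
        if _validate(polylines, contacts):
            return GroundTruth(spec, polylines, branches, crossings, contacts)
    raise RuntimeError(
        f"could not grow a valid network for seed {spec.seed}; "
        "spec leaves too little room"
    )


@dataclass(frozen=True)
class DegradationSpec:
    """Acquisition degradations applied to the ideal render.

    Defaults describe a plain clean acquisition: constant background, a
    mild optical blur, no vignetting, no staining heterogeneity, no noise.
    """

    vignette_amplitude: float = 0.0
    stain_heterogeneity: float = 0.0
    gaussian_noise_std: float = 0.0
    background_level: float = 0.1
    #: optical blur, scaled to the generator's reduced canvas so the
    #: blur-to-width ratio matches typical whole-mount acquisitions
    psf_sigma: float = 0.3


def render(gt: GroundTruth, deg: DegradationSpec | None = None,
           seed: int = 0) -> GrayImage:
    """Rasterise the network as a bright-on-dark micrograph.

    Tube cross-profile: a flat plateau of peak signal 0.8 blurred by a
    Gaussian PSF, crossing half maximum exactly at the true tube boundary;
    overlapping tubes combine by maximum.
    Degradations applied in order vignette -> stain heterogeneity -> noise,
    then clipped to [0, 1].  Deterministic for fixed (gt, deg, seed).
    """
    from scipy.special import erf

    deg = deg or DegradationSpec()
    rng = np.random.default_rng(seed % 2**31)
    size = gt.spec.image_size
    signal = np.zeros((size, size))
    for poly in gt.polylines:
        half = poly.width / 2.0
        pad = half + 4.0 * deg.psf_sigma
        d, arc, sl = _polyline_distance(poly, size, pad)
        # plateau tube blurred by the optical PSF: intensity crosses half
        # maximum exactly at the true tube boundary d = width/2
        profile = PEAK * 0.5 * (
            1.0 + erf((half - d) / (deg.psf_sigma * math.sqrt(2.0)))
        )
        if deg.stain_heterogeneity > 0:
            profile = profile * _stain_profile(
                arc, poly.length, deg.stain_heterogeneity, rng
            )
        signal[sl] = np.maximum(signal[sl], profile)
    img = deg.background_level + signal
    if deg.vignette_amplitude > 0:
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        cy = cx = (size - 1) / 2.0
        rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy ** 2 + cx ** 2)
        img = img + deg.vignette_amplitude * (1.0 - rho2)
    if deg.gaussian_noise_std > 0:
        img = img + rng.normal(0.0, deg.gaussian_noise_std, img.shape)
    return GrayImage(np.clip(img, 0.0, 1.0))


def _stain_profile(arc: np.ndarray, length: float, std: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative staining modulation along the tube axis."""
    n_ctrl = max(int(length / 20.0) + 2, 4)
    ctrl = 1.0 + rng.normal(0.0, std, n_ctrl)
    ctrl = np.clip(ctrl, 0.3, 1.7)
    xs = np.linspace(0.0, max(length, 1e-9), n_ctrl)
    return np.interp(arc, xs, ctrl)


def ground_truth_record(gt: GroundTruth) -> MorphometricsRecord:
    """Exact morphometrics of a ground-truth network (the oracle record)."""
    area = gt.true_area
    length = gt.true_total_length
    return MorphometricsRecord(
        filename="ground_truth",
        vessel_area_px2=area,
        skeleton_length_px=length,
        mean_width_px=area / length if length > 0 else float("nan"),
        n_branch_points=gt.true_branch_count,
        n_crossing_points=gt.true_crossing_count,
    )
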