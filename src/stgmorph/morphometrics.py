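"""Per-neuron morphometric battery.

Soma-to-tip paths and tortuosity, total wiring, furcation profile, branch
orders, branch angles, downstream-length symmetry index, Rall power at
branch points, linearized (somatofugal path-length) Sholl analysis,
x-y kernel spatial density, hair-like neurite detection, diameters by
branch order, and a one-row-per-neuron summary.

Because STG neurons are unipolar (the soma sits outside the neuropil),
the classic concentric-sphere Sholl analysis is replaced by a linearized
variant: distances are somatofugal *path* lengths, and a crossing is a
parent-child node pair whose cumulative path-length interval straddles a
sampled distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .geometry import NeuronGeometry

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- paths

@dataclass
class PathRecord:
    """One soma-to-tip traversal."""

    tip_node_id: int
    node_sequence: tuple[int, ...]  # soma -> tip
    path_length: float  # µm
    euclidean_distance: float  # µm
    tortuosity: float | None  # None when the tip coincides with the soma
    branch_order_at_tip: int


def enumerate_paths(geometry: NeuronGeometry) -> list[PathRecord]:
    """One record per terminating tip (axon leaves excluded).

    Path length is the sum of consecutive inter-node distances; tortuosity
    is path length over the straight soma-to-tip distance (``None`` and
    excluded from distributions when that distance is zero).
    """
    tips = geometry.terminating_tips
    if not tips:
        logger.warning("geometry %s has no terminating tips", geometry.label)
        return []
    bp = set(geometry.branch_point_ids)
    records = []
    for tip in sorted(tips):
        seq = geometry.path_to_root(tip)
        plen = geometry.somatofugal_distance(tip)
        eucl = float(
            np.linalg.norm(geometry.position(tip) - geometry.position(geometry.soma_node_id))
        )
        tort = plen / eucl if eucl > 0 else None
        order = sum(1 for nid in seq[:-1] if nid in bp)
        records.append(PathRecord(tip, tuple(seq), plen, eucl, tort, order))
    return records


def tortuosity(geometry: NeuronGeometry, tip_node_id: int) -> float | None:
    """Path length divided by the Euclidean soma-to-tip distance (>= 1)."""
    plen = geometry.somatofugal_distance(tip_node_id)
    eucl = float(
        np.linalg.norm(
            geometry.position(tip_node_id) - geometry.position(geometry.soma_node_id)
        )
    )
    if eucl == 0.0:
        return None
    return plen / eucl


def total_wiring(geometry: NeuronGeometry, exclude_axons: bool = True) -> float:
    """Total cable length in µm, by default omitting tagged axon segments."""
    return geometry.total_cable(exclude_axons=exclude_axons)


# ------------------------------------------------------------- furcations

@dataclass
class FurcationProfile:
    daughter_counts: dict[int, int]  # branch point node id -> number of daughters
    proportions: dict[str, float]  # {"bifurcation", "trifurcation", "multifurcation"}

    @property
    def n_branch_points(self) -> int:
        return len(self.daughter_counts)


def furcation_profile(geometry: NeuronGeometry) -> FurcationProfile:
    """Daughter counts per branch point and bi/tri/multi-furcation shares.

    A branch point is a non-soma node with >= 2 children; primary filaments
    leaving the soma do not make the soma a furcation.
    """
    counts = {nid: len(geometry.children[nid]) for nid in geometry.branch_point_ids}
    n = len(counts)
    if n == 0:
        props = {"bifurcation": 0.0, "trifurcation": 0.0, "multifurcation": 0.0}
    else:
        props = {
            "bifurcation": sum(1 for c in counts.values() if c == 2) / n,
            "trifurcation": sum(1 for c in counts.values() if c == 3) / n,
            "multifurcation": sum(1 for c in counts.values() if c >= 4) / n,
        }
    return FurcationProfile(counts, props)


def branch_orders(geometry: NeuronGeometry) -> dict[int, int]:
    """Branch order per branch point.

    The first branch point relative to the soma has order 0; thereafter the
    order counts the branch points passed between the first branch point
    and the node along its unique path to the soma.
    """
    bp = set(geometry.branch_point_ids)
    orders: dict[int, int] = {}
    count: dict[int, int] = {geometry.soma_node_id: 0}  # branch points strictly above
    stack = [geometry.soma_node_id]
    while stack:
        nid = stack.pop()
        here = count[nid]
        if nid in bp:
            orders[nid] = here
            here += 1
        for c in geometry.children[nid]:
            count[c] = here
            stack.append(c)
    return orders


# ----------------------------------------------------------- branch angle

@dataclass(frozen=True)
class BranchAngleInput:
    """Triangle for one (parent, daughter) pair at a furcation.

    ``p_mid`` is the branch point (shared proximal endpoint); ``p_1`` and
    ``p_2`` are the distal endpoints of the parent and daughter segments.
    """

    p_mid: np.ndarray
    p_1: np.ndarray
    p_2: np.ndarray


def branch_angle(inp: BranchAngleInput) -> float | None:
    """Branch angle in degrees, referenced to the parent's continuation.

    The law of cosines on triangle (P1, Pmid, P2) gives the angle at Pmid;
    the reported angle is 180 − θ_mid, so a straight continuation scores 0°
    and a perpendicular daughter 90°.  Degenerate (zero-side) triangles
    return ``None``.
    """
    p_mid = np.asarray(inp.p_mid, float)
    p_1 = np.asarray(inp.p_1, float)
    p_2 = np.asarray(inp.p_2, float)
    a = np.linalg.norm(p_1 - p_mid)  # side opposite P2... adjacent sides at Pmid
    b = np.linalg.norm(p_2 - p_mid)
    c = np.linalg.norm(p_1 - p_2)
    if a == 0 or b == 0:
        return None
    cos_mid = (a * a + b * b - c * c) / (2 * a * b)
    cos_mid = min(1.0, max(-1.0, cos_mid))
    theta_mid = math.degrees(math.acos(cos_mid))
    return 180.0 - theta_mid


def branch_angles(geometry: NeuronGeometry) -> list[dict]:
    """All (parent, daughter) branch angles using tracer-defined segment endpoints.

    At multi-furcations every (parent, daughter) combination yields one
    angle; daughter-daughter angles are not reported.  Endpoints are the
    stored distal endpoints of the adjacent segments (no resampling);
    degenerate triangles are skipped.
    """
    seg_by_end = geometry.segment_by_end
    out = []
    for bp_id in geometry.branch_point_ids:
        parent_seg = seg_by_end.get(bp_id)
        if parent_seg is None:
            continue
        p_mid = geometry.position(bp_id)
        p_1 = geometry.position(parent_seg.start)
        for seg in geometry.segments:
            if seg.start != bp_id:
                continue
            p_2 = geometry.position(seg.end)
            angle = branch_angle(BranchAngleInput(p_mid, p_1, p_2))
            if angle is None:
                continue
            out.append(
                {
                    "branch_point": bp_id,
                    "daughter_segment": seg.segment_id,
                    "angle_deg": angle,
                }
            )
    return out


# -------------------------------------------------------- symmetry index

@dataclass(frozen=True)
class SymmetryInput:
    d_1: float  # summed downstream segment length of daughter 1, µm
    d_2: float


def symmetry_index(inp: SymmetryInput) -> float:
    """S = min(d1, d2) / max(d1, d2); 1 is a perfectly balanced bifurcation."""
    d1, d2 = inp.d_1, inp.d_2
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("downstream lengths must be >= 0 and not both zero")
    lo, hi = sorted((d1, d2))
    if lo == 0:
        logger.warning("daughter with zero downstream length; symmetry index 0")
        return 0.0
    return lo / hi


def symmetry_indices(geometry: NeuronGeometry) -> dict[int, float]:
    """Symmetry index at every bifurcating branch point (multifurcations excluded).

    The downstream length of a daughter is the summed cable of the daughter
    edge and everything below it.
    """
    downstream: dict[int, float] = {}

    order = []
    stack = [geometry.soma_node_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(geometry.children[nid])
    for nid in reversed(order):
        downstream[nid] = sum(
            downstream[c] + geometry.edge_length(c) for c in geometry.children[nid]
        )

    out = {}
    for bp_id in geometry.branch_point_ids:
        kids = geometry.children[bp_id]
        if len(kids) != 2:
            continue
        d1 = downstream[kids[0]] + geometry.edge_length(kids[0])
        d2 = downstream[kids[1]] + geometry.edge_length(kids[1])
        out[bp_id] = symmetry_index(SymmetryInput(d1, d2))
    return out


# ------------------------------------------------------------ Rall power

RALL_X_MIN = 1e-3
RALL_X_MAX = 20.0
RALL_TOL = 1e-6


@dataclass(frozen=True)
class RallInput:
    parent_radius: float
    daughter_radii: tuple[float, ...]


@dataclass
class RallResult:
    exponent: float
    converged: bool
    clamped_at_bound: bool
    residual: float


def rall_power(inp: RallInput) -> RallResult:
    """Exponent X with parent^X = Σ daughter_i^X, found numerically.

    f(X) = parent^X − Σ daughter_i^X is bracketed over [1e-3, 20]; an
    interior sign change is solved by Brent's method to 1e-6.  When f has
    no interior root, |f| is minimized on the interval and the result is
    clamped at a bound and flagged.
    """
    p = inp.parent_radius
    ds = inp.daughter_radii
    if p <= 0 or any(d <= 0 for d in ds) or len(ds) < 2:
        raise ValueError("Rall power needs a positive parent radius and >= 2 positive daughters")

    def f(x: float) -> float:
        return p**x - sum(d**x for d in ds)

    lo, hi = RALL_X_MIN, RALL_X_MAX
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return RallResult(lo, True, True, 0.0)
    if fhi == 0.0:
        return RallResult(hi, True, True, 0.0)
    if flo * fhi < 0:
        x = float(optimize.brentq(f, lo, hi, xtol=RALL_TOL))
        return RallResult(x, True, False, abs(f(x)))
    # no interior root: minimize |f|, which may be multimodal — coarse scan
    # to bracket the global minimum, then local refinement
    xs = np.linspace(lo, hi, 4001)
    absf = np.abs(p**xs - sum(d**xs for d in ds))
    k = int(np.argmin(absf))
    a, b_ = xs[max(0, k - 1)], xs[min(len(xs) - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda x: abs(f(x)), bounds=(a, b_), method="bounded",
        options={"xatol": RALL_TOL},
    )
    x = float(res.x)
    if abs(f(lo)) <= abs(f(x)):  # prefer the bound on flat ties
        x = lo
    if abs(f(hi)) < abs(f(x)):
        x = hi
    clamped = (x - lo < 1e-2) or (hi - x < 1e-2)
    resid = abs(f(x))
    return RallResult(x, resid < RALL_TOL, clamped, resid)


def rall_powers(geometry: NeuronGeometry) -> dict[int, RallResult]:
    """Rall power at every branch point with radii (parent/daughter segment means)."""
    if not geometry.has_radii:
        raise ValueError("Rall power needs radius-annotated input")
    seg_by_end = geometry.segment_by_end
    out = {}
    for bp_id in geometry.branch_point_ids:
        parent_seg = seg_by_end.get(bp_id)
        if parent_seg is None:
            continue
        p_r = _segment_mean_radius(geometry, parent_seg.node_ids)
        d_rs = tuple(
            _segment_mean_radius(geometry, s.node_ids)
            for s in geometry.segments
            if s.start == bp_id
        )
        if len(d_rs) >= 2 and p_r and all(d_rs):
            out[bp_id] = rall_power(RallInput(p_r, d_rs))
    return out


def _segment_mean_radius(geometry: NeuronGeometry, node_ids) -> float | None:
    radii = [geometry.nodes[nid].radius for nid in node_ids[1:]]
    radii = [r for r in radii if r is not None]
    return float(np.mean(radii)) if radii else None


# -------------------------------------------------------------- Sholl

@dataclass
class ShollProfile:
    distances: np.ndarray  # sampled somatofugal path distances, µm
    counts: np.ndarray  # crossings at each distance
    normalized_counts: np.ndarray  # counts / max count
    normalized_distances: np.ndarray  # distances / max soma-to-tip path length


def linearized_sholl(geometry: NeuronGeometry, n_distances: int = 100) -> ShollProfile:
    """Crossing counts at linearly spaced somatofugal path distances.

    For each sampled distance D, the count is the number of parent-child
    node pairs whose cumulative path-length interval [d_parent, d_child)
    straddles D (half-open, so a node exactly at D counts once).  Axon
    segments are excluded.
    """
    axon = geometry.axon_node_ids
    intervals = []
    max_plen = 0.0
    for nid, node in geometry.nodes.items():
        if node.parent_id is None or nid in axon:
            continue
        d0 = geometry.somatofugal_distance(node.parent_id)
        d1 = geometry.somatofugal_distance(nid)
        intervals.append((d0, d1))
        max_plen = max(max_plen, d1)
    distances = np.linspace(0.0, max_plen, n_distances)
    starts = np.array([i[0] for i in intervals])
    ends = np.array([i[1] for i in intervals])
    counts = np.array(
        [int(np.sum((starts <= d) & (d < ends))) for d in distances], dtype=int
    )
    max_count = counts.max() if counts.size and counts.max() > 0 else 1
    return ShollProfile(
        distances,
        counts,
        counts / max_count,
        distances / max_plen if max_plen > 0 else distances,
    )


# ------------------------------------------------------- spatial density

@dataclass
class DensityMap:
    node_ids: list[int]
    values: np.ndarray  # scaled to [0, 1], max exactly 1
    bandwidth_rule: str = "scott"


def spatial_density(geometry: NeuronGeometry) -> DensityMap:
    """Gaussian KDE over node x-y coordinates, rescaled to a max of 1.

    Bandwidth follows Scott's rule; each node's value is its relative
    density of neighbors in the x-y (bird's-eye) plane.
    """
    node_ids = sorted(geometry.nodes)
    if len(node_ids) < 3:
        raise ValueError("spatial density needs at least 3 nodes")
    xy = geometry.coordinates(node_ids)[:, :2].T
    kde = stats.gaussian_kde(xy, bw_method="scott")
    vals = kde(xy)
    vals = vals / vals.max()
    return DensityMap(node_ids, vals, "scott")


# ---------------------------------------------------- hair-like neurites

def detect_hairlike(
    geometry: NeuronGeometry,
    max_diameter: float = 1.0,
    min_length: float = 50.0,
) -> list[dict]:
    """Find thin (< 1 µm diameter) neurite stretches longer than 50 µm.

    A hair-like filament is a maximal connected run of edges whose nodes
    are all thinner than ``max_diameter`` along its full extent.  Needs
    radius-annotated input.
    """
    if not geometry.has_radii:
        raise ValueError("hair-like detection needs radius-annotated input")
    thin = {
        nid for nid, n in geometry.nodes.items() if n.radius is not None and 2 * n.radius < max_diameter
    }
    # connected components of the thin-node forest (edges with both ends thin)
    visited: set[int] = set()
    out = []
    for seed in sorted(thin):
        if seed in visited:
            continue
        comp = {seed}
        stack = [seed]
        visited.add(seed)
        while stack:
            nid = stack.pop()
            nbrs = list(geometry.children[nid])
            pid = geometry.nodes[nid].parent_id
            if pid is not None:
                nbrs.append(pid)
            for nb in nbrs:
                if nb in thin and nb not in visited:
                    visited.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        length = sum(
            geometry.edge_length(nid)
            for nid in comp
            if geometry.nodes[nid].parent_id in comp
        )
        if length > min_length:
            out.append({"node_ids": sorted(comp), "length_um": length})
    return out


# ------------------------------------------------- diameters by order

def diameter_by_order(geometry: NeuronGeometry) -> dict[str, dict]:
    """Diameter samples and statistics by neurite class (1°, 2°, 3°, tip).

    The primary (1°) neurite is the main path from the soma to the tagged
    axon(s); secondary segments branch from it, tertiary from those; the
    tip class collects terminating filaments.  Each segment contributes
    its mean node diameter.  Needs radii and tagged axons.
    """
    if not geometry.has_radii:
        raise ValueError("diameter-by-order needs radius-annotated input")
    from .subtrees import main_path

    primary = main_path(geometry)
    seg_class: dict[int, str] = {sid: "1" for sid in primary}
    seg_by_end = geometry.segment_by_end
    parent_of: dict[int, int | None] = {}
    for s in geometry.segments:
        pseg = seg_by_end.get(s.start)
        parent_of[s.segment_id] = pseg.segment_id if pseg else None
    for s in geometry.segments:
        if s.segment_id in seg_class:
            continue
        p = parent_of[s.segment_id]
        if p in primary:
            seg_class[s.segment_id] = "2"
        elif p is not None and seg_class.get(p) == "2":
            seg_class[s.segment_id] = "3"

    terminal = set(geometry.terminal_segment_ids) - geometry.axon_segment_ids
    samples: dict[str, list[float]] = {"1": [], "2": [], "3": [], "tip": []}
    for s in geometry.segments:
        if s.segment_id in geometry.axon_segment_ids:
            continue
        r = _segment_mean_radius(geometry, s.node_ids)
        if r is None:
            continue
        # terminating filaments form their own class regardless of order
        if s.segment_id in terminal:
            samples["tip"].append(2 * r)
            continue
        cls = seg_class.get(s.segment_id)
        if cls in samples:
            samples[cls].append(2 * r)

    out = {}
    for cls, vals in samples.items():
        arr = np.asarray(vals)
        if arr.size:
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            cv = sd / mean if mean > 0 else float("nan")
        else:
            mean = sd = cv = float("nan")
        out[cls] = {"diameters": vals, "mean": mean, "sd": sd, "cv": cv, "n": len(vals)}
    return out


# ------------------------------------------------------------- summary

@dataclass
class NeuronSummary:
    """One-row anatomical summary (the columns of the per-neuron table)."""

    label: str
    cell_type: str
    n_soma_to_tip_paths: int
    n_branch_points: int
    n_subtrees: int | None
    total_wiring_um: float
    tortuosity_mean: float
    tortuosity_sd: float
    path_length_mean_um: float
    path_length_sd_um: float
    diameter_1_um: float | None = None
    diameter_2_mean_um: float | None = None
    diameter_2_sd_um: float | None = None
    diameter_3_mean_um: float | None = None
    diameter_3_sd_um: float | None = None
    diameter_tip_mean_um: float | None = None
    diameter_tip_sd_um: float | None = None
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "label": self.label,
            "cell_type": self.cell_type,
            "soma_to_tip_neurites": self.n_soma_to_tip_paths,
            "branch_points": self.n_branch_points,
            "subtrees": self.n_subtrees,
            "total_wiring_um": self.total_wiring_um,
            "tortuosity_mean": self.tortuosity_mean,
            "tortuosity_sd": self.tortuosity_sd,
            "path_length_mean_um": self.path_length_mean_um,
            "path_length_sd_um": self.path_length_sd_um,
            "diam_1_um": self.diameter_1_um,
            "diam_2_mean_um": self.diameter_2_mean_um,
            "diam_2_sd_um": self.diameter_2_sd_um,
            "diam_3_mean_um": self.diameter_3_mean_um,
            "diam_3_sd_um": self.diameter_3_sd_um,
            "diam_tip_mean_um": self.diameter_tip_mean_um,
            "diam_tip_sd_um": self.diameter_tip_sd_um,
        }
        row.update(self.extras)
        return row


def summarize(geometry: NeuronGeometry) -> NeuronSummary:
    """Compute the full per-neuron summary row.

    Subtree count needs tagged axons and is ``None`` without them; diameter
    columns need radii.
    """
    paths = enumerate_paths(geometry)
    torts = np.array([p.tortuosity for p in paths if p.tortuosity is not None])
    plens = np.array([p.path_length for p in paths])

    n_subtrees: int | None = None
    if geometry.axon_segment_ids:
        from .subtrees import detect_subtrees

        n_subtrees = len(detect_subtrees(geometry))

    diam_kwargs: dict = {}
    if geometry.has_radii and geometry.axon_segment_ids:
        d = diameter_by_order(geometry)
        diam_kwargs = {
            "diameter_1_um": d["1"]["mean"],
            "diameter_2_mean_um": d["2"]["mean"],
            "diameter_2_sd_um": d["2"]["sd"],
            "diameter_3_mean_um": d["3"]["mean"],
            "diameter_3_sd_um": d["3"]["sd"],
            "diameter_tip_mean_um": d["tip"]["mean"],
            "diameter_tip_sd_um": d["tip"]["sd"],
        }

    def _m(a):
        return float(a.mean()) if a.size else float("nan")

    def _s(a):
        return float(a.std(ddof=1)) if a.size > 1 else 0.0

    return NeuronSummary(
        label=geometry.label,
        cell_type=geometry.cell_type,
        n_soma_to_tip_paths=len(paths),
        n_branch_points=len(geometry.branch_point_ids),
        n_subtrees=n_subtrees,
        total_wiring_um=total_wiring(geometry, exclude_axons=True),
        tortuosity_mean=_m(torts),
        tortuosity_sd=_s(torts),
        path_length_mean_um=_m(plens),
        path_length_sd_um=_s(plens),
        **diam_kwargs,
    )
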