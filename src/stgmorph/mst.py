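"""Wiring-cost-constrained minimal spanning neurite tree synthesis.

Synthetic trees are grown greedily from a root (the reference neuron's
first branch point) over carrier points sampled uniformly in an ellipsoid
approximating the space the real arbor occupies.  Each attachment
minimizes::

    cost(p, n) = ||p - n|| + bf * (PL(n) + ||p - n||)

over tree nodes n, where PL(n) is n's path length to the root and bf is
the balancing factor trading total cable against root-to-tip path length.
Low bf minimizes cable (compact wiring, long paths); high bf shortens
paths at the expense of cable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import NeuronGeometry, SkeletonNode
from .subtrees import Ellipsoid

logger = logging.getLogger(__name__)

DEFAULT_BF_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass
class MSTConfig:
    bf: float
    root: np.ndarray  # (3,) µm
    carrier_count: int
    volume: Ellipsoid | None = None
    seed: int = 0

    def __post_init__(self):
        if self.bf < 0:
            raise ValueError("balancing factor must be >= 0")
        if self.carrier_count < 1:
            raise ValueError("carrier_count must be >= 1")
        self.root = np.asarray(self.root, dtype=float)


@dataclass
class MSTResult:
    config: MSTConfig
    geometry: NeuronGeometry
    total_cable_um: float
    n_branch_points: int
    root_path_lengths: np.ndarray  # per non-root node, µm
    distributions: dict = field(default_factory=dict)


# ----------------------------------------------------------- volume fit

def fit_bounding_ellipsoid(
    geometry: NeuronGeometry, coverage: float = 0.95
) -> Ellipsoid:
    """Covariance ellipsoid over node coordinates scaled to cover >= ``coverage``.

    Semi-axes follow the covariance eigenvectors, scaled so that at least
    the requested fraction of nodes lies inside.  Degenerate (coplanar)
    clouds get a 1 µm semi-axis floor with a warning.
    """
    coords = geometry.coordinates()
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.min(evals) <= 1e-12:
        logger.warning("degenerate node cloud; flooring semi-axes at 1 µm")
        evals = np.maximum(evals, 1.0)
    base = np.sqrt(evals)
    local = (coords - center) @ evecs
    m = np.linalg.norm(local / base, axis=1)
    # k-th order statistic so that >= coverage of the nodes land inside
    k = int(np.ceil(coverage * len(m)))
    scale = float(np.sort(m)[max(k - 1, 0)]) * (1 + 1e-12)
    return Ellipsoid(center, np.maximum(scale * base, 1.0), evecs)


def sample_carrier_points(volume: Ellipsoid, n: int, seed: int = 0) -> np.ndarray:
    """``n`` points uniform in the ellipsoid, reproducible under ``seed``.

    Uniform unit-ball samples (Gaussian direction, U^(1/3) radius) are
    mapped through the ellipsoid's affine transform; the image of a
    uniform ball under an affine map is uniform in the image ellipsoid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    ball = g * r[:, None]
    return ball * volume.semi_axes @ volume.orientation.T + volume.center


# --------------------------------------------------------------- growth

def grow_mst(config: MSTConfig, carrier_points: np.ndarray) -> MSTResult:
    """Grow the tree by greedy wiring-cost attachment.

    Starting from the root, the unconnected carrier point p minimizing
    ``||p−n|| + bf·(PL(n) + ||p−n||)`` over tree nodes n is attached to
    its best node; ties break toward the lowest carrier index.  Carrier
    points coincident with an existing node are merged with a warning.
    Attachment happens only at existing nodes (no mid-edge splitting).
    """
    pts = np.atleast_2d(np.asarray(carrier_points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one carrier point")
    bf = config.bf
    root = config.root

    coords = [root]
    pl = [0.0]  # path length to root per tree node
    parent: list[int] = [-1]

    n_pts = pts.shape[0]
    unattached = np.ones(n_pts, dtype=bool)
    # best attachment per carrier point, updated as nodes join (Prim-style)
    d_root = np.linalg.norm(pts - root, axis=1)
    best_cost = d_root + bf * (0.0 + d_root)
    best_node = np.zeros(n_pts, dtype=int)
    point_of_node = [-1]  # tree node index -> carrier index (root = -1)

    merged = 0
    for _ in range(n_pts):
        idx_candidates = np.flatnonzero(unattached)
        costs = best_cost[idx_candidates]
        # lowest cost; ties -> lowest carrier index (flatnonzero is sorted)
        k = idx_candidates[int(np.argmin(costs))]
        n_at = int(best_node[k])
        dist = float(np.linalg.norm(pts[k] - coords[n_at]))
        unattached[k] = False
        if dist == 0.0:
            merged += 1
            point_of_node.append(int(k))  # merged into n_at; no new node
            # record as zero-length merge: skip adding a node
            continue
        coords.append(pts[k])
        pl.append(pl[n_at] + dist)
        parent.append(n_at)
        new_idx = len(coords) - 1
        point_of_node.append(int(k))
        if unattached.any():
            d_new = np.linalg.norm(pts - coords[new_idx], axis=1)
            cost_new = d_new + bf * (pl[new_idx] + d_new)
            better = cost_new < best_cost
            best_cost[better] = cost_new[better]
            best_node[better] = new_idx
    if merged:
        logger.warning("merged %d duplicate carrier point(s)", merged)

    nodes = [
        SkeletonNode(i + 1, coords[i], None, None if parent[i] == -1 else parent[i] + 1)
        for i in range(len(coords))
    ]
    geom = NeuronGeometry(
        nodes, label=f"mst_bf{bf:g}", cell_type="synthetic", merge_zero_edges=False
    )
    total = geom.total_cable()
    return MSTResult(
        config=config,
        geometry=geom,
        total_cable_um=total,
        n_branch_points=len(geom.branch_point_ids),
        root_path_lengths=np.asarray(pl[1:]),
        distributions=_mst_distributions(geom),
    )


def _mst_distributions(geom: NeuronGeometry) -> dict:
    from . import morphometrics as mm

    paths = mm.enumerate_paths(geom)
    orders = list(mm.branch_orders(geom).values())
    return {
        "branch_order": np.asarray(orders, dtype=float),
        "neurite_length": np.asarray([p.path_length for p in paths]),
        "tortuosity": np.asarray(
            [p.tortuosity for p in paths if p.tortuosity is not None]
        ),
    }


# --------------------------------------------------------------- tuning

def tune_carrier_points(
    reference: NeuronGeometry,
    bf_tune: float = 0.0,
    tolerance: float = 0.20,
    seed: int = 0,
    max_steps: int = 30,
    volume: Ellipsoid | None = None,
) -> int:
    """Find a carrier count whose MST branch-point count matches the reference.

    Doubling then bisection over the carrier count until the grown MST's
    branch-point count is within ``tolerance`` (default 20%) of the
    reference neuron's count at ``bf_tune``.  The returned count is meant
    to be reused for the full bf sweep.
    """
    target = len(reference.branch_point_ids)
    if target < 1:
        raise ValueError("reference must have at least one branch point")
    vol = volume if volume is not None else fit_bounding_ellipsoid(reference)
    root = _reference_root(reference)

    def bp_count(n: int) -> int:
        pts = sample_carrier_points(vol, n, seed)
        cfg = MSTConfig(bf=bf_tune, root=root, carrier_count=n, volume=vol, seed=seed)
        return grow_mst(cfg, pts).n_branch_points

    lo, hi = 1, max(4, 2 * target)
    steps = 0
    best = (float("inf"), hi)
    while steps < max_steps:
        steps += 1
        c = bp_count(hi)
        err = abs(c - target) / target
        if err < best[0]:
            best = (err, hi)
        if err <= tolerance:
            return hi
        if c >= target:
            break
        lo, hi = hi, hi * 2
    while steps < max_steps and hi - lo > 1:
        steps += 1
        mid = (lo + hi) // 2
        c = bp_count(mid)
        err = abs(c - target) / target
        if err < best[0]:
            best = (err, mid)
        if err <= tolerance:
            return mid
        if c < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"carrier tuning did not converge in {max_steps} steps; "
        f"best count {best[1]} (relative error {best[0]:.2f})"
    )


def _reference_root(reference: NeuronGeometry) -> np.ndarray:
    """Root of the synthetic tree: the reference's first branch point."""
    bps = reference.branch_point_ids
    if not bps:
        raise ValueError("reference has no branch point")
    first = min(bps, key=lambda nid: reference.somatofugal_distance(nid))
    return reference.position(first)


# ---------------------------------------------------------------- sweep

def bf_sweep(
    reference: NeuronGeometry,
    bf_values: tuple[float, ...] = DEFAULT_BF_GRID,
    seed: int = 0,
    carrier_count: int | None = None,
    tolerance: float = 0.20,
) -> list[MSTResult]:
    """Grow one MST per balancing factor over a shared carrier point set.

    The carrier count is tuned at bf = 0 (unless given) and frozen across
    the sweep, so differences between bf values reflect the cost trade-off
    and not resampling noise.
    """
    vol = fit_bounding_ellipsoid(reference)
    root = _reference_root(reference)
    if carrier_count is None:
        carrier_count = tune_carrier_points(
            reference, bf_tune=0.0, tolerance=tolerance, seed=seed, volume=vol
        )
    pts = sample_carrier_points(vol, carrier_count, seed)
    out = []
    for bf in bf_values:
        cfg = MSTConfig(bf=bf, root=root, carrier_count=carrier_count, volume=vol, seed=seed)
        out.append(grow_mst(cfg, pts))
    return out


# ----------------------------------------------------------- comparison

N_HIST_BINS = 50


def _norm_hist(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    counts, _ = np.histogram(values, bins=N_HIST_BINS, range=(lo, hi))
    m = counts.max()
    return counts / m if m > 0 else counts.astype(float)


def divergence(a: np.ndarray, b: np.ndarray, lo: float, hi: float) -> float:
    """Sum of absolute bin differences between max-normalized histograms."""
    return float(np.abs(_norm_hist(a, lo, hi) - _norm_hist(b, lo, hi)).sum())


def compare_distributions(
    reference: NeuronGeometry, sweep: list[MSTResult]
) -> list[dict]:
    """Per-bf comparison of synthetic vs reference morphometrics.

    For each metric the divergence is the sum of absolute differences of
    50-bin histograms normalized to their maxima over the union range;
    a flag records whether the MST's total wiring is within 20% of the
    reference's.
    """
    from . import morphometrics as mm

    ref_paths = mm.enumerate_paths(reference)
    ref = {
        "branch_order": np.asarray(list(mm.branch_orders(reference).values()), float),
        "neurite_length": np.asarray([p.path_length for p in ref_paths]),
        "tortuosity": np.asarray(
            [p.tortuosity for p in ref_paths if p.tortuosity is not None]
        ),
    }
    ref_wiring = mm.total_wiring(reference, exclude_axons=True)
    ref_bp = len(reference.branch_point_ids)

    rows = []
    for res in sweep:
        row = {
            "bf": res.config.bf,
            "total_cable_um": res.total_cable_um,
            "n_branch_points": res.n_branch_points,
            "wiring_within_20pct": bool(
                abs(res.total_cable_um - ref_wiring) <= 0.20 * ref_wiring
            ),
            "bp_within_20pct": bool(abs(res.n_branch_points - ref_bp) <= 0.20 * ref_bp),
        }
        for metric, ref_vals in ref.items():
            syn_vals = res.distributions[metric]
            if len(ref_vals) == 0 or len(syn_vals) == 0:
                row[f"divergence_{metric}"] = float("nan")
                continue
            lo = min(ref_vals.min(), syn_vals.min())
            hi = max(ref_vals.max(), syn_vals.max())
            if hi <= lo:
                hi = lo + 1.0
            row[f"divergence_{metric}"] = divergence(syn_vals, ref_vals, lo, hi)
        rows.append(row)
    return rows
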