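"""Synthetic unipolar STG-like neuron skeletons with known ground truth.

The generator emulates the structure of the real reconstructions: a soma
offset from the neuropil, a primary neurite carrying one or several
unbranched axons (>= 20 µm, so candidate detection finds them), subtrees
rooted on the primary whose tip clusters tile space on a grid (or are
placed at random), a bifurcation-dominated furcation mix, soma-to-tip
path lengths mostly in 200-800 µm, and optional per-node radii tapering
from the thick primary to thin tips with multiplicative log-normal noise.

Growth uses direction inheritance: each branch continues its parent's
direction, perturbed by ``tortuosity_factor``-scaled jitter plus
attraction toward the subtree's designated field center.  At
``tortuosity_factor = 0`` directions never change, so every soma-to-tip
path is exactly collinear (tortuosity 1) — a degenerate but useful
calibration case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .geometry import NeuronGeometry, SkeletonNode


@dataclass
class SyntheticNeuronSpec:
    """Ground-truth parameters of one synthetic neuron.

    Lengths in µm.  Defaults emulate a mid-sized single-axon STG neuron:
    soma ~150 µm from the neuropil, ~12 subtrees tiling a grid at 120 µm
    spacing with 25 µm tip dispersion, ~90% bifurcations, diameters
    tapering 18 -> 7 -> 3.5 -> 1.5 µm across 1°/2°/3°/tip classes, and
    soma-to-tip paths targeted at 200-800 µm.
    """

    seed: int = 0
    soma_offset: float = 150.0
    n_axons: int = 1
    primary_length: float = 300.0
    n_subtrees: int = 12
    tips_per_subtree: tuple[int, int] = (3, 8)  # inclusive uniform range
    subtree_layout: str = "tiled-grid"  # or "random"
    field_dispersion: float = 25.0
    tile_spacing: float = 120.0
    tortuosity_factor: float = 0.45
    furcation_mix: dict = field(default_factory=lambda: {2: 0.90, 3: 0.08, 4: 0.02})
    taper: tuple[float, float, float, float] | None = (18.0, 7.0, 3.5, 1.5)
    radius_noise_sigma: float = 0.0
    target_path_length_range: tuple[float, float] = (200.0, 800.0)
    step_length: float = 10.0
    axon_length: float = 40.0
    cell_type: str = "synthetic"
    label: str = "synthetic"

    def validate(self) -> None:
        if not (1 <= self.n_axons <= 5):
            raise ValueError("n_axons must be in 1..5")
        if self.subtree_layout not in ("tiled-grid", "random"):
            raise ValueError("subtree_layout must be 'tiled-grid' or 'random'")
        if self.subtree_layout == "tiled-grid" and self.tile_spacing <= 0:
            raise ValueError("tiled layout needs tile_spacing > 0")
        total = sum(self.furcation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("furcation_mix probabilities must sum to 1")
        for v in (
            self.soma_offset,
            self.primary_length,
            self.field_dispersion,
            self.step_length,
            self.axon_length,
        ):
            if v < 0:
                raise ValueError("lengths must be non-negative")
        if self.tortuosity_factor < 0:
            raise ValueError("tortuosity_factor must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class GroundTruth:
    """Designed structure of the emitted geometry."""

    subtree_tip_ids: list[list[int]]  # per subtree, tip node ids
    subtree_field_centers: list[list[float]]
    axon_tip_ids: list[int]
    designed_path_lengths: dict[int, float]  # tip id -> designed length
    designed_radii: dict[int, float]  # node id -> designed radius (no noise)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subtree_tip_ids": self.subtree_tip_ids,
                "subtree_field_centers": self.subtree_field_centers,
                "axon_tip_ids": self.axon_tip_ids,
                "designed_path_lengths": self.designed_path_lengths,
                "designed_radii": self.designed_radii,
            },
            indent=2,
        )


class _Builder:
    def __init__(self, spec: SyntheticNeuronSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.nodes: list[SkeletonNode] = []
        self.next_id = 1
        self.radius_class: dict[int, str] = {}

    def add(self, pos: np.ndarray, parent: int | None, rclass: str) -> int:
        nid = self.next_id
        self.next_id += 1
        self.nodes.append(SkeletonNode(nid, np.asarray(pos, float), None, parent))
        self.radius_class[nid] = rclass
        return nid

    def chain(
        self,
        start_id: int,
        start_pos: np.ndarray,
        direction: np.ndarray,
        length: float,
        rclass: str,
        pull_target: np.ndarray | None = None,
    ) -> tuple[int, np.ndarray, np.ndarray]:
        """Grow a jittered chain; returns (end id, end pos, end direction)."""
        tf = self.spec.tortuosity_factor
        step = self.spec.step_length
        n_steps = max(1, int(round(length / step)))
        step_len = length / n_steps
        pos = np.asarray(start_pos, float)
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        nid = start_id
        for _ in range(n_steps):
            if tf > 0:
                jitter = tf * self.rng.standard_normal(3)
                pull = np.zeros(3)
                if pull_target is not None:
                    to_t = pull_target - pos
                    norm = np.linalg.norm(to_t)
                    if norm > 1e-9:
                        pull = 0.6 * to_t / norm
                d = d + jitter + pull
                d = d / np.linalg.norm(d)
            pos = pos + d * step_len
            nid = self.add(pos, nid, rclass)
        return nid, pos, d


def generate_neuron(spec: SyntheticNeuronSpec) -> tuple[NeuronGeometry, GroundTruth]:
    """Build one synthetic neuron; same spec (same seed) gives identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec, rng)

    soma_pos = np.zeros(3)
    soma = b.add(soma_pos, None, "1")
    forward = np.array([1.0, 0.0, 0.0])

    # primary neurite: soma -> neuropil entry -> through the neuropil
    trunk_len = spec.soma_offset + spec.primary_length
    n_trunk = max(4, int(round(trunk_len / spec.step_length)))
    trunk_ids = [soma]
    pos, d, nid = soma_pos, forward.copy(), soma
    for _ in range(n_trunk):
        if spec.tortuosity_factor > 0:
            d = d + 0.3 * spec.tortuosity_factor * rng.standard_normal(3)
            d /= np.linalg.norm(d)
        pos = pos + d * (trunk_len / n_trunk)
        nid = b.add(pos, nid, "1")
        trunk_ids.append(nid)
    trunk_end_pos, trunk_end_dir = pos, d

    # axons: unbranched terminal filaments from the distal trunk
    axon_tip_ids = []
    axon_attach = [trunk_ids[-1]]
    for k in range(1, spec.n_axons):
        axon_attach.append(trunk_ids[-(1 + 2 * k)])
    for k, attach in enumerate(axon_attach):
        a_dir = trunk_end_dir if spec.tortuosity_factor == 0 else _unit(
            trunk_end_dir + 0.8 * rng.standard_normal(3)
        )
        end, _, _ = b.chain(
            attach,
            b.nodes[attach - 1].position,
            a_dir,
            spec.axon_length + 5.0 * k,
            "axon",
        )
        axon_tip_ids.append(end)

    # subtree roots on the interior trunk (inside the neuropil portion)
    first_neuropil = int(round(spec.soma_offset / (trunk_len / n_trunk)))
    candidates = trunk_ids[max(1, first_neuropil) : -1]
    if len(candidates) < spec.n_subtrees:
        raise ValueError("primary neurite too short for the requested subtree count")
    idx = np.linspace(0, len(candidates) - 1, spec.n_subtrees).round().astype(int)
    root_ids = [candidates[i] for i in idx]

    centers = _field_centers(spec, rng, trunk_end_pos)

    subtree_tip_ids: list[list[int]] = []
    designed_lengths: dict[int, float] = {}
    for s_idx, root in enumerate(root_ids):
        root_pos = b.nodes[root - 1].position
        n_tips = int(rng.integers(spec.tips_per_subtree[0], spec.tips_per_subtree[1] + 1))
        topo = _topology(n_tips, spec.furcation_mix, rng)
        lo, hi = spec.target_path_length_range
        target_total = float(rng.uniform(lo, hi))
        depth = max(1, _depth(topo))
        edge_len = max(
            2 * spec.step_length, (target_total - _trunk_dist(b, root)) / depth
        )
        tips = _embed(
            b,
            root,
            root_pos,
            trunk_end_dir if spec.tortuosity_factor == 0 else _unit(centers[s_idx] - root_pos),
            topo,
            edge_len,
            centers[s_idx],
            depth_label=2,
        )
        subtree_tip_ids.append(tips)
        for t in tips:
            designed_lengths[t] = target_total

    geom = NeuronGeometry(
        b.nodes,
        label=spec.label,
        cell_type=spec.cell_type,
        merge_zero_edges=False,
    )

    # radii per taper class, optional log-normal noise
    designed_radii: dict[int, float] = {}
    if spec.taper is not None:
        d1, d2, d3, dtip = spec.taper
        class_diam = {"1": d1, "2": d2, "3": d3, "tip": dtip, "axon": d2}
        terminal_tipward = _terminal_nodes(geom, set(axon_tip_ids))
        new_nodes = []
        for n in geom.nodes.values():
            cls = b.radius_class[n.node_id]
            if n.node_id in terminal_tipward:
                cls = "tip"
            diam = class_diam[cls]
            designed_radii[n.node_id] = diam / 2.0
            noise = (
                float(np.exp(spec.radius_noise_sigma * rng.standard_normal()))
                if spec.radius_noise_sigma > 0
                else 1.0
            )
            new_nodes.append(
                SkeletonNode(n.node_id, n.position, diam / 2.0 * noise, n.parent_id)
            )
        geom = NeuronGeometry(
            new_nodes,
            label=spec.label,
            cell_type=spec.cell_type,
            merge_zero_edges=False,
        )

    # tag axons: terminal segments ending at the designed axon tips
    axon_sids = [
        s.segment_id for s in geom.segments if s.end in set(axon_tip_ids)
    ]
    geom.tag_axon_segments(axon_sids)

    gt = GroundTruth(
        subtree_tip_ids=subtree_tip_ids,
        subtree_field_centers=[list(map(float, c)) for c in centers],
        axon_tip_ids=axon_tip_ids,
        designed_path_lengths=designed_lengths,
        designed_radii=designed_radii,
    )
    return geom, gt


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _trunk_dist(b: _Builder, root: int) -> float:
    """Somatofugal distance of a trunk node (chain of straight-ish steps)."""
    dist = 0.0
    nid = root
    while True:
        node = b.nodes[nid - 1]
        if node.parent_id is None:
            return dist
        dist += float(np.linalg.norm(node.position - b.nodes[node.parent_id - 1].position))
        nid = node.parent_id


def _field_centers(
    spec: SyntheticNeuronSpec, rng: np.random.Generator, trunk_end: np.ndarray
) -> list[np.ndarray]:
    """Designated tip-cluster centers: a spaced grid (tiling) or random."""
    n = spec.n_subtrees
    mid = np.array([spec.soma_offset + spec.primary_length / 2.0, 0.0, 0.0])
    if spec.subtree_layout == "tiled-grid":
        side = int(np.ceil(np.sqrt(n)))
        centers = []
        for k in range(n):
            i, j = divmod(k, side)
            centers.append(
                mid
                + np.array(
                    [
                        (i - (side - 1) / 2.0) * spec.tile_spacing,
                        (j - (side - 1) / 2.0) * spec.tile_spacing + spec.tile_spacing,
                        0.0,
                    ]
                )
            )
        return centers
    extent = spec.tile_spacing * max(2.0, np.sqrt(n))
    return [
        mid + np.array([rng.uniform(-extent, extent), rng.uniform(-extent, extent), 0.0])
        for _ in range(n)
    ]


def _topology(n_tips: int, furcation_mix: dict, rng: np.random.Generator):
    """Nested-list topology: a leaf is None; a branch is a list of children."""
    if n_tips <= 1:
        return None
    ks = sorted(furcation_mix)
    probs = np.array([furcation_mix[k] for k in ks])
    d = int(rng.choice(ks, p=probs / probs.sum()))
    d = min(d, n_tips)
    if d < 2:
        d = 2
    # split tips among daughters, each at least one
    cuts = rng.multinomial(n_tips - d, np.full(d, 1.0 / d)) + 1
    return [_topology(int(c), furcation_mix, rng) for c in cuts]


def _depth(topo) -> int:
    if topo is None:
        return 1
    return 1 + max(_depth(c) for c in topo)


def _embed(
    b: _Builder,
    node: int,
    pos: np.ndarray,
    direction: np.ndarray,
    topo,
    edge_len: float,
    center: np.ndarray,
    depth_label: int,
) -> list[int]:
    """Recursively grow a subtree topology; returns tip node ids."""
    spec = b.spec
    rng = b.rng
    rclass = {2: "2", 3: "3"}.get(depth_label, "3")
    if topo is None:
        # leaf branch: end near the field center (dispersed)
        target = center + spec.field_dispersion * rng.standard_normal(3)
        length = max(edge_len, float(np.linalg.norm(target - pos))) if spec.tortuosity_factor > 0 else edge_len
        end, _, _ = b.chain(node, pos, direction, length, "tip", pull_target=target)
        return [end]
    end, epos, edir = b.chain(
        node, pos, direction, edge_len, rclass,
        pull_target=center if spec.tortuosity_factor > 0 else None,
    )
    tips = []
    for child in topo:
        if spec.tortuosity_factor == 0:
            cdir = edir
        else:
            cdir = _unit(edir + 0.9 * rng.standard_normal(3))
        tips.extend(
            _embed(b, end, epos, cdir, child, edge_len, center, depth_label + 1)
        )
    return tips


def _terminal_nodes(geom: NeuronGeometry, axon_tips: set[int]) -> set[int]:
    """Nodes interior to terminal (non-axon) segments."""
    out: set[int] = set()
    for s in geom.segments:
        if s.end in axon_tips:
            continue
        if not geom.children[s.end]:
            out.update(s.node_ids[1:])
    return out


# ------------------------------------------------------------ population

def generate_population(
    template: SyntheticNeuronSpec,
    n: int,
    seed: int = 0,
    jitter: float = 0.0,
) -> list[tuple[NeuronGeometry, GroundTruth]]:
    """``n`` neurons with independent sub-seeds derived from ``seed``.

    With ``jitter`` > 0 the per-neuron specs get multiplicative
    perturbations of the continuous size parameters (emulating
    animal-to-animal variability).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = replace(template, seed=sub_seed, label=f"{template.label}_{i}")
        if jitter > 0:
            jrng = np.random.default_rng(sub_seed + 1)
            spec = replace(
                spec,
                primary_length=spec.primary_length * float(jrng.lognormal(0, jitter)),
                field_dispersion=spec.field_dispersion * float(jrng.lognormal(0, jitter)),
            )
        out.append(generate_neuron(spec))
    return out


TEMPLATES = {
    "gm-like": SyntheticNeuronSpec(
        label="gm-like", n_axons=3, n_subtrees=16, primary_length=400.0,
        tips_per_subtree=(4, 10),
    ),
    "lg-like": SyntheticNeuronSpec(label="lg-like", n_axons=1, n_subtrees=12),
    "lp-like": SyntheticNeuronSpec(label="lp-like", n_axons=1, n_subtrees=10),
    "pd-like": SyntheticNeuronSpec(
        label="pd-like", n_axons=1, n_subtrees=6, tips_per_subtree=(2, 6)
    ),
}


# --------------------------------------------------------- scrambled twin

def scrambled_twin(
    geometry: NeuronGeometry, ground_truth: GroundTruth, seed: int = 0
) -> tuple[NeuronGeometry, GroundTruth]:
    """Re-assign tip coordinates randomly across subtree fields.

    The permuted neuron keeps its topology and per-subtree tip counts but
    loses the spatial tiling, so the tiling bootstrap should *not* reject
    the null on it (a calibration control).
    """
    rng = np.random.default_rng(seed)
    tip_ids = [t for sub in ground_truth.subtree_tip_ids for t in sub]
    coords = np.array([geometry.position(t) for t in tip_ids])
    perm = rng.permutation(len(tip_ids))
    new_pos = {tip_ids[i]: coords[perm[i]] for i in range(len(tip_ids))}
    nodes = [
        SkeletonNode(
            n.node_id,
            new_pos.get(n.node_id, n.position),
            n.radius,
            n.parent_id,
        )
        for n in geometry.nodes.values()
    ]
    twin = NeuronGeometry(
        nodes,
        label=geometry.label + "_scrambled",
        cell_type=geometry.cell_type,
        merge_zero_edges=False,
    )
    # re-derive axon segments by matching terminal ends
    axon_ends = {
        s.end for s in geometry.segments if s.segment_id in geometry.axon_segment_ids
    }
    twin.tag_axon_segments(
        [s.segment_id for s in twin.segments if s.end in axon_ends]
    )
    return twin, ground_truth
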