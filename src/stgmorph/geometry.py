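"""Core skeleton geometry: nodes, segments, and the rooted neuron tree.

Everything downstream (morphometrics, subtree analysis, MST comparison)
consumes :class:`NeuronGeometry`, a rooted acyclic tree of 3D nodes in µm
with optional per-node radii, a tagged soma (the root), and axon segments
tagged at the segment level.

STG neurons are unipolar: the soma sits apart from the neuropil and joins
the arbor through a single primary neurite, so the root is the soma and
"terminating tips" are leaves that are neither the soma nor the end of a
tagged axon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CELL_TYPES = ("GM", "LG", "LP", "PD", "synthetic", "other")


class SkeletonError(Exception):
    """Base class for skeleton parsing/validation failures."""


class SkeletonFormatError(SkeletonError):
    """Malformed input text (bad row, unknown reference, duplicate id)."""


class SkeletonStructureError(SkeletonError):
    """Text parsed but the graph is not a valid rooted tree."""


@dataclass(frozen=True)
class SkeletonNode:
    """A single traced point.

    Parameters
    ----------
    node_id : int
        Arbitrary label; no ordering semantics.
    position : ndarray shape (3,)
        Coordinates in µm.
    radius : float or None
        Radius in µm; ``None`` when the tracer recorded no thickness.
    parent_id : int or None
        ``None`` marks the root (the soma).
    """

    node_id: int
    position: np.ndarray
    radius: float | None
    parent_id: int | None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SkeletonFormatError(
                f"node {self.node_id}: position must be 3 finite coordinates"
            )
        object.__setattr__(self, "position", pos)
        if self.radius is not None and not (self.radius > 0):
            raise SkeletonFormatError(
                f"node {self.node_id}: radius must be > 0, got {self.radius}"
            )


@dataclass(frozen=True)
class Segment:
    """A maximal unbranched chain of nodes.

    Interior nodes have exactly one child: topological events (the root,
    branch points, leaves) occur only at segment ends.  ``nodes[0]`` is the
    proximal end and is shared with the parent segment.
    """

    segment_id: int
    node_ids: tuple[int, ...]
    length: float

    @property
    def start(self) -> int:
        return self.node_ids[0]

    @property
    def end(self) -> int:
        return self.node_ids[-1]


@dataclass
class ValidationFinding:
    kind: str  # "cycle" | "disconnected" | "multiple_roots" | "bad_radius" | ...
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, kind: str, message: str) -> None:
        self.findings.append(ValidationFinding(kind, message))

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [{"kind": f.kind, "message": f.message} for f in self.findings],
        }


class NeuronGeometry:
    """Rooted acyclic tree of 3D nodes; the substrate of every analysis.

    Parameters
    ----------
    nodes : iterable of SkeletonNode
    soma_node_id : int, optional
        Defaults to the unique root (node with no parent).
    label : str
        Neuron name, e.g. ``"GM2"``.
    cell_type : str
        One of ``GM, LG, LP, PD, synthetic, other``.
    node_types : mapping node_id -> int, optional
        SWC structure codes kept for round-tripping (1 soma, 2 axon).
    merge_zero_edges : bool
        Merge duplicate consecutive nodes (tracer artifacts) with a warning.
    check : bool
        Raise on structural violations; set False to build a deliberately
        broken geometry and inspect it with :func:`validate`.
    """

    def __init__(
        self,
        nodes: Iterable[SkeletonNode],
        soma_node_id: int | None = None,
        label: str = "",
        cell_type: str = "other",
        node_types: Mapping[int, int] | None = None,
        merge_zero_edges: bool = True,
        check: bool = True,
    ):
        node_list = list(nodes)
        self.nodes: dict[int, SkeletonNode] = {}
        for n in node_list:
            if n.node_id in self.nodes:
                raise SkeletonFormatError(f"duplicate node id {n.node_id}")
            self.nodes[n.node_id] = n

        roots = [n.node_id for n in node_list if n.parent_id is None]
        if check:
            for n in node_list:
                if n.parent_id is not None and n.parent_id not in self.nodes:
                    raise SkeletonFormatError(
                        f"node {n.node_id} references missing parent {n.parent_id}"
                    )
            if len(roots) != 1:
                raise SkeletonStructureError(
                    f"expected exactly one root, found {len(roots)}"
                )
        self._roots = roots

        if merge_zero_edges and check:
            self._merge_duplicate_nodes()

        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id in self.children:
                self.children[n.parent_id].append(n.node_id)
        for kids in self.children.values():
            kids.sort()

        if soma_node_id is None:
            soma_node_id = self._roots[0] if self._roots else next(iter(self.nodes))
        if check and soma_node_id != self._roots[0]:
            raise SkeletonStructureError("soma must be the root node")
        self.soma_node_id = soma_node_id

        if cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        self.label = label
        self.cell_type = cell_type
        self.units = "um"
        self.node_types = dict(node_types) if node_types else {}
        self.axon_segment_ids: set[int] = set()

        if check and self._find_cycle_nodes():
            raise SkeletonStructureError("parent links form a cycle")

        self._segments: list[Segment] | None = None
        self._somatofugal: dict[int, float] | None = None

    # ------------------------------------------------------------------ build
    def _merge_duplicate_nodes(self) -> None:
        """Collapse children coincident with their parent (zero-length edges)."""
        merged: dict[int, int] = {}  # removed id -> surviving id
        by_parent: dict[int, list[SkeletonNode]] = {}
        for n in self.nodes.values():
            if n.parent_id is not None:
                by_parent.setdefault(n.parent_id, []).append(n)

        def resolve(nid: int) -> int:
            while nid in merged:
                nid = merged[nid]
            return nid

        for n in list(self.nodes.values()):
            if n.parent_id is None:
                continue
            parent = self.nodes.get(resolve(n.parent_id))
            if parent is not None and np.allclose(
                n.position, parent.position, atol=0.0
            ):
                merged[n.node_id] = parent.node_id
        if not merged:
            return
        logger.warning("merged %d duplicate consecutive node(s)", len(merged))
        for removed in merged:
            del self.nodes[removed]
        remapped = {}
        for nid, n in self.nodes.items():
            pid = n.parent_id
            if pid is not None and pid not in self.nodes:
                remapped[nid] = SkeletonNode(nid, n.position, n.radius, resolve(pid))
        self.nodes.update(remapped)

    def _find_cycle_nodes(self) -> set[int]:
        """Nodes whose parent chain never reaches a root."""
        state: dict[int, int] = {}  # 0 visiting, 1 safe, 2 cyclic
        bad: set[int] = set()
        for start in self.nodes:
            chain = []
            nid: int | None = start
            while nid is not None and nid in self.nodes and nid not in state:
                state[nid] = 0
                chain.append(nid)
                nid = self.nodes[nid].parent_id
            cyclic = nid is not None and nid in state and state.get(nid) != 1 and (
                nid in chain or state.get(nid) == 2
            )
            for c in chain:
                state[c] = 2 if cyclic else 1
            if cyclic:
                bad.update(chain)
        return bad

    # ------------------------------------------------------------- topology
    @property
    def root(self) -> int:
        return self.soma_node_id

    def position(self, node_id: int) -> np.ndarray:
        return self.nodes[node_id].position

    @property
    def leaves(self) -> list[int]:
        return [nid for nid, kids in self.children.items() if not kids]

    @property
    def branch_point_ids(self) -> list[int]:
        """Non-soma nodes with >= 2 children (the root is never a furcation)."""
        return [
            nid
            for nid, kids in self.children.items()
            if len(kids) >= 2 and nid != self.soma_node_id
        ]

    def edge_length(self, child_id: int) -> float:
        n = self.nodes[child_id]
        return float(np.linalg.norm(n.position - self.nodes[n.parent_id].position))

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from the soma to ``node_id`` inclusive."""
        out = []
        nid: int | None = node_id
        while nid is not None:
            out.append(nid)
            nid = self.nodes[nid].parent_id
        out.reverse()
        return out

    def somatofugal_distance(self, node_id: int) -> float:
        """Cumulative path length (µm) from the soma along the tree."""
        if self._somatofugal is None:
            dist = {self.soma_node_id: 0.0}
            stack = [self.soma_node_id]
            while stack:
                nid = stack.pop()
                for c in self.children[nid]:
                    dist[c] = dist[nid] + self.edge_length(c)
                    stack.append(c)
            self._somatofugal = dist
        return self._somatofugal[node_id]

    def descendants(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            for c in self.children[nid]:
                out.append(c)
                stack.append(c)
        return out

    # ------------------------------------------------------------- segments
    @property
    def segments(self) -> list[Segment]:
        """Maximal unbranched chains, derived deterministically by DFS."""
        if self._segments is None:
            segs: list[Segment] = []
            stack = [
                (self.soma_node_id, c) for c in reversed(self.children[self.soma_node_id])
            ]
            while stack:
                start, first = stack.pop()
                chain = [start, first]
                cur = first
                while len(self.children[cur]) == 1:
                    cur = self.children[cur][0]
                    chain.append(cur)
                length = sum(self.edge_length(c) for c in chain[1:])
                segs.append(Segment(len(segs), tuple(chain), length))
                for c in reversed(self.children[cur]):
                    stack.append((cur, c))
            self._segments = segs
        return self._segments

    @property
    def segment_by_end(self) -> dict[int, Segment]:
        return {s.end: s for s in self.segments}

    @property
    def terminal_segment_ids(self) -> list[int]:
        leaf = set(self.leaves)
        return [s.segment_id for s in self.segments if s.end in leaf]

    # ----------------------------------------------------------------- axons
    def tag_axon_segments(self, segment_ids: Iterable[int]) -> None:
        term = set(self.terminal_segment_ids)
        for sid in segment_ids:
            if sid not in term:
                raise ValueError(
                    f"segment {sid} is not a terminal filament; axons must end at a leaf"
                )
            self.axon_segment_ids.add(sid)

    @property
    def axon_node_ids(self) -> set[int]:
        """Nodes strictly inside axon segments (the shared start node excluded)."""
        out: set[int] = set()
        for s in self.segments:
            if s.segment_id in self.axon_segment_ids:
                out.update(s.node_ids[1:])
        return out

    @property
    def terminating_tips(self) -> list[int]:
        """Leaves that are neither the soma nor an axon terminal."""
        axon = self.axon_node_ids
        return [
            nid for nid in self.leaves if nid != self.soma_node_id and nid not in axon
        ]

    # ------------------------------------------------------------------ misc
    def total_cable(self, exclude_axons: bool = False) -> float:
        skip = self.axon_node_ids if exclude_axons else set()
        return sum(
            self.edge_length(nid)
            for nid, n in self.nodes.items()
            if n.parent_id is not None and nid not in skip
        )

    def coordinates(self, node_ids: Sequence[int] | None = None) -> np.ndarray:
        if node_ids is None:
            node_ids = sorted(self.nodes)
        return np.array([self.nodes[nid].position for nid in node_ids], dtype=float)

    @property
    def has_radii(self) -> bool:
        return all(n.radius is not None for n in self.nodes.values())

    def n_nodes(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<NeuronGeometry {self.label or 'unnamed'} ({self.cell_type}): "
            f"{len(self.nodes)} nodes, {len(self.segments)} segments, "
            f"{len(self.terminating_tips)} tips>"
        )


def validate(geometry: NeuronGeometry) -> ValidationReport:
    """Report violations of the tree invariants; empty report <=> valid.

    Checks: single root, acyclicity, connectivity, positive radii,
    axon segments terminating at leaves.  Report-only; never raises.
    """
    report = ValidationReport()
    roots = [nid for nid, n in geometry.nodes.items() if n.parent_id is None]
    if len(roots) == 0:
        report.add("no_root", "no root node (every node has a parent)")
    elif len(roots) > 1:
        report.add("multiple_roots", f"{len(roots)} roots found: {sorted(roots)}")

    cyclic = geometry._find_cycle_nodes()
    if cyclic:
        report.add("cycle", f"parent links form a cycle through {sorted(cyclic)[:5]}")

    for nid, n in geometry.nodes.items():
        if n.parent_id is not None and n.parent_id not in geometry.nodes:
            report.add("orphan", f"node {nid} references missing parent {n.parent_id}")

    # connectivity: every node must reach the soma through parent links
    if not cyclic and len(roots) >= 1:
        reachable = {geometry.soma_node_id}
        stack = [geometry.soma_node_id]
        while stack:
            for c in geometry.children.get(stack.pop(), []):
                reachable.add(c)
                stack.append(c)
        stray = set(geometry.nodes) - reachable
        if stray:
            report.add(
                "disconnected",
                f"{len(stray)} node(s) not connected to the soma, e.g. {sorted(stray)[:5]}",
            )

    for nid, n in geometry.nodes.items():
        if n.radius is not None and not (n.radius > 0):
            report.add("bad_radius", f"node {nid} has non-positive radius {n.radius}")

    if not cyclic:
        term = set(geometry.terminal_segment_ids)
        for sid in geometry.axon_segment_ids:
            if sid not in term:
                report.add("axon_not_terminal", f"axon segment {sid} does not end at a leaf")
    return report


@dataclass
class SomaPositionSet:
    """Per-preparation soma coordinates with the neuropil center, in µm.

    Orientation convention (anterior nerve up, posterior nerve down) is a
    metadata flag only; no rotation is computed.
    """

    soma_positions: dict[str, dict[str, np.ndarray]]  # prep -> label -> xy(z)
    neuropil_centers: dict[str, np.ndarray]  # prep -> center
    oriented_anterior_up: bool = True

    def normalized(self) -> "SomaPositionSet":
        """Translate each preparation so its neuropil center is at the origin."""
        out_pos: dict[str, dict[str, np.ndarray]] = {}
        out_ctr: dict[str, np.ndarray] = {}
        for prep, somata in self.soma_positions.items():
            if prep not in self.neuropil_centers:
                raise ValueError(f"preparation {prep!r} has no neuropil center")
            ctr = np.asarray(self.neuropil_centers[prep], dtype=float)
            out_pos[prep] = {
                label: np.asarray(p, dtype=float) - ctr for label, p in somata.items()
            }
            out_ctr[prep] = ctr - ctr
        return SomaPositionSet(out_pos, out_ctr, self.oriented_anterior_up)


def normalize_soma_positions(position_set: SomaPositionSet) -> SomaPositionSet:
    """Center each preparation's soma coordinates on its neuropil center."""
    return position_set.normalized()


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(math.dist(tuple(a), tuple(b)))
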