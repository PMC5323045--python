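"""Read and write skeletal reconstructions (SWC and the skeleton hoc dialect).

SWC is the 7-column exchange format (id, type, x, y, z, radius, parent);
hoc is the sectioned format the tracing tools exported: ``create`` section
declarations, ``pt3dadd(x, y, z, diam)`` point statements, and ``connect``
statements linking sections.  Only that skeleton subset of hoc is
supported; any other statement is ignored with a logged warning.

All coordinates are µm; no unit inference is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .geometry import (
    NeuronGeometry,
    SkeletonFormatError,
    SkeletonNode,
    SkeletonStructureError,
)

logger = logging.getLogger(__name__)

SWC_SOMA = 1
SWC_AXON = 2
SWC_NEURITE = 3


def parse_swc(text: str, label: str = "", cell_type: str = "other") -> NeuronGeometry:
    """Parse 7-column SWC text into a validated :class:`NeuronGeometry`.

    Type 1 marks the soma, type 2 the axon(s); any other type is a plain
    neurite.  A non-positive radius is treated as "radius not recorded".
    Terminal chains of type-2 nodes are tagged as axon segments.
    """
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SkeletonFormatError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SkeletonFormatError(f"SWC line {lineno}: {exc}") from exc
        if nid in seen:
            raise SkeletonFormatError(f"SWC line {lineno}: duplicate node id {nid}")
        seen.add(nid)
        rows.append((nid, ntype, x, y, z, r, parent))

    if not rows:
        raise SkeletonFormatError("empty SWC file")

    ids = {r[0] for r in rows}
    for nid, _, _, _, _, _, parent in rows:
        if parent != -1 and parent not in ids:
            raise SkeletonFormatError(
                f"node {nid} references parent {parent} absent from the file"
            )

    nodes = []
    types: dict[int, int] = {}
    for nid, ntype, x, y, z, r, parent in rows:
        radius = r if r > 0 else None
        if r <= 0 and r != -1.0:
            logger.warning("node %d: non-positive radius %g treated as absent", nid, r)
        nodes.append(SkeletonNode(nid, np.array([x, y, z]), radius, None if parent == -1 else parent))
        types[nid] = ntype

    roots = [n.node_id for n in nodes if n.parent_id is None]
    if len(roots) > 1:
        raise SkeletonStructureError(f"SWC has {len(roots)} roots; expected 1")

    geom = NeuronGeometry(nodes, label=label, cell_type=cell_type, node_types=types)

    soma_candidates = [nid for nid, t in types.items() if t == SWC_SOMA]
    if not soma_candidates:
        logger.warning("no type-1 (soma) node; using the root as soma")
    elif geom.soma_node_id not in soma_candidates:
        # soma = the type-1 node closest (by path) to the root
        best = min(soma_candidates, key=lambda nid: len(geom.path_to_root(nid)))
        if best != geom.soma_node_id:
            logger.warning(
                "type-1 node %d is not the root %d; root kept as soma", best, geom.soma_node_id
            )

    # terminal segments made entirely of axon-typed nodes -> axon segments
    axon_sids = [
        s.segment_id
        for s in geom.segments
        if s.segment_id in set(geom.terminal_segment_ids)
        and all(types.get(nid) == SWC_AXON for nid in s.node_ids[1:])
    ]
    if axon_sids:
        geom.tag_axon_segments(axon_sids)
    return geom


def write_swc(geometry: NeuronGeometry) -> str:
    """Serialize to standard SWC: soma as id 1, parents before children.

    Axon segment nodes are emitted as type 2; a missing radius is written
    as ``-1`` (readers of this module round-trip it back to "absent").
    """
    from .geometry import validate as _validate

    report = _validate(geometry)
    if not report.ok:
        raise SkeletonStructureError(
            "refusing to serialize invalid geometry: "
            + "; ".join(f.message for f in report.findings)
        )

    axon_nodes = geometry.axon_node_ids
    order: list[int] = []
    stack = [geometry.soma_node_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        for c in reversed(geometry.children[nid]):
            stack.append(c)
    new_id = {nid: i + 1 for i, nid in enumerate(order)}

    lines = ["# id type x y z radius parent"]
    for nid in order:
        n = geometry.nodes[nid]
        if nid == geometry.soma_node_id:
            ntype = SWC_SOMA
        elif nid in axon_nodes:
            ntype = SWC_AXON
        else:
            ntype = SWC_NEURITE
        r = n.radius if n.radius is not None else -1.0
        parent = -1 if n.parent_id is None else new_id[n.parent_id]
        x, y, z = (float(v) for v in n.position)
        # repr gives the shortest decimal that round-trips the float exactly
        lines.append(
            f"{new_id[nid]} {ntype} {x!r} {y!r} {z!r} {float(r)!r} {parent}"
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------- hoc

_CREATE_RE = re.compile(r"^\s*create\s+(.*)$")
_PT3DADD_RE = re.compile(r"pt3dadd\s*\(\s*([^)]*)\)")
_CONNECT_RE = re.compile(
    r"^\s*connect\s+([\w\[\]]+)\s*\(\s*([\d.]+)\s*\)\s*,\s*([\w\[\]]+)\s*(?:\(\s*([\d.]+)\s*\))?"
)
_ACCESS_RE = re.compile(r"^\s*access\s+([\w\[\]]+)")
_BLOCK_RE = re.compile(r"^\s*([\w\[\]]+)\s*\{")


@dataclass
class _HocSection:
    name: str
    points: list[tuple[float, float, float, float]]  # x y z diam
    parent: str | None = None
    parent_pos: float = 1.0


def parse_hoc(text: str, label: str = "", cell_type: str = "other") -> NeuronGeometry:
    """Parse skeleton hoc text into a validated :class:`NeuronGeometry`.

    Each section becomes one or more derived segments; diameters are halved
    to radii; ``connect child(0), parent(pos)`` attaches the child's 0-end
    to the parent's 0- or 1-end (pos rounded to the nearer end).  Loops in
    the connect graph are a structure error.
    """
    sections: dict[str, _HocSection] = {}
    current: str | None = None
    depth = 0

    def expand_create(spec: str) -> list[str]:
        names = []
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            m = re.match(r"^(\w+)\[(\d+)\]$", token)
            if m:
                base, n = m.group(1), int(m.group(2))
                names.extend(f"{base}[{i}]" for i in range(n))
            else:
                names.append(token)
        return names

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        m = _CREATE_RE.match(line)
        if m:
            for name in expand_create(m.group(1)):
                sections.setdefault(name, _HocSection(name, []))
            continue
        m = _CONNECT_RE.match(line)
        if m:
            child, child_pos, parent = m.group(1), float(m.group(2)), m.group(3)
            parent_pos = float(m.group(4)) if m.group(4) is not None else 1.0
            for name in (child, parent):
                if name not in sections:
                    raise SkeletonFormatError(
                        f"hoc line {lineno}: connect references unknown section {name!r}"
                    )
            if child_pos > 0.5:
                # "connect child(1), parent(pos)": swap orientation by treating
                # the parent as attaching at the child's far end is not part of
                # the skeleton dialect; warn and attach the 0-end regardless.
                logger.warning("hoc line %d: child attach position %g; using 0-end", lineno, child_pos)
            sections[child].parent = parent
            sections[child].parent_pos = parent_pos
            continue
        m = _ACCESS_RE.match(line)
        if m:
            name = m.group(1)
            sections.setdefault(name, _HocSection(name, []))
            current = name
            continue
        m = _BLOCK_RE.match(line)
        if m and m.group(1) in sections:
            current = m.group(1)
            depth += 1
            line = line.split("{", 1)[1]
        if "}" in line:
            depth = max(0, depth - line.count("}"))
            if depth == 0:
                pass  # keep `current` for bare pt3dadd after the block
        for pm in _PT3DADD_RE.finditer(line):
            vals = [float(v) for v in pm.group(1).replace(",", " ").split()]
            if len(vals) != 4:
                raise SkeletonFormatError(
                    f"hoc line {lineno}: pt3dadd needs 4 values, got {len(vals)}"
                )
            if current is None:
                raise SkeletonFormatError(
                    f"hoc line {lineno}: pt3dadd outside any section"
                )
            sections[current].points.append(tuple(vals))
        if not any(
            (m_ is not None)
            for m_ in (
                _CREATE_RE.match(line),
                _PT3DADD_RE.search(line),
                _BLOCK_RE.match(line),
            )
        ) and line not in ("}",) and "pt3dclear" not in line:
            if not _PT3DADD_RE.search(raw):
                logger.debug("hoc line %d ignored: %s", lineno, raw.strip())

    sections = {k: s for k, s in sections.items() if s.points}
    if not sections:
        raise SkeletonFormatError("hoc file contains no pt3dadd points")

    # detect connect cycles (tracers were instructed to avoid loops)
    for name in sections:
        seen = {name}
        cur = sections[name].parent
        while cur is not None:
            if cur in seen:
                raise SkeletonStructureError(f"connect statements form a loop at {cur!r}")
            seen.add(cur)
            cur = sections[cur].parent if cur in sections else None

    roots = [s for s in sections.values() if s.parent is None or s.parent not in sections]
    if len(roots) != 1:
        raise SkeletonStructureError(f"hoc has {len(roots)} root sections; expected 1")

    # soma section: name containing 'soma', else the root section
    soma_sec = next((s for s in sections.values() if "soma" in s.name.lower()), roots[0])

    nodes: list[SkeletonNode] = []
    first_id: dict[str, int] = {}
    last_id: dict[str, int] = {}
    next_id = 1

    def emit(section: _HocSection, parent_node: int | None) -> None:
        nonlocal next_id
        prev = parent_node
        for i, (x, y, z, diam) in enumerate(section.points):
            radius = diam / 2.0 if diam > 0 else None
            nodes.append(SkeletonNode(next_id, np.array([x, y, z]), radius, prev))
            if i == 0:
                first_id[section.name] = next_id
            prev = next_id
            next_id += 1
        last_id[section.name] = prev

    # emit in dependency order (parents first)
    emitted: set[str] = set()
    order: list[_HocSection] = []

    def visit(sec: _HocSection) -> None:
        if sec.name in emitted:
            return
        if sec.parent in sections:
            visit(sections[sec.parent])
        emitted.add(sec.name)
        order.append(sec)

    for sec in sections.values():
        visit(sec)
    for sec in order:
        if sec.parent in sections:
            attach = last_id[sec.parent] if sec.parent_pos >= 0.5 else first_id[sec.parent]
        else:
            attach = None
        emit(sec, attach)

    geom = NeuronGeometry(nodes, label=label, cell_type=cell_type)
    # soma: remap if the soma section's first surviving node is not the root
    soma_first = first_id.get(soma_sec.name)
    if soma_first is not None and soma_first in geom.nodes and soma_first != geom.soma_node_id:
        logger.warning("soma section is not the root section; root kept as tree root")
    return geom


def tag_axons(
    geometry: NeuronGeometry,
    manual_ids: list[int] | None = None,
    min_unbranched_length: float = 20.0,
    auto_tag: bool = False,
) -> dict:
    """Tag axon segments and report auto-detected candidates.

    Axons in these reconstructions were manually selected terminal filaments
    that do not branch for at least ``min_unbranched_length`` µm (default
    20 µm).  Terminal segments at least that long are *reported* as
    candidates; only ``manual_ids`` (always tagged, regardless of length)
    and — when ``auto_tag`` is set — the candidates are actually tagged.

    Returns a dict with ``tagged`` and ``candidates`` segment id lists.
    """
    manual_ids = list(manual_ids or [])
    terminal = set(geometry.terminal_segment_ids)
    for sid in manual_ids:
        if sid not in terminal:
            raise ValueError(f"manual axon id {sid} is not a terminal filament")

    candidates = [
        s.segment_id
        for s in geometry.segments
        if s.segment_id in terminal and s.length >= min_unbranched_length
    ]
    to_tag = set(manual_ids)
    if auto_tag:
        to_tag.update(candidates)
    geometry.tag_axon_segments(to_tag)
    return {"tagged": sorted(to_tag), "candidates": candidates}
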