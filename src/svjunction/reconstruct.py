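"""Fragment graphs, derivative-structure enumeration and duplication calls.

The reference span is partitioned at every breakpoint and copy-number
boundary into fragment nodes weighted by the rearranged homolog's copy
count; junction edges connect oriented fragment ends.  Candidate
derivatives are exhaustive walks that consume every node exactly its copy
count and every junction edge exactly once, from the left span terminus to
the right one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    FORWARD,
    REVERSE,
    RETAINED,
    DUPLICATE_COPY,
    BreakpointSide,
    CopyNumberSegment,
    DerivativeStructure,
    JunctionRecord,
    SegmentUse,
)

LEFT = "L"
RIGHT = "R"

IDENTICAL = "identical"
COMPATIBLE = "compatible"
DISTINCT = "distinct"

TANDEM = "tandem"
INTERSPERSED = "interspersed"


class GraphError(ValueError):
    pass


class InfeasibleWalkError(RuntimeError):
    """No walk satisfies the node copy counts and junction edges."""


@dataclass(frozen=True)
class FragmentNode:
    contig: str
    start: int
    end: int
    count: int  # copies on the rearranged homolog

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionEdge:
    node_a: int
    end_a: str
    node_b: int
    end_b: str
    junction: Optional[JunctionRecord] = None


@dataclass
class FragmentGraph:
    contig: str
    span: tuple[int, int]
    nodes: list[FragmentNode]
    edges: list[JunctionEdge]
    half_edges: list[tuple[int, str, JunctionRecord]] = field(default_factory=list)

    def to_dot(self) -> str:
        lines = ["graph fragments {"]
        for i, n in enumerate(self.nodes):
            lines.append(f'  n{i} [label="{n.contig}:{n.start}-{n.end} x{n.count}"];')
        for e in self.edges:
            lines.append(f"  n{e.node_a} -- n{e.node_b} "
                         f'[label="{e.end_a}-{e.end_b}"];')
        for i, (node, end, _) in enumerate(self.half_edges):
            lines.append(f'  h{i} [shape=circle,label="?"];')
            lines.append(f"  n{node} -- h{i} [style=dashed];")
        lines.append("}")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        lines = ["#kind\ta\tb\tdetail"]
        for i, n in enumerate(self.nodes):
            lines.append(f"S\tn{i}\t{n.contig}:{n.start}-{n.end}\tcount={n.count}")
        for e in self.edges:
            lines.append(f"L\tn{e.node_a}{e.end_a}\tn{e.node_b}{e.end_b}\tjunction")
        for node, end, _ in self.half_edges:
            lines.append(f"L\tn{node}{end}\t.\thalf")
        return "\n".join(lines)


def _cut_positions(side: BreakpointSide, role: str) -> int:
    """Reference boundary (start of the right-hand atomic fragment) for a side."""
    if role == "left":
        return side.position + 1 if side.orientation == FORWARD else side.position
    return side.position if side.orientation == FORWARD else side.position + 1


def build_fragment_graph(
    junctions: Sequence[JunctionRecord],
    cn: Sequence[CopyNumberSegment],
    span: tuple[int, int],
    contig: Optional[str] = None,
    diploid_state: int = 2,
    tol: int = 0,
) -> FragmentGraph:
    """Partition ``span`` at breakpoints/CN boundaries and attach junction edges.

    One-sided junctions become half-edges rather than being discarded.
    """
    sides = []
    for j in junctions:
        if j.side1 is not None:
            sides.append((j.side1, "left"))
        if j.side2 is not None:
            sides.append((j.side2, "right"))
    if contig is None:
        contigs = {s.contig for s, _ in sides} or {seg.contig for seg in cn}
        if len(contigs) != 1:
            raise GraphError(f"expected a single contig, got {sorted(contigs)}")
        contig = contigs.pop()
    lo, hi = span
    for side, _ in sides:
        if side.contig == contig and not (lo <= side.position <= hi):
            raise GraphError(f"junction side {side} outside span {span}")

    bounds = {lo, hi + 1}
    for side, role in sides:
        bounds.add(_cut_positions(side, role))
    for seg in cn:
        if seg.contig == contig:
            bounds.add(max(lo, seg.start))
            bounds.add(min(hi + 1, seg.end + 1))
    cuts = sorted(b for b in bounds if lo <= b <= hi + 1)

    def state_at(pos: int) -> int:
        for seg in cn:
            if seg.contig == contig and seg.start <= pos <= seg.end:
                return seg.state
        return diploid_state

    nodes = [
        FragmentNode(contig, a, b - 1, max(0, state_at(a) - 1))
        for a, b in zip(cuts, cuts[1:])
    ]

    starts = {n.start: i for i, n in enumerate(nodes)}
    ends = {n.end: i for i, n in enumerate(nodes)}

    def attach(side: BreakpointSide, role: str) -> tuple[int, str]:
        if role == "left":
            wants_end = side.orientation == FORWARD
        else:
            wants_end = side.orientation == REVERSE
        table = ends if wants_end else starts
        for delta in range(tol + 1):
            for pos in (side.position - delta, side.position + delta):
                if pos in table:
                    return table[pos], RIGHT if wants_end else LEFT
        raise GraphError(f"no fragment boundary matches side {side}")

    edges: list[JunctionEdge] = []
    half_edges: list[tuple[int, str, JunctionRecord]] = []
    for j in junctions:
        if j.side1 is not None and j.side2 is not None:
            na, ea = attach(j.side1, "left")
            nb, eb = attach(j.side2, "right")
            edges.append(JunctionEdge(na, ea, nb, eb, j))
        elif j.side1 is not None:
            na, ea = attach(j.side1, "left")
            half_edges.append((na, ea, j))
        elif j.side2 is not None:
            nb, eb = attach(j.side2, "right")
            half_edges.append((nb, eb, j))
    return FragmentGraph(contig, span, nodes, edges, half_edges)


# ---------------------------------------------------------------------------
# structure enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(
    graph: FragmentGraph,
    max_solutions: int = 64,
    name: str = "der",
) -> list[DerivativeStructure]:
    """All terminus-to-terminus walks honouring copy counts and junction edges.

    Deterministically ordered (lexicographic by segment sequence); a
    uniquely-determined rearrangement yields exactly one structure.
    """
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        raise GraphError("empty graph")
    counts = [node.count for node in nodes]
    if counts[0] < 1 or counts[-1] < 1:
        raise InfeasibleWalkError("a span terminus has copy count 0")

    incident: dict[tuple[int, str], list[int]] = {}
    for idx, e in enumerate(graph.edges):
        incident.setdefault((e.node_a, e.end_a), []).append(idx)
        incident.setdefault((e.node_b, e.end_b), []).append(idx)

    solutions: list[tuple] = []
    seen: set[tuple] = set()

    def visit_orientation(entered: str) -> str:
        return FORWARD if entered == LEFT else REVERSE

    def dfs(node: int, entered: str, remaining: list[int], edges_left: set[int],
            path: tuple) -> None:
        if len(solutions) >= max_solutions:
            return
        exit_end = RIGHT if entered == LEFT else LEFT
        at_terminus = node == n - 1 and exit_end == RIGHT
        if at_terminus and not edges_left and not any(remaining):
            if path not in seen:
                seen.add(path)
                solutions.append(path)
            return
        # junction edges from the exit end
        for idx in incident.get((node, exit_end), ()):
            if idx not in edges_left:
                continue
            e = graph.edges[idx]
            if (e.node_a, e.end_a) == (node, exit_end):
                nxt, nxt_end = e.node_b, e.end_b
            else:
                nxt, nxt_end = e.node_a, e.end_a
            if remaining[nxt] <= 0:
                continue
            remaining[nxt] -= 1
            edges_left.discard(idx)
            dfs(nxt, nxt_end, remaining, edges_left,
                path + ((nxt, visit_orientation(nxt_end)),))
            edges_left.add(idx)
            remaining[nxt] += 1
        # reference adjacency
        nxt = node + 1 if exit_end == RIGHT else node - 1
        if 0 <= nxt < n and remaining[nxt] > 0:
            nxt_end = LEFT if exit_end == RIGHT else RIGHT
            remaining[nxt] -= 1
            dfs(nxt, nxt_end, remaining, edges_left,
                path + ((nxt, visit_orientation(nxt_end)),))
            remaining[nxt] += 1

    remaining = list(counts)
    remaining[0] -= 1
    dfs(0, LEFT, remaining, set(range(len(graph.edges))),
        ((0, FORWARD),))

    if not solutions:
        bottleneck = next((i for i, c in enumerate(counts) if c == 0 and 0 < i < n - 1),
                          None)
        raise InfeasibleWalkError(
            f"no consistent walk (check node {bottleneck} / junction edges)")

    structures = []
    for path in sorted(solutions):
        first_visit: set[int] = set()
        segs = []
        for node_idx, orientation in path:
            node = nodes[node_idx]
            provenance = RETAINED if node_idx not in first_visit else DUPLICATE_COPY
            first_visit.add(node_idx)
            segs.append(SegmentUse(node.contig, node.start, node.end,
                                   orientation, provenance))
        structures.append(DerivativeStructure(name, segs))
    return structures


def normalize_structure(structure: DerivativeStructure) -> tuple:
    """Canonical form: reference-adjacent same-orientation runs merged.

    Two structures describe the same derivative iff their normal forms are
    equal, regardless of how finely the reference was fragmented.
    """
    merged: list[list] = []
    for seg in structure.segments:
        if merged:
            prev = merged[-1]
            if prev[0] == seg.contig and prev[3] == seg.orientation:
                if seg.orientation == FORWARD and seg.start == prev[2] + 1:
                    prev[2] = seg.end
                    continue
                if seg.orientation == REVERSE and seg.end == prev[1] - 1:
                    prev[1] = seg.start
                    continue
        merged.append([seg.contig, seg.start, seg.end, seg.orientation])
    return tuple(tuple(item) for item in merged)


# ---------------------------------------------------------------------------
# duplication architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationCall:
    contig: str
    start: int
    end: int
    architecture: str  # tandem | interspersed
    orientation: str  # FORWARD (direct) | REVERSE (inverted)
    adjacent_to_other_duplicate: bool


def _covered_fraction(target: SegmentUse, others: Iterable[SegmentUse]) -> float:
    events = []
    for s in others:
        if s.contig != target.contig:
            continue
        lo = max(s.start, target.start)
        hi = min(s.end, target.end)
        if lo <= hi:
            events.append((lo, hi))
    if not events:
        return 0.0
    events.sort()
    covered = 0
    cursor = None
    for lo, hi in events:
        if cursor is None or lo > cursor:
            covered += hi - lo + 1
            cursor = hi
        elif hi > cursor:
            covered += hi - cursor
            cursor = hi
    return covered / target.length


def classify_duplications(structure: DerivativeStructure,
                          min_cover: float = 0.5) -> list[DuplicationCall]:
    """Tandem/interspersed calls for every duplicated fragment in a structure.

    A ``duplicate_copy`` segment counts as a duplication only when its
    interval is still substantially present elsewhere in the derivative
    (a moved copy of a deleted fragment is copy-neutral, not a duplication).
    Tandem means the copy sits immediately adjacent to its template in
    direct orientation; everything else is interspersed.
    """
    segs = structure.segments
    calls: list[DuplicationCall] = []
    for i, seg in enumerate(segs):
        if seg.provenance == RETAINED:
            continue
        others = [s for k, s in enumerate(segs) if k != i]
        if _covered_fraction(seg, others) < min_cover:
            continue
        neighbors = [segs[k] for k in (i - 1, i + 1) if 0 <= k < len(segs)]
        tandem = seg.orientation == FORWARD and any(
            nb.contig == seg.contig and nb.start == seg.start and nb.end == seg.end
            and nb.orientation == FORWARD
            for nb in neighbors
        )
        adjacent_dup = any(nb.provenance != RETAINED for nb in neighbors)
        calls.append(DuplicationCall(
            seg.contig, seg.start, seg.end,
            TANDEM if tandem else INTERSPERSED,
            seg.orientation, adjacent_dup,
        ))
    return calls


def has_nested_deletion(structure: DerivativeStructure) -> bool:
    """True when a duplicate copy skips retained reference across a junction.

    Detects the descriptor signature of a duplication carrying a nested
    deletion: two derivative-adjacent forward segments, at least one a
    duplicate copy, whose junction skips a reference gap that is still
    present elsewhere in the derivative.
    """
    segs = structure.segments
    for a, b in zip(segs, segs[1:]):
        if a.contig != b.contig:
            continue
        if a.orientation != FORWARD or b.orientation != FORWARD:
            continue
        if a.provenance == RETAINED and b.provenance == RETAINED:
            continue
        gap = b.start - a.end - 1
        if gap <= 0:
            continue
        probe = SegmentUse(a.contig, a.end + 1, b.start - 1, FORWARD)
        others = [s for s in segs if s is not a and s is not b]
        if _covered_fraction(probe, others) > 0.5:
            return True
    return False


# ---------------------------------------------------------------------------
# structure-derived junctions / CN (fixture and simulator support)
# ---------------------------------------------------------------------------

def structure_implied_junctions(structure: DerivativeStructure,
                                case_id: str = "case") -> list[JunctionRecord]:
    """Junctions implied by non-reference-adjacent derivative neighbours."""
    out = []
    jid = 1
    for a, b in zip(structure.segments, structure.segments[1:]):
        reference_adjacent = (
            a.contig == b.contig
            and a.orientation == FORWARD and b.orientation == FORWARD
            and b.start == a.end + 1
        )
        if reference_adjacent:
            continue
        side1 = (BreakpointSide(a.contig, a.end, FORWARD)
                 if a.orientation == FORWARD
                 else BreakpointSide(a.contig, a.start, REVERSE))
        side2 = (BreakpointSide(b.contig, b.start, FORWARD)
                 if b.orientation == FORWARD
                 else BreakpointSide(b.contig, b.end, REVERSE))
        out.append(JunctionRecord(case_id, jid, side1, side2))
        jid += 1
    return out


def structure_cn(structure: DerivativeStructure, span: tuple[int, int],
                 contig: Optional[str] = None,
                 diploid_state: int = 2) -> list[CopyNumberSegment]:
    """Copy-number profile over ``span`` implied by a derivative structure."""
    if contig is None:
        contig = structure.contigs[0]
    lo, hi = span
    events: dict[int, int] = {}
    for s in structure.segments:
        if s.contig != contig:
            continue
        a, b = max(lo, s.start), min(hi, s.end)
        if a > b:
            continue
        events[a] = events.get(a, 0) + 1
        events[b + 1] = events.get(b + 1, 0) - 1
    cuts = sorted(set(events) | {lo, hi + 1})
    cuts = [c for c in cuts if lo <= c <= hi + 1]
    out: list[CopyNumberSegment] = []
    cover = 0
    for a, b in zip(cuts, cuts[1:]):
        cover += events.get(a, 0)
        state = diploid_state - 1 + cover
        if out and out[-1].state == state and out[-1].end + 1 == a:
            out[-1] = CopyNumberSegment(contig, out[-1].start, b - 1, state)
        else:
            out.append(CopyNumberSegment(contig, a, b - 1, state))
    return out


# ---------------------------------------------------------------------------
# junction comparison
# ---------------------------------------------------------------------------

def _sides_match(a: Optional[BreakpointSide], b: Optional[BreakpointSide],
                 tolerance: int) -> bool:
    if a is None or b is None:
        return a is b
    return (a.contig == b.contig
            and abs(a.position - b.position) <= tolerance
            and a.orientation == b.orientation)


def junction_equivalence(a: JunctionRecord, b: JunctionRecord,
                         tolerance: int = 5) -> str:
    """identical / compatible / distinct comparison of two junctions."""
    exact = _sides_match(a.side1, b.side1, 0) and _sides_match(a.side2, b.side2, 0)
    if exact:
        mh_ok = (a.microhomology_seq is None or b.microhomology_seq is None
                 or a.microhomology_seq == b.microhomology_seq)
        ins_a = None if a.insertion_blocks is None else "".join(
            blk.sequence for blk in a.insertion_blocks)
        ins_b = None if b.insertion_blocks is None else "".join(
            blk.sequence for blk in b.insertion_blocks)
        ins_ok = ins_a is None or ins_b is None or ins_a == ins_b
        if mh_ok and ins_ok:
            return IDENTICAL
    if (_sides_match(a.side1, b.side1, tolerance)
            and _sides_match(a.side2, b.side2, tolerance)):
        return COMPATIBLE
    return DISTINCT


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def structure_to_bed(structure: DerivativeStructure) -> str:
    """BED6 of segment uses in derivative order (0-based half-open)."""
    lines = []
    for i, seg in enumerate(structure.segments):
        lines.append("\t".join([
            seg.contig, str(seg.start - 1), str(seg.end),
            f"{structure.name}_seg{i}_{seg.provenance}", "0", seg.orientation,
        ]))
    return "\n".join(lines)
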