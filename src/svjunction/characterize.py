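"""Nucleotide-level characterization of breakpoint junctions from split reads.

Pipeline: split reads bridging a candidate junction are clustered into
:class:`SplitReadGroup` objects, assembled into a consensus, re-mapped onto
the reference with a built-in exact-seed anchor-and-extend aligner, and
resolved into :class:`~svjunction.core.JunctionRecord` objects carrying
microhomology, insertion decomposition and annotations.

Microhomology is defined by junction-shift ambiguity: the maximal run over
which the breakpoint can slide without changing the derivative sequence.
Reported placements are canonicalized by left-alignment.  ``N`` bases never
match.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .core import (
    FORWARD,
    REVERSE,
    MISSING,
    BreakpointSide,
    GenomeModel,
    InsertionBlock,
    JunctionRecord,
    base_at,
    flank,
    reverse_complement,
)
from .io.sam import SamRecord, read_parts

DEFAULT_MIN_ANCHOR = 20
DEFAULT_CLUSTER_TOL = 50
DEFAULT_MIN_SUPPORT = 2
DEFAULT_TEMPLATED_WINDOW = 100
DEFAULT_MIN_TEMPLATED = 10
DEFAULT_SNV_WINDOW = 1000


class MultiJunctionError(ValueError):
    """A consensus maps as more than two substantial segments."""


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

def _slide(genome: GenomeModel, side_a: BreakpointSide, side_b: BreakpointSide,
           role_a: str, role_b: str, off_a, off_b, max_scan: int) -> int:
    run = 0
    for j in range(1, max_scan + 1):
        a = base_at(genome, side_a, off_a(j), role_a)
        b = base_at(genome, side_b, off_b(j), role_b)
        if a is None or b is None or a == "N" or b == "N" or a != b:
            break
        run += 1
    return run


def compute_microhomology(
    genome: GenomeModel,
    side1: BreakpointSide,
    side2: BreakpointSide,
    max_scan: int = 500,
) -> tuple[int, str, BreakpointSide, BreakpointSide]:
    """Microhomology length/sequence and the canonical (left-aligned) sides.

    ``side1`` is the left (segment-ending) side, ``side2`` the right
    (segment-starting) side.  The breakpoint can slide one step right for
    every base where side1's reference continuation equals side2's retained
    flank, and one step left for every base where side1's retained flank
    equals side2's reference continuation; microhomology is the total slide
    range.  The canonical placement puts the junction at the left end.
    """
    # slide right: continuation past side1 vs retained start of side2
    right = _slide(genome, side1, side2, "left", "right",
                   lambda j: -(j - 1), lambda j: j, max_scan)
    # slide left: retained end of side1 vs continuation before side2
    left = _slide(genome, side1, side2, "left", "right",
                  lambda j: j, lambda j: -(j - 1), max_scan)
    mh = left + right
    sign1 = -1 if side1.orientation == FORWARD else +1
    sign2 = -1 if side2.orientation == FORWARD else +1
    canon1 = replace(side1, position=side1.position + sign1 * left)
    canon2 = replace(side2, position=side2.position + sign2 * left)
    if mh == 0:
        return 0, "", canon1, canon2
    seq = flank(genome, canon2, mh, role="right").sequence
    return mh, seq, canon1, canon2


# ---------------------------------------------------------------------------
# insertion decomposition
# ---------------------------------------------------------------------------

def _windows(genome: GenomeModel, sides: Iterable[BreakpointSide], window: int):
    """(sequence, contig, ref_start, strand) for +/- strands of each flank window."""
    out = []
    for side in sides:
        if side is None:
            continue
        length = genome.lengths[side.contig]
        lo = max(1, side.position - window)
        hi = min(length, side.position + window)
        seq = genome.sequence(side.contig, lo, hi)
        out.append((seq, side.contig, lo, FORWARD))
        out.append((reverse_complement(seq), side.contig, lo, REVERSE))
    return out


def _longest_prefix_match(fragment: str, windows) -> Optional[tuple[int, str, int, int, str]]:
    """Longest exact prefix of ``fragment`` found in any window, either strand."""
    best = None
    for seq, contig, ref_lo, strand in windows:
        n = len(seq)
        for j in range(n):
            if seq[j] != fragment[0]:
                continue
            m = 1
            limit = min(len(fragment), n - j)
            while m < limit and seq[j + m] == fragment[m]:
                m += 1
            if best is None or m > best[0]:
                if strand == FORWARD:
                    src = (contig, ref_lo + j, ref_lo + j + m - 1)
                else:
                    hi = ref_lo + n - 1
                    src = (contig, hi - (j + m - 1), hi - j)
                best = (m, src[0], src[1], src[2], strand)
    return best


def decompose_insertion(
    genome: GenomeModel,
    insert: str,
    side1: Optional[BreakpointSide],
    side2: Optional[BreakpointSide],
    window: int = DEFAULT_TEMPLATED_WINDOW,
    min_templated: int = DEFAULT_MIN_TEMPLATED,
) -> list[InsertionBlock]:
    """Greedy left-to-right cover of an insert by templated/non-templated blocks.

    Maximal exact matches (either strand) to the +/-``window`` flanks of both
    sides that reach ``min_templated`` become templated blocks with a source;
    uncovered stretches become non-templated blocks.
    """
    if window < min_templated:
        raise ConfigurationError("window smaller than min_templated")
    if not insert:
        return []
    windows = _windows(genome, (side1, side2), window)
    blocks: list[InsertionBlock] = []
    i = 0
    nt_start = None
    while i < len(insert):
        hit = _longest_prefix_match(insert[i:], windows) if windows else None
        if hit is not None and hit[0] >= min_templated:
            if nt_start is not None:
                blocks.append(InsertionBlock("non_templated", insert[nt_start:i]))
                nt_start = None
            m, contig, lo, hi, strand = hit
            blocks.append(
                InsertionBlock("templated", insert[i : i + m], contig, lo, hi, strand)
            )
            i += m
        else:
            if nt_start is None:
                nt_start = i
            i += 1
    if nt_start is not None:
        blocks.append(InsertionBlock("non_templated", insert[nt_start:]))
    return blocks


# ---------------------------------------------------------------------------
# built-in aligner (exact 31-mer seeds, exact extension)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    q_start: int  # 0-based inclusive on the query
    q_end: int
    contig: str
    r_start: int  # 1-based inclusive on the reference
    r_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start + 1


class GenomeIndex:
    """Exact k-mer index of a :class:`GenomeModel` for consensus re-mapping."""

    def __init__(self, genome: GenomeModel, k: int = 21, max_hits: int = 8):
        self.genome = genome
        self.k = k
        self.max_hits = max_hits
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                hits = self._index[kmer]
                if len(hits) <= max_hits:
                    hits.append((contig, i + 1))

    def align(self, query: str) -> list[LocalAlignment]:
        """All maximal exact local matches of ``query`` (both strands)."""
        k = self.k
        query = query.upper()
        found: dict[tuple, LocalAlignment] = {}
        for i in range(0, len(query) - k + 1):
            kmer = query[i : i + k]
            for strand, lookup in ((FORWARD, kmer), (REVERSE, reverse_complement(kmer))):
                hits = self._index.get(lookup, ())
                if len(hits) > self.max_hits:
                    continue
                for contig, pos in hits:
                    aln = self._extend(query, i, contig, pos, strand)
                    key = (aln.contig, aln.strand, aln.q_start, aln.r_start)
                    prev = found.get(key)
                    if prev is None or aln.length > prev.length:
                        found[key] = aln
        # prune alignments wholly contained in a longer one on the same diagonal
        alns = sorted(found.values(), key=lambda a: -a.length)
        kept: list[LocalAlignment] = []
        for a in alns:
            redundant = any(
                b.contig == a.contig and b.strand == a.strand
                and b.q_start <= a.q_start and a.q_end <= b.q_end
                and self._same_diagonal(a, b)
                for b in kept
            )
            if not redundant:
                kept.append(a)
        kept.sort(key=lambda a: (a.q_start, -a.length))
        return kept

    @staticmethod
    def _same_diagonal(a: LocalAlignment, b: LocalAlignment) -> bool:
        if a.strand == FORWARD:
            return a.r_start - a.q_start == b.r_start - b.q_start
        return a.r_end + a.q_start == b.r_end + b.q_start

    def _extend(self, query: str, q_i: int, contig: str, r_pos: int, strand: str) -> LocalAlignment:
        seq = self.genome.contigs[contig]
        k = self.k
        if strand == FORWARD:
            qs, rs = q_i, r_pos  # seed start (1-based ref)
            while qs > 0 and rs > 1 and query[qs - 1] == seq[rs - 2] != "N":
                qs -= 1
                rs -= 1
            qe, re_ = q_i + k - 1, r_pos + k - 1
            while qe + 1 < len(query) and re_ < len(seq) and query[qe + 1] == seq[re_] != "N":
                qe += 1
                re_ += 1
            return LocalAlignment(qs, qe, contig, rs, re_, FORWARD)
        # reverse: query matches revcomp(ref); query start maps to ref end
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        qs = q_i
        re_ = r_pos + k - 1  # ref end corresponds to query seed start
        while qs > 0 and re_ < len(seq) and query[qs - 1] == comp[seq[re_]] != "N":
            qs -= 1
            re_ += 1
        qe = q_i + k - 1
        rs = r_pos
        while qe + 1 < len(query) and rs > 1 and query[qe + 1] == comp[seq[rs - 2]] != "N":
            qe += 1
            rs -= 1
        return LocalAlignment(qs, qe, contig, rs, re_, REVERSE)


# ---------------------------------------------------------------------------
# split-read collection
# ---------------------------------------------------------------------------

def _flip_side(side: BreakpointSide) -> BreakpointSide:
    return replace(side, orientation=REVERSE if side.orientation == FORWARD else FORWARD)


def _side_key(side: BreakpointSide) -> tuple:
    return (side.contig, side.position, side.orientation)


@dataclass
class SplitReadGroup:
    """Split reads supporting one candidate oriented junction."""

    side1: BreakpointSide
    side2: BreakpointSide
    members: list[str] = field(default_factory=list)  # canonically oriented reads

    @property
    def support(self) -> int:
        return len(self.members)


def _junctions_from_parts(parts, read_seq):
    """Oriented side pairs (canonical) implied by consecutive read parts."""
    out = []
    parts = sorted(parts, key=lambda p: p[0])
    for left, right in zip(parts, parts[1:]):
        _, _, c1, rs1, re1, st1 = left
        _, _, c2, rs2, re2, st2 = right
        s1 = BreakpointSide(c1, re1 if st1 == FORWARD else rs1, st1)
        s2 = BreakpointSide(c2, rs2 if st2 == FORWARD else re2, st2)
        a = (_side_key(s1), _side_key(s2))
        b = (_side_key(_flip_side(s2)), _side_key(_flip_side(s1)))
        if b < a:
            out.append((_flip_side(s2), _flip_side(s1), reverse_complement(read_seq)))
        else:
            out.append((s1, s2, read_seq))
    return out


def collect_split_reads(
    alignments: Sequence[SamRecord],
    candidates: Optional[Sequence[tuple[str, int, int]]] = None,
    tol: int = DEFAULT_CLUSTER_TOL,
    min_support: int = DEFAULT_MIN_SUPPORT,
    candidate_pad: int = 1000,
) -> list[SplitReadGroup]:
    """Cluster SA-linked split reads into oriented junction groups.

    Reads whose primary and supplementary segments map to two loci are
    clustered by oriented side pair with positional tolerance ``tol``;
    groups below ``min_support`` are discarded.  With ``candidates``
    supplied, only groups inside the padded candidate regions survive.
    """
    skipped = 0
    observations = []  # (side1, side2, oriented_read)
    for rec in alignments:
        if rec.flag & 0x900:  # supplementary/secondary carry no new split info
            continue
        if rec.seq in ("*", "", None):
            skipped += 1
            continue
        parts = read_parts(rec)
        if len(parts) < 2:
            continue
        read_seq = reverse_complement(rec.seq) if rec.flag & 0x10 else rec.seq
        observations.extend(_junctions_from_parts(parts, read_seq))

    by_shape = defaultdict(list)
    for s1, s2, seq in observations:
        by_shape[(s1.contig, s1.orientation, s2.contig, s2.orientation)].append((s1, s2, seq))

    groups: list[SplitReadGroup] = []
    for shape, obs in sorted(by_shape.items()):
        obs.sort(key=lambda o: (o[0].position, o[1].position))
        current: Optional[SplitReadGroup] = None
        for s1, s2, seq in obs:
            if (current is not None
                    and abs(s1.position - current.side1.position) <= tol
                    and abs(s2.position - current.side2.position) <= tol):
                current.members.append(seq)
            else:
                current = SplitReadGroup(s1, s2, [seq])
                groups.append(current)

    groups = [g for g in groups if g.support >= min_support]
    if candidates is not None:
        padded = [(c, max(1, lo - candidate_pad), hi + candidate_pad)
                  for c, lo, hi in candidates]

        def inside(side: BreakpointSide) -> bool:
            return any(c == side.contig and lo <= side.position <= hi
                       for c, lo, hi in padded)

        groups = [g for g in groups if inside(g.side1) or inside(g.side2)]
    groups.sort(key=lambda g: (_side_key(g.side1), _side_key(g.side2)))
    collect_split_reads.last_skipped = skipped  # diagnostic counter
    return groups


# ---------------------------------------------------------------------------
# consensus assembly
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSequence:
    sequence: str
    support: list[int]
    contributing: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if len(self.support) != len(self.sequence):
            raise ValueError("support length != sequence length")
        if self.contributing < 1:
            raise ValueError("contributing reads must be >= 1")


_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _offset_by_kmers(seed: str, read: str, k: int) -> Optional[int]:
    index: dict[str, int] = {}
    for i in range(len(seed) - k + 1):
        index.setdefault(seed[i : i + k], i)
    votes: Counter = Counter()
    for i in range(len(read) - k + 1):
        j = index.get(read[i : i + k])
        if j is not None:
            votes[j - i] += 1
    if not votes:
        return None
    return votes.most_common(1)[0][0]


def _overlap_offset(consensus: str, read: str, min_overlap: int,
                    max_mismatch_frac: float = 0.1) -> Optional[tuple[int, int]]:
    best = None  # (matches, offset)
    for off in range(-(len(read) - min_overlap), len(consensus) - min_overlap + 1):
        lo = max(0, off)
        hi = min(len(consensus), off + len(read))
        ov = hi - lo
        if ov < min_overlap:
            continue
        mism = sum(1 for p in range(lo, hi) if consensus[p] != read[p - off])
        if mism > max(1, int(ov * max_mismatch_frac)):
            continue
        matches = ov - mism
        if best is None or matches > best[0]:
            best = (matches, off)
    if best is None:
        return None
    return best[1], best[0]


def build_consensus(
    group: SplitReadGroup,
    seed_k: int = 21,
    min_overlap: int = 20,
) -> ConsensusSequence:
    """Star alignment around a seed read, then greedy overlap merging.

    Reads are anchored to the seed by shared k-mers; reads without a shared
    k-mer are merged afterwards by best suffix-prefix overlap, preferring
    merges that maximize support and then length.  Columns are resolved by
    majority vote (ties by base order A<C<G<T).
    """
    members = list(group.members)
    if not members:
        raise ValueError("empty split-read group")
    seed = max(members, key=lambda s: (len(s), s))
    placed: list[tuple[int, str]] = []
    unplaced: list[str] = []
    for read in members:
        off = _offset_by_kmers(seed, read, seed_k)
        if off is None:
            unplaced.append(read)
        else:
            placed.append((off, read))

    def vote(columns: dict[int, Counter]) -> tuple[str, list[int]]:
        seq = []
        sup = []
        for pos in sorted(columns):
            counts = columns[pos]
            base = min(counts, key=lambda b: (-counts[b], _BASE_ORDER.get(b, 5)))
            seq.append(base)
            sup.append(sum(counts.values()))
        return "".join(seq), sup

    columns: dict[int, Counter] = defaultdict(Counter)
    for off, read in placed:
        for i, b in enumerate(read):
            columns[off + i][b] += 1
    consensus, support = vote(columns)
    origin = min(columns)

    # greedy merge pass for reads that shared no seed k-mer
    merged_any = True
    low_confidence = False
    while unplaced and merged_any:
        merged_any = False
        scored = []
        for read in unplaced:
            hit = _overlap_offset(consensus, read, min_overlap)
            if hit is not None:
                scored.append((hit[1], len(read), read, hit[0]))
        if scored:
            scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
            _, _, read, off = scored[0]
            unplaced.remove(read)
            for i, b in enumerate(read):
                columns[origin + off + i][b] += 1
            consensus, support = vote(columns)
            origin = min(columns)
            merged_any = True
    if unplaced:
        low_confidence = True
    contributing = len(members) - len(unplaced)
    # low-support overhangs cannot be reliably error-corrected: trim them
    if contributing >= 3:
        min_edge = 3 if contributing >= 5 else 2
        lo, hi = 0, len(consensus)
        while lo < hi and support[lo] < min_edge:
            lo += 1
        while hi > lo and support[hi - 1] < min_edge:
            hi -= 1
        consensus, support = consensus[lo:hi], support[lo:hi]
    return ConsensusSequence(consensus, support, contributing, low_confidence)


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

def resolve_junction(
    consensus: ConsensusSequence,
    genome: GenomeModel,
    index: Optional[GenomeIndex] = None,
    case_id: str = "case",
    junction_id: int = 1,
    support: int = 1,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    edge_slack: int = 5,
    multi_junction_min: int = 50,
    templated_window: int = DEFAULT_TEMPLATED_WINDOW,
    min_templated: int = DEFAULT_MIN_TEMPLATED,
) -> JunctionRecord:
    """Resolve a consensus into a junction record with MH/insertion fields.

    The consensus must map as exactly two anchor segments (one covering the
    start, one the end, each >= ``min_anchor``).  A middle alignment longer
    than ``multi_junction_min`` raises :class:`MultiJunctionError`; fewer
    than two anchors yields an unresolved record with MISSING fields.
    """
    if index is None:
        index = GenomeIndex(genome)
    seq = consensus.sequence
    alns = [a for a in index.align(seq) if a.length >= min_anchor]

    lefts = [a for a in alns if a.q_start <= edge_slack]
    rights = [a for a in alns if a.q_end >= len(seq) - 1 - edge_slack]
    left = max(lefts, key=lambda a: (a.q_end, a.length), default=None)
    right = min(rights, key=lambda a: (a.q_start, -a.length), default=None)

    unresolved = JunctionRecord(
        case_id, junction_id, None, None,
        MISSING, MISSING, MISSING, MISSING,
        support=support, consensus=seq,
    )
    if left is None or right is None or left == right:
        return unresolved

    middles = [a for a in alns
               if a not in (left, right)
               and a.q_start > left.q_end - min_anchor
               and a.q_end < right.q_start + min_anchor]
    if any(a.length >= multi_junction_min for a in middles):
        raise MultiJunctionError("consensus spans more than one junction")

    if left.strand == FORWARD:
        side1 = BreakpointSide(left.contig, left.r_end, FORWARD)
    else:
        side1 = BreakpointSide(left.contig, left.r_start, REVERSE)

    gap = right.q_start - left.q_end - 1
    overlap = max(0, -gap)
    if right.strand == FORWARD:
        side2 = BreakpointSide(right.contig, right.r_start + overlap, FORWARD)
    else:
        side2 = BreakpointSide(right.contig, right.r_end - overlap, REVERSE)

    if gap > 0:
        insert = seq[left.q_end + 1 : right.q_start]
        blocks = decompose_insertion(genome, insert, side1, side2,
                                     window=templated_window,
                                     min_templated=min_templated)
        return JunctionRecord(
            case_id, junction_id, side1, side2,
            microhomology_len=0, microhomology_seq="",
            insertion_len=len(insert), insertion_blocks=blocks,
            support=support, consensus=seq,
        )
    mh, mh_seq, canon1, canon2 = compute_microhomology(genome, side1, side2)
    return JunctionRecord(
        case_id, junction_id, canon1, canon2,
        microhomology_len=mh, microhomology_seq=mh_seq,
        insertion_len=0, insertion_blocks=[],
        support=support, consensus=seq,
    )


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

def annotate_repeats(
    junction: JunctionRecord,
    track: dict[str, list[tuple[int, int, str]]],
) -> JunctionRecord:
    """Annotate each side with the overlapping repeat element (or None).

    ``track`` maps contig -> sorted (start, end, name) with 1-based
    inclusive containment.
    """

    def lookup(side: Optional[BreakpointSide]) -> Optional[str]:
        if side is None:
            return None
        intervals = track.get(side.contig, [])
        starts = [iv[0] for iv in intervals]
        i = bisect.bisect_right(starts, side.position)
        for j in range(max(0, i - 5), i):
            lo, hi, name = intervals[j]
            if lo <= side.position <= hi:
                return name
        return None

    return replace(junction, repeat1=lookup(junction.side1), repeat2=lookup(junction.side2))


# ---------------------------------------------------------------------------
# junction-proximal SNVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvRecord:
    contig: str
    position: int
    ref: str
    alt: str
    distance: int
    frequency: Optional[float]
    novel: Optional[bool]  # None when no frequency table was available
    unfiltered: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")


def find_novel_snvs(
    alignments: Sequence[SamRecord],
    genome: GenomeModel,
    junctions: Sequence[JunctionRecord],
    window: int = DEFAULT_SNV_WINDOW,
    freq_table: Optional[dict[tuple[str, int, str, str], float]] = None,
    af_threshold: float = 0.0,
    min_frac: float = 0.25,
    min_depth: int = 8,
) -> list[SnvRecord]:
    """Mismatch pileup within ``window`` of any junction side.

    Candidate SNVs present in ``freq_table`` above ``af_threshold`` are
    marked non-novel; with no table every candidate is flagged unfiltered.
    """
    sides: dict[str, list[int]] = defaultdict(list)
    for j in junctions:
        for side in (j.side1, j.side2):
            if side is not None:
                sides[side.contig].append(side.position)
    for positions in sides.values():
        positions.sort()
    if not sides:
        return []

    def near(contig: str, pos: int) -> Optional[int]:
        positions = sides.get(contig)
        if not positions:
            return None
        i = bisect.bisect_left(positions, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(positions[j] - pos)
                if best is None or d < best:
                    best = d
        return best if best is not None and best <= window else None

    depth: Counter = Counter()
    alts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for rec in alignments:
        if rec.flag & 0x100 or rec.seq in ("*", "", None):
            continue
        q = 0
        r = rec.pos
        for length, op in rec.cigar_ops():
            if op in ("S", "I"):
                q += length
            elif op == "D":
                r += length
            elif op == "M":
                seq = genome.contigs.get(rec.rname)
                for k in range(length):
                    pos = r + k
                    if seq is None or near(rec.rname, pos) is None:
                        continue
                    depth[(rec.rname, pos)] += 1
                    base = rec.seq[q + k]
                    if base != seq[pos - 1]:
                        alts[(rec.rname, pos)][base] += 1
                q += length
                r += length

    out: list[SnvRecord] = []
    for (contig, pos), counter in sorted(alts.items()):
        d = depth[(contig, pos)]
        if d < min_depth:
            continue
        alt, n = counter.most_common(1)[0]
        if alt == "N" or n / d < min_frac:
            continue
        ref_base = genome.contigs[contig][pos - 1]
        dist = near(contig, pos)
        if freq_table is None:
            out.append(SnvRecord(contig, pos, ref_base, alt, dist, None, None, True))
            continue
        freq = freq_table.get((contig, pos, ref_base, alt))
        novel = freq is None or freq <= af_threshold
        out.append(SnvRecord(contig, pos, ref_base, alt, dist, freq, novel, False))
    return out
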