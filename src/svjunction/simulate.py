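"""Synthetic references, planted rearrangements and read simulation.

Every sequence-level operation in the package is testable hermetically:
a :class:`PlantSpec` describes an ordered segment plan plus the chemistry
of each junction (blunt, engineered microhomology, non-templated and/or
templated insertion), and :func:`plant_rearrangement` edits a copy of the
reference so the requested chemistry holds exactly, emitting the expected
junction table alongside the derivative.  :func:`generate_reads` samples
fragments and writes split alignment records computed analytically from
the truth mapping — no external aligner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    FORWARD,
    REVERSE,
    RETAINED,
    DUPLICATE_COPY,
    BreakpointSide,
    CopyNumberSegment,
    DerivativeStructure,
    GenomeModel,
    InsertionBlock,
    JunctionRecord,
    SegmentUse,
    reverse_complement,
)
from .characterize import compute_microhomology, decompose_insertion
from .io.sam import SamRecord

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ChemistryError(RuntimeError):
    """Requested junction chemistry could not be engineered."""


def random_reference(length: int, gc_fraction: float, seed: int,
                     contig: str = "sim1") -> GenomeModel:
    """Reproducible random reference with the requested GC content."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    seq = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return GenomeModel({contig: "".join(seq)})


# ---------------------------------------------------------------------------
# plant specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One insertion block: non-templated random bases or a templated copy.

    Templated blocks are copied from ``side`` (1 or 2) at ``offset`` bases
    from that side's position (reference-forward), on ``strand``.
    """

    kind: str  # templated | non_templated
    length: int
    strand: str = FORWARD
    side: int = 2
    offset: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("templated", "non_templated"):
            raise ValueError(f"bad block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("block length must be >= 1")


@dataclass(frozen=True)
class Chemistry:
    kind: str  # blunt | microhomology | insertion
    mh: int = 0
    blocks: tuple[BlockSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("blunt", "microhomology", "insertion"):
            raise ValueError(f"bad chemistry {self.kind!r}")
        if self.kind == "microhomology" and self.mh < 1:
            raise ValueError("microhomology chemistry needs mh >= 1")
        if self.kind == "insertion" and not self.blocks:
            raise ValueError("insertion chemistry needs blocks")
        if self.mh > 0 and self.blocks:
            raise ValueError("MH and insertion cannot both be positive")


BLUNT = Chemistry("blunt")


@dataclass
class PlantSpec:
    """A planted rearrangement: segment plan + per-junction chemistry."""

    contig: str
    segments: list[tuple[int, int, str]]  # (start, end, orientation)
    chemistries: list[Chemistry]
    snvs: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 42
    name: str = "plant"

    def __post_init__(self) -> None:
        if len(self.chemistries) != max(0, len(self.segments) - 1):
            raise ValueError("need exactly one chemistry per junction")
        for start, end, orient in self.segments:
            if start > end or orient not in (FORWARD, REVERSE):
                raise ValueError(f"bad segment ({start}, {end}, {orient})")


@dataclass(frozen=True)
class MapEntry:
    """Mapping of a derivative interval (0-based inclusive) back to reference."""

    der_start: int
    der_end: int
    kind: str  # ref | ins
    contig: Optional[str] = None
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    strand: str = FORWARD


@dataclass
class SimulatedTruth:
    genome: GenomeModel
    name: str
    derivative: str
    junctions: list[JunctionRecord]
    cn: list[CopyNumberSegment]
    structure: DerivativeStructure
    segment_map: list[MapEntry]
    spec: PlantSpec

    def rebuild(self) -> str:
        """Reassemble the derivative from truth segments and junction inserts."""
        parts = []
        for seg, junction in zip(self.structure.segments,
                                 list(self.junctions) + [None]):
            raw = self.genome.sequence(seg.contig, seg.start, seg.end)
            parts.append(raw if seg.orientation == FORWARD else reverse_complement(raw))
            if junction is not None and junction.insertion_blocks:
                parts.extend(b.sequence for b in junction.insertion_blocks)
        return "".join(parts)


# ---------------------------------------------------------------------------
# junction-side arithmetic on a mutable buffer
# ---------------------------------------------------------------------------

def _left_side(segment: tuple[int, int, str], contig: str) -> BreakpointSide:
    start, end, orient = segment
    return BreakpointSide(contig, end if orient == FORWARD else start, orient)


def _right_side(segment: tuple[int, int, str], contig: str) -> BreakpointSide:
    start, end, orient = segment
    return BreakpointSide(contig, start if orient == FORWARD else end, orient)


class _Buffer:
    """Mutable contig with derivative-space base access around junction sides."""

    def __init__(self, seq: str):
        self.bases = list(seq)

    def __len__(self) -> int:
        return len(self.bases)

    def get(self, pos: int) -> Optional[str]:
        if 1 <= pos <= len(self.bases):
            return self.bases[pos - 1]
        return None

    def set(self, pos: int, base: str) -> None:
        if 1 <= pos <= len(self.bases):
            self.bases[pos - 1] = base

    # derivative-space reads relative to a side; role as in core.base_at
    def read(self, side: BreakpointSide, offset: int, role: str) -> Optional[str]:
        pos = _side_pos(side, offset, role)
        b = self.get(pos)
        if b is None:
            return None
        return _COMP[b] if side.orientation == REVERSE else b

    def write(self, side: BreakpointSide, offset: int, role: str, value: str) -> None:
        pos = _side_pos(side, offset, role)
        self.set(pos, _COMP[value] if side.orientation == REVERSE else value)


def _side_pos(side: BreakpointSide, offset: int, role: str) -> int:
    if role == "left":
        into = -1 if side.orientation == FORWARD else +1
    else:
        into = +1 if side.orientation == FORWARD else -1
    if offset >= 1:
        return side.position + into * (offset - 1)
    return side.position - into * (1 - offset)


def _other_base(rng: np.random.Generator, *avoid: Optional[str]) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _engineer_junction(buf: _Buffer, rng: np.random.Generator,
                       side1: BreakpointSide, side2: BreakpointSide,
                       chem: Chemistry, window: int,
                       min_templated: int) -> tuple[str, list[InsertionBlock]]:
    """Mutate the buffer so the junction exhibits ``chem``; return the insert."""
    k = chem.mh if chem.kind == "microhomology" else 0
    # engineer the homologous run: side2's first k retained bases copy side1's
    # continuation, so the breakpoint slides right across exactly k bases
    for j in range(1, k + 1):
        v = buf.read(side1, -(j - 1), "left")
        if v is None:
            raise ChemistryError("microhomology run exceeds contig edge")
        buf.write(side2, j, "right", v)
    # right cap
    a = buf.read(side1, -k, "left")
    b = buf.read(side2, k + 1, "right")
    if a is not None and b is not None and a == b:
        buf.write(side2, k + 1, "right", _other_base(rng, a))
    # left cap (keeps the planted placement canonical / left-aligned)
    a = buf.read(side1, 1, "left")
    b = buf.read(side2, 0, "right")
    if a is not None and b is not None and a == b:
        buf.write(side2, 0, "right", _other_base(rng, a))

    if chem.kind != "insertion":
        return "", []

    blocks: list[InsertionBlock] = []
    sides = {1: side1, 2: side2}
    for spec in chem.blocks:
        if spec.kind == "templated":
            side = sides[spec.side]
            lo = _side_pos(side, 1, "left" if spec.side == 1 else "right")
            start = lo + spec.offset
            end = start + spec.length - 1
            raw = "".join(buf.bases[start - 1 : end])
            if len(raw) != spec.length:
                raise ChemistryError("templated source outside contig")
            seq = raw if spec.strand == FORWARD else reverse_complement(raw)
            blocks.append(InsertionBlock("templated", seq, side.contig,
                                         start, end, spec.strand))
        else:
            seq = "".join(_BASES[rng.integers(0, 4, size=spec.length)])
            blocks.append(InsertionBlock("non_templated", seq))
    insert = "".join(b.sequence for b in blocks)
    # cap the insert edges so anchor extension stops exactly at the breakpoints
    a = buf.read(side1, 0, "left")
    if a is not None and insert[0] == a:
        blk = blocks[0]
        if blk.kind == "non_templated":
            blocks[0] = replace(blk, sequence=_other_base(rng, a) + blk.sequence[1:])
        else:
            buf.write(side1, 0, "left", _other_base(rng, insert[0]))
    insert = "".join(blk.sequence for blk in blocks)
    b = buf.read(side2, 0, "right")
    if b is not None and insert[-1] == b:
        blk = blocks[-1]
        if blk.kind == "non_templated":
            # a 1-bp block must keep its left cap too
            avoid = (b, a) if len(insert) == 1 else (b,)
            blocks[-1] = replace(blk, sequence=blk.sequence[:-1] + _other_base(rng, *avoid))
        else:
            buf.write(side2, 0, "right", _other_base(rng, insert[-1]))
    insert = "".join(blk.sequence for blk in blocks)
    return insert, blocks


def _coverage_cn(spec: PlantSpec, contig_length: int) -> list[CopyNumberSegment]:
    events: dict[int, int] = {}
    lo = min(s[0] for s in spec.segments)
    hi = max(s[1] for s in spec.segments)
    for start, end, _ in spec.segments:
        events[start] = events.get(start, 0) + 1
        events[end + 1] = events.get(end + 1, 0) - 1
    cuts = sorted(set(events) | {lo, hi + 1})
    out = []
    cover = 0
    for a, b in zip(cuts, cuts[1:]):
        cover += events.get(a, 0)
        out.append(CopyNumberSegment(spec.contig, a, b - 1, 1 + cover))
    # merge equal neighbours
    merged: list[CopyNumberSegment] = []
    for seg in out:
        if merged and merged[-1].state == seg.state and merged[-1].end + 1 == seg.start:
            merged[-1] = CopyNumberSegment(seg.contig, merged[-1].start, seg.end, seg.state)
        else:
            merged.append(seg)
    return merged


def plant_rearrangement(
    genome: GenomeModel,
    spec: PlantSpec,
    window: int = 100,
    min_templated: int = 10,
    max_attempts: int = 100,
    verify: bool = True,
) -> SimulatedTruth:
    """Engineer ``spec`` into a copy of ``genome`` and emit the ground truth.

    Junction chemistry that cannot be realised for the drawn flanks (for
    example an accidental homology extension) is re-drawn with the next
    seed; a :class:`ChemistryError` is raised after ``max_attempts``.
    """
    last_error: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            return _plant_once(genome, spec, rng, window, min_templated, verify)
        except ChemistryError as exc:
            last_error = exc
    raise ChemistryError(f"chemistry infeasible after {max_attempts} attempts: {last_error}")


def _plant_once(genome, spec, rng, window, min_templated, verify) -> SimulatedTruth:
    buf = _Buffer(genome.contigs[spec.contig])
    contig = spec.contig

    junctions_plan = []
    for i, chem in enumerate(spec.chemistries):
        side1 = _left_side(spec.segments[i], contig)
        side2 = _right_side(spec.segments[i + 1], contig)
        junctions_plan.append((side1, side2, chem))

    inserts: list[tuple[str, list[InsertionBlock]]] = []
    for side1, side2, chem in junctions_plan:
        inserts.append(_engineer_junction(buf, rng, side1, side2, chem,
                                          window, min_templated))
    for pos, alt in spec.snvs:
        # planted SNVs live on the derivative haplotype only; they are applied
        # during read generation, not to the reference
        if not (1 <= pos <= len(buf)):
            raise ChemistryError(f"SNV position {pos} outside contig")

    contigs = dict(genome.contigs)
    contigs[contig] = "".join(buf.bases)
    mutated = GenomeModel(contigs)

    # derivative + map
    der_parts: list[str] = []
    segment_map: list[MapEntry] = []
    cursor = 0
    seen: dict[tuple[int, int], int] = {}
    seg_uses: list[SegmentUse] = []
    for i, (start, end, orient) in enumerate(spec.segments):
        raw = mutated.sequence(contig, start, end)
        if orient == REVERSE:
            raw = reverse_complement(raw)
        segment_map.append(MapEntry(cursor, cursor + len(raw) - 1, "ref",
                                    contig, start, end, orient))
        der_parts.append(raw)
        cursor += len(raw)
        count = seen.get((start, end), 0)
        seen[(start, end)] = count + 1
        seg_uses.append(SegmentUse(contig, start, end, orient,
                                   RETAINED if count == 0 else DUPLICATE_COPY))
        if i < len(inserts):
            insert, _ = inserts[i]
            if insert:
                segment_map.append(MapEntry(cursor, cursor + len(insert) - 1, "ins"))
                der_parts.append(insert)
                cursor += len(insert)
    derivative = "".join(der_parts)

    records: list[JunctionRecord] = []
    for jid, ((side1, side2, chem), (insert, blocks)) in enumerate(
            zip(junctions_plan, inserts), start=1):
        if chem.kind == "insertion":
            rec = JunctionRecord(spec.name, jid, side1, side2,
                                 microhomology_len=0, microhomology_seq="",
                                 insertion_len=len(insert),
                                 insertion_blocks=blocks)
        else:
            k = chem.mh if chem.kind == "microhomology" else 0
            mh_seq = ""
            if k:
                from .core import flank as _flank
                mh_seq = _flank(mutated, side2, k, role="right").sequence
            rec = JunctionRecord(spec.name, jid, side1, side2,
                                 microhomology_len=k, microhomology_seq=mh_seq,
                                 insertion_len=0, insertion_blocks=[])
        records.append(rec)

    truth = SimulatedTruth(
        mutated, spec.name, derivative, records,
        _coverage_cn(spec, len(buf)),
        DerivativeStructure(spec.name, seg_uses, records),
        segment_map, spec,
    )
    if verify:
        _verify_truth(truth, window, min_templated)
    return truth


def _verify_truth(truth: SimulatedTruth, window: int, min_templated: int) -> None:
    for rec, chem in zip(truth.junctions, truth.spec.chemistries):
        mh, _, canon1, canon2 = compute_microhomology(truth.genome, rec.side1, rec.side2)
        if chem.kind != "insertion":
            want = chem.mh if chem.kind == "microhomology" else 0
            if mh != want or canon1 != rec.side1 or canon2 != rec.side2:
                raise ChemistryError(
                    f"engineered MH check failed (got {mh}, want {want})")
        else:
            insert = "".join(b.sequence for b in rec.insertion_blocks)
            got = decompose_insertion(truth.genome, insert, rec.side1, rec.side2,
                                      window=window, min_templated=min_templated)
            want_shape = [(b.kind, len(b.sequence)) for b in rec.insertion_blocks
                          if b.kind == "templated" and len(b.sequence) >= min_templated]
            got_shape = [(b.kind, len(b.sequence)) for b in got if b.kind == "templated"]
            if got_shape != want_shape:
                raise ChemistryError(
                    f"insert decomposition drifted: {got_shape} != {want_shape}")
    if truth.rebuild() != truth.derivative:
        raise ChemistryError("truth reconstruction does not reproduce derivative")


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryConfig:
    library_type: str = "paired_end"  # or mate_pair
    read_length: int = 150
    fragment_mean: int = 350
    fragment_sd: int = 50
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.library_type not in ("paired_end", "mate_pair"):
            raise ValueError(f"bad library type {self.library_type!r}")
        if self.read_length > self.fragment_mean:
            raise ValueError("read length must not exceed fragment size")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str


MIN_PART = 20


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    bases = list(seq)
    hits = np.flatnonzero(rng.random(len(bases)) < rate)
    for i in hits:
        bases[i] = _other_base(rng, bases[i])
    return "".join(bases)


def _apply_snvs(derivative: str, truth: SimulatedTruth) -> str:
    """Apply planted haplotype SNVs to the derivative before sampling reads."""
    if not truth.spec.snvs:
        return derivative
    bases = list(derivative)
    lookup = dict(truth.spec.snvs)
    for entry in truth.segment_map:
        if entry.kind != "ref":
            continue
        for pos, alt in lookup.items():
            if entry.ref_start <= pos <= entry.ref_end:
                if entry.strand == FORWARD:
                    d = entry.der_start + (pos - entry.ref_start)
                    bases[d] = alt
                else:
                    d = entry.der_start + (entry.ref_end - pos)
                    bases[d] = _COMP[alt]
    return "".join(bases)


def _pieces_for(truth: SimulatedTruth, s: int, e: int):
    """Reference pieces of derivative interval [s, e] (0-based inclusive)."""
    out = []
    for entry in truth.segment_map:
        lo = max(s, entry.der_start)
        hi = min(e, entry.der_end)
        if lo > hi or entry.kind != "ref":
            continue
        if entry.strand == FORWARD:
            r_lo = entry.ref_start + (lo - entry.der_start)
            r_hi = entry.ref_start + (hi - entry.der_start)
        else:
            r_hi = entry.ref_end - (lo - entry.der_start)
            r_lo = entry.ref_end - (hi - entry.der_start)
        out.append((lo, hi, entry.contig, r_lo, r_hi, entry.strand))
    return out


def _records_for_read(read_name: str, read_seq: str, truth: SimulatedTruth,
                      s: int, e: int, read_reverse: bool,
                      pair_flags: int) -> list[SamRecord]:
    pieces = [p for p in _pieces_for(truth, s, e) if p[1] - p[0] + 1 >= MIN_PART]
    if not pieces:
        return []
    L = e - s + 1

    def read_coords(lo: int, hi: int) -> tuple[int, int]:
        if read_reverse:
            return e - hi, e - lo
        return lo - s, hi - s

    parts = []
    for lo, hi, contig, r_lo, r_hi, strand in pieces:
        q_lo, q_hi = read_coords(lo, hi)
        rec_reverse = (strand == REVERSE) != read_reverse
        parts.append((q_lo, q_hi, contig, r_lo, r_hi, rec_reverse))
    parts.sort(key=lambda p: p[0])
    primary = max(parts, key=lambda p: p[1] - p[0])

    def cigar_for(q_lo, q_hi, rec_reverse):
        m = q_hi - q_lo + 1
        lead = (L - 1 - q_hi) if rec_reverse else q_lo
        tail = L - lead - m
        out = ""
        if lead:
            out += f"{lead}S"
        out += f"{m}M"
        if tail:
            out += f"{tail}S"
        return out

    def sa_entry(part):
        q_lo, q_hi, contig, r_lo, r_hi, rec_reverse = part
        return (f"{contig},{r_lo},{'-' if rec_reverse else '+'},"
                f"{cigar_for(q_lo, q_hi, rec_reverse)},60,0")

    records = []
    for part in parts:
        q_lo, q_hi, contig, r_lo, r_hi, rec_reverse = part
        flag = pair_flags
        if rec_reverse:
            flag |= 0x10
        if part != primary:
            flag |= 0x800
        seq = reverse_complement(read_seq) if rec_reverse else read_seq
        tags = {}
        others = [p for p in parts if p != part]
        if others:
            tags["SA"] = ";".join(sa_entry(p) for p in others) + ";"
        records.append(SamRecord(read_name, flag, contig, r_lo, 60,
                                 cigar_for(q_lo, q_hi, rec_reverse),
                                 seq=seq, qual="*", tags=tags))
    return records


def generate_reads(
    truth: SimulatedTruth,
    lib: LibraryConfig,
) -> tuple[list[FastqRead], list[SamRecord]]:
    """Uniform fragment sampling with analytically computed split alignments."""
    rng = np.random.default_rng(lib.seed)
    derivative = _apply_snvs(truth.derivative, truth)
    L = len(derivative)
    if L <= lib.fragment_mean:
        raise ValueError("derivative shorter than fragment size")
    rl = lib.read_length
    n_pairs = int(round(lib.coverage * L / (2 * rl)))
    if n_pairs < 1:
        raise ValueError("coverage yields zero fragments")

    fastq: list[FastqRead] = []
    sam: list[SamRecord] = []
    for i in range(n_pairs):
        frag = int(np.clip(rng.normal(lib.fragment_mean, lib.fragment_sd), rl, L))
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag - 1
        r1 = _apply_errors(derivative[start : start + rl], rng, lib.error_rate)
        r2 = _apply_errors(reverse_complement(derivative[end - rl + 1 : end + 1]),
                           rng, lib.error_rate)
        name = f"{truth.name}:frag{i}"
        fastq.append(FastqRead(name + "/1", r1, "I" * rl))
        fastq.append(FastqRead(name + "/2", r2, "I" * rl))
        sam.extend(_records_for_read(name, r1, truth, start, start + rl - 1,
                                     False, 0x1 | 0x40))
        sam.extend(_records_for_read(name, r2, truth, end - rl + 1, end,
                                     True, 0x1 | 0x80))
    return fastq, sam


def write_fastq(reads: Sequence[FastqRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")


# ---------------------------------------------------------------------------
# convenience plans
# ---------------------------------------------------------------------------

def single_deletion_plan(contig_length: int, contig: str = "sim1",
                         chemistry: Chemistry = BLUNT, seed: int = 42,
                         name: str = "plant",
                         left_end: Optional[int] = None,
                         right_start: Optional[int] = None) -> PlantSpec:
    """Two-segment plan deleting the middle of the contig."""
    p1 = left_end if left_end is not None else contig_length // 3
    p2 = right_start if right_start is not None else 2 * contig_length // 3
    return PlantSpec(contig,
                     [(1, p1, FORWARD), (p2, contig_length, FORWARD)],
                     [chemistry], seed=seed, name=name)


def del_inv_del_plan(contig_length: int, contig: str = "sim1",
                     chem1: Chemistry = BLUNT, chem2: Chemistry = BLUNT,
                     seed: int = 42, name: str = "plant") -> PlantSpec:
    """Three-segment DEL-INV-DEL plan (middle retained inverted)."""
    q = contig_length // 5
    return PlantSpec(
        contig,
        [(1, q, FORWARD), (2 * q, 3 * q, REVERSE), (4 * q, contig_length, FORWARD)],
        [chem1, chem2], seed=seed, name=name)
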