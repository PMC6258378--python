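"""Shared genomic data types, coordinate conventions and sequence utilities.

Conventions used throughout the package:

* All coordinates are 1-based and inclusive at both ends.
* A breakpoint junction is an ordered pair of :class:`BreakpointSide` objects:
  ``side1`` is the *left* side (the derivative segment ending at the junction)
  and ``side2`` the *right* side (the segment beginning at the junction).
* Orientation ``+`` on a left side means the retained flank is
  reference-forward ending at ``position``; ``-`` means the retained flank is
  the reverse-complement and ends with the complement of the base at
  ``position``.  The mirror-image convention holds for right sides.
* ``N`` bases never match anything in homology computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

MISSING = None

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = frozenset("ACGTN")

FORWARD = "+"
REVERSE = "-"


class AlphabetError(ValueError):
    """A sequence contains characters outside the ACGTN alphabet."""


class CoordinateError(ValueError):
    """A position falls outside the owning contig."""


def _check_alphabet(seq: str) -> str:
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters: {sorted(bad)}")
    return seq.upper()


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string (involution, length preserving)."""
    _check_alphabet(seq)
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeModel:
    """A set of named uppercase ACGTN contigs."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        cleaned = {}
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            seq = _check_alphabet(seq)
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            cleaned[name] = seq
        self.contigs = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def sequence(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig`` between 1-based inclusive ``start``..``end``."""
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class BreakpointSide:
    """One oriented side of a breakpoint junction."""

    contig: str
    position: int
    orientation: str  # FORWARD or REVERSE

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.position < 1:
            raise CoordinateError(f"position {self.position} < 1")

    def validate(self, genome: GenomeModel) -> None:
        if self.position > genome.lengths[self.contig]:
            raise CoordinateError(
                f"{self.contig}:{self.position} beyond contig end"
            )


@dataclass(frozen=True)
class InsertionBlock:
    """A block of inserted junction sequence.

    ``kind`` is ``templated`` (copied from near the junction; carries a
    reference source) or ``non_templated`` (no identifiable source).
    """

    kind: str
    sequence: str
    source_contig: Optional[str] = None
    source_start: Optional[int] = None
    source_end: Optional[int] = None
    source_strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("templated", "non_templated"):
            raise ValueError(f"bad block kind {self.kind!r}")
        if len(self.sequence) < 1:
            raise ValueError("insertion blocks must be non-empty")
        if self.kind == "templated":
            if None in (self.source_contig, self.source_start, self.source_end,
                        self.source_strand):
                raise ValueError("templated blocks need a full source")

    def check_source(self, genome: GenomeModel) -> bool:
        """True iff the source interval reproduces ``sequence``."""
        if self.kind != "templated":
            return True
        raw = genome.sequence(self.source_contig, self.source_start, self.source_end)
        if self.source_strand == REVERSE:
            raw = reverse_complement(raw)
        return raw == self.sequence.upper()


@dataclass
class JunctionRecord:
    """A nucleotide-resolved (or partially resolved) breakpoint junction."""

    case_id: str
    junction_id: int
    side1: Optional[BreakpointSide]
    side2: Optional[BreakpointSide]
    microhomology_len: Optional[int] = MISSING
    microhomology_seq: Optional[str] = MISSING
    insertion_len: Optional[int] = MISSING
    insertion_blocks: Optional[list[InsertionBlock]] = MISSING
    repeat1: Optional[str] = None
    repeat2: Optional[str] = None
    support: int = 0
    consensus: Optional[str] = MISSING

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be >= 0")
        if (self.microhomology_len is not MISSING
                and self.microhomology_seq is not MISSING
                and self.microhomology_seq is not None
                and self.microhomology_len != len(self.microhomology_seq)):
            raise ValueError("microhomology_len != len(microhomology_seq)")
        if (self.insertion_len is not None and self.insertion_blocks):
            total = sum(len(b.sequence) for b in self.insertion_blocks)
            if total != self.insertion_len:
                raise ValueError("insertion_len != sum of block lengths")
        if (self.microhomology_len or 0) > 0 and (self.insertion_len or 0) > 0:
            raise ValueError(
                "microhomology and insertion are mutually exclusive at one junction"
            )

    @property
    def resolved(self) -> bool:
        """Both MH and insertion fields determined (the Table-2 non-NA rows)."""
        return self.microhomology_len is not MISSING and self.insertion_len is not MISSING


@dataclass(frozen=True)
class CopyNumberSegment:
    """A reference interval with an integer copy-number state (2 = diploid)."""

    contig: str
    start: int
    end: int
    state: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.start}>{self.end}")
        if self.state < 0:
            raise ValueError("copy-number state must be >= 0")


def validate_cn_profile(segments: Iterable[CopyNumberSegment]) -> list[CopyNumberSegment]:
    """Sort one case's CN segments and reject overlaps within a contig."""
    out = sorted(segments, key=lambda s: (s.contig, s.start))
    for a, b in zip(out, out[1:]):
        if a.contig == b.contig and b.start <= a.end:
            raise ValueError(f"overlapping CN segments {a} / {b}")
    return out


RETAINED = "retained"
DUPLICATE_COPY = "duplicate_copy"
UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class SegmentUse:
    """One use of a reference interval inside a derivative chromosome."""

    contig: str
    start: int
    end: int
    orientation: str  # FORWARD (direct) or REVERSE (inverted)
    provenance: str = RETAINED

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.start}>{self.end}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.provenance not in (RETAINED, DUPLICATE_COPY, UNCERTAIN):
            raise ValueError(f"bad provenance {self.provenance!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DerivativeStructure:
    """Ordered, oriented list of reference segments composing a derivative."""

    name: str
    segments: list[SegmentUse]
    junctions: list[JunctionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("derivative structure must contain segments")

    @property
    def contigs(self) -> list[str]:
        seen: list[str] = []
        for seg in self.segments:
            if seg.contig not in seen:
                seen.append(seg.contig)
        return seen

    def sequence(self, genome: GenomeModel) -> str:
        parts = []
        for seg in self.segments:
            raw = genome.sequence(seg.contig, seg.start, seg.end)
            parts.append(raw if seg.orientation == FORWARD else reverse_complement(raw))
        return "".join(parts)

    def translate(self, offset: int) -> "DerivativeStructure":
        """Shift all coordinates by ``offset`` (labels preserved)."""
        return DerivativeStructure(
            self.name,
            [replace(s, start=s.start + offset, end=s.end + offset) for s in self.segments],
            list(self.junctions),
        )


# -- flank extraction ---------------------------------------------------------

@dataclass(frozen=True)
class Flank:
    """A retained flank read toward (or away from) a junction."""

    sequence: str
    truncated: bool

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sequence


def flank(genome: GenomeModel, side: BreakpointSide, k: int, role: str = "left") -> Flank:
    """The ``k`` retained bases of ``side`` reading toward the junction.

    For a *left* side the returned string ends at the junction; for a *right*
    side it starts at the junction.  Truncation at a contig edge is reported
    via :attr:`Flank.truncated` rather than raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if role not in ("left", "right"):
        raise ValueError("role must be 'left' or 'right'")
    side.validate(genome)
    length = genome.lengths[side.contig]
    p = side.position
    # Which direction along the reference does the retained flank extend?
    if role == "left":
        away_from_junction = -1 if side.orientation == FORWARD else +1
    else:
        away_from_junction = +1 if side.orientation == FORWARD else -1
    if away_from_junction == -1:
        start = max(1, p - k + 1)
        raw = genome.sequence(side.contig, start, p)
        truncated = start > p - k + 1
    else:
        end = min(length, p + k - 1)
        raw = genome.sequence(side.contig, p, end)
        truncated = end < p + k - 1
    if side.orientation == REVERSE:
        raw = reverse_complement(raw)
    return Flank(raw, truncated)


def base_at(genome: GenomeModel, side: BreakpointSide, offset: int, role: str = "left") -> Optional[str]:
    """Base ``offset`` steps from the junction along a side's derivative axis.

    ``offset`` >= 1 walks *away* from the junction through retained sequence;
    ``offset`` <= 0 walks past the junction into non-retained sequence
    (offset 0 is the first base beyond the breakpoint).  Returns ``None`` off
    the contig end.  Bases on REVERSE sides are complemented.
    """
    p = side.position
    if role == "left":
        into_flank = -1 if side.orientation == FORWARD else +1
    else:
        into_flank = +1 if side.orientation == FORWARD else -1
    if offset >= 1:
        pos = p + into_flank * (offset - 1)
    else:
        pos = p - into_flank * (1 - offset)
    if not (1 <= pos <= genome.lengths[side.contig]):
        return None
    b = genome.contigs[side.contig][pos - 1]
    if side.orientation == REVERSE:
        b = b.translate(_COMPLEMENT)
    return b


# -- FASTA --------------------------------------------------------------------

_FASTA_WIDTH = 60


def write_fasta(genome: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path: str) -> GenomeModel:
    contigs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = re.split(r"\s+", line[1:])[0]
                if name in contigs:
                    raise ValueError(f"duplicate contig {name!r}")
                contigs[name] = []
            else:
                if name is None:
                    raise ValueError("sequence before first FASTA header")
                contigs[name].append(line)
    return GenomeModel({k: "".join(v) for k, v in contigs.items()})
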