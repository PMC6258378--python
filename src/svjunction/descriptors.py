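"""Parsing and interpretation of complex-rearrangement descriptor strings.

The grammar is a pragmatic HGVS-like subset covering genomic ``del``,
``inv``, ``dup``, ``ins`` and ``delins`` clauses with optionally nested,
possibly uncertain (``?``) payloads, e.g.::

    NC_000005.9:g.[16715952_16736553del;16736554_16758649inv;16758650_16771432del]

Full HGVS compliance is explicitly not attempted.  Coordinates are 1-based
inclusive; ``pter``/``qter`` endpoints are resolved against a contig length.

The module also derives derivative-chromosome structures from parsed
descriptors, tokenized copy-number/orientation pattern strings
(``DEL-INV-DEL`` style) and the deletions/duplications group label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .core import (
    FORWARD,
    REVERSE,
    RETAINED,
    DUPLICATE_COPY,
    UNCERTAIN,
    CopyNumberSegment,
    DerivativeStructure,
    SegmentUse,
)

PTER = "pter"
QTER = "qter"

OP_KINDS = ("del", "inv", "dup", "ins", "delins")

PATTERN_TOKENS = ("DEL", "DUP", "DUPinv", "INV", "N", "DIP")

DELETIONS_ONLY = "deletions_only"
DUPLICATIONS_ONLY = "duplications_only"
DELETIONS_AND_DUPLICATIONS = "deletions_and_duplications"

GROUP_LABELS = (DELETIONS_ONLY, DUPLICATIONS_ONLY, DELETIONS_AND_DUPLICATIONS)


class DescriptorParseError(ValueError):
    """Malformed descriptor text; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class ConsistencyError(ValueError):
    """Descriptor operations contradict each other."""


class NoCnvError(ValueError):
    """A copy-number profile contains no aberrant segment."""


@dataclass(frozen=True)
class PayloadItem:
    """One element of an ins/delins payload: an oriented source interval."""

    start: Optional[int]  # None when uncertain ("?")
    end: Optional[int]
    inverted: bool = False
    uncertain: bool = False

    def serialize(self) -> str:
        if self.uncertain and self.start is None:
            return "?"
        text = f"{_fmt(self.start)}_{_fmt(self.end)}"
        if self.inverted:
            text += "inv"
        return text


@dataclass
class DescriptorOp:
    """One semicolon-separated clause of a descriptor."""

    kind: str
    start: Optional[int]
    end: Optional[int]
    payload: list[PayloadItem] = field(default_factory=list)
    uncertain: bool = False

    def __post_init__(self) -> None:
        if self.kind not in OP_KINDS:
            raise ValueError(f"unknown op kind {self.kind!r}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"malformed interval {self.start}_{self.end}")

    def serialize(self) -> str:
        target = f"{_fmt(self.start)}_{_fmt(self.end)}"
        if self.kind in ("ins", "delins"):
            inner = ";".join(item.serialize() for item in self.payload)
            return f"{target}{self.kind}[{inner}]"
        return f"{target}{self.kind}"


def _fmt(value: Optional[int]) -> str:
    if value is None:
        return "?"
    return str(value)


# -- tokenizer / parser -------------------------------------------------------

_ENDPOINT_RE = re.compile(r"(\d+|pter|qter|\?)")


def _parse_endpoint(text: str, offset: int, contig_length: Optional[int]) -> Optional[int]:
    if text == "?":
        return None
    if text == PTER:
        return 1
    if text == QTER:
        if contig_length is None:
            raise DescriptorParseError("qter endpoint needs a contig length", offset)
        return contig_length
    return int(text)


def _split_clauses(body: str, base_offset: int) -> list[tuple[str, int]]:
    """Split on top-level semicolons, keeping offsets; brackets may nest."""
    clauses: list[tuple[str, int]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(body):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise DescriptorParseError("unbalanced brackets", base_offset + i)
        elif ch == ";" and depth == 0:
            clauses.append((body[start:i], base_offset + start))
            start = i + 1
    if depth != 0:
        raise DescriptorParseError("unbalanced brackets", base_offset + len(body))
    clauses.append((body[start:], base_offset + start))
    return [(c, o) for c, o in clauses if c.strip()]


_CLAUSE_RE = re.compile(
    r"^(?P<start>\d+|pter|qter|\?)_(?P<end>\d+|pter|qter|\?)"
    r"(?P<kind>delins|del|inv|dup|ins)?"
    r"(?P<rest>.*)$",
    re.DOTALL,
)


def _parse_payload(text: str, offset: int, contig_length: Optional[int]) -> list[PayloadItem]:
    text = text.strip()
    if text.startswith("[") and text.endswith("]"):
        inner = text[1:-1]
        inner_offset = offset + 1
    else:
        inner = text
        inner_offset = offset
    items: list[PayloadItem] = []
    for raw, item_offset in _split_clauses(inner, inner_offset):
        raw = raw.strip()
        if raw == "?":
            items.append(PayloadItem(None, None, uncertain=True))
            continue
        m = re.match(r"^(\d+|pter|qter|\?)_(\d+|pter|qter|\?)(inv)?$", raw)
        if not m:
            raise DescriptorParseError(f"malformed payload item {raw!r}", item_offset)
        start = _parse_endpoint(m.group(1), item_offset, contig_length)
        end = _parse_endpoint(m.group(2), item_offset, contig_length)
        inverted = m.group(3) is not None
        uncertain = start is None or end is None
        if start is not None and end is not None and start > end:
            # Reversed coordinate order denotes an inverted interval.
            start, end = end, start
            inverted = True
        items.append(PayloadItem(start, end, inverted=inverted, uncertain=uncertain))
    if not items:
        raise DescriptorParseError("empty payload", offset)
    return items


def parse_descriptor(text: str, contig_length: Optional[int] = None) -> list[DescriptorOp]:
    """Parse a descriptor string into a list of :class:`DescriptorOp`.

    Whitespace inside the descriptor is tolerated.  ``?`` clauses and
    coordinates yield uncertain ops; they are never silently dropped.
    """
    compact = re.sub(r"\s+", "", text)
    m = re.search(r"g\.\[", compact)
    if m:
        body_start = m.end()
        if not compact.endswith("]"):
            raise DescriptorParseError("missing closing bracket", len(compact))
        body = compact[body_start:-1]
    else:
        body_start = 0
        body = compact
    ops: list[DescriptorOp] = []
    for clause, offset in _split_clauses(body, body_start):
        cm = _CLAUSE_RE.match(clause)
        if not cm:
            raise DescriptorParseError(f"malformed clause {clause!r}", offset)
        start = _parse_endpoint(cm.group("start"), offset, contig_length)
        end = _parse_endpoint(cm.group("end"), offset, contig_length)
        kind = cm.group("kind")
        rest = cm.group("rest")
        uncertain = start is None or end is None
        if kind is None:
            raise DescriptorParseError(f"clause {clause!r} lacks an operation suffix", offset)
        if kind in ("ins", "delins"):
            payload = _parse_payload(rest, offset, contig_length)
            uncertain = uncertain or any(p.uncertain for p in payload)
            ops.append(DescriptorOp(kind, start, end, payload, uncertain=uncertain))
        else:
            if rest:
                raise DescriptorParseError(f"unexpected suffix {rest!r}", offset)
            ops.append(DescriptorOp(kind, start, end, uncertain=uncertain))
    if not ops:
        raise DescriptorParseError("descriptor contains no operations", body_start)
    return ops


def serialize_descriptor(ops: Sequence[DescriptorOp], accession: Optional[str] = None) -> str:
    body = ";".join(op.serialize() for op in ops)
    prefix = f"{accession}:" if accession else ""
    return f"{prefix}g.[{body}]"


# -- structure building -------------------------------------------------------

def _sorted_ops(ops: Sequence[DescriptorOp], overlap_tolerance: int) -> list[DescriptorOp]:
    """Sort in-place ops by target and truncate tiny typographic overlaps."""
    known = [op for op in ops if op.start is not None]
    unknown = [op for op in ops if op.start is None]
    known.sort(key=lambda op: (op.start, op.end))
    inv_targets = [(op.start, op.end) for op in known if op.kind == "inv"]
    out: list[DescriptorOp] = []
    prev_end = None
    for op in known:
        nested_in_inv = op.kind == "del" and any(
            a <= op.start and op.end <= b for a, b in inv_targets
        )
        if nested_in_inv:
            out.append(op)
            continue
        if op.kind != "ins" and prev_end is not None and op.start <= prev_end:
            overlap = prev_end - op.start + 1
            if overlap > overlap_tolerance:
                raise ConsistencyError(
                    f"ops overlap by {overlap} bp at {op.start} (tolerance {overlap_tolerance})"
                )
            if prev_end + 1 > op.end:
                continue  # fully swallowed typographic sliver
            op = replace(op, start=prev_end + 1)
        if op.kind != "ins":
            prev_end = op.end
        out.append(op)
    return out + unknown


def _payload_segments(payload: Iterable[PayloadItem]) -> list[SegmentUse]:
    segs = []
    for item in payload:
        if item.start is None:
            continue  # fully uncertain element: no placeable segment
        provenance = UNCERTAIN if item.uncertain else DUPLICATE_COPY
        segs.append(
            SegmentUse(
                "",  # contig filled by caller
                item.start,
                item.end,
                REVERSE if item.inverted else FORWARD,
                provenance,
            )
        )
    return segs


def descriptor_to_structure(
    ops: Sequence[DescriptorOp],
    span: tuple[int, int],
    contig: str = "ref",
    name: str = "der",
    overlap_tolerance: int = 2,
) -> DerivativeStructure:
    """Interpret parsed ops as an ordered derivative-chromosome structure.

    Retained reference sequence is interleaved with the effects of each op:
    deletions are omitted, inversions flip orientation in place (deletions
    nested inside an inversion are honoured, with the retained pieces
    emitted in reversed order), ``dup`` places a tandem direct copy after
    its template, and ins/delins payload copies are placed at the target
    with their stated orientation and ``duplicate_copy`` provenance.
    """
    span_start, span_end = span
    ordered = _sorted_ops(ops, overlap_tolerance)
    # deletions nested inside an inversion target are consumed by that inversion
    consumed: set[int] = set()
    for i, op in enumerate(ordered):
        if op.kind != "inv" or op.start is None:
            continue
        for j, other in enumerate(ordered):
            if j == i or j in consumed or other.kind != "del" or other.start is None:
                continue
            if op.start <= other.start and other.end <= op.end:
                consumed.add(j)

    segments: list[SegmentUse] = []

    def retained(a: int, b: int, orientation: str = FORWARD) -> None:
        if a <= b:
            segments.append(SegmentUse(contig, a, b, orientation, RETAINED))

    pos = span_start
    for i, op in enumerate(ordered):
        if i in consumed:
            continue
        if op.start is None:
            # Placeless uncertain op: record payload copies as uncertain uses.
            for seg in _payload_segments(op.payload):
                segments.append(replace(seg, contig=contig, provenance=UNCERTAIN))
            continue
        if op.start > pos:
            retained(pos, op.start - 1)
        if op.kind == "del":
            pos = max(pos, op.end + 1)
        elif op.kind == "inv":
            nested = sorted(
                (ordered[j] for j in consumed
                 if op.start <= ordered[j].start and ordered[j].end <= op.end),
                key=lambda o: o.start,
            )
            pieces = []
            p = op.start
            for d in nested:
                if d.start > p:
                    pieces.append((p, d.start - 1))
                p = max(p, d.end + 1)
            if p <= op.end:
                pieces.append((p, op.end))
            for a, b in reversed(pieces):
                retained(a, b, REVERSE)
            pos = max(pos, op.end + 1)
        elif op.kind == "dup":
            retained(op.start, op.end)
            segments.append(SegmentUse(contig, op.start, op.end, FORWARD, DUPLICATE_COPY))
            pos = max(pos, op.end + 1)
        elif op.kind == "ins":
            # insertion immediately after the target's first coordinate
            if op.start >= pos:
                retained(op.start, op.start)
                pos = op.start + 1
            for seg in _payload_segments(op.payload):
                segments.append(replace(seg, contig=contig))
        elif op.kind == "delins":
            for seg in _payload_segments(op.payload):
                segments.append(replace(seg, contig=contig))
            pos = max(pos, op.end + 1)
    if pos <= span_end:
        retained(pos, span_end)
    if not segments:
        retained(span_start, span_end)
    return DerivativeStructure(name, segments)


def descriptor_span(ops: Sequence[DescriptorOp]) -> tuple[int, int]:
    """Smallest reference interval covering all op targets and payloads."""
    coords: list[int] = []
    for op in ops:
        if op.start is not None:
            coords.extend((op.start, op.end))
        for item in op.payload:
            if item.start is not None:
                coords.extend((item.start, item.end))
    if not coords:
        raise ValueError("no placeable coordinates in op list")
    return min(coords), max(coords)


# -- pattern derivation -------------------------------------------------------

@dataclass(frozen=True)
class PatternString:
    """Hyphen-joined tokens over the closed {DEL, DUP, DUPinv, INV, N, DIP} set."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("pattern must be non-empty")
        for tok in self.tokens:
            if tok not in PATTERN_TOKENS:
                raise ValueError(f"unknown pattern token {tok!r}")

    def __str__(self) -> str:
        return "-".join(self.tokens)

    @classmethod
    def parse(cls, text: str) -> "PatternString":
        cleaned = text.replace("–", "-").strip()
        return cls(tuple(t for t in cleaned.split("-") if t))

    def count(self, *tokens: str) -> int:
        return sum(1 for t in self.tokens if t in tokens)


_MIN_SLIVER = 10


def structure_to_pattern(
    structure: DerivativeStructure,
    cn: Optional[Sequence[CopyNumberSegment]] = None,
    span: Optional[tuple[int, int]] = None,
) -> PatternString:
    """Tokenize a derivative structure into its left-to-right reference pattern.

    The reference span is partitioned at every segment-use boundary; each
    fragment is emitted as one token from its net copy count and orientation
    on the rearranged homolog: absent -> DEL, single inverted -> INV, single
    direct -> N, multiple copies -> DUP (DUPinv when the duplicate copy is
    inverted).  Adjacent fragments merge only when the same segment uses
    generated them, so distinct shattered fragments keep distinct tokens.
    """
    segs = structure.segments
    contig = structure.contigs[0]
    relevant = [s for s in segs if s.contig == contig]
    if span is None:
        lo = min(s.start for s in relevant)
        hi = max(s.end for s in relevant)
    else:
        lo, hi = span
    bounds = {lo, hi + 1}
    for s in relevant:
        bounds.add(max(lo, s.start))
        bounds.add(min(hi + 1, s.end + 1))
    cuts = sorted(bounds)

    fragments = []
    for a, b in zip(cuts, cuts[1:]):
        frag_lo, frag_hi = a, b - 1
        cover = [i for i, s in enumerate(relevant)
                 if s.start <= frag_lo and frag_hi <= s.end]
        retained_ids = [i for i in cover if relevant[i].provenance == RETAINED]
        copy_ids = [i for i in cover if relevant[i].provenance != RETAINED]
        total = len(cover)
        if total == 0:
            token = "DEL"
        elif total == 1:
            only = relevant[cover[0]]
            token = "INV" if only.orientation == REVERSE else "N"
        else:
            inverted_copy = any(relevant[i].orientation == REVERSE for i in copy_ids)
            token = "DUPinv" if inverted_copy else "DUP"
        fragments.append({
            "lo": frag_lo, "hi": frag_hi, "token": token,
            "ids": frozenset(cover), "retained_only": bool(retained_ids) and not copy_ids,
        })

    # drop tiny untouched slivers produced by 1-2 bp typographic gaps
    fragments = [
        f for f in fragments
        if not (f["token"] == "N" and f["retained_only"]
                and f["hi"] - f["lo"] + 1 < _MIN_SLIVER)
    ]

    merged: list[dict] = []
    for f in fragments:
        if merged:
            prev = merged[-1]
            same = prev["token"] == f["token"] and (
                (prev["ids"] & f["ids"]) or (not prev["ids"] and not f["ids"])
            )
            if same:
                prev["hi"] = f["hi"]
                prev["ids"] = prev["ids"] | f["ids"]
                continue
        merged.append(dict(f))

    # trim plain retained flanks at the edges
    while merged and merged[0]["token"] == "N" and merged[0]["retained_only"]:
        merged.pop(0)
    while merged and merged[-1]["token"] == "N" and merged[-1]["retained_only"]:
        merged.pop()
    if not merged:
        return PatternString(("N",))
    return PatternString(tuple(f["token"] for f in merged))


def pattern_for_descriptor(
    ops: Sequence[DescriptorOp],
    contig: str = "ref",
    span: Optional[tuple[int, int]] = None,
) -> PatternString:
    if span is None:
        span = descriptor_span(ops)
    structure = descriptor_to_structure(ops, span, contig=contig)
    return structure_to_pattern(structure, span=span)


# -- group classification -----------------------------------------------------

def classify_group(cnv: Sequence[CopyNumberSegment], diploid_state: int = 2) -> str:
    """Classify a case's CN profile into the three-group scheme."""
    losses = any(s.state < diploid_state for s in cnv)
    gains = any(s.state > diploid_state for s in cnv)
    if not losses and not gains:
        raise NoCnvError("profile contains no aberrant segment")
    if losses and gains:
        return DELETIONS_AND_DUPLICATIONS
    return DELETIONS_ONLY if losses else DUPLICATIONS_ONLY


# -- ISCN copy-number extraction ---------------------------------------------

_ISCN_GROUP_RE = re.compile(
    r"(?P<chrom>\d+|X|Y)[pq][\d.]+(?:[pq][\d.]+)?\s*\((?P<body>[^()]*)\)\s*(?:x(?P<state>\d+))?"
)


def parse_iscn_cnv(text: str) -> list[CopyNumberSegment]:
    """Extract (interval, state) pairs from a CMA ISCN-style result string.

    Handles both per-segment states ``(a_bx1, c_dx3)`` and whole-group
    states ``(a-b)x3``; thousands separators and stray spaces inside
    numbers are tolerated.  Anything beyond x-state intervals (karyotype
    syntax proper) is out of scope.
    """
    segments: list[CopyNumberSegment] = []
    for m in _ISCN_GROUP_RE.finditer(text):
        chrom = m.group("chrom")
        body = re.sub(r"(?<=\d),(?=\d{3}\b)", "", m.group("body"))
        body = re.sub(r"(?<=\d),(?=\d{3}[_–-])", "", body)
        outer_state = m.group("state")
        for item in body.split(","):
            item = re.sub(r"\s+", "", item)
            if not item:
                continue
            im = re.match(r"^(\d+)[_–—-](\d+)(?:x(\d+))?$", item)
            if not im:
                continue
            state = im.group(3) or outer_state
            if state is None:
                continue
            segments.append(
                CopyNumberSegment(chrom, int(im.group(1)), int(im.group(2)), int(state))
            )
    if not segments:
        raise NoCnvError(f"no x-state intervals found in {text!r}")
    return segments
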