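"""Minimal SAM text dialect reader/writer.

Handles the subset used by the package: header optional, mandatory columns,
``S``/``M``/``I``/``D`` CIGAR operations and string/int tags including the
``SA`` supplementary-alignment tag.  Written deliberately in-house so that
header-less fragments and synthetic records round-trip byte-exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_PAIRED = 0x1
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class SamFormatError(ValueError):
    pass


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    if cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise SamFormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), o) for n, o in ops]


def cigar_spans(cigar: str) -> tuple[int, int, int, int]:
    """(leading clip, aligned query length, reference length, total read length)."""
    ops = parse_cigar(cigar)
    lead = 0
    qlen = rlen = total = 0
    seen_aligned = False
    for n, op in ops:
        if op in ("S", "H"):
            if not seen_aligned:
                lead += n
            total += n if op == "S" else 0
        elif op in ("M", "=", "X"):
            seen_aligned = True
            qlen += n
            rlen += n
            total += n
        elif op == "I":
            seen_aligned = True
            qlen += n
            total += n
        elif op in ("D", "N"):
            rlen += n
    return lead, qlen, rlen, total


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict[str, str] = field(default_factory=dict)

    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    def to_line(self) -> str:
        fields = [
            self.qname, str(self.flag), self.rname, str(self.pos), str(self.mapq),
            self.cigar, self.rnext, str(self.pnext), str(self.tlen), self.seq, self.qual,
        ]
        for key, value in self.tags.items():
            kind = "i" if re.fullmatch(r"-?\d+", value) else "Z"
            fields.append(f"{key}:{kind}:{value}")
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "SamRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise SamFormatError(f"record has {len(fields)} fields (< 11)")
        tags = {}
        for raw in fields[11:]:
            parts = raw.split(":", 2)
            if len(parts) != 3:
                raise SamFormatError(f"malformed tag {raw!r}")
            tags[parts[0]] = parts[2]
        return cls(
            fields[0], int(fields[1]), fields[2], int(fields[3]), int(fields[4]),
            fields[5], fields[6], int(fields[7]), int(fields[8]), fields[9],
            fields[10], tags,
        )


def read_sam(path_or_lines, strict: bool = False) -> tuple[list[str], list[SamRecord], int]:
    """Read SAM text; returns (header lines, records, bad-record count)."""
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    header: list[str] = []
    records: list[SamRecord] = []
    bad = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("@"):
            header.append(line.rstrip("\n"))
            continue
        try:
            records.append(SamRecord.from_line(line))
        except (SamFormatError, ValueError) as exc:
            bad += 1
            if strict:
                raise SamFormatError(f"line {i + 1}: {exc}") from exc
    return header, records, bad


def write_sam(records: Iterable[SamRecord], path: str,
              contig_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        if contig_lengths:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name, length in contig_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def _part_from(rname: str, pos: int, strand_reverse: bool, cigar: str,
               read_length: int):
    lead, qlen, rlen, total = cigar_spans(cigar)
    q_start_seq = lead
    q_end_seq = lead + qlen - 1
    if strand_reverse:
        q_start = read_length - 1 - q_end_seq
        q_end = read_length - 1 - q_start_seq
    else:
        q_start, q_end = q_start_seq, q_end_seq
    strand = "-" if strand_reverse else "+"
    return (q_start, q_end, rname, pos, pos + rlen - 1, strand)


def read_parts(rec: SamRecord):
    """All mapped parts of a read (primary + SA entries), in read coordinates.

    Each part is ``(q_start, q_end, rname, ref_start, ref_end, strand)`` with
    query coordinates on the read as sequenced (0-based inclusive).
    """
    if rec.cigar == "*":
        return []
    _, _, _, total = cigar_spans(rec.cigar)
    parts = [_part_from(rec.rname, rec.pos, rec.is_reverse, rec.cigar, total)]
    sa = rec.tags.get("SA", "")
    for entry in filter(None, sa.split(";")):
        fields = entry.split(",")
        if len(fields) < 4:
            continue
        parts.append(_part_from(fields[0], int(fields[1]), fields[2] == "-",
                                fields[3], total))
    return parts
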