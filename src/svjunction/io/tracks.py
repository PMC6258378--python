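"""Repeat tracks, allele-frequency tables and junction table readers/writers."""

from __future__ import annotations

import json
from typing import Optional

from ..core import (
    FORWARD,
    BreakpointSide,
    InsertionBlock,
    JunctionRecord,
)

RepeatTrack = dict[str, list[tuple[int, int, str]]]


def read_repeat_track(path: str) -> RepeatTrack:
    """Read a RepeatMasker ``.out`` file or BED6 into 1-based intervals.

    BED intervals (0-based half-open, tab-separated, name in column 4) are
    converted; RepeatMasker rows are whitespace-separated with the element
    name in column 10 and 1-based inclusive coordinates.
    """
    track: RepeatTrack = {}
    with open(path) as fh:
        lines = fh.readlines()
    is_rm = any(line.lstrip().startswith("SW") or "repeat" in line.lower()
                for line in lines[:3]) and not (lines and "\t" in lines[0])
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if "\t" in line:
            fields = stripped.split("\t")
            if len(fields) < 4:
                continue
            contig, start0, end0, name = fields[0], fields[1], fields[2], fields[3]
            track.setdefault(contig, []).append((int(start0) + 1, int(end0), name))
        else:
            fields = stripped.split()
            if not fields or not fields[0].replace(".", "").isdigit():
                continue  # header lines of the .out format
            if len(fields) < 10:
                continue
            contig, begin, end, name = fields[4], fields[5], fields[6], fields[9]
            track.setdefault(contig, []).append((int(begin), int(end), name))
    for intervals in track.values():
        intervals.sort()
    return track


def read_freq_table(path: str) -> dict[tuple[str, int, str, str], float]:
    """TSV of (contig, pos, ref, alt, AF); a header line is tolerated."""
    table: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5 or not fields[1].isdigit():
                continue
            table[(fields[0], int(fields[1]), fields[2], fields[3])] = float(fields[4])
    return table


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------

JUNCTION_TSV_COLUMNS = [
    "Case", "Category", "Chromosome", "Junction", "Side1", "Side2",
    "Side1:Repeat", "Side2:Repeat", "MH(bp)", "Ins(bp)",
]


def _na(value) -> str:
    return "NA" if value is None else str(value)


def write_junction_tsv(records: list[JunctionRecord], path: str,
                       category: str = "NA") -> None:
    """Write records in the published junction-table column schema."""
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_TSV_COLUMNS) + "\n")
        for rec in records:
            chrom = rec.side1.contig if rec.side1 else (
                rec.side2.contig if rec.side2 else "NA")
            fh.write("\t".join([
                rec.case_id, category, chrom, str(rec.junction_id),
                _na(rec.side1.position if rec.side1 else None),
                _na(rec.side2.position if rec.side2 else None),
                _na(rec.repeat1), _na(rec.repeat2),
                _na(rec.microhomology_len), _na(rec.insertion_len),
            ]) + "\n")


def read_junction_tsv(path: str) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            rows.append({
                "case": row["Case"], "category": row["Category"],
                "chromosome": row["Chromosome"], "junction": int(row["Junction"]),
                "side1": None if row["Side1"] == "NA" else int(row["Side1"]),
                "side2": None if row["Side2"] == "NA" else int(row["Side2"]),
                "repeat1": None if row["Side1:Repeat"] == "NA" else row["Side1:Repeat"],
                "repeat2": None if row["Side2:Repeat"] == "NA" else row["Side2:Repeat"],
                "mh": None if row["MH(bp)"] == "NA" else int(row["MH(bp)"]),
                "ins": None if row["Ins(bp)"] == "NA" else int(row["Ins(bp)"]),
            })
    return rows


def _side_dict(side: Optional[BreakpointSide]):
    if side is None:
        return None
    return {"contig": side.contig, "position": side.position,
            "orientation": side.orientation}


def _side_from(data) -> Optional[BreakpointSide]:
    if data is None:
        return None
    return BreakpointSide(data["contig"], data["position"], data["orientation"])


def write_junction_json(records: list[JunctionRecord], path: str) -> None:
    """Extended JSON with orientations, insertion blocks and consensus."""
    payload = []
    for rec in records:
        blocks = None
        if rec.insertion_blocks is not None:
            blocks = [{
                "kind": b.kind, "sequence": b.sequence,
                "source_contig": b.source_contig, "source_start": b.source_start,
                "source_end": b.source_end, "source_strand": b.source_strand,
            } for b in rec.insertion_blocks]
        payload.append({
            "case_id": rec.case_id, "junction_id": rec.junction_id,
            "side1": _side_dict(rec.side1), "side2": _side_dict(rec.side2),
            "microhomology_len": rec.microhomology_len,
            "microhomology_seq": rec.microhomology_seq,
            "insertion_len": rec.insertion_len,
            "insertion_blocks": blocks,
            "repeat1": rec.repeat1, "repeat2": rec.repeat2,
            "support": rec.support, "consensus": rec.consensus,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_junction_json(path: str) -> list[JunctionRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    records = []
    for item in payload:
        blocks = None
        if item["insertion_blocks"] is not None:
            blocks = [InsertionBlock(
                b["kind"], b["sequence"], b["source_contig"],
                b["source_start"], b["source_end"], b["source_strand"],
            ) for b in item["insertion_blocks"]]
        records.append(JunctionRecord(
            item["case_id"], item["junction_id"],
            _side_from(item["side1"]), _side_from(item["side2"]),
            item["microhomology_len"], item["microhomology_seq"],
            item["insertion_len"], blocks,
            item["repeat1"], item["repeat2"], item["support"], item["consensus"],
        ))
    return records


def read_cn_tsv(path: str):
    """Copy-number TSV: contig, start, end, state (header optional)."""
    from ..core import CopyNumberSegment

    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4 or not fields[1].isdigit():
                continue
            out.append(CopyNumberSegment(fields[0], int(fields[1]),
                                         int(fields[2]), int(fields[3])))
    return out


def write_cn_tsv(segments, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstate\n")
        for seg in segments:
            fh.write(f"{seg.contig}\t{seg.start}\t{seg.end}\t{seg.state}\n")
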