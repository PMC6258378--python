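"""VCF 4.2 breakend output (paired BND records with MATEID).

Microhomology is carried in HOMLEN/HOMSEQ and inserted junction sequence in
SVINSSEQ, matching common SV-caller conventions.
"""

from __future__ import annotations

from typing import Optional

from ..core import FORWARD, GenomeModel, JunctionRecord


def _bracket(mate: str, forward_join: bool) -> str:
    return f"[{mate}[" if forward_join else f"]{mate}]"


def _alt_for(side, other, t: str, left_role: bool) -> str:
    mate = f"{other.contig}:{other.position}"
    if left_role:
        # breakend at the end of a derivative segment
        if side.orientation == FORWARD:
            return t + (_bracket(mate, True) if other.orientation == FORWARD
                        else _bracket(mate, False))
        return (_bracket(mate, True) if other.orientation == FORWARD
                else _bracket(mate, False)) + t
    # breakend at the start of a derivative segment
    if side.orientation == FORWARD:
        return (_bracket(mate, False) if other.orientation == FORWARD
                else _bracket(mate, True)) + t
    return t + (_bracket(mate, False) if other.orientation == FORWARD
                else _bracket(mate, True))


_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint microhomology">
##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Sequence of breakpoint microhomology">
##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Inserted sequence at the junction">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting split reads">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: list[JunctionRecord], path: str,
              genome: Optional[GenomeModel] = None) -> None:
    lines = []
    contigs = []
    for rec in records:
        if rec.side1 is None or rec.side2 is None:
            continue
        for side in (rec.side1, rec.side2):
            if side.contig not in contigs:
                contigs.append(side.contig)
        base = f"{rec.case_id}_{rec.junction_id}"
        info_common = []
        if rec.microhomology_len:
            info_common.append(f"HOMLEN={rec.microhomology_len}")
            if rec.microhomology_seq:
                info_common.append(f"HOMSEQ={rec.microhomology_seq}")
        if rec.insertion_blocks:
            ins = "".join(b.sequence for b in rec.insertion_blocks)
            info_common.append(f"SVINSSEQ={ins}")
        info_common.append(f"SUPPORT={rec.support}")

        def ref_base(side) -> str:
            if genome is not None and side.contig in genome:
                return genome.contigs[side.contig][side.position - 1]
            return "N"

        t1, t2 = ref_base(rec.side1), ref_base(rec.side2)
        alt1 = _alt_for(rec.side1, rec.side2, t1, left_role=True)
        alt2 = _alt_for(rec.side2, rec.side1, t2, left_role=False)
        info1 = ";".join(["SVTYPE=BND", f"MATEID={base}_2"] + info_common)
        info2 = ";".join(["SVTYPE=BND", f"MATEID={base}_1"] + info_common)
        lines.append(f"{rec.side1.contig}\t{rec.side1.position}\t{base}_1\t"
                     f"{t1}\t{alt1}\t.\tPASS\t{info1}")
        lines.append(f"{rec.side2.contig}\t{rec.side2.position}\t{base}_2\t"
                     f"{t2}\t{alt2}\t.\tPASS\t{info2}")
    with open(path, "w") as fh:
        header = _HEADER
        contig_lines = ""
        if genome is not None:
            contig_lines = "".join(
                f"##contig=<ID={c},length={genome.lengths[c]}>\n" for c in contigs)
        head, tail = header.rsplit("#CHROM", 1)
        fh.write(head + contig_lines + "#CHROM" + tail)
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_vcf_candidates(path: str) -> list[tuple[str, int, int]]:
    """Candidate SV intervals from a VCF (END intervals or BND points)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            contig, pos, info = fields[0], int(fields[1]), fields[7]
            end = pos
            for item in info.split(";"):
                if item.startswith("END="):
                    end = int(item[4:])
            out.append((contig, min(pos, end), max(pos, end)))
    return out
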