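"""Bundled cohort fixtures: 21 cases, 83 junction rows, patterns and labels.

The tables ship as package data.  ``NA`` values are preserved as ``None``
(never coerced to 0) — the resolved-junction statistic depends on it.  Raw
descriptor strings are stored verbatim alongside a parseable ``clean`` form
(faithful orientations, typos repaired) and a ``normalized`` form
(consistent with the printed pattern strings); see the project notes for
the per-case normalization decisions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from ..core import CopyNumberSegment
from ..descriptors import (
    GROUP_LABELS,
    DescriptorOp,
    PatternString,
    parse_descriptor,
    parse_iscn_cnv,
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class CaseRow:
    case: str
    raw_case: str
    chromosome: str
    accession: str
    group: str
    inheritance: Optional[str]
    pathogenicity: str
    cma_iscn: str
    descriptor_raw: str
    descriptor_clean: str
    descriptor_normalized: str


@dataclass(frozen=True)
class JunctionRow:
    case: str
    category: str
    chromosome: str
    junction: int
    side1: Optional[int]
    side2: Optional[int]
    repeat1: Optional[str]
    repeat2: Optional[str]
    mh: Optional[int]
    ins: Optional[int]

    @property
    def resolved(self) -> bool:
        return self.mh is not None and self.ins is not None


@dataclass
class FixtureBundle:
    table1: list[CaseRow]
    table2: list[JunctionRow]
    table3: dict[str, tuple[PatternString, PatternString]]  # case -> (CMA, WGS)
    mechanisms: dict[str, str]
    overrides: dict[str, tuple[str, str]]  # case -> (mechanism, reason)
    contig_lengths: dict[str, int]

    @property
    def cases(self) -> list[str]:
        return [row.case for row in self.table1]

    def case_row(self, case: str) -> CaseRow:
        for row in self.table1:
            if row.case == case:
                return row
        raise KeyError(case)

    def junctions_for(self, case: str) -> list[JunctionRow]:
        return [r for r in self.table2 if r.case == case]

    def cn_profile(self, case: str) -> list[CopyNumberSegment]:
        return parse_iscn_cnv(self.case_row(case).cma_iscn)

    def descriptor_ops(self, case: str, which: str = "normalized") -> list[DescriptorOp]:
        row = self.case_row(case)
        text = {
            "raw": row.descriptor_raw,
            "clean": row.descriptor_clean,
            "normalized": row.descriptor_normalized,
        }[which]
        return parse_descriptor(text, contig_length=self.contig_lengths[row.chromosome])


def _rows(name: str) -> list[dict[str, str]]:
    ref = resources.files("svjunction.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _maybe_int(value: str) -> Optional[int]:
    return None if value == "NA" else int(value)


def _maybe_str(value: str) -> Optional[str]:
    return None if value == "NA" else value


def load_fixture() -> FixtureBundle:
    """Load and validate the bundled cohort tables (schema violations fatal)."""
    table1 = [
        CaseRow(
            r["case"], r["raw_case"], r["chromosome"], r["accession"], r["group"],
            _maybe_str(r["inheritance"]), r["pathogenicity"], r["cma_iscn"],
            r["descriptor_raw"], r["descriptor_clean"], r["descriptor_normalized"],
        )
        for r in _rows("table1.tsv")
    ]
    table2 = [
        JunctionRow(
            r["case"], r["category"], r["chromosome"], int(r["junction"]),
            _maybe_int(r["side1"]), _maybe_int(r["side2"]),
            _maybe_str(r["repeat1"]), _maybe_str(r["repeat2"]),
            _maybe_int(r["mh"]), _maybe_int(r["ins"]),
        )
        for r in _rows("table2.tsv")
    ]
    table3 = {
        r["case"]: (PatternString.parse(r["cma_pattern"]),
                    PatternString.parse(r["wgs_pattern"]))
        for r in _rows("table3.tsv")
    }
    mechanisms = {r["case"]: r["mechanism"] for r in _rows("mechanisms.tsv")}
    overrides = {r["case"]: (r["mechanism"], r["reason"]) for r in _rows("overrides.tsv")}
    contigs = {r["chromosome"]: int(r["length"]) for r in _rows("contigs.tsv")}

    bundle = FixtureBundle(table1, table2, table3, mechanisms, overrides, contigs)
    _validate(bundle)
    return bundle


def _validate(bundle: FixtureBundle) -> None:
    cases = bundle.cases
    if len(cases) != 21 or len(set(cases)) != 21:
        raise FixtureError(f"expected 21 unique cases, found {len(cases)}")
    if len(bundle.table2) != 83:
        raise FixtureError(f"expected 83 junction rows, found {len(bundle.table2)}")
    keys = {(r.case, r.junction) for r in bundle.table2}
    if len(keys) != 83:
        raise FixtureError("duplicate (case, junction) keys in table2")
    for row in bundle.table1:
        if row.group not in GROUP_LABELS:
            raise FixtureError(f"bad group {row.group!r} for {row.case}")
        if row.chromosome not in bundle.contig_lengths:
            raise FixtureError(f"no contig length for chromosome {row.chromosome}")
    case_set = set(cases)
    for row in bundle.table2:
        if row.case not in case_set:
            raise FixtureError(f"table2 case {row.case!r} missing from table1")
    if set(bundle.table3) != case_set:
        raise FixtureError("table3 cases inconsistent with table1")
    if set(bundle.mechanisms) != case_set:
        raise FixtureError("mechanism labels inconsistent with table1")
    for case in bundle.overrides:
        if case not in case_set:
            raise FixtureError(f"override for unknown case {case!r}")
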