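"""Per-junction repair-mechanism signatures and per-case mechanism calls.

Signature thresholds follow the junction-chemistry ranges associated with
the canonical repair pathways: blunt joints and 1-4 bp microhomology for
NHEJ, microhomology-dependent joints with templated inserts for MMEJ,
5-25 bp insertion scars for Polθ-driven alt-NHEJ and 1-5 bp microhomology
for replicative template switching (FoSTeS/MMBIR).  The case-level call is
a documented decision tree over the group label and junction flags; the
expert per-case partition is reproduced only with an explicit override
table, never silently.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import REVERSE, RETAINED, DerivativeStructure
from .descriptors import (
    DELETIONS_ONLY,
    DUPLICATIONS_ONLY,
    GROUP_LABELS,
)
from .reconstruct import DuplicationCall, INTERSPERSED, TANDEM, _covered_fraction

CHROMOTHRIPSIS = "chromothripsis"
CHROMOANASYNTHESIS = "chromoanasynthesis"
AMBIGUOUS = "ambiguous"

BLUNT_NHEJ = "blunt_NHEJ"
SHORT_MH_NHEJ = "short_MH_NHEJ"
MMEJ = "MMEJ"
ALT_NHEJ_POLQ = "altNHEJ_polQ_insert"
REPLICATIVE_MH = "replicative_MH"
REPEAT_ALU = "repeat_mediated_Alu"
REPEAT_LINE = "repeat_mediated_LINE"
NOVEL_SNV = "novel_SNV_nearby"


@dataclass(frozen=True)
class SignatureConfig:
    nhej_mh_max: int = 4
    polq_insert_min: int = 5
    polq_insert_max: int = 25
    replicative_mh_min: int = 1
    replicative_mh_max: int = 5
    ambiguous_nontemplated_insert_gt: int = 8
    alu_identity_hr_bound: float = 90.0
    templated_window: int = 100
    snv_window: int = 1000

    def __post_init__(self) -> None:
        if self.polq_insert_min > self.polq_insert_max:
            raise ValueError("polq insert min > max")
        if self.replicative_mh_min > self.replicative_mh_max:
            raise ValueError("replicative MH min > max")
        for name in ("nhej_mh_max", "polq_insert_min", "polq_insert_max",
                     "replicative_mh_min", "replicative_mh_max",
                     "ambiguous_nontemplated_insert_gt", "templated_window",
                     "snv_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = SignatureConfig()


def repeat_family(name: Optional[str]) -> Optional[str]:
    """Coarse repeat-class from a RepeatMasker element name."""
    if not name:
        return None
    if name.startswith("Alu"):
        return "Alu"
    if name.startswith(("L1", "L2", "L3", "L4", "HAL")):
        return "LINE"
    if name.startswith("MIR"):
        return "MIR"
    if name.startswith(("LTR", "MLT", "MST", "THE", "MER", "HERV")):
        return "LTR"
    return "other"


def same_repeat_family(repeat1: Optional[str], repeat2: Optional[str]) -> bool:
    f1, f2 = repeat_family(repeat1), repeat_family(repeat2)
    return f1 is not None and f1 == f2 and f1 != "other"


# ---------------------------------------------------------------------------
# junction scoring
# ---------------------------------------------------------------------------

@dataclass
class JunctionSignature:
    flags: set[str]
    evidence: list[tuple[str, object, object]]  # (flag, value, threshold)


def _mh_of(j) -> Optional[int]:
    return getattr(j, "microhomology_len", getattr(j, "mh", None))


def _ins_of(j) -> Optional[int]:
    return getattr(j, "insertion_len", getattr(j, "ins", None))


def _nontemplated_of(j) -> Optional[int]:
    blocks = getattr(j, "insertion_blocks", None)
    if blocks:
        return sum(len(b.sequence) for b in blocks if b.kind == "non_templated")
    return _ins_of(j)


def _has_templated(j) -> bool:
    blocks = getattr(j, "insertion_blocks", None)
    return bool(blocks) and any(b.kind == "templated" for b in blocks)


def score_junction(j, config: SignatureConfig = DEFAULT_CONFIG,
                   has_novel_snv: bool = False) -> Optional[JunctionSignature]:
    """Signature flags for one resolved junction; None when unresolved."""
    mh = _mh_of(j)
    ins = _ins_of(j)
    if mh is None or ins is None:
        return None
    nt = _nontemplated_of(j) or 0
    flags: set[str] = set()
    evidence: list[tuple[str, object, object]] = []

    if mh == 0 and ins == 0:
        flags.add(BLUNT_NHEJ)
        evidence.append((BLUNT_NHEJ, (mh, ins), (0, 0)))
    if 1 <= mh <= config.nhej_mh_max and ins < config.polq_insert_min:
        flags.add(SHORT_MH_NHEJ)
        evidence.append((SHORT_MH_NHEJ, mh, (1, config.nhej_mh_max)))
    if mh >= 2 or _has_templated(j):
        flags.add(MMEJ)
        evidence.append((MMEJ, mh if mh >= 2 else "templated insert", 2))
    if nt >= config.polq_insert_min:
        flags.add(ALT_NHEJ_POLQ)
        within = nt <= config.polq_insert_max
        evidence.append((ALT_NHEJ_POLQ, nt,
                         (config.polq_insert_min, config.polq_insert_max)
                         if within else f"> {config.polq_insert_max} (magnitude)"))
    if config.replicative_mh_min <= mh <= config.replicative_mh_max:
        flags.add(REPLICATIVE_MH)
        evidence.append((REPLICATIVE_MH, mh,
                         (config.replicative_mh_min, config.replicative_mh_max)))
    r1 = getattr(j, "repeat1", None)
    r2 = getattr(j, "repeat2", None)
    if same_repeat_family(r1, r2):
        fam = repeat_family(r1)
        if fam == "Alu":
            flags.add(REPEAT_ALU)
            evidence.append((REPEAT_ALU, (r1, r2), "same Alu family"))
        elif fam == "LINE":
            flags.add(REPEAT_LINE)
            evidence.append((REPEAT_LINE, (r1, r2), "same LINE family"))
    if has_novel_snv:
        flags.add(NOVEL_SNV)
        evidence.append((NOVEL_SNV, True, f"<= {config.snv_window} bp"))
    return JunctionSignature(flags, evidence)


# ---------------------------------------------------------------------------
# BFB / ring signature
# ---------------------------------------------------------------------------

def detect_bfb_ring(
    structure: DerivativeStructure,
    contig_length: int,
    tol: int = 1000,
) -> tuple[bool, list[str]]:
    """Terminal inverted-duplication-replacing-terminal-deletion signature.

    True iff one terminus carries a terminal deletion whose position in the
    derivative is occupied by an inverted, duplicated copy of the opposite
    terminal region.
    """
    segs = structure.segments
    retained = [s for s in segs if s.provenance == RETAINED]
    copies = [s for s in segs if s.provenance != RETAINED]
    if not retained:
        return False, ["no retained segments; not evaluable"]
    min_ret = min(s.start for s in retained)
    max_ret = max(s.end for s in retained)
    footprint_lo = min(s.start for s in segs)
    footprint_hi = max(s.end for s in segs)
    if footprint_lo > tol + 1 and footprint_hi < contig_length - tol:
        return False, ["structure does not reach either terminus; not evaluable"]

    first_ret = next(i for i, s in enumerate(segs) if s.provenance == RETAINED)
    last_ret = max(i for i, s in enumerate(segs) if s.provenance == RETAINED)
    evidence: list[str] = []

    def duplicated(c) -> bool:
        return _covered_fraction(c, [s for s in segs if s is not c]) >= 0.5

    # left terminus deleted, replaced by inverted copy of the right terminal arm
    if min_ret > 1:
        for c in segs[:first_ret]:
            if (c.provenance != RETAINED and c.orientation == REVERSE
                    and c.end >= contig_length - tol and duplicated(c)):
                evidence.append(
                    f"terminal deletion 1-{min_ret - 1} replaced by inverted "
                    f"duplicated copy of {c.start}-{c.end}")
                return True, evidence
    # right terminus deleted, replaced by inverted copy of the left terminal arm
    if max_ret < contig_length:
        for c in segs[last_ret + 1 :]:
            if (c.provenance != RETAINED and c.orientation == REVERSE
                    and c.start <= 1 + tol and duplicated(c)):
                evidence.append(
                    f"terminal deletion {max_ret + 1}-{contig_length} replaced "
                    f"by inverted duplicated copy of {c.start}-{c.end}")
                return True, evidence
    evidence.append("no terminal inverted-duplication replacement found")
    return False, evidence


# ---------------------------------------------------------------------------
# case-level mechanism call
# ---------------------------------------------------------------------------

@dataclass
class CaseProfile:
    case_id: str
    group: str
    junctions: list  # JunctionRecord or fixture JunctionRow
    duplication_calls: list[DuplicationCall] = field(default_factory=list)
    structure: Optional[DerivativeStructure] = None
    has_novel_snv: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"bad group {self.group!r}")

    @property
    def resolved_junctions(self) -> list:
        return [j for j in self.junctions
                if _mh_of(j) is not None and _ins_of(j) is not None]


@dataclass
class CaseMechanismCall:
    case_id: str
    group: str
    suggestion: str
    bfb_ring_flag: bool
    evidence: list[str]
    overridden: bool = False


class UnclassifiableError(ValueError):
    pass


def call_case_mechanism(
    profile: CaseProfile,
    config: SignatureConfig = DEFAULT_CONFIG,
    overrides: Optional[dict[str, tuple[str, str]]] = None,
    bfb_ring_flag: bool = False,
) -> CaseMechanismCall:
    """Decision tree: large non-templated inserts -> ambiguous; else by group.

    The tree is deliberately simple and documented; the expert judgment in
    the published per-case partition is expressed through ``overrides``
    (case -> (mechanism, reason)), and every call carries its evidence.
    """
    evidence: list[str] = []
    resolved = profile.resolved_junctions
    if not profile.junctions:
        raise UnclassifiableError(f"{profile.case_id}: no junctions at all")
    if not resolved:
        suggestion = CHROMOTHRIPSIS if profile.group == DELETIONS_ONLY else CHROMOANASYNTHESIS
        evidence.append("no resolved junctions; call from group label alone")
    else:
        threshold = config.ambiguous_nontemplated_insert_gt
        large = [(_nontemplated_of(j) or 0) for j in resolved
                 if (_nontemplated_of(j) or 0) > threshold]
        if large:
            suggestion = AMBIGUOUS
            evidence.append(
                f"non-templated inserts {sorted(large)} exceed {threshold} bp")
        elif profile.group == DELETIONS_ONLY:
            suggestion = CHROMOTHRIPSIS
            evidence.append("deletions-only profile without large inserts")
        else:
            suggestion = CHROMOANASYNTHESIS
            evidence.append("duplication-containing profile without large inserts")
    overridden = False
    if overrides and profile.case_id in overrides:
        suggestion, reason = overrides[profile.case_id]
        evidence.append(f"override applied: {reason}")
        overridden = True
    if bfb_ring_flag:
        evidence.append("terminal inverted-duplication (BFB/ring) signature present")
    return CaseMechanismCall(profile.case_id, profile.group, suggestion,
                             bfb_ring_flag, evidence, overridden)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(profiles: Sequence[CaseProfile]) -> dict:
    """Cohort statistics table (counts, MH distribution, duplication mix)."""
    if not profiles:
        raise ValueError("need at least one case")
    junctions = [j for p in profiles for j in p.junctions]
    resolved = [j for p in profiles for j in p.resolved_junctions]
    mh_values = [_mh_of(j) for j in junctions if _mh_of(j) is not None]
    mh_bearing = [v for v in mh_values if v >= 2]
    blunt = [j for j in resolved if _mh_of(j) == 0 and _ins_of(j) == 0]
    ins_sizes = sorted(_ins_of(j) for j in resolved if (_ins_of(j) or 0) > 0)

    groups: dict[str, list[CaseProfile]] = {label: [] for label in GROUP_LABELS}
    for p in profiles:
        groups[p.group].append(p)

    def per_case_counts(group_profiles: Iterable[CaseProfile]) -> list[int]:
        return [len(p.junctions) for p in group_profiles]

    per_group = {}
    for label, members in groups.items():
        counts = per_case_counts(members)
        per_group[label] = {
            "cases": len(members),
            "junctions_per_case_mean": round(sum(counts) / len(counts)) if counts else 0,
            "junctions_per_case_range": (min(counts), max(counts)) if counts else (0, 0),
        }

    all_counts = per_case_counts(profiles)
    dups = [c for p in profiles for c in p.duplication_calls]
    tandem = [c for c in dups if c.architecture == TANDEM]
    interspersed = [c for c in dups if c.architecture == INTERSPERSED]
    inverted = [c for c in dups if c.orientation == REVERSE]
    adjacent = [c for c in interspersed if c.adjacent_to_other_duplicate]

    summary = {
        "junctions_total": len(junctions),
        "junctions_resolved": len(resolved),
        "junctions_per_case_mean": round(sum(all_counts) / len(all_counts)),
        "junctions_per_case_range": (min(all_counts), max(all_counts)),
        "groups": per_group,
        "mh_count": len(mh_bearing),
        "mh_min": min(mh_bearing) if mh_bearing else None,
        "mh_max": max(mh_bearing) if mh_bearing else None,
        "mh_median": statistics.median(mh_bearing) if mh_bearing else None,
        "blunt_count": len(blunt),
        "insertion_sizes": ins_sizes,
        "duplicated_fragments": len(dups),
        "duplications_tandem": len(tandem),
        "duplications_interspersed": len(interspersed),
        "duplications_inverted": len(inverted),
        "pct_interspersed": round(100 * len(interspersed) / len(dups)) if dups else None,
        "pct_inverted": round(100 * len(inverted) / len(dups)) if dups else None,
        "pct_adjacent_to_other_duplicate": (
            round(100 * len(adjacent) / len(interspersed)) if interspersed else None),
    }
    return summary
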