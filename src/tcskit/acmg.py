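"""ACMG/AMP evidence combination and the cohort's variant triage filters.

Evidence codes carry their guideline default strengths (PVS1 very strong,
PS* strong, PM* moderate, PP* supporting; BA1 stand-alone, BS* strong,
BP* supporting) with structural support for per-use overrides. The
combiner implements the published five-tier combining clauses; evidence
satisfying both a pathogenic-side and a benign-side clause resolves to
uncertain significance with a conflict warning.

Triage reproduces the upstream filters of a Mendelian exome workup:
variants with allele frequency above 0.01% (the maximum of the worldwide
and admixed-American values supplied), with a non-matching inheritance
mode, or with fewer than two patient manifestations matching the gene's
phenotype spectrum are excluded, each with its triggering rule recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .errors import ValidationError
from .hgvs import ProteinConsequence, SpliceClass

__all__ = [
    "EvidenceCode",
    "Classification",
    "TriageRecord",
    "TriageResult",
    "combine",
    "triage",
    "double_count_guard",
    "suggest_evidence",
    "VALID_CODES",
]

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")

#: code -> (default strength, direction)
VALID_CODES: dict[str, tuple[str, str]] = {}
VALID_CODES["PVS1"] = ("very_strong", "pathogenic")
for _i in range(1, 5):
    VALID_CODES[f"PS{_i}"] = ("strong", "pathogenic")
for _i in range(1, 7):
    VALID_CODES[f"PM{_i}"] = ("moderate", "pathogenic")
for _i in range(1, 6):
    VALID_CODES[f"PP{_i}"] = ("supporting", "pathogenic")
VALID_CODES["BA1"] = ("stand_alone", "benign")
for _i in range(1, 5):
    VALID_CODES[f"BS{_i}"] = ("strong", "benign")
for _i in range(1, 8):
    VALID_CODES[f"BP{_i}"] = ("supporting", "benign")


@dataclass(frozen=True)
class EvidenceCode:
    """One applied evidence criterion, optionally with a strength override."""

    code: str
    strength: Optional[str] = None  # None -> guideline default
    note: str = ""
    rationale: str = ""  # e.g. "lof", "splice_prediction"

    def __post_init__(self):
        if self.code not in VALID_CODES:
            raise ValidationError(
                f"unknown evidence code {self.code!r}; valid codes: "
                f"{', '.join(sorted(VALID_CODES))}"
            )
        if self.strength is not None and self.strength not in STRENGTHS:
            raise ValidationError(
                f"unknown strength {self.strength!r}; valid: {', '.join(STRENGTHS)}"
            )

    @property
    def effective_strength(self) -> str:
        return self.strength or VALID_CODES[self.code][0]

    @property
    def direction(self) -> str:
        return VALID_CODES[self.code][1]


@dataclass(frozen=True)
class Classification:
    """Five-tier verdict with the combining clause that fired."""

    tier: str
    fired_rule: str
    warnings: tuple[str, ...] = ()


def _as_codes(evidence: Iterable[Union[EvidenceCode, str]]) -> list[EvidenceCode]:
    out = []
    seen = set()
    for e in evidence:
        code = EvidenceCode(e) if isinstance(e, str) else e
        if code.code in seen:
            raise ValidationError(f"duplicate evidence code {code.code}")
        seen.add(code.code)
        out.append(code)
    return out


def _pathogenic_tier(vs: int, s: int, m: int, p: int) -> Optional[tuple[str, str]]:
    # extra very-strong codes count toward the strong tally
    s = s + max(0, vs - 1)
    vs = min(vs, 1)
    if vs and s >= 1:
        return "pathogenic", "1 very strong + >=1 strong"
    if vs and m >= 2:
        return "pathogenic", "1 very strong + >=2 moderate"
    if vs and m == 1 and p >= 1:
        return "pathogenic", "1 very strong + 1 moderate + >=1 supporting"
    if vs and p >= 2:
        return "pathogenic", "1 very strong + >=2 supporting"
    if s >= 2:
        return "pathogenic", ">=2 strong"
    if s == 1 and m >= 3:
        return "pathogenic", "1 strong + >=3 moderate"
    if s == 1 and m == 2 and p >= 2:
        return "pathogenic", "1 strong + 2 moderate + >=2 supporting"
    if s == 1 and m == 1 and p >= 4:
        return "pathogenic", "1 strong + 1 moderate + >=4 supporting"
    if vs and m == 1:
        return "likely_pathogenic", "1 very strong + 1 moderate"
    if s == 1 and 1 <= m <= 2:
        return "likely_pathogenic", "1 strong + 1-2 moderate"
    if s == 1 and p >= 2:
        return "likely_pathogenic", "1 strong + >=2 supporting"
    if m >= 3:
        return "likely_pathogenic", ">=3 moderate"
    if m == 2 and p >= 2:
        return "likely_pathogenic", "2 moderate + >=2 supporting"
    if m == 1 and p >= 4:
        return "likely_pathogenic", "1 moderate + >=4 supporting"
    return None


def _benign_tier(ba: int, bs: int, bp: int) -> Optional[tuple[str, str]]:
    if ba >= 1:
        return "benign", "1 stand-alone"
    if bs >= 2:
        return "benign", ">=2 benign strong"
    if bs == 1 and bp >= 1:
        return "likely_benign", "1 benign strong + 1 benign supporting"
    if bp >= 2:
        return "likely_benign", ">=2 benign supporting"
    return None


def combine(evidence: Iterable[Union[EvidenceCode, str]]) -> Classification:
    """Combine evidence codes into a five-tier classification.

    Accepts :class:`EvidenceCode` objects or bare code strings. Codes must
    be unique per variant. When the evidence simultaneously satisfies a
    pathogenic-side and a benign-side clause the verdict is uncertain
    significance with a conflict warning.
    """

    codes = _as_codes(evidence)
    vs = s = m = p = ba = bs = bp = 0
    for c in codes:
        st = c.effective_strength
        if c.direction == "pathogenic":
            if st == "very_strong":
                vs += 1
            elif st == "strong":
                s += 1
            elif st == "moderate":
                m += 1
            elif st == "supporting":
                p += 1
            else:
                raise ValidationError(f"{c.code}: stand_alone is a benign-only strength")
        else:
            if st == "stand_alone":
                ba += 1
            elif st == "strong":
                bs += 1
            else:
                bp += 1
    path = _pathogenic_tier(vs, s, m, p)
    ben = _benign_tier(ba, bs, bp)
    if path and ben:
        return Classification(
            "uncertain_significance",
            "conflict",
            (f"conflicting evidence: {path[1]} vs {ben[1]}",),
        )
    if path:
        return Classification(path[0], path[1])
    if ben:
        return Classification(ben[0], ben[1])
    return Classification("uncertain_significance", "no clause matched")


def double_count_guard(evidence: Iterable[Union[EvidenceCode, str]]) -> list[str]:
    """Warn about double-counted loss-of-function evidence.

    PVS1 already captures the LOF consequence, so PM4 (protein length
    change) alongside PVS1 is flagged, as is PP3 when its rationale is the
    same LOF argument. Warnings only; nothing is removed.
    """

    codes = {c.code: c for c in _as_codes(evidence)}
    warnings = []
    if "PVS1" in codes and "PM4" in codes:
        warnings.append(
            "PVS1 + PM4: protein length change double-counts LOF evidence "
            "already captured by PVS1"
        )
    if "PVS1" in codes and "PP3" in codes:
        pp3 = codes["PP3"]
        text = (pp3.rationale + " " + pp3.note).lower()
        if "lof" in text or "loss-of-function" in text or "loss of function" in text:
            warnings.append(
                "PVS1 + PP3: computational support restates the LOF rationale "
                "already captured by PVS1"
            )
    return warnings


@dataclass(frozen=True)
class TriageRecord:
    """Per-variant facts the upstream filters act on."""

    variant_id: str
    af_worldwide: Optional[float] = None
    af_admixed_american: Optional[float] = None
    inheritance_match: bool = True
    n_matching_manifestations: int = 0

    def __post_init__(self):
        for af in (self.af_worldwide, self.af_admixed_american):
            if af is not None and not 0 <= af <= 1:
                raise ValidationError(f"{self.variant_id}: allele frequency {af} not in [0,1]")
        if self.n_matching_manifestations < 0:
            raise ValidationError("n_matching_manifestations must be >= 0")

    @property
    def allele_frequency(self) -> float:
        values = [af for af in (self.af_worldwide, self.af_admixed_american) if af is not None]
        return max(values) if values else 0.0


@dataclass(frozen=True)
class TriageResult:
    kept: tuple[TriageRecord, ...]
    excluded: tuple[tuple[TriageRecord, tuple[str, ...]], ...]
    warnings: tuple[str, ...] = ()


def triage(
    records: Iterable[TriageRecord],
    af_max: float = 1e-4,
    min_manifestations: int = 2,
) -> TriageResult:
    """Partition candidate variants into kept and excluded with reasons.

    A record is excluded iff its allele frequency exceeds ``af_max``
    (default 0.01%), its inheritance mode does not match the gene, or it
    has fewer than ``min_manifestations`` matching patient manifestations.
    Missing frequencies are treated as 0 with a provenance warning.
    """

    kept, excluded, warnings = [], [], []
    for rec in records:
        if rec.af_worldwide is None and rec.af_admixed_american is None:
            warnings.append(
                f"{rec.variant_id}: no allele frequency supplied; treated as 0"
            )
        reasons = []
        if rec.allele_frequency > af_max:
            reasons.append("allele_frequency")
        if not rec.inheritance_match:
            reasons.append("inheritance")
        if rec.n_matching_manifestations < min_manifestations:
            reasons.append("manifestations")
        if reasons:
            excluded.append((rec, tuple(reasons)))
        else:
            kept.append(rec)
    return TriageResult(tuple(kept), tuple(excluded), tuple(warnings))


def suggest_evidence(
    consequence: Union[ProteinConsequence, SpliceClass],
    gene_mechanism: str = "other",
    present_in_databases: bool = False,
) -> set[EvidenceCode]:
    """Suggest candidate evidence codes from a computed consequence.

    PVS1 is suggested only for a null consequence (frameshift, nonsense,
    or canonical splice disruption) in a gene with an established
    loss-of-function mechanism; PM2 when the variant is absent from the
    supplied population resources. Suggestions only — curation confirms.
    """

    suggestions: set[EvidenceCode] = set()
    if isinstance(consequence, SpliceClass):
        null = consequence.canonical
        note = f"{consequence.site} {consequence.offset:+d} splice disruption"
    else:
        null = consequence.kind in ("frameshift", "nonsense")
        note = f"{consequence.kind} ({consequence.hgvs_p})"
    if null and gene_mechanism == "LOF_established":
        suggestions.add(EvidenceCode("PVS1", note=note, rationale="lof"))
    if not present_in_databases:
        suggestions.add(EvidenceCode("PM2", note="absent from population databases"))
    return suggestions
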