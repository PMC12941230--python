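"""Cohort-level phenotype frequencies and diagnostic yield.

Two percent-display conventions coexist in clinical cohort reporting and
both are implemented here, each bound to its context: per-feature
frequencies are truncated to whole percents (9/11 -> 81%), while
diagnostic yield and per-gene shares are rounded half-up to one decimal
(10/11 -> 90.9%). Unknown clinical cells stay in the denominator but
never count as present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "PhenotypeMatrix",
    "CohortRecord",
    "phenotype_frequencies",
    "diagnostic_yield",
    "gene_share",
    "floor_percent",
    "percent_1dp",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

_CELLS = ("present", "absent", "unknown")


def floor_percent(count: int, total: int) -> int:
    """Whole-percent truncation used for feature frequencies."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return math.floor(100 * count / total)


def percent_1dp(count: int, total: int) -> float:
    """One-decimal half-up rounding used for yield and gene shares."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


class PhenotypeMatrix:
    """Patients x clinical features, each cell present/absent/unknown."""

    def __init__(self, frame: pd.DataFrame):
        bad = set(frame.to_numpy().ravel()) - set(_CELLS)
        if bad:
            raise ValidationError(f"phenotype cells must be {_CELLS}, found {sorted(bad)}")
        self.frame = frame  # index = features, columns = patients

    @property
    def features(self) -> list[str]:
        return list(self.frame.index)

    @property
    def patients(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_patients(self) -> int:
        return self.frame.shape[1]

    @classmethod
    def read_csv(cls, path) -> "PhenotypeMatrix":
        try:
            frame = pd.read_csv(path, index_col=0)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot read phenotype matrix: {exc}", source=str(path)) from None
        return cls(frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def phenotype_frequencies(m: PhenotypeMatrix) -> pd.DataFrame:
    """Per-feature counts and truncated whole percents.

    Denominators are the full cohort size; unknown cells are reported
    separately and never counted as present.
    """

    if m.n_patients == 0:
        raise ValidationError("empty phenotype matrix")
    rows = []
    for feature in m.features:
        cells = m.frame.loc[feature]
        n_present = int((cells == "present").sum())
        n_absent = int((cells == "absent").sum())
        n_unknown = int((cells == "unknown").sum())
        rows.append(
            {
                "feature": feature,
                "n_present": n_present,
                "n_absent": n_absent,
                "n_unknown": n_unknown,
                "n_patients": m.n_patients,
                "percent": floor_percent(n_present, m.n_patients),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortRecord:
    """One patient's molecular outcome.

    ``solved`` is true only when a pathogenic variant is assigned; a
    candidate CNV alone leaves the patient unsolved even though an
    affected gene is recorded.
    """

    patient_id: str
    affected_gene: str  # TCOF1 | POLR1D | POLR1C | none
    solved: bool

    def __post_init__(self):
        if self.affected_gene not in ("TCOF1", "POLR1D", "POLR1C", "POLR1B", "none"):
            raise ValidationError(f"unexpected gene {self.affected_gene!r}")


def diagnostic_yield(cohort: Iterable[CohortRecord]) -> tuple[float, float]:
    """Solved fraction and its one-decimal percent."""
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("empty cohort")
    n_solved = sum(rec.solved for rec in cohort)
    return n_solved / len(cohort), percent_1dp(n_solved, len(cohort))


def gene_share(cohort: Iterable[CohortRecord], gene: str, solved_only: bool = False) -> tuple[float, float]:
    """Fraction and one-decimal percent of patients assigned to ``gene``."""
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("empty cohort")
    hits = sum(
        rec.affected_gene == gene and (rec.solved or not solved_only) for rec in cohort
    )
    return hits / len(cohort), percent_1dp(hits, len(cohort))


def read_cohort_tsv(path) -> list[CohortRecord]:
    records = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("patient_id", "affected_gene", "solved"):
                    if col not in header:
                        raise ParseError(f"cohort TSV missing column {col!r}", lineno, str(path))
                continue
            row = dict(zip(header, fields))
            records.append(
                CohortRecord(
                    row["patient_id"],
                    row["affected_gene"],
                    row["solved"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return records


def write_cohort_tsv(cohort: Iterable[CohortRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\taffected_gene\tsolved\n")
        for rec in cohort:
            fh.write(f"{rec.patient_id}\t{rec.affected_gene}\t{str(rec.solved).lower()}\n")
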