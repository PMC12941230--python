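"""Pedigree structures, autosomal-dominant segregation checks, and the
informative-transmission count backing PP1 co-segregation evidence.

Files use a PED-like TSV dialect: the standard six columns (family,
individual, father, mother, sex, affected) plus a seventh carrier column,
since co-segregation needs genotype status separately from phenotype.
Affected accepts yes/no/unknown or the PED codes 2/1/0(-9); carrier
accepts yes/no/untested or 1/0/. . Parents must resolve within the file
(0 = founder) and the graph must be acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import ParseError, ValidationError

__all__ = [
    "Individual",
    "Pedigree",
    "read_ped",
    "write_ped",
    "SegregationReport",
    "Violation",
    "check_ad_segregation",
    "count_informative_transmissions",
]

_AFFECTED_MAP = {
    "yes": "yes", "2": "yes", "affected": "yes",
    "no": "no", "1": "no", "unaffected": "no",
    "unknown": "unknown", "0": "unknown", "-9": "unknown", ".": "unknown",
}
_CARRIER_MAP = {
    "yes": "yes", "1": "yes", "carrier": "yes",
    "no": "no", "0": "no", "noncarrier": "no",
    "untested": "untested", ".": "untested", "-9": "untested",
}


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str] = None  # None = founder
    mother: Optional[str] = None
    sex: str = "0"  # 1 male, 2 female, 0 unknown
    affected: str = "unknown"  # yes | no | unknown
    carrier: str = "untested"  # yes | no | untested
    family: str = "F1"

    def __post_init__(self):
        if self.affected not in ("yes", "no", "unknown"):
            raise ValidationError(f"{self.iid}: affected must be yes/no/unknown")
        if self.carrier not in ("yes", "no", "untested"):
            raise ValidationError(f"{self.iid}: carrier must be yes/no/untested")


class Pedigree:
    """A validated pedigree: parents resolve or are founders, no cycles."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise ValidationError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise ValidationError(
                        f"{ind.iid}: parent {parent!r} not present in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        # DFS over the child -> parent graph; a back edge is a cycle
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {iid: WHITE for iid in self.individuals}

        def visit(iid: str):
            colour[iid] = GREY
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if colour[parent] == GREY:
                    raise ValidationError(f"pedigree cycle involving {parent!r}")
                if colour[parent] == WHITE:
                    visit(parent)
            colour[iid] = BLACK

        for iid in self.individuals:
            if colour[iid] == WHITE:
                visit(iid)

    def __len__(self) -> int:
        return len(self.individuals)

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.father is None and i.mother is None]

    def parents_of(self, iid: str) -> list[Individual]:
        ind = self.individuals[iid]
        return [self.individuals[p] for p in (ind.father, ind.mother) if p is not None]

    def parent_child_links(self) -> list[tuple[Individual, Individual]]:
        links = []
        for ind in self.individuals.values():
            for parent in self.parents_of(ind.iid):
                links.append((parent, ind))
        return links


def read_ped(path) -> Pedigree:
    """Read the 6+1 column PED dialect (carrier column optional)."""
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("PED line has fewer than 6 columns", lineno, str(path))
            fam, iid, father, mother, sex, affected = fields[:6]
            carrier = fields[6] if len(fields) > 6 else "untested"
            aff = _AFFECTED_MAP.get(affected.strip().lower())
            car = _CARRIER_MAP.get(carrier.strip().lower())
            if aff is None:
                raise ParseError(f"bad affected value {affected!r}", lineno, str(path))
            if car is None:
                raise ParseError(f"bad carrier value {carrier!r}", lineno, str(path))
            if iid in (father, mother):
                raise ValidationError(f"{iid} listed as its own parent")
            individuals.append(
                Individual(
                    iid,
                    father if father not in ("0", "") else None,
                    mother if mother not in ("0", "") else None,
                    sex,
                    aff,
                    car,
                    fam,
                )
            )
    return Pedigree(individuals)


def write_ped(p: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in p.individuals.values():
            fh.write(
                "\t".join(
                    [
                        ind.family,
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        ind.sex,
                        ind.affected,
                        ind.carrier,
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class Violation:
    iid: str
    kind: str  # affected_noncarrier | unaffected_carrier | de_novo_or_untested
    informational: bool = False


@dataclass(frozen=True)
class SegregationReport:
    consistent: bool
    violations: tuple[Violation, ...]
    n_informative: int  # individuals with both phenotype and genotype known

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        if self.n_informative == 0:
            out.append("no_informative_individuals")
        return tuple(out)


def check_ad_segregation(p: Pedigree) -> SegregationReport:
    """Check carrier/phenotype co-occurrence under an autosomal-dominant model.

    Violations: an affected non-carrier (phenocopy or misassignment) and
    an unaffected carrier (incomplete penetrance) break consistency; an
    affected carrier with no carrier among its tested parents is flagged
    de-novo-or-untested, informational only.
    """

    violations = []
    n_informative = 0
    for ind in p.individuals.values():
        if ind.affected != "unknown" and ind.carrier != "untested":
            n_informative += 1
        if ind.affected == "yes" and ind.carrier == "no":
            violations.append(Violation(ind.iid, "affected_noncarrier"))
        if ind.affected == "no" and ind.carrier == "yes":
            violations.append(Violation(ind.iid, "unaffected_carrier"))
        if ind.affected == "yes" and ind.carrier == "yes":
            parents = p.parents_of(ind.iid)
            tested = [pa for pa in parents if pa.carrier != "untested"]
            if parents and tested and not any(pa.carrier == "yes" for pa in tested):
                violations.append(
                    Violation(ind.iid, "de_novo_or_untested", informational=True)
                )
    consistent = not any(not v.informational for v in violations)
    return SegregationReport(consistent, tuple(violations), n_informative)


def count_informative_transmissions(p: Pedigree) -> int:
    """Parent-to-child links where both are affected carriers.

    Each such link is one informative meiosis supporting co-segregation
    (the count behind PP1). Invariant to the order individuals appear in
    the file.
    """

    n = 0
    for parent, child in p.parent_child_links():
        if (
            parent.affected == "yes"
            and parent.carrier == "yes"
            and child.affected == "yes"
            and child.carrier == "yes"
        ):
            n += 1
    return n
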