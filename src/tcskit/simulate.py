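"""Seeded generators for every input class the pipeline consumes.

The depth simulator emulates capture-based exome coverage over a
single-gene target at the study's operating point (~100x mean depth):
per-base counts are Poisson with a multiplicative structure
``depth ~ Poisson(mean_depth * s_i * b_e * c/2)`` where ``s_i`` is a
per-sample library-size factor (lognormal, sigma 0.1), ``b_e`` a per-exon
capture bias shared across samples (lognormal, sigma 0.2), and ``c`` the
copy number (2 = diploid). Copy-number events are exon-aligned. Optional
gamma mixing adds overdispersion; an optional missing fraction drops
positions to exercise the NA-exclusion rule. Everything is reproducible
from the config seed.

Also here: a random complete-CDS generator, random autosomal-dominant
pedigrees with carrier truth, and the fixed eleven-patient three-family
TCS cohort fixture (phenotype matrix plus molecular outcomes) used by the
cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortRecord, PhenotypeMatrix
from .depth_screen import DepthTable
from .errors import ValidationError
from .genome_model import TranscriptModel
from .hgvs import CodingSequence
from .pedigree import Individual, Pedigree

__all__ = [
    "DepthSimConfig",
    "TruthRecord",
    "simulate_depth_cohort",
    "random_cds",
    "random_pedigree",
    "five_carrier_pedigree",
    "tcs_cohort",
]


@dataclass(frozen=True)
class DepthSimConfig:
    """Cohort coverage simulation settings (defaults = study conditions)."""

    n_controls: int = 14
    mean_depth: float = 100.0
    sigma_sample: float = 0.1
    sigma_exon: float = 0.2
    cnv_events: tuple = ()  # (sample, (exon indices...), copy number)
    seed: int = 0
    missing_fraction: float = 0.0
    overdispersion: float = 0.0  # gamma mixing variance; 0 = pure Poisson

    def __post_init__(self):
        if self.n_controls < 3:
            raise ValidationError("need at least 3 controls")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.sigma_sample < 0 or self.sigma_exon < 0:
            raise ValidationError("spreads must be >= 0")
        for sample, exons, c in self.cnv_events:
            if c not in (0, 1, 2, 3):
                raise ValidationError(f"copy number {c} not in {{0,1,2,3}}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth per sample and exon."""

    sample: str
    exon_index: int
    copy_number: int

    @property
    def expected_ratio(self) -> float:
        return self.copy_number / 2


def simulate_depth_cohort(
    t: TranscriptModel, cfg: DepthSimConfig
) -> tuple[DepthTable, list[TruthRecord]]:
    """Simulate per-base coverage over the transcript's exons for a cohort.

    The cohort holds ``n_controls`` diploid controls (C01, C02, ...) plus
    one extra sample per distinct sample named in ``cnv_events``. Returns
    the depth table and the complete per-sample, per-exon copy-number
    truth.
    """

    rng = np.random.default_rng(cfg.seed)
    controls = [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    event_samples = []
    for sample, _, _ in cfg.cnv_events:
        if sample not in controls and sample not in event_samples:
            event_samples.append(sample)
    samples = controls + event_samples

    copy = {(s, ex.index): 2 for s in samples for ex in t.exons}
    for sample, exons, c in cfg.cnv_events:
        for exon_index in exons:
            if exon_index not in [ex.index for ex in t.exons]:
                raise ValidationError(f"cnv event names unknown exon {exon_index}")
            copy[(sample, exon_index)] = c

    s_factor = {s: rng.lognormal(0.0, cfg.sigma_sample) for s in samples}
    b_exon = {ex.index: rng.lognormal(0.0, cfg.sigma_exon) for ex in t.exons}

    chroms, positions, depths = [], [], {s: [] for s in samples}
    for ex in t.exons:
        n = len(ex.genomic)
        pos = np.arange(ex.genomic.start + 1, ex.genomic.end + 1)
        chroms.extend([ex.genomic.chrom] * n)
        positions.extend(pos.tolist())
        for s in samples:
            lam = cfg.mean_depth * s_factor[s] * b_exon[ex.index] * copy[(s, ex.index)] / 2
            rate = np.full(n, lam)
            if cfg.overdispersion > 0:
                shape = 1.0 / cfg.overdispersion
                rate = rate * rng.gamma(shape, cfg.overdispersion, size=n)
            depths[s].extend(rng.poisson(rate).astype(float).tolist())

    frame = pd.DataFrame({"chrom": chroms, "pos": positions, **depths})
    if cfg.missing_fraction > 0:
        for s in samples:
            drop = rng.random(len(frame)) < cfg.missing_fraction
            frame.loc[drop, s] = np.nan
    truth = [
        TruthRecord(s, ex.index, copy[(s, ex.index)]) for s in samples for ex in t.exons
    ]
    return DepthTable(frame), truth


_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOP_CODONS = ("TAA", "TAG", "TGA")


def random_cds(n_codons: int, seed: int, label: str = "synthetic_cds") -> CodingSequence:
    """A random complete CDS: ATG, ``n_codons - 2`` non-stop codons, a stop."""
    if n_codons < 2:
        raise ValidationError("need at least start + stop codons")
    rng = np.random.default_rng(seed)
    middle = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return CodingSequence(label, "ATG" + "".join(middle) + stop)


def random_pedigree(
    n_generations: int,
    seed: int,
    penetrance: float = 1.0,
    children_per_couple: int = 2,
) -> Pedigree:
    """Random pedigree under autosomal-dominant transmission.

    One founder carrier marries in; each child of a couple inherits the
    variant with probability 1/2 when a parent carries it, and married-in
    spouses are non-carriers. Affected status equals carrier status with
    the given penetrance; all individuals are tested (carrier truth is in
    the carrier field).
    """

    if n_generations < 2:
        raise ValidationError("need at least 2 generations")
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    counter = iter(range(1, 10_000))

    def make(gen, carrier, father=None, mother=None, sex=None):
        iid = f"G{gen}-{next(counter):03d}"
        if sex is None:
            sex = "1" if rng.random() < 0.5 else "2"
        affected = "yes" if (carrier and rng.random() < penetrance) else "no"
        ind = Individual(iid, father, mother, sex, affected, "yes" if carrier else "no")
        individuals.append(ind)
        return ind

    founder = make(1, carrier=True, sex="1")
    spouse = make(1, carrier=False, sex="2")
    couples = [(founder, spouse)]
    for gen in range(2, n_generations + 1):
        next_couples = []
        for fa, mo in couples:
            parent_carrier = fa.carrier == "yes" or mo.carrier == "yes"
            for _ in range(children_per_couple):
                carrier = parent_carrier and rng.random() < 0.5
                child = make(gen, carrier, father=fa.iid, mother=mo.iid)
                if gen < n_generations:
                    partner = make(gen, carrier=False, sex="2" if child.sex == "1" else "1")
                    next_couples.append(
                        (child, partner) if child.sex == "1" else (partner, child)
                    )
        couples = next_couples
    return Pedigree(individuals)


def five_carrier_pedigree() -> Pedigree:
    """Three-generation preset with five affected carriers.

    A founder carrier transmits to two affected children, each of whom
    transmits to one affected grandchild: five affected carriers, four
    informative parent-to-child transmissions. Married-in spouses are
    unaffected non-carriers.
    """

    def ind(iid, father, mother, sex, affected, carrier):
        return Individual(iid, father, mother, sex, affected, carrier)

    return Pedigree(
        [
            ind("I-1", None, None, "1", "yes", "yes"),
            ind("I-2", None, None, "2", "no", "no"),
            ind("II-1", "I-1", "I-2", "2", "yes", "yes"),
            ind("II-2", "I-1", "I-2", "1", "yes", "yes"),
            ind("II-3", None, None, "1", "no", "no"),
            ind("II-4", None, None, "2", "no", "no"),
            ind("III-1", "II-3", "II-1", "2", "yes", "yes"),
            ind("III-2", "II-2", "II-4", "1", "yes", "yes"),
            ind("III-3", "II-2", "II-4", "2", "no", "no"),
        ]
    )


# ---------------------------------------------------------------------------
# Eleven-patient, three-family TCS cohort fixture
# ---------------------------------------------------------------------------

_PATIENTS = [f"P{i}" for i in range(1, 12)]

# feature -> 11 cells; "+" present, "-" absent, "?" unknown
_PHENOTYPE_ROWS: dict[str, str] = {
    "perinatal_complications":                "++?+?----?-",
    "neonatal_intubation_or_tracheostomy":    "-+--?------",
    "neonatal_feeding_tube_or_gastrostomy":   "+---?------",
    "microcephaly":                           "------++---",
    "cleft_palate":                           "------++---",
    "preauricular_hair_displacement":         "----++-----",
    "auricular_abnormalities":                "+++-++++++-",
    "external_auditory_canal_atresia":        "++--++--++-",
    "microtia":                               "+++--+--+--",
    "hearing_loss":                           "++?-?++++--",
    "hearing_aid":                            "+++---+-+--",
    "lower_lid_coloboma":                     "-----------",
    "downslanted_palpebral_fissures":         "+++++-+-+++",
    "malar_hypoplasia":                       "+++++-+-+--",
    "mandibular_hypoplasia_micrognathia":     "+++++++++++",
    "dental_abnormalities":                   "++---+++---",
    "chewing_swallowing_problems":            "----+---+--",
    "delayed_speech_development":             "++-+-++++--",
    "intellectual_disability":                "-+---+-----",
}

_CELL_MAP = {"+": "present", "-": "absent", "?": "unknown"}

_GENES = {
    "P1": ("TCOF1", True),
    "P2": ("TCOF1", True),
    "P3": ("TCOF1", True),
    "P4": ("TCOF1", True),
    "P5": ("TCOF1", True),
    # candidate heterozygous CNV only -> molecularly unsolved
    "P6": ("POLR1C", False),
    "P7": ("POLR1D", True),
    "P8": ("POLR1D", True),
    "P9": ("POLR1D", True),
    "P10": ("POLR1D", True),
    "P11": ("POLR1D", True),
}


def tcs_cohort() -> tuple[PhenotypeMatrix, list[CohortRecord]]:
    """The fixed eleven-patient TCS cohort: clinical features and outcomes.

    Cells transcribe the cohort's published presence/absence table
    (textual severity entries reduced to present; 'Unknown' kept as
    unknown). One patient carries only a candidate CNV and counts as
    unsolved in the diagnostic yield.
    """

    data = {}
    for feature, cells in _PHENOTYPE_ROWS.items():
        if len(cells) != len(_PATIENTS):
            raise ValidationError(f"fixture row {feature} has {len(cells)} cells")
        data[feature] = [_CELL_MAP[c] for c in cells]
    frame = pd.DataFrame(data, index=_PATIENTS).T
    matrix = PhenotypeMatrix(frame)
    cohort = [CohortRecord(p, _GENES[p][0], _GENES[p][1]) for p in _PATIENTS]
    return matrix, cohort
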