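"""Exon-level read-depth CNV screening against a control cohort.

The screen mirrors how a single-gene candidate CNV is chased in clinical
exome data: per-base coverage (samtools-depth style) is reduced to per-exon
arithmetic means (missing bases excluded), each sample is scaled by its own
mean coverage over the target exons (library-size correction), the test
sample's relative coverage is divided per exon by the control-cohort
median, and the resulting ratios are assigned copy states by band
membership (a heterozygous deletion sits near 0.5 of the diploid
baseline). Consecutive exons sharing a non-diploid state are merged into a
single candidate segment.

Because the scaling denominator here is the screened target itself, a real
event biases every ratio of the carrier sample (a 2-of-9-exon deletion
inflates all its ratios by 9/8). The pipeline therefore recalibrates each
sample's ratio vector by its own median (``ScreenConfig.recentre``), which
cancels the shared factor exactly as long as fewer than half the exons are
non-diploid — the same trick genome-wide read-depth callers rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genome_model import ExonModel, TranscriptModel

__all__ = [
    "DepthTable",
    "ExonDepthSummary",
    "CnvCall",
    "ScreenConfig",
    "exon_mean_depth",
    "exon_mean_matrix",
    "sample_scale_factors",
    "normalize_vs_controls",
    "call_states",
    "cohort_screen",
    "CnvScreen",
    "CnvScreenResult",
    "plot_exon_ratios",
]

STATE_HOM_DEL = "hom_del"
STATE_HET_DEL = "het_del"
STATE_DIPLOID = "diploid"
STATE_DUP = "dup"
STATE_NO_CALL = "no_call"


class DepthTable:
    """Per-base depth for one or more samples.

    Wraps a DataFrame with columns ``chrom``, ``pos`` (1-based) and one
    float column per sample; NaN marks a missing base call. A position
    absent from the table is missing for every sample; an explicit 0 is a
    covered base with zero reads.
    """

    def __init__(self, frame: pd.DataFrame):
        if "chrom" not in frame.columns or "pos" not in frame.columns:
            raise ValidationError("depth table needs 'chrom' and 'pos' columns")
        frame = frame.reset_index(drop=True)
        for chrom, sub in frame.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing within chromosome {chrom}"
                )
        depths = frame[self._sample_cols(frame)]
        if (depths.to_numpy(dtype=float) < 0).any():
            raise ValidationError("depths must be >= 0 where present")
        self.frame = frame

    @staticmethod
    def _sample_cols(frame: pd.DataFrame) -> list[str]:
        return [c for c in frame.columns if c not in ("chrom", "pos")]

    @property
    def samples(self) -> list[str]:
        return self._sample_cols(self.frame)

    @classmethod
    def read_tsv(cls, path) -> "DepthTable":
        """Read a samtools-depth dialect TSV (header: chrom, pos, samples...)."""
        try:
            frame = pd.read_csv(path, sep="\t", na_values=["NA"])
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot read depth TSV: {exc}", source=str(path)) from None
        if "chrom" not in frame.columns:
            raise ParseError("depth TSV must have a 'chrom' header column", source=str(path))
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass(frozen=True)
class ExonDepthSummary:
    """Arithmetic mean of per-base coverage over one exon for one sample."""

    sample_id: str
    exon_index: int
    mean_depth: float  # NaN when undefined (all bases missing)
    n_bases: int
    n_missing: int

    @property
    def defined(self) -> bool:
        return self.n_missing < self.n_bases

    @property
    def covered_fraction(self) -> float:
        return (self.n_bases - self.n_missing) / self.n_bases


@dataclass(frozen=True)
class ScreenConfig:
    """Ratio bands and coverage requirements for copy-state calling."""

    het_del_band: tuple[float, float] = (0.35, 0.65)
    hom_del_max: float = 0.15
    dup_min: float = 1.35
    min_covered_fraction: float = 0.8
    recentre: bool = True

    def __post_init__(self):
        low, high = self.het_del_band
        if not (self.hom_del_max < low <= high < self.dup_min):
            raise ValidationError(
                "band ordering violated: need hom_del_max < het_del_band.low <= "
                "het_del_band.high < dup_min"
            )
        if not 0 < self.min_covered_fraction <= 1:
            raise ValidationError("min_covered_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CnvCall:
    """A candidate segment of consecutive exons in a non-diploid state."""

    exon_start: int
    exon_end: int
    ratio: float
    state: str
    confidence: str = "ok"

    @property
    def n_exons(self) -> int:
        return self.exon_end - self.exon_start + 1


def exon_mean_depth(depth: DepthTable, exon: ExonModel, sample: str) -> ExonDepthSummary:
    """Mean per-base coverage over one exon, excluding missing positions.

    Positions absent from the table count as missing, not zero. An exon
    entirely outside the table yields an all-missing summary (mean NaN).
    """

    if sample not in depth.samples:
        raise ValidationError(f"unknown sample {sample!r}")
    g = exon.genomic
    frame = depth.frame
    mask = (
        (frame["chrom"] == g.chrom) & (frame["pos"] > g.start) & (frame["pos"] <= g.end)
    )
    values = frame.loc[mask, sample].to_numpy(dtype=float)
    n_present = int(np.isfinite(values).sum())
    n_bases = len(g)
    mean = float(np.nanmean(values)) if n_present else float("nan")
    return ExonDepthSummary(sample, exon.index, mean, n_bases, n_bases - n_present)


def exon_mean_matrix(
    depth: DepthTable, t: TranscriptModel, samples=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-exon mean depths and covered fractions, exons x samples."""
    samples = list(samples) if samples is not None else depth.samples
    means = {}
    covered = {}
    for s in samples:
        col_m, col_c = {}, {}
        for ex in t.exons:
            summ = exon_mean_depth(depth, ex, s)
            col_m[ex.index] = summ.mean_depth
            col_c[ex.index] = summ.covered_fraction
        means[s] = col_m
        covered[s] = col_c
    idx = [ex.index for ex in t.exons]
    return (
        pd.DataFrame(means).reindex(idx),
        pd.DataFrame(covered).reindex(idx),
    )


def sample_scale_factors(means: pd.DataFrame) -> pd.Series:
    """Library-size scale per sample: mean of its defined exon means.

    Dividing a sample's exon means by its scale yields relative coverage
    with mean 1 over the target.
    """

    scales = means.mean(axis=0, skipna=True)
    dead = scales.index[means.notna().sum(axis=0) == 0].tolist()
    if dead:
        raise ValidationError(f"samples with no defined exon mean: {dead}")
    return scales


@dataclass(frozen=True)
class NormalizedRatios:
    """Per-exon test/control-median ratios with confidence flags."""

    ratios: pd.Series
    n_controls: int
    low_confidence: bool


def normalize_vs_controls(
    test: pd.Series, controls: pd.DataFrame, recentre: bool = False
) -> NormalizedRatios:
    """Divide a test sample's scaled exon means by the control-cohort median.

    The median is over controls only (test excluded by construction).
    Exons whose control median is 0 get a NaN ratio (-> no_call). Fewer
    than 3 controls flags the result low-confidence but still computes.
    With ``recentre`` the ratio vector is divided by its own median,
    removing any residual sample-level miscalibration.
    """

    n_controls = controls.shape[1]
    low_confidence = n_controls < 3
    med = controls.median(axis=1, skipna=True)
    med = med.where(med > 0)
    ratios = test / med
    if recentre:
        centre = ratios.median(skipna=True)
        if np.isfinite(centre) and centre > 0:
            ratios = ratios / centre
    return NormalizedRatios(ratios, n_controls, low_confidence)


def _state_for(ratio: float, cfg: ScreenConfig) -> str:
    if not np.isfinite(ratio):
        return STATE_NO_CALL
    if ratio <= cfg.hom_del_max:
        return STATE_HOM_DEL
    low, high = cfg.het_del_band
    if low <= ratio <= high:
        return STATE_HET_DEL
    if ratio >= cfg.dup_min:
        return STATE_DUP
    return STATE_DIPLOID


def call_states(
    ratios: pd.Series,
    cfg: ScreenConfig | None = None,
    callable_mask: pd.Series | None = None,
    confidence: str = "ok",
) -> list[CnvCall]:
    """Assign per-exon copy states and merge consecutive same-state exons.

    Returns candidate calls only (diploid and no_call exons are dropped
    after delimiting segments). Merged segments span consecutive exon
    indices; the reported ratio is the mean over member exons.
    """

    cfg = cfg or ScreenConfig()
    states, values = {}, {}
    for exon_index, ratio in ratios.items():
        usable = callable_mask is None or bool(callable_mask.get(exon_index, True))
        states[exon_index] = _state_for(float(ratio), cfg) if usable else STATE_NO_CALL
        values[exon_index] = float(ratio)
    calls: list[CnvCall] = []
    run: list[int] = []

    def flush():
        if run and states[run[0]] not in (STATE_DIPLOID, STATE_NO_CALL):
            member = [values[i] for i in run]
            calls.append(
                CnvCall(run[0], run[-1], float(np.mean(member)), states[run[0]], confidence)
            )
        run.clear()

    for exon_index in sorted(states):
        if run and (states[exon_index] != states[run[-1]] or exon_index != run[-1] + 1):
            flush()
        run.append(exon_index)
    flush()
    return calls


_REPORT_COLUMNS = [
    "sample",
    "chrom",
    "exon_span",
    "c_span",
    "mean_ratio",
    "state",
    "n_exons",
    "confidence",
]


def cohort_screen(
    depth: DepthTable,
    t: TranscriptModel,
    samples=None,
    config: ScreenConfig | None = None,
    test_samples=None,
    control_samples=None,
) -> pd.DataFrame:
    """Screen every test sample against the rest of the cohort.

    By default each sample is tested in turn against all others as
    controls (leave-one-out); alternatively a fixed ``control_samples``
    set is used for the given ``test_samples``. Returns a candidate report
    with one row per non-diploid merged segment, deterministically ordered
    by sample then exon span.
    """

    cfg = config or ScreenConfig()
    samples = list(samples) if samples is not None else depth.samples
    if not samples:
        raise ValidationError("no samples to screen")
    means, covered = exon_mean_matrix(depth, t, samples)
    scales = sample_scale_factors(means)
    rel = means.div(scales, axis=1)
    tests = list(test_samples) if test_samples is not None else samples
    rows = []
    for s in tests:
        ctrl = (
            [c for c in control_samples if c != s]
            if control_samples is not None
            else [c for c in samples if c != s]
        )
        norm = normalize_vs_controls(rel[s], rel[ctrl], recentre=cfg.recentre)
        callable_mask = covered[s] >= cfg.min_covered_fraction
        conf = "low_confidence" if norm.low_confidence else "ok"
        for call in call_states(norm.ratios, cfg, callable_mask, confidence=conf):
            first = t.exon(call.exon_start)
            last = t.exon(call.exon_end)
            rows.append(
                {
                    "sample": s,
                    "chrom": t.chrom,
                    "exon_span": f"{call.exon_start}-{call.exon_end}",
                    "c_span": f"c.{first.cdna_start}-{last.cdna_end}",
                    "mean_ratio": round(call.ratio, 4),
                    "state": call.state,
                    "n_exons": call.n_exons,
                    "confidence": conf,
                }
            )
    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if not report.empty:
        report = report.sort_values(
            ["sample", "exon_span"], kind="mergesort", ignore_index=True
        )
    return report


class CnvScreen:
    """Model-style wrapper: a depth cohort screened against a transcript.

    ``CnvScreen(depth, transcript).fit()`` returns a
    :class:`CnvScreenResult` carrying the per-exon ratio matrix, candidate
    calls and a text ``summary()``.
    """

    def __init__(
        self,
        depth: DepthTable,
        transcript: TranscriptModel,
        samples=None,
        config: ScreenConfig | None = None,
        test_samples=None,
        control_samples=None,
    ):
        self.depth = depth
        self.transcript = transcript
        self.samples = list(samples) if samples is not None else depth.samples
        self.config = config or ScreenConfig()
        self.test_samples = list(test_samples) if test_samples is not None else None
        self.control_samples = (
            list(control_samples) if control_samples is not None else None
        )

    def fit(self) -> "CnvScreenResult":
        means, covered = exon_mean_matrix(self.depth, self.transcript, self.samples)
        scales = sample_scale_factors(means)
        rel = means.div(scales, axis=1)
        tests = self.test_samples if self.test_samples is not None else self.samples
        ratio_cols = {}
        for s in tests:
            ctrl = (
                [c for c in self.control_samples if c != s]
                if self.control_samples is not None
                else [c for c in self.samples if c != s]
            )
            ratio_cols[s] = normalize_vs_controls(
                rel[s], rel[ctrl], recentre=self.config.recentre
            ).ratios
        report = cohort_screen(
            self.depth,
            self.transcript,
            self.samples,
            self.config,
            self.test_samples,
            self.control_samples,
        )
        return CnvScreenResult(self, pd.DataFrame(ratio_cols), means, covered, report)


class CnvScreenResult:
    """Fitted screen: ratio matrix, exon means and the candidate report."""

    def __init__(self, model: CnvScreen, ratios, means, covered, candidates):
        self.model = model
        self.ratios = ratios
        self.exon_means = means
        self.covered_fractions = covered
        self.candidates = candidates

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"CNV screen: {self.model.transcript.gene} "
            f"({self.model.transcript.transcript_id}), "
            f"{len(self.model.transcript.exons)} exons, "
            f"{len(self.model.samples)} samples",
            f"het_del band [{cfg.het_del_band[0]}, {cfg.het_del_band[1]}], "
            f"hom_del <= {cfg.hom_del_max}, dup >= {cfg.dup_min}",
            f"candidate segments: {len(self.candidates)}",
        ]
        if not self.candidates.empty:
            lines.append(self.candidates.to_string(index=False))
        return "\n".join(lines)

    def plot(self, path, highlight: str | None = None):
        plot_exon_ratios(self.ratios, path, highlight=highlight)


def plot_exon_ratios(ratios: pd.DataFrame, path, highlight: str | None = None) -> None:
    """Bar plot of normalized per-exon ratios, one group per exon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    n = ratios.shape[1]
    width = 0.8 / max(n, 1)
    x = np.arange(len(ratios.index), dtype=float)
    for k, col in enumerate(ratios.columns):
        color = "crimson" if col == highlight else "steelblue"
        ax.bar(x + k * width, ratios[col].to_numpy(), width=width, label=col, color=color)
    ax.axhline(1.0, ls="--", c="grey", lw=1)
    ax.axhline(0.5, ls=":", c="grey", lw=1)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([str(i) for i in ratios.index])
    ax.set_xlabel("exon")
    ax.set_ylabel("normalized depth ratio")
    if n <= 6:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
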