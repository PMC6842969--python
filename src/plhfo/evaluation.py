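"""Channel ranking, resection ratios, outcome statistics, and the power confound.

For each seizure and each measure, channels whose measure series exceeds
``mean + 2.5 * SD`` -- pooled over all channels and ictal windows of that
seizure -- at any ictal window are "suprathreshold".  The resection ratio
is the percentage of suprathreshold channels that lie in the resected
tissue, computed either over the whole seizure or over the first k
channels to cross the threshold (the "early channels" variant, k = 9 by
default).  Ratios of seizures from good-outcome (Engel I-II) and
poor-outcome (Engel IV) patients are compared with a two-sided
Mann-Whitney U test at the Bonferroni-corrected level 0.01 (five tests).

The confound analysis quantifies each coupling measure's dependence on
plain HFO power: the per-channel slope of log(measure) versus
log(HFO power) across preictal + ictal + postictal windows, and the
Pearson correlation of the raw series.  Amplitude-weighted measures (MVL,
PLHG) show slope near 1 and high correlation; scale-invariant ones (PLV,
MI) do not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .coupling import MEASURES, MeasureMatrix, WindowConfig, sliding_measures
from .io import SeizureCase
from .preprocessing import BandConfig, decompose, downsample_to_512, median_reference

__all__ = [
    "StudyConfig",
    "ThresholdResult",
    "ResectionRatio",
    "GroupComparison",
    "ConfoundStats",
    "EvaluationResult",
    "zscore_matrix",
    "apply_threshold",
    "resection_ratio",
    "compare_groups",
    "confound_analysis",
    "run_study",
]

logger = logging.getLogger(__name__)

GOOD_OUTCOMES = ("I", "II")
POOR_OUTCOMES = ("IV",)

#: Suprathreshold criterion in pooled-SD units.
THRESHOLD_SD = 2.5
#: Bonferroni-corrected significance level (0.05 over five measures).
ALPHA = 0.01


@dataclass(frozen=True)
class StudyConfig:
    """End-to-end pipeline settings for :func:`run_study`."""

    bands: BandConfig = field(default_factory=BandConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    measures: tuple[str, ...] = MEASURES
    mi_bins: int = 18
    mi_phase_correction: bool = True
    early_k: int = 9
    target_rate: float = 512.0
    apply_median_reference: bool = True
    seizures_per_subject: int | None = 2
    undefined_ratio_as_zero: bool = False


@dataclass
class ThresholdResult:
    """Per-seizure suprathreshold channel set for one measure.

    ``first_crossing`` holds, per channel, the absolute window index of the
    earliest ictal window exceeding the threshold (-1 if never);
    ``crossing_z`` the z-score at that window, used for early-k
    tie-breaking.
    """

    measure_name: str
    threshold_value: float
    pooled_mean: float
    pooled_sd: float
    suprathreshold: np.ndarray
    first_crossing: np.ndarray
    crossing_z: np.ndarray
    ictal_window_span: tuple[int, int]


@dataclass
class ResectionRatio:
    seizure_id: str | None
    measure_name: str
    variant: str  # "whole_seizure" | "early_k"
    k: int | None
    numerator: int
    denominator: int

    @property
    def ratio(self) -> float | None:
        """Percentage of selected channels that are resected; None if undefined."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


@dataclass
class GroupComparison:
    measure_name: str
    variant: str
    good_group: list[float]
    poor_group: list[float]
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class ConfoundStats:
    """Dependence of one measure on HFO power, per channel and aggregated."""

    measure_name: str
    slopes: np.ndarray
    correlations: np.ndarray

    @property
    def slope_mean(self) -> float:
        return float(np.mean(self.slopes)) if self.slopes.size else float("nan")

    @property
    def slope_sem(self) -> float:
        return float(stats.sem(self.slopes)) if self.slopes.size > 1 else float("nan")

    @property
    def pearson_mean(self) -> float:
        return float(np.mean(self.correlations)) if self.correlations.size else float("nan")

    @property
    def pearson_sem(self) -> float:
        return float(stats.sem(self.correlations)) if self.correlations.size > 1 else float("nan")


def _pooled_stats(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def zscore_matrix(m: MeasureMatrix, ictal_span: tuple[int, int]) -> MeasureMatrix:
    """Z-score a measure matrix by its pooled ictal statistics.

    Mean and SD pool all channels and all ictal windows.  Thresholding the
    raw values at mean + 2.5*SD is then exactly z > 2.5.
    """
    w0, w1 = ictal_span
    if w1 <= w0:
        raise ValueError("empty ictal window span")
    mean, sd = _pooled_stats(m.values[:, w0:w1])
    if sd == 0:
        raise ValueError("pooled ictal SD is zero; z-scores undefined")
    return replace(m, values=(m.values - mean) / sd)


def apply_threshold(m: MeasureMatrix, ictal_span: tuple[int, int]) -> ThresholdResult:
    """Flag channels exceeding mean + 2.5*SD at any ictal window.

    The threshold pools all channels and ictal windows of this seizure and
    measure.  ``first_crossing`` is the earliest suprathreshold ictal
    window per channel.
    """
    w0, w1 = ictal_span
    if w1 - w0 < 2:
        raise ValueError("ictal span must cover at least 2 windows")
    ictal = m.values[:, w0:w1]
    mean, sd = _pooled_stats(ictal)
    threshold = mean + THRESHOLD_SD * sd
    n_ch = m.n_channels
    supra = np.zeros(n_ch, dtype=bool)
    first = np.full(n_ch, -1, dtype=int)
    cross_z = np.full(n_ch, np.nan)
    if sd == 0:
        warnings.warn(
            f"{m.measure_name}: pooled ictal SD is zero; no channel can exceed "
            "the threshold",
            stacklevel=2,
        )
    else:
        above = ictal > threshold
        for ch in range(n_ch):
            hits = np.nonzero(above[ch])[0]
            if hits.size:
                supra[ch] = True
                first[ch] = w0 + int(hits[0])
                cross_z[ch] = (ictal[ch, hits[0]] - mean) / sd
    return ThresholdResult(
        measure_name=m.measure_name,
        threshold_value=float(threshold),
        pooled_mean=mean,
        pooled_sd=sd,
        suprathreshold=supra,
        first_crossing=first,
        crossing_z=cross_z,
        ictal_window_span=(w0, w1),
    )


def resection_ratio(
    t: ThresholdResult,
    resected: np.ndarray,
    variant: str = "whole_seizure",
    k: int = 9,
    seizure_id: str | None = None,
) -> ResectionRatio:
    """Percentage of threshold-selected channels lying in the resected tissue.

    ``whole_seizure`` counts every suprathreshold channel; ``early_k``
    keeps only the first ``k`` channels ordered by threshold-crossing
    time, breaking ties by larger z at the crossing window, then by
    channel index.  A seizure with no suprathreshold channels yields an
    undefined ratio (denominator 0).
    """
    resected = np.asarray(resected, dtype=bool)
    selected = np.nonzero(t.suprathreshold)[0]
    if variant == "early_k":
        order = sorted(
            selected,
            key=lambda ch: (t.first_crossing[ch], -t.crossing_z[ch], ch),
        )
        selected = np.asarray(order[: min(k, len(order))], dtype=int)
    elif variant != "whole_seizure":
        raise ValueError(f"unknown variant {variant!r}")
    denom = int(selected.size)
    num = int(resected[selected].sum()) if denom else 0
    if denom == 0:
        logger.info(
            "%s/%s: no suprathreshold channel; resection ratio undefined",
            seizure_id,
            t.measure_name,
        )
    return ResectionRatio(
        seizure_id=seizure_id,
        measure_name=t.measure_name,
        variant=variant,
        k=k if variant == "early_k" else None,
        numerator=num,
        denominator=denom,
    )


def compare_groups(
    ratios: list[ResectionRatio],
    outcomes: dict[str, str],
    undefined_as_zero: bool = False,
) -> GroupComparison:
    """Mann-Whitney U test of resection ratios between outcome groups.

    Seizures with a good outcome (Engel I-II) form one group, poor outcome
    (Engel IV) the other; Engel III (absent from the study design) is
    excluded.  Undefined ratios are excluded by default, or mapped to 0%
    with ``undefined_as_zero``.  The test is two-sided; with small
    tie-free samples scipy computes the exact null distribution.
    """
    if not ratios:
        raise ValueError("no ratios to compare")
    name, variant = ratios[0].measure_name, ratios[0].variant
    good, poor = [], []
    for r in ratios:
        val = r.ratio
        if val is None:
            if undefined_as_zero:
                val = 0.0
            else:
                logger.info("%s/%s: undefined ratio excluded from group test", r.seizure_id, name)
                continue
        outcome = outcomes[r.seizure_id]
        if outcome in GOOD_OUTCOMES:
            good.append(val)
        elif outcome in POOR_OUTCOMES:
            poor.append(val)
    if not good or not poor:
        raise ValueError(
            f"{name}/{variant}: both outcome groups must be non-empty "
            f"(good n={len(good)}, poor n={len(poor)})"
        )
    res = stats.mannwhitneyu(good, poor, alternative="two-sided", method="auto")
    return GroupComparison(
        measure_name=name,
        variant=variant,
        good_group=good,
        poor_group=poor,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def confound_analysis(
    measure: MeasureMatrix, power: MeasureMatrix, min_windows: int = 3
) -> ConfoundStats:
    """Per-channel dependence of a coupling measure on HFO power.

    Pools all available windows (preictal + ictal + postictal).  The
    log-log slope is the OLS slope of log(measure) on log(power) over
    windows where both are strictly positive; the Pearson correlation uses
    the raw series.  Channels with fewer than ``min_windows`` usable
    windows are skipped with a notice.
    """
    if measure.values.shape != power.values.shape:
        raise ValueError("measure and power matrices must be aligned")
    slopes, corrs = [], []
    for ch in range(measure.n_channels):
        y, x = measure.values[ch], power.values[ch]
        ok = (y > 0) & (x > 0)
        if ok.sum() < min_windows:
            logger.info(
                "%s: channel %d has %d usable windows (< %d); skipped",
                measure.measure_name,
                ch,
                int(ok.sum()),
                min_windows,
            )
            continue
        fit = stats.linregress(np.log(x[ok]), np.log(y[ok]))
        slopes.append(fit.slope)
        corrs.append(stats.pearsonr(x, y).statistic)
    return ConfoundStats(
        measure_name=measure.measure_name,
        slopes=np.asarray(slopes, dtype=float),
        correlations=np.asarray(corrs, dtype=float),
    )


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

@dataclass
class SeizureSummary:
    case_id: str | None
    subject_id: str | None
    outcome: str
    measures: dict  # name -> {"threshold": ..., "suprathreshold": [...], ...}


@dataclass
class EvaluationResult:
    seizures: list[SeizureSummary]
    comparisons: list[GroupComparison]
    confounds: list[ConfoundStats]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seizures": [
                {
                    "case_id": s.case_id,
                    "subject_id": s.subject_id,
                    "outcome": s.outcome,
                    "measures": s.measures,
                }
                for s in self.seizures
            ],
            "comparisons": [
                {
                    "measure_name": c.measure_name,
                    "variant": c.variant,
                    "good_group": c.good_group,
                    "poor_group": c.poor_group,
                    "u_statistic": c.u_statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ],
            "confounds": [
                {
                    "measure_name": c.measure_name,
                    "slopes": c.slopes.tolist(),
                    "correlations": c.correlations.tolist(),
                    "slope_mean": c.slope_mean,
                    "slope_sem": c.slope_sem,
                    "pearson_mean": c.pearson_mean,
                    "pearson_sem": c.pearson_sem,
                    "n_channels": int(c.slopes.size),
                }
                for c in self.confounds
            ],
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationResult":
        seizures = [
            SeizureSummary(s["case_id"], s["subject_id"], s["outcome"], s["measures"])
            for s in doc["seizures"]
        ]
        comparisons = [
            GroupComparison(
                c["measure_name"],
                c["variant"],
                list(c["good_group"]),
                list(c["poor_group"]),
                c["u_statistic"],
                c["p_value"],
            )
            for c in doc["comparisons"]
        ]
        confounds = [
            ConfoundStats(
                c["measure_name"],
                np.asarray(c["slopes"], dtype=float),
                np.asarray(c["correlations"], dtype=float),
            )
            for c in doc["confounds"]
        ]
        return cls(seizures, comparisons, confounds, list(doc.get("notes", [])))


def _scale_index(idx: int, factor: int) -> int:
    return int(round(idx / factor))


def analyze_case(case: SeizureCase, config: StudyConfig) -> dict:
    """Run preprocessing, decomposition, measures and thresholding on one case.

    Returns a dict with the per-measure matrices, threshold results and
    resection ratios.  Channels masked out in the recording are dropped
    after the median reference and excluded from everything downstream.
    """
    rec = case.recording
    onset, offset = case.seizure_onset, case.seizure_offset
    b0, b1 = case.baseline_span
    resected = case.resected

    if config.apply_median_reference:
        rec = median_reference(rec)
    if rec.rate != config.target_rate:
        factor = int(round(rec.rate / config.target_rate))
        rec = downsample_to_512(rec, config.target_rate)
        onset, offset = _scale_index(onset, factor), _scale_index(offset, factor)
        b1 = _scale_index(b1, factor)
        b0 = b1 - int(round((case.baseline_span[1] - case.baseline_span[0]) / factor))

    usable = rec.channel_mask
    from .io import Recording as _Recording

    rec = _Recording(
        rec.samples[usable],
        rec.rate,
        [lab for lab, u in zip(rec.channel_labels, usable) if u],
    )
    resected = resected[usable]

    bands = decompose(rec, config.bands)
    baseline_mean = None
    if "PLHG" in config.measures:
        baseline_mean = bands.a_hfo[:, b0:b1].mean(axis=1)
    mats = sliding_measures(
        bands,
        config.windows,
        which=config.measures,
        baseline_mean=baseline_mean,
        mi_bins=config.mi_bins,
        mi_phase_correction=config.mi_phase_correction,
        channel_labels=rec.channel_labels,
    )
    out = {"matrices": {}, "thresholds": {}, "ratios": {}, "resected": resected}
    for m in mats:
        span = m.windows_within(onset, offset)
        t = apply_threshold(m, span)
        out["matrices"][m.measure_name] = m
        out["thresholds"][m.measure_name] = t
        out["ratios"][m.measure_name] = {
            "whole_seizure": resection_ratio(t, resected, "whole_seizure", seizure_id=case.case_id),
            "early_k": resection_ratio(
                t, resected, "early_k", k=config.early_k, seizure_id=case.case_id
            ),
        }
    return out


def run_study(cases: list[SeizureCase], config: StudyConfig | None = None) -> EvaluationResult:
    """Full pipeline over a batch of seizure cases.

    Per case: median reference, resampling to the target rate, band
    decomposition, sliding measures, per-seizure thresholding and both
    resection-ratio variants.  Across cases: Mann-Whitney comparison of
    good- versus poor-outcome ratios per measure and variant, and the
    pooled confound analysis against HFO power.  When subject ids are
    present, at most ``config.seizures_per_subject`` seizures per subject
    enter the group statistics (avoids bias toward subjects with many
    recorded seizures).
    """
    config = config or StudyConfig()
    if not cases:
        raise ValueError("need at least one seizure case")

    if config.seizures_per_subject is not None:
        kept: list[SeizureCase] = []
        seen: dict[str, int] = {}
        for case in cases:
            sid = case.subject_id
            if sid is None:
                kept.append(case)
                continue
            seen.setdefault(sid, 0)
            if seen[sid] < config.seizures_per_subject:
                kept.append(case)
                seen[sid] += 1
        cases = kept

    notes: list[str] = []
    summaries: list[SeizureSummary] = []
    all_ratios: dict[tuple[str, str], list[ResectionRatio]] = {}
    confound_acc: dict[str, list[ConfoundStats]] = {}
    outcomes: dict[str, str] = {}

    for i, case in enumerate(cases):
        case_id = case.case_id or f"case{i:03d}"
        try:
            res = analyze_case(case, config)
        except Exception as exc:  # re-raise with case context
            raise type(exc)(f"[{case_id}] {exc}") from exc
        outcomes[case_id] = case.outcome
        measures_doc = {}
        for name, t in res["thresholds"].items():
            rr = res["ratios"][name]
            for variant, r in rr.items():
                r.seizure_id = case_id
                all_ratios.setdefault((name, variant), []).append(r)
            measures_doc[name] = {
                "threshold": t.threshold_value,
                "suprathreshold": np.nonzero(t.suprathreshold)[0].tolist(),
                "first_crossing": t.first_crossing.tolist(),
                "resection_ratios": {
                    variant: {
                        "numerator": r.numerator,
                        "denominator": r.denominator,
                        "ratio": r.ratio,
                        "k": r.k,
                    }
                    for variant, r in rr.items()
                },
            }
        if "HFO_POWER" in res["matrices"]:
            power = res["matrices"]["HFO_POWER"]
            for name, m in res["matrices"].items():
                if name == "HFO_POWER":
                    continue
                confound_acc.setdefault(name, []).append(confound_analysis(m, power))
        summaries.append(
            SeizureSummary(case_id, case.subject_id, case.outcome, measures_doc)
        )

    comparisons: list[GroupComparison] = []
    for (name, variant), ratios in sorted(all_ratios.items()):
        try:
            comparisons.append(
                compare_groups(ratios, outcomes, config.undefined_ratio_as_zero)
            )
        except ValueError as exc:
            notes.append(f"group comparison skipped for {name}/{variant}: {exc}")
            logger.info("group comparison skipped for %s/%s: %s", name, variant, exc)

    confounds = [
        ConfoundStats(
            name,
            np.concatenate([c.slopes for c in parts]) if parts else np.array([]),
            np.concatenate([c.correlations for c in parts]) if parts else np.array([]),
        )
        for name, parts in sorted(confound_acc.items())
    ]
    return EvaluationResult(summaries, comparisons, confounds, notes)
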