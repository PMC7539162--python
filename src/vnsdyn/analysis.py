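"""Evaluation and findings layer.

Covers the three analysis products: (1) baseline quality-assurance
tests comparing the cross-validated models against the mean predictor
(which scores exactly 0% under the matched-normalization fit metric)
and the naive previous-value predictor; (2) statistical comparisons of
fit, model order and dead-time delays across biomarkers (Shapiro-Wilk
normality gate choosing paired t vs Wilcoxon signed-rank; Mauchly
sphericity gate and one-way repeated-measures ANOVA with partial eta
squared for the three-way delay comparison); and (3) population
response curves — resampled experimental curves and zero-state
simulated curves on a common 250-second grid with the stimulus active
over t in (10, 130) s — whose active-versus-sham separation exposes the
dynamic response signatures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AdministrationDataset, UniformSeries
from .series_prep import build_input_waveform
from .statespace import fit_percent, simulate

__all__ = [
    "BaselineReport",
    "ComparisonReport",
    "ResponseCurve",
    "naive_predictor_fit",
    "run_baseline_tests",
    "compare_paired",
    "compare_delays",
    "experimental_response_curves",
    "simulated_response_curves",
]

CURVE_PRE_S = 10
CURVE_STIM_S = 120
CURVE_POST_S = 120
CURVE_LEN_S = CURVE_PRE_S + CURVE_STIM_S + CURVE_POST_S  # 250


# ---------------------------------------------------------------------------
# report containers


@dataclass
class PairedTestOutcome:
    test_used: str       # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float
    passed: bool = False


@dataclass
class BaselineReport:
    """Model-vs-baseline quality assurance for one biomarker."""

    model_fits: np.ndarray
    naive_fits: np.ndarray
    mean_fits: np.ndarray          # exactly 0 under matched normalization
    naive_test: PairedTestOutcome
    mean_test: PairedTestOutcome
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.naive_test.passed and self.mean_test.passed

    def to_dict(self) -> dict:
        return {
            "model_fits": self.model_fits.tolist(),
            "naive_fits": self.naive_fits.tolist(),
            "mean_fits": self.mean_fits.tolist(),
            "alpha": self.alpha,
            "passed": self.passed,
            "naive_test": vars(self.naive_test),
            "mean_test": vars(self.mean_test),
            "note": "one-sided alternative: model fit > baseline fit; "
                    "no multiple-testing correction applied",
        }


@dataclass
class ComparisonReport:
    comparison: str
    test_used: str
    statistic: float
    p_value: float
    dof: tuple
    normality_p: list = field(default_factory=list)
    sphericity_p: float | None = None
    effect_size: float | None = None

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["dof"] = list(self.dof)
        return d


@dataclass
class ResponseCurve:
    """Population mean +- SEM response on the 250-s grid (% of rest)."""

    time_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    group: str
    source: str                      # "experimental" | "simulated"
    biomarker: str = ""
    n_subjects: int = 0
    stim_window_s: tuple = (CURVE_PRE_S, CURVE_PRE_S + CURVE_STIM_S)
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.time_s, "mean": self.mean,
                             "sem": self.sem})


# ---------------------------------------------------------------------------
# baselines


def naive_predictor_fit(dataset: AdministrationDataset) -> float:
    """Fit% of the previous-value (naive) predictor on one record.

    yhat_k = y_{k-1}, scored from the second sample onward; slowly
    varying series score close to (but below) 100%, while white noise
    scores about -41% in expectation.
    """
    y = dataset.y
    if len(y) < 3:
        raise ValueError("need at least 3 samples for the naive predictor")
    return fit_percent(y[1:], y[:-1])


def _gated_paired_test(a, b, alpha, alternative):
    """Shapiro-Wilk gate on the differences, then paired t or Wilcoxon."""
    diffs = np.asarray(a, float) - np.asarray(b, float)
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            return PairedTestOutcome("paired_t", 0.0, 1.0, np.nan, False)
        raise ValueError("zero-variance differences: test undefined")
    sw_p = float(stats.shapiro(diffs).pvalue)
    if sw_p > alpha:
        res = stats.ttest_rel(a, b, alternative=alternative)
        return PairedTestOutcome("paired_t", float(res.statistic),
                                 float(res.pvalue), sw_p)
    res = stats.wilcoxon(diffs, alternative=alternative)
    return PairedTestOutcome("wilcoxon", float(res.statistic),
                             float(res.pvalue), sw_p)


def run_baseline_tests(model_fits, naive_fits, alpha: float = 0.05,
                       ) -> BaselineReport:
    """Mean test and naive test on per-subject average fit percentages.

    ``model_fits`` and ``naive_fits`` hold one value per subject (the
    across-fold average of cross-validated test fits).  The mean-
    predictor baseline is exactly 0% by construction.  Both tests are
    one-sided (model fit above baseline) with a Shapiro-Wilk gate
    choosing between paired t and Wilcoxon signed-rank.
    """
    model_fits = np.asarray(model_fits, float)
    naive_fits = np.asarray(naive_fits, float)
    if len(model_fits) < 6:
        warnings.warn("fewer than 6 subjects: baseline tests are weak",
                      RuntimeWarning)
    mean_fits = np.zeros_like(model_fits)
    naive_test = _gated_paired_test(model_fits, naive_fits, alpha, "greater")
    mean_test = _gated_paired_test(model_fits, mean_fits, alpha, "greater")
    naive_test.passed = naive_test.p_value < alpha
    mean_test.passed = mean_test.p_value < alpha
    return BaselineReport(model_fits, naive_fits, mean_fits,
                          naive_test, mean_test, alpha)


# ---------------------------------------------------------------------------
# statistical comparisons


def compare_paired(a, b, alpha: float = 0.05,
                   comparison: str = "paired") -> ComparisonReport:
    """Two-sided paired comparison with a Shapiro-Wilk normality gate."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length paired samples, n >= 3")
    diffs = a - b
    if np.allclose(diffs, diffs[0]) and diffs[0] != 0:
        raise ValueError("zero-variance differences: test undefined")
    if np.all(diffs == 0):
        return ComparisonReport(comparison, "paired_t", 0.0, 1.0,
                                (len(a) - 1,), [np.nan])
    sw_p = float(stats.shapiro(diffs).pvalue)
    if sw_p > alpha:
        res = stats.ttest_rel(a, b)
        return ComparisonReport(comparison, "paired_t",
                                float(res.statistic), float(res.pvalue),
                                (len(a) - 1,), [sw_p])
    res = stats.wilcoxon(diffs)
    return ComparisonReport(comparison, "wilcoxon", float(res.statistic),
                            float(res.pvalue), (len(a) - 1,), [sw_p])


def compare_delays(delay_sets: dict, alpha: float = 0.05) -> ComparisonReport:
    """Three-way repeated-measures comparison of onset-delay sets.

    ``delay_sets`` maps three condition names to equal-length arrays
    (one triple per subject).  Mauchly's test gates sphericity, then a
    one-way repeated-measures ANOVA with (2, 2(n-1)) degrees of freedom
    reports F, p and partial eta squared.
    """
    import pingouin as pg

    names = list(delay_sets)
    if len(names) != 3:
        raise ValueError("delay comparison expects exactly 3 sets")
    arrays = [np.asarray(delay_sets[k], float) for k in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays) or n < 3:
        raise ValueError("need equal-length sets with n >= 3 subjects")

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 3),
        "condition": np.repeat(names, n),
        "delay": np.concatenate(arrays),
    })
    normality_p = [float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else np.nan
                   for a in arrays]
    if all(np.ptp(a - arrays[0]) == 0 for a in arrays):
        return ComparisonReport("delay_three_way", "rm_anova", 0.0, 1.0,
                                (2, 2 * (n - 1)), normality_p, np.nan, 0.0)
    try:
        spher = pg.sphericity(long, dv="delay", within="condition",
                              subject="subject")
        spher_p = float(spher.pval)
    except Exception:
        spher_p = np.nan
    aov = pg.rm_anova(data=long, dv="delay", within="condition",
                      subject="subject", detailed=False, effsize="np2")
    f_val = float(aov["F"].iloc[0])
    p_val = float(aov["p_unc"].iloc[0])
    eta = float(aov["np2"].iloc[0])
    return ComparisonReport("delay_three_way", "rm_anova", f_val, p_val,
                            (2, 2 * (n - 1)), normality_p, spher_p, eta)


# ---------------------------------------------------------------------------
# population response curves


def _curve_from_subject_means(subject_means, group, source, biomarker, flags):
    """Cross-subject mean +- SEM from per-subject mean curves (% of rest)."""
    arr = np.vstack(subject_means) * 100.0
    mean = np.nanmean(arr, axis=0)
    n_sub = arr.shape[0]
    if n_sub > 1:
        counts = np.sum(~np.isnan(arr), axis=0)
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1))
        sem = np.where(counts > 1, sem, 0.0)
    else:
        sem = np.zeros_like(mean)
        flags = flags + ["single_subject_sem_zero"]
    return ResponseCurve(np.arange(arr.shape[1], dtype=float), mean, sem,
                         group, source, biomarker, n_sub, flags=flags)


def experimental_response_curves(datasets, group: str, biomarker: str,
                                 ) -> ResponseCurve:
    """Population curve of the resampled experimental responses.

    Each administration window is cut to the 250-s display grid (10 s
    before onset through 120 s after the stimulus ends), averaged
    across the subject's administrations, then averaged across subjects
    with SEM.  Missing tail samples of truncated records are carried as
    NaN and excluded per time point.
    """
    subset = [d for d in datasets
              if d.group == group and d.biomarker == biomarker]
    if not subset:
        raise ValueError(f"no datasets for group={group!r}, "
                         f"biomarker={biomarker!r}")
    flags = []
    by_subject = {}
    for d in subset:
        start = d.onset_index - CURVE_PRE_S
        seg = d.y[start:start + CURVE_LEN_S]
        if len(seg) < CURVE_LEN_S:
            flags.append(f"truncated:{d.label()}")
            seg = np.concatenate([seg, np.full(CURVE_LEN_S - len(seg),
                                               np.nan)])
        by_subject.setdefault(d.subject, []).append(seg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        subject_means = [np.nanmean(np.vstack(v), axis=0)
                         for v in by_subject.values()]
    return _curve_from_subject_means(subject_means, group, "experimental",
                                     biomarker, flags)


def standard_simulation_input() -> UniformSeries:
    """The 250-s zero-state simulation input: stimulus over (10, 130) s."""
    return build_input_waveform(CURVE_LEN_S, CURVE_PRE_S,
                                width_s=CURVE_STIM_S)


def simulated_response_curves(cv_results, group: str, biomarker: str,
                              ) -> ResponseCurve:
    """Population curve of zero-state model simulations.

    Every cross-validated model is solved forward from the equilibrium
    x=0 with the innovations ignored under the standard 250-s stimulus
    input, guaranteeing identical pre-stimulus behavior across groups;
    per-subject averages over the 4 fold models are then averaged
    across the group with SEM.
    """
    u = standard_simulation_input()
    subject_means = []
    for r in cv_results:
        if r.group != group or r.biomarker != biomarker:
            continue
        sims = [simulate(m, u).values for m in r.models]
        subject_means.append(np.mean(np.vstack(sims), axis=0))
    if not subject_means:
        raise ValueError(f"no CV results for group={group!r}, "
                         f"biomarker={biomarker!r}")
    return _curve_from_subject_means(subject_means, group, "simulated",
                                     biomarker, [])


# ---------------------------------------------------------------------------
# report drivers


def evaluate_cohort(cv_results, alpha: float = 0.05) -> dict:
    """Baseline tests per biomarker plus biomarker/delay comparisons.

    Expects CV results for both biomarkers of each subject.  Returns a
    JSON-serializable report dictionary.
    """
    report = {"alpha": alpha, "baselines": {}, "comparisons": {}}
    by_bm = {"hr": [], "ppg_amp": []}
    for r in cv_results:
        by_bm[r.biomarker].append(r)
    for bm, rs in by_bm.items():
        if not rs:
            continue
        model_fits = [r.mean_fit for r in rs]
        naive_fits = [float(np.mean(r.naive_fits)) for r in rs]
        report["baselines"][bm] = run_baseline_tests(
            model_fits, naive_fits, alpha).to_dict()

    hr = {r.subject: r for r in by_bm["hr"]}
    ppg = {r.subject: r for r in by_bm["ppg_amp"]}
    shared = sorted(set(hr) & set(ppg))
    if len(shared) >= 3:
        hr_fit = [hr[s].mean_fit for s in shared]
        ppg_fit = [ppg[s].mean_fit for s in shared]
        report["comparisons"]["fit_hr_vs_ppg"] = compare_paired(
            hr_fit, ppg_fit, alpha, "fit_hr_vs_ppg").to_dict()
        hr_ord = [hr[s].mean_order for s in shared]
        ppg_ord = [ppg[s].mean_order for s in shared]
        report["comparisons"]["order_hr_vs_ppg"] = compare_paired(
            hr_ord, ppg_ord, alpha, "order_hr_vs_ppg").to_dict()
    return report


def response_curve_suite(datasets, cv_results) -> list[ResponseCurve]:
    """All eight population curves: {experimental, simulated} x
    {active, sham} x {hr, ppg_amp} (curves without data are skipped)."""
    curves = []
    for biomarker in ("hr", "ppg_amp"):
        for group in ("active", "sham"):
            try:
                curves.append(experimental_response_curves(
                    datasets, group, biomarker))
            except ValueError:
                pass
            try:
                curves.append(simulated_response_curves(
                    cv_results, group, biomarker))
            except ValueError:
                pass
    return curves


def write_reports(report: dict, curves, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "evaluation_report.json").write_text(json.dumps(report, indent=1))
    for c in curves:
        c.to_frame().to_csv(
            out / f"curves_{c.source}_{c.group}_{c.biomarker}.csv",
            index=False)


def plot_response_curves(curves, path=None):
    """Optional visual: numeric curve CSVs are the contract; this is
    presentation only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    biomarkers = sorted({c.biomarker for c in curves})
    sources = ["experimental", "simulated"]
    fig, axes = plt.subplots(len(biomarkers), 2,
                             figsize=(10, 3.2 * len(biomarkers)),
                             squeeze=False)
    for i, bm in enumerate(biomarkers):
        for j, src in enumerate(sources):
            ax = axes[i][j]
            for c in curves:
                if c.biomarker != bm or c.source != src:
                    continue
                color = "tab:red" if c.group == "active" else "tab:gray"
                ax.plot(c.time_s, c.mean, color=color, label=c.group)
                ax.fill_between(c.time_s, c.mean - c.sem, c.mean + c.sem,
                                color=color, alpha=0.3)
            ax.axvspan(CURVE_PRE_S, CURVE_PRE_S + CURVE_STIM_S,
                       color="orange", alpha=0.1)
            ax.set_title(f"{bm} - {src}")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("% of rest")
            ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
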