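"""Monte-Carlo summarization: bias, precision, precision ratios, plots.

Per scenario: replicate mean, bias against the true value, sample SD
(n-1 denominator), the ratio SD_hap / SD_geno (values below 1 mean the
haplotype route is more precise), and a one-sample t-test of the
replicates against the true value.  Aggregation reproduces the style of
the published summary table: unweighted averages and maxima across
scenarios, overall and stratified by sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CrossScenario, ReplicateResult, ScenarioRun

__all__ = [
    "ScenarioSummary",
    "AggregateSummary",
    "InsufficientDataError",
    "DegenerateTestError",
    "summarize_scenario",
    "summarize_run",
    "bias_test",
    "welch_test",
    "aggregate",
    "precision_ratio_table",
    "summaries_to_frame",
    "plot_ratio_by_r2",
    "plot_ratio_selected",
    "plot_bias_by_sample_size",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable replicates."""


class DegenerateTestError(ValueError):
    """A test statistic is undefined (zero variance)."""


@dataclass(frozen=True)
class ScenarioSummary:
    """Replicate-level summary of one scenario."""

    scenario: CrossScenario | None
    true_r2: float
    n_reps: int
    n_defined_reps: int
    mean_hap: float
    mean_geno: float
    bias_hap: float
    bias_geno: float
    sd_hap: float
    sd_geno: float
    ratio_of_precision: float  # sd_hap / sd_geno; nan when sd_geno == 0
    p_hap: float
    p_geno: float
    mean_abs_diff: float  # mean per-replicate |r2_geno - r2_hap|
    sd_diff: float  # SD of per-replicate (r2_geno - r2_hap)

    @property
    def abs_bias_hap(self) -> float:
        return abs(self.bias_hap)

    @property
    def abs_bias_geno(self) -> float:
        return abs(self.bias_geno)


@dataclass(frozen=True)
class AggregateSummary:
    """Across-scenario aggregates (unweighted over scenarios)."""

    n_scenarios: int
    avg_abs_bias_hap: float
    avg_abs_bias_geno: float
    max_abs_bias_hap: float
    max_abs_bias_geno: float
    avg_sd_hap: float
    avg_sd_geno: float
    max_sd_hap: float
    max_sd_geno: float
    by_sample_size: dict
    avg_mean_abs_diff: float
    avg_sd_diff: float


def _defined_estimates(reps: Iterable[ReplicateResult]) -> tuple[np.ndarray, np.ndarray, int]:
    hap, geno, total = [], [], 0
    for r in reps:
        total += 1
        if r.defined_both:
            hap.append(r.r2_hap.r2)
            geno.append(r.r2_geno.r2)
    return np.asarray(hap), np.asarray(geno), total


def bias_test(estimates, true_r2: float) -> float:
    """Two-sided one-sample t-test p-value of replicate estimates vs the truth.

    ``estimates`` may be an array of r^2 values or replicate results.
    """
    est = list(estimates)
    if est and isinstance(est[0], ReplicateResult):
        arr = np.asarray([r.r2_hap.r2 for r in est], dtype=float)
    else:
        arr = np.asarray(est, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need >= 2 replicates for a t-test")
    # guard against exact ties (std picks up only rounding dust)
    if np.std(arr, ddof=1) <= 1e-12 * max(1.0, float(np.abs(arr).max())):
        raise DegenerateTestError("zero replicate variance; test undefined")
    return float(stats.ttest_1samp(arr, popmean=true_r2).pvalue)


def welch_test(hap_estimates, geno_estimates) -> float:
    """Welch two-sample t-test p-value comparing the two estimator samples."""
    return float(
        stats.ttest_ind(np.asarray(hap_estimates), np.asarray(geno_estimates),
                        equal_var=False).pvalue
    )


def summarize_scenario(
    reps: Sequence[ReplicateResult],
    true_r2: float,
    scenario: CrossScenario | None = None,
) -> ScenarioSummary:
    """Summarize one scenario's replicates against the benchmark value.

    Replicates with an undefined estimate on either route are excluded and
    counted via ``n_defined_reps``.  Raises
    :class:`InsufficientDataError` with fewer than two usable replicates.
    """
    hap, geno, total = _defined_estimates(reps)
    if hap.size < 2:
        raise InsufficientDataError(
            f"need >= 2 defined replicates, got {hap.size} of {total}"
        )
    sd_hap = float(np.std(hap, ddof=1))
    sd_geno = float(np.std(geno, ddof=1))
    diff = geno - hap
    try:
        p_hap = bias_test(hap, true_r2)
    except DegenerateTestError:
        p_hap = math.nan
    try:
        p_geno = bias_test(geno, true_r2)
    except DegenerateTestError:
        p_geno = math.nan
    return ScenarioSummary(
        scenario=scenario,
        true_r2=float(true_r2),
        n_reps=total,
        n_defined_reps=int(hap.size),
        mean_hap=float(hap.mean()),
        mean_geno=float(geno.mean()),
        bias_hap=float(hap.mean() - true_r2),
        bias_geno=float(geno.mean() - true_r2),
        sd_hap=sd_hap,
        sd_geno=sd_geno,
        ratio_of_precision=sd_hap / sd_geno if sd_geno > 0 else math.nan,
        p_hap=p_hap,
        p_geno=p_geno,
        mean_abs_diff=float(np.abs(diff).mean()),
        sd_diff=float(np.std(diff, ddof=1)),
    )


def summarize_run(run: ScenarioRun) -> ScenarioSummary:
    """Convenience wrapper: summarize a :class:`ScenarioRun`."""
    return summarize_scenario(run.replicates, run.true_ld.r2, run.scenario)


def aggregate(summaries: Sequence[ScenarioSummary]) -> AggregateSummary:
    """Unweighted aggregates of absolute bias and SD across scenarios.

    ``by_sample_size`` maps each sample size found among the scenarios to a
    dict with the same average/maximum fields restricted to that stratum.
    """
    if not summaries:
        raise InsufficientDataError("no scenario summaries to aggregate")

    def block(items: Sequence[ScenarioSummary]) -> dict:
        ab_h = np.array([s.abs_bias_hap for s in items])
        ab_g = np.array([s.abs_bias_geno for s in items])
        sd_h = np.array([s.sd_hap for s in items])
        sd_g = np.array([s.sd_geno for s in items])
        return {
            "n_scenarios": len(items),
            "avg_abs_bias_hap": float(ab_h.mean()),
            "avg_abs_bias_geno": float(ab_g.mean()),
            "max_abs_bias_hap": float(ab_h.max()),
            "max_abs_bias_geno": float(ab_g.max()),
            "avg_sd_hap": float(sd_h.mean()),
            "avg_sd_geno": float(sd_g.mean()),
            "max_sd_hap": float(sd_h.max()),
            "max_sd_geno": float(sd_g.max()),
        }

    overall = block(summaries)
    by_n: dict[int, dict] = {}
    sizes = sorted({s.scenario.n for s in summaries if s.scenario is not None})
    for n in sizes:
        by_n[n] = block([s for s in summaries if s.scenario is not None and s.scenario.n == n])
    return AggregateSummary(
        n_scenarios=overall["n_scenarios"],
        avg_abs_bias_hap=overall["avg_abs_bias_hap"],
        avg_abs_bias_geno=overall["avg_abs_bias_geno"],
        max_abs_bias_hap=overall["max_abs_bias_hap"],
        max_abs_bias_geno=overall["max_abs_bias_geno"],
        avg_sd_hap=overall["avg_sd_hap"],
        avg_sd_geno=overall["avg_sd_geno"],
        max_sd_hap=overall["max_sd_hap"],
        max_sd_geno=overall["max_sd_geno"],
        by_sample_size=by_n,
        avg_mean_abs_diff=float(np.mean([s.mean_abs_diff for s in summaries])),
        avg_sd_diff=float(np.mean([s.sd_diff for s in summaries])),
    )


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Flatten scenario summaries into a tidy DataFrame (one row per scenario)."""
    rows = []
    for s in summaries:
        row = {
            "true_r2": s.true_r2,
            "n_reps": s.n_reps,
            "n_defined_reps": s.n_defined_reps,
            "mean_hap": s.mean_hap,
            "mean_geno": s.mean_geno,
            "bias_hap": s.bias_hap,
            "bias_geno": s.bias_geno,
            "abs_bias_hap": s.abs_bias_hap,
            "abs_bias_geno": s.abs_bias_geno,
            "sd_hap": s.sd_hap,
            "sd_geno": s.sd_geno,
            "ratio_of_precision": s.ratio_of_precision,
            "p_hap": s.p_hap,
            "p_geno": s.p_geno,
            "mean_abs_diff": s.mean_abs_diff,
            "sd_diff": s.sd_diff,
        }
        if s.scenario is not None:
            scn = s.scenario
            row = {
                "pM_A": scn.pM_A, "pN_A": scn.pN_A,
                "pM_B": scn.pM_B, "pN_B": scn.pN_B,
                "r2_A": scn.r2_A, "r2_B": scn.r2_B,
                "n": scn.n, "seed": scn.seed,
                **row,
            }
        rows.append(row)
    return pd.DataFrame(rows)


def precision_ratio_table(
    summaries: Sequence[ScenarioSummary], by: str = "r2"
) -> pd.DataFrame:
    """Min/mean/max of the precision ratio per stratum.

    ``by='r2'`` stratifies on the within-line r^2 level (assumed shared by
    both lines); ``by='frequency'`` on the unordered pair of line allele
    frequencies at locus M.  Raises if a requested stratum has no scenarios.
    """
    if not summaries:
        raise InsufficientDataError("no scenario summaries")
    if any(s.scenario is None for s in summaries):
        raise ValueError("precision_ratio_table requires scenario metadata")
    df = summaries_to_frame(summaries)
    if by == "r2":
        key = df["r2_A"]
    elif by == "frequency":
        key = [
            f"{min(a, b):.2f}/{max(a, b):.2f}"
            for a, b in zip(df["pM_A"], df["pM_B"])
        ]
    else:
        raise ValueError(f"unknown stratification {by!r}")
    out = (
        df.assign(stratum=key)
        .groupby("stratum")["ratio_of_precision"]
        .agg(["min", "mean", "max", "count"])
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# figures

def plot_ratio_by_r2(summaries, path):
    """Precision ratio of every scenario, grouped by within-line r^2 level."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summaries_to_frame(summaries)
    fig, ax = plt.subplots(figsize=(6, 4))
    levels = sorted(df["r2_A"].unique())
    data = [df.loc[df["r2_A"] == lv, "ratio_of_precision"].dropna() for lv in levels]
    ax.boxplot(data, tick_labels=[f"{lv:g}" for lv in levels])
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"within-line $r^2$")
    ax.set_ylabel(r"SD$_{hap}$ / SD$_{geno}$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ratio_selected(summaries, path, n: int = 900):
    """Precision ratio vs r^2 for each frequency pair at one sample size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summaries_to_frame(summaries)
    df = df[df["n"] == n]
    fig, ax = plt.subplots(figsize=(6, 4))
    df = df.assign(
        pair=[f"{min(a, b):g}/{max(a, b):g}" for a, b in zip(df["pM_A"], df["pM_B"])]
    )
    for pair, grp in df.groupby("pair"):
        grp = grp.sort_values("r2_A")
        ax.plot(grp["r2_A"], grp["ratio_of_precision"], marker="o", label=pair)
    ax.set_xlabel(r"within-line $r^2$")
    ax.set_ylabel(r"SD$_{hap}$ / SD$_{geno}$")
    ax.legend(fontsize=6, ncol=3, title="line freqs")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bias_by_sample_size(summaries, path):
    """Mean estimate ± SD against the truth, by sample size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summaries_to_frame(summaries).sort_values("n")
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(df))
    ax.errorbar(x - 0.1, df["mean_hap"], yerr=df["sd_hap"], fmt="o", label="haplotype")
    ax.errorbar(x + 0.1, df["mean_geno"], yerr=df["sd_geno"], fmt="s", label="genotype")
    ax.plot(x, df["true_r2"], "k_", markersize=12, label="true")
    ax.set_xticks(x)
    ax.set_xticklabels(df["n"].astype(int), rotation=45, fontsize=7)
    ax.set_xlabel("sample size")
    ax.set_ylabel(r"$\hat r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
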