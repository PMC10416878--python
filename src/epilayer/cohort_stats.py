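"""Cohort-level statistics on per-slide layer summaries.

Two reporting stages: a one-way ANOVA F-test comparing a slide summary
statistic (median or SD of layer number) across diagnosis severity groups,
and a survival analysis in which the cohort is split at the median of the
per-slide median layer counts into equal low/high groups, summarized with
Kaplan-Meier curves and a Cox proportional-hazards fit on the
progression-free interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .cell_model import validate_cohort_table
from .errors import ParameterError

__all__ = ["GroupComparison", "SurvivalReport", "compare_groups", "survival_split", "plot_km"]


@dataclass
class GroupComparison:
    statistic: str
    group_stats: dict[str, dict]  # label -> {n, mean, median}
    f_statistic: float
    p_value: float


@dataclass
class SurvivalReport:
    threshold: float                 # cohort median of median_layers
    group_sizes: dict[str, int]      # {"low": ..., "high": ...}
    km_curves: dict[str, pd.DataFrame]  # per group: time, at_risk, survival
    hazard_ratio: float | None
    cox_coef: float | None
    cox_se: float | None
    p_wald: float | None
    p_likelihood_ratio: float | None
    assignments: pd.DataFrame = field(repr=False, default=None)  # slide_id -> risk group


def compare_groups(cohort: pd.DataFrame, statistic: str = "median_layers") -> GroupComparison:
    """One-way ANOVA of a per-slide summary statistic across diagnosis groups.

    Degenerate inputs are resolved explicitly from the sums of squares:
    all-equal values give F = 0, p = 1; perfectly separated groups with zero
    within-group variance give F = inf, p = 0 (below machine floor).
    """
    validate_cohort_table(cohort)
    if statistic not in ("median_layers", "sd_layers"):
        raise ParameterError(f"unsupported statistic {statistic!r}")
    groups = {label: sub[statistic].to_numpy(float) for label, sub in cohort.groupby("diagnosis_group")}
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least 2 diagnosis groups")
    for label, values in groups.items():
        if len(values) < 2:
            raise ParameterError(f"group '{label}' has fewer than 2 slides")

    samples = list(groups.values())
    grand = np.concatenate(samples)
    ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_within <= 1e-300:
        f_stat, p = (0.0, 1.0) if ss_between <= 1e-300 else (float("inf"), 0.0)
    else:
        f_stat, p = stats.f_oneway(*samples)
    return GroupComparison(
        statistic=statistic,
        group_stats={
            label: {"n": int(len(v)), "mean": float(v.mean()), "median": float(np.median(v))}
            for label, v in groups.items()
        },
        f_statistic=float(f_stat),
        p_value=float(p),
    )


def survival_split(
    cohort: pd.DataFrame, extra_covariates: Sequence[str] = ()
) -> SurvivalReport:
    """Median split of the cohort by layer number, KM curves and Cox PH fit.

    Slides are stable-sorted by (median_layers, slide_id); the first
    floor(n/2) form the low-layer group and the remaining ceil(n/2) the
    high-layer group (ties at the threshold broken by slide id).  The Cox
    model regresses the progression-free interval on the high-group
    indicator plus any ``extra_covariates`` columns, with the Efron tie
    approximation; an all-censored cohort yields a warning and undefined
    p-values.
    """
    cohort = validate_cohort_table(cohort).copy()
    ordered = cohort.sort_values(["median_layers", "slide_id"], kind="stable").reset_index(drop=True)
    n = len(ordered)
    n_low = n // 2
    ordered["risk_group"] = ["low"] * n_low + ["high"] * (n - n_low)
    threshold = float(ordered["median_layers"].median())

    km_curves: dict[str, pd.DataFrame] = {}
    for label, sub in ordered.groupby("risk_group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["pfi_time"], event_observed=sub["pfi_event"], label=label)
        table = kmf.event_table
        km_curves[label] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(float),
                "survival": kmf.survival_function_[label].to_numpy(float),
            }
        ).merge(
            pd.DataFrame({"time": table.index.to_numpy(float), "at_risk": table["at_risk"].to_numpy()}),
            on="time",
            how="left",
        )

    if int(ordered["pfi_event"].sum()) == 0:
        warnings.warn("all-censored cohort: survival comparison undefined", stacklevel=2)
        hr = coef = se = p_wald = p_lr = None
    else:
        df = ordered[["pfi_time", "pfi_event"]].copy()
        df["high_layers"] = (ordered["risk_group"] == "high").astype(float)
        for cov in extra_covariates:
            df[cov] = ordered[cov].to_numpy(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="pfi_time", event_col="pfi_event")  # Efron ties (lifelines default)
        coef = float(cph.params_["high_layers"])
        se = float(cph.standard_errors_["high_layers"])
        hr = float(np.exp(coef))
        p_wald = float(cph.summary.loc["high_layers", "p"])
        p_lr = float(cph.log_likelihood_ratio_test().p_value)

    return SurvivalReport(
        threshold=threshold,
        group_sizes={"low": n_low, "high": n - n_low},
        km_curves=km_curves,
        hazard_ratio=hr,
        cox_coef=coef,
        cox_se=se,
        p_wald=p_wald,
        p_likelihood_ratio=p_lr,
        assignments=ordered[["slide_id", "risk_group"]],
    )


def plot_km(report: SurvivalReport, path: str | Path) -> None:
    """Save a Kaplan-Meier step plot of the low/high layer-number groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in sorted(report.km_curves.items()):
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"{label} layers (n={report.group_sizes[label]})")
    ax.set_xlabel("progression-free interval (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if report.p_likelihood_ratio is not None:
        ax.set_title(f"median split at {report.threshold:.1f} layers "
                     f"(LR p = {report.p_likelihood_ratio:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
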