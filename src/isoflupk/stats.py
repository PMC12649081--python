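"""Bioanalysis statistics: fractional excretion, censored summaries,
and baseline-versus-time repeated-measures comparisons.

The baseline comparison follows the classical balanced one-within-factor
repeated-measures ANOVA (subject as random effect, time as fixed
effect), which for balanced data is exactly the random-intercept mixed
model.  Post hoc, each post-baseline time is compared with baseline by a
paired t-test on within-subject differences and the p-values are
Bonferroni-adjusted (multiplied by the number of post-baseline
comparisons, capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FESample",
    "CensoredSummary",
    "RMAnovaResult",
    "fractional_excretion",
    "censored_summary",
    "rm_anova_baseline",
    "electrolyte_prepost",
]


@dataclass(frozen=True)
class FESample:
    """Paired urine/plasma analyte and creatinine measurements.

    The analyte pair and the creatinine pair must each be in the same
    units (any units — the ratios cancel them).
    """

    analyte: str
    urine_conc: float
    plasma_conc: float
    urine_creatinine: float
    plasma_creatinine: float

    def __post_init__(self) -> None:
        for name in ("urine_conc", "plasma_conc", "urine_creatinine", "plasma_creatinine"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0 for a valid sample")


def fractional_excretion(s: FESample) -> float:
    """Urinary fractional excretion in percent.

    FE = [(U_x / P_x) / (U_cr / P_cr)] * 100 — the analyte's urinary
    clearance relative to creatinine clearance.
    """
    return (s.urine_conc / s.plasma_conc) / (s.urine_creatinine / s.plasma_creatinine) * 100.0


@dataclass
class CensoredSummary:
    """Above-LOQ summary at one time point (mean/SD over quantifiable values)."""

    time_h: float
    mean: float | None  # None when all values are censored (reported ND)
    sd: float | None
    n_above_loq: int
    n_total: int

    @property
    def label(self) -> str:
        if self.n_above_loq == 0:
            return "ND"
        if self.sd is None:
            return f"{self.mean:.2f}"
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def censored_summary(values, loq: float, time_h: float = float("nan")) -> CensoredSummary:
    """Summarize one time point's concentrations under LOQ censoring.

    Values below the LOQ are counted but excluded from mean/SD; a time
    at which every horse is below LOQ is reported as ND.
    """
    v = np.asarray(values, dtype=float)
    above = v[v >= loq]
    if above.size == 0:
        return CensoredSummary(time_h, None, None, 0, v.size)
    sd = float(above.std(ddof=1)) if above.size > 1 else None
    return CensoredSummary(time_h, float(above.mean()), sd, int(above.size), int(v.size))


@dataclass
class RMAnovaResult:
    """Omnibus repeated-measures ANOVA plus per-time post hoc table."""

    f_stat: float
    p_value: float
    df_time: int
    df_resid: int
    balanced: bool
    table: pd.DataFrame  # one row per post-baseline time


def _balanced(pivot: pd.DataFrame) -> bool:
    return not pivot.isna().any().any()


def rm_anova_baseline(
    data: pd.DataFrame, alpha: float = 0.05, baseline_time: float = 0.0
) -> RMAnovaResult:
    """Baseline-versus-time analysis of a long biomarker series.

    ``data`` holds columns subject_id, time_h, value with one value per
    subject and time; ``baseline_time`` (default 0 h) marks the pre-dose
    measurement.  Subjects lacking a baseline are dropped with a
    warning.  The omnibus F uses the balanced decomposition on
    complete-case subjects; the post hoc paired t-tests are
    pairwise-complete with per-comparison n reported.
    """
    required = {"subject_id", "time_h", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"long series needs columns {sorted(required)}")
    df = data.copy()
    with_baseline = set(df.loc[df["time_h"] == baseline_time, "subject_id"])
    dropped = set(df["subject_id"]) - with_baseline
    if dropped:
        warnings.warn(f"dropping subjects without baseline: {sorted(map(str, dropped))}")
        df = df[df["subject_id"].isin(with_baseline)]
    times = np.sort(df["time_h"].unique())
    if len(with_baseline) < 2 or times.size < 2:
        raise ValueError("need >=2 subjects and >=2 time points including baseline")

    pivot = df.pivot_table(index="subject_id", columns="time_h", values="value", aggfunc="first")
    balanced = _balanced(pivot)
    complete = pivot.dropna()
    y = complete.to_numpy(dtype=float)
    n, t = y.shape
    if n >= 2 and t >= 2:
        grand = y.mean()
        ss_subj = t * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_res = ss_tot - ss_subj - ss_time
        df_time = t - 1
        df_res = (n - 1) * (t - 1)
        ms_res = ss_res / df_res
        if ms_res <= 0 or not np.isfinite(ms_res):
            f_stat, p_value = 0.0, 1.0  # degenerate: no residual variation
        else:
            f_stat = (ss_time / df_time) / ms_res
            p_value = float(sps.f.sf(f_stat, df_time, df_res))
    else:
        f_stat, p_value, df_time, df_res = float("nan"), float("nan"), 0, 0

    post_times = [tt for tt in times if tt != baseline_time]
    m = len(post_times)
    rows = []
    base = pivot[baseline_time]
    for tt in post_times:
        paired = pd.concat([base, pivot[tt]], axis=1).dropna()
        diffs = paired.iloc[:, 1] - paired.iloc[:, 0]
        n_pair = len(diffs)
        if n_pair >= 2 and diffs.std(ddof=1) > 0:
            t_stat, p_raw = sps.ttest_rel(paired.iloc[:, 1], paired.iloc[:, 0])
            t_stat, p_raw = float(t_stat), float(p_raw)
        elif n_pair >= 2:
            t_stat = 0.0 if diffs.mean() == 0 else float("inf")
            p_raw = 1.0 if diffs.mean() == 0 else 0.0
        else:
            t_stat, p_raw = float("nan"), float("nan")
        p_adj = min(p_raw * m, 1.0) if np.isfinite(p_raw) else float("nan")
        rows.append(
            {
                "time_h": tt,
                "n": n_pair,
                "mean_diff": float(diffs.mean()) if n_pair else float("nan"),
                "t_stat": t_stat,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
            }
        )
    return RMAnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        df_time=int(df_time),
        df_resid=int(df_res),
        balanced=balanced,
        table=pd.DataFrame(rows),
    )


def electrolyte_prepost(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pre/post comparison of plasma electrolytes and their fractional excretion.

    ``df`` is the electrolyte table with columns subject_id,
    phase (pre|post), analyte, plasma_value, urine_value,
    plasma_creatinine, urine_creatinine.  For each analyte the plasma
    concentration and the FE are each compared pre vs post by a paired
    t-test (a two-time-point special case of the baseline machinery, so
    the Bonferroni factor within each endpoint is 1).
    """
    required = {
        "subject_id",
        "phase",
        "analyte",
        "plasma_value",
        "urine_value",
        "plasma_creatinine",
        "urine_creatinine",
    }
    if not required <= set(df.columns):
        raise ValueError(f"electrolyte table needs columns {sorted(required)}")
    work = df.copy()
    work["fe_pct"] = (
        (work["urine_value"] / work["plasma_value"])
        / (work["urine_creatinine"] / work["plasma_creatinine"])
        * 100.0
    )
    rows = []
    for analyte, grp in work.groupby("analyte", sort=True):
        wide_p = grp.pivot_table(index="subject_id", columns="phase", values="plasma_value")
        wide_f = grp.pivot_table(index="subject_id", columns="phase", values="fe_pct")
        row: dict = {"analyte": analyte}
        for label, wide in (("plasma", wide_p), ("fe", wide_f)):
            paired = wide.dropna()
            pre, post = paired["pre"], paired["post"]
            _, p = sps.ttest_rel(post, pre)
            row.update(
                {
                    f"{label}_pre_mean": float(pre.mean()),
                    f"{label}_pre_sd": float(pre.std(ddof=1)),
                    f"{label}_post_mean": float(post.mean()),
                    f"{label}_post_sd": float(post.std(ddof=1)),
                    f"{label}_pre_median": float(pre.median()),
                    f"{label}_post_median": float(post.median()),
                    f"{label}_p": float(p),
                    f"{label}_significant": bool(p < alpha),
                    f"{label}_n": int(len(paired)),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
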