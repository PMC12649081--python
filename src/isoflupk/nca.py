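"""Non-compartmental analysis (NCA) of single-subject concentration profiles.

Implements the standard model-free summary of a concentration-time
profile: Cmax/Tmax, terminal slope (lambda_z) by best-fit log-linear
regression, linear-up/log-down trapezoidal AUC, extrapolation to
infinity, and a cohort summary table (mean +/- SD, median, range).

BLQ handling: a leading below-LOQ observation at t=0 anchors the profile
at (0, 0); embedded and trailing BLQ points are excluded from both the
terminal regression and the trapezoidal integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConcProfile",
    "NCAResult",
    "NoQuantifiableData",
    "TerminalPhaseNotEstimable",
    "find_cmax_tmax",
    "fit_lambda_z",
    "auc_linuplogdown",
    "extrapolate_auc",
    "run_nca",
    "nca_cohort_summary",
    "read_conc_csv",
    "write_nca_csv",
]


class NoQuantifiableData(ValueError):
    """Profile contains no quantifiable (above-LOQ) observation."""


class TerminalPhaseNotEstimable(ValueError):
    """Too few terminal points, or the best terminal slope is nonnegative."""


@dataclass
class ConcProfile:
    """One subject's concentration-time series with censoring flags.

    times are hours post-dose (strictly increasing), concs in ng/mL.
    BLQ points carry conc = 0 internally; ``loq`` is the assay limit of
    quantitation in ng/mL.
    """

    subject_id: str
    times: np.ndarray
    concs: np.ndarray
    blq_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    loq: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.blq_flags is None:
            self.blq_flags = np.zeros(self.times.shape, dtype=bool)
        self.blq_flags = np.asarray(self.blq_flags, dtype=bool)
        if not (self.times.shape == self.concs.shape == self.blq_flags.shape):
            raise ValueError("times, concs and blq_flags must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concs < 0):
            raise ValueError("concentrations must be nonnegative")
        # censored values are zero internally
        self.concs = np.where(self.blq_flags, 0.0, self.concs)

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of above-LOQ observations."""
        return ~self.blq_flags & (self.concs > 0)


@dataclass
class NCAResult:
    """Per-subject non-compartmental outputs."""

    subject_id: str
    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float  # 1/h
    t_half: float  # h
    auc_last: float  # ng*h/mL
    auc_inf: float  # ng*h/mL
    pct_extrap: float  # %
    n_lambda_points: int
    r2_adj: float


def find_cmax_tmax(profile: ConcProfile) -> tuple[float, float]:
    """Maximum observed quantifiable concentration and its time.

    Ties are broken by the earliest time (argmax on the raw array).
    """
    mask = profile.quantifiable
    if not mask.any():
        raise NoQuantifiableData(f"profile {profile.subject_id!r} is entirely BLQ")
    concs = np.where(mask, profile.concs, -np.inf)
    idx = int(np.argmax(concs))
    return float(profile.concs[idx]), float(profile.times[idx])


def _adjusted_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x; returns (slope, intercept, adjusted R^2)."""
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), r2_adj


def fit_lambda_z(profile: ConcProfile) -> tuple[float, int, float]:
    """Best-fit terminal elimination rate constant.

    Candidate windows are all suffixes (>= 3 points) of the quantifiable
    observations strictly after Tmax — the Tmax point itself is never
    included.  For each window ln(conc) is regressed on time; the window
    with the highest adjusted R^2 wins, with ties (within 1e-4) resolved
    in favor of more points.  Returns (lambda_z, n_points, r2_adj).
    """
    _, tmax = find_cmax_tmax(profile)
    mask = profile.quantifiable & (profile.times > tmax)
    t = profile.times[mask]
    c = profile.concs[mask]
    if t.size < 3:
        raise TerminalPhaseNotEstimable(
            f"profile {profile.subject_id!r}: need >=3 quantifiable post-peak points, "
            f"have {t.size}"
        )
    logc = np.log(c)
    best: tuple[float, int, float] | None = None  # (r2_adj, n, lambda_z)
    for start in range(t.size - 2):
        slope, _, r2_adj = _adjusted_r2(t[start:], logc[start:])
        n = t.size - start
        if slope >= 0:
            continue
        if best is None or r2_adj > best[0] + 1e-4:
            best = (r2_adj, n, -slope)
        elif abs(r2_adj - best[0]) <= 1e-4 and n > best[1]:
            best = (r2_adj, n, -slope)
    if best is None:
        raise TerminalPhaseNotEstimable(
            f"profile {profile.subject_id!r}: no window with a negative terminal slope"
        )
    r2_adj, n, lambda_z = best
    return lambda_z, n, r2_adj


def auc_linuplogdown(profile: ConcProfile) -> float:
    """AUC to the last quantifiable observation, linear-up/log-down rule.

    Per interval: linear trapezoid when C2 >= C1 or either endpoint is
    zero; logarithmic trapezoid (C1 - C2) * dt / ln(C1/C2) when the
    concentration is falling and both endpoints are positive.  The
    profile is anchored at (0, 0) if it does not start at t = 0.
    """
    mask = profile.quantifiable
    if not mask.any():
        raise NoQuantifiableData(f"profile {profile.subject_id!r} is entirely BLQ")
    last_q = np.max(np.where(mask)[0])
    # span from time 0 to the last quantifiable point; embedded BLQ excluded
    keep = mask.copy()
    keep[: last_q + 1] &= True
    t = profile.times[keep]
    c = profile.concs[keep]
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    auc = 0.0
    for i in range(t.size - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c2 >= c1 or c1 == 0.0 or c2 == 0.0:
            auc += 0.5 * (c1 + c2) * dt
        else:
            auc += (c1 - c2) * dt / np.log(c1 / c2)
    return float(auc)


def extrapolate_auc(
    auc_last: float, clast_observed: float, lambda_z: float
) -> tuple[float, float]:
    """Extrapolate AUC to infinity: AUCinf = AUClast + Clast/lambda_z.

    Returns (auc_inf, pct_extrap) with pct_extrap in percent of AUCinf.
    """
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    auc_inf = auc_last + clast_observed / lambda_z
    pct = 0.0 if auc_inf == 0 else 100.0 * (auc_inf - auc_last) / auc_inf
    return float(auc_inf), float(pct)


def run_nca(profile: ConcProfile) -> NCAResult:
    """Full single-subject NCA: Cmax/Tmax, lambda_z, AUClast, AUCinf.

    Clast for the extrapolation is the observed last quantifiable
    concentration (not the lambda_z-predicted value).
    """
    cmax, tmax = find_cmax_tmax(profile)
    lambda_z, n_pts, r2_adj = fit_lambda_z(profile)
    auc_last = auc_linuplogdown(profile)
    mask = profile.quantifiable
    clast = float(profile.concs[np.max(np.where(mask)[0])])
    auc_inf, pct_extrap = extrapolate_auc(auc_last, clast, lambda_z)
    return NCAResult(
        subject_id=profile.subject_id,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lambda_z,
        t_half=float(np.log(2.0) / lambda_z),
        auc_last=auc_last,
        auc_inf=auc_inf,
        pct_extrap=pct_extrap,
        n_lambda_points=n_pts,
        r2_adj=r2_adj,
    )


_SUMMARY_COLS = [
    "cmax",
    "tmax",
    "lambda_z",
    "t_half",
    "auc_last",
    "auc_inf",
    "pct_extrap",
]


def nca_cohort_summary(results: list[NCAResult]) -> pd.DataFrame:
    """Cohort summary: mean, SD (n-1), median, min, max per parameter.

    With a single subject the SD is reported as 0 and flagged via n=1.
    """
    if not results:
        raise ValueError("no NCA results to summarize")
    df = pd.DataFrame([vars(r) for r in results])
    rows = []
    for col in _SUMMARY_COLS:
        v = df[col].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": col,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def read_conc_csv(path: str | Path, loq: float = 0.0) -> list[ConcProfile]:
    """Read a long-format concentration CSV into per-subject profiles.

    Expected columns: subject_id, time_h, conc_ng_ml, blq.  BLQ rows may
    carry an empty concentration; they are stored as 0 with the flag set.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "time_h", "conc_ng_ml", "blq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"concentration CSV {path} has no data rows")
    profiles = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_h")
        blq = grp["blq"].astype(bool).to_numpy()
        conc = grp["conc_ng_ml"].to_numpy(dtype=float)
        conc = np.where(blq | ~np.isfinite(conc), 0.0, conc)
        profiles.append(
            ConcProfile(
                subject_id=str(sid),
                times=grp["time_h"].to_numpy(dtype=float),
                concs=conc,
                blq_flags=blq,
                loq=loq,
            )
        )
    return profiles


def write_nca_csv(results: list[NCAResult], path: str | Path) -> None:
    """Write per-subject NCA rows followed by a summary block."""
    per_subject = pd.DataFrame([vars(r) for r in results])
    per_subject.to_csv(path, index=False)
    summary = nca_cohort_summary(results)
    with open(path, "a") as fh:
        fh.write("\n")
        summary.to_csv(fh, index=False)
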