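"""Synthetic study-data generators.

Emulates the statistical structure of a 12-horse single-dose
intramuscular study — plasma drug concentrations from the population PK
model with multiplicative assay error and LOQ censoring, mono-exponentially
declining urine concentrations, a cortisol-suppression time course with
its nadir at 36 h, and pre/post electrolyte panels with the matching
fractional-excretion shifts — so every analysis stage can be exercised
end-to-end without any external data.

The cortisol and electrolyte generators are SHAPE TEMPLATES with
controllable effect sizes (including a null mode), not mechanistic PD
models: their job is to stress the statistics stage, not to predict
biology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pk_model import DoseEvent, predict_concentration
from .population import TABLE_POP, PopulationModel, sample_individuals

__all__ = [
    "StudyConfig",
    "PLASMA_SCHEDULE_H",
    "URINE_SCHEDULE_H",
    "gen_plasma",
    "gen_urine",
    "gen_cortisol",
    "gen_electrolytes",
]

#: plasma sampling schedule, hours post-dose (5/10/15/30/45 min, then
#: 1-312 h)
PLASMA_SCHEDULE_H: tuple[float, ...] = (
    5 / 60, 10 / 60, 15 / 60, 0.5, 0.75, 1, 2, 3, 4, 5, 6, 8, 12, 18, 24,
    30, 36, 48, 60, 72, 96, 120, 168, 192, 216, 240, 312,
)

#: urine collection schedule, hours post-dose
URINE_SCHEDULE_H: tuple[float, ...] = (24, 48, 72, 96, 120, 168, 192, 216, 240, 312, 336, 360)


@dataclass(frozen=True)
class StudyConfig:
    """Study-design constants for the synthetic generators."""

    n_horses: int = 12
    dose_mg: float = 20.0
    bw_mean_kg: float = 556.5
    bw_sd_kg: float = 58.4
    sample_bw: bool = False  # draw per-horse body weights vs. fix at the mean
    pop: PopulationModel = TABLE_POP
    plasma_schedule_h: tuple[float, ...] = PLASMA_SCHEDULE_H
    urine_schedule_h: tuple[float, ...] = URINE_SCHEDULE_H
    plasma_loq: float = 0.01  # ng/mL
    urine_loq: float = 0.05  # ng/mL
    # urine decline: U(t) = U24 * exp(-kz (t - 24)), lognormal U24
    urine_u24_gm: float = 13.0  # geometric mean at 24 h, ng/mL
    urine_u24_log_sd: float = 0.5
    urine_kz_mean: float = 0.012  # 1/h; counts above LOQ reach ~0 by 360 h
    urine_kz_sd: float = 0.002
    urine_noise_log_sd: float = 0.25
    # cortisol suppression template
    cortisol_baseline_mean: float = 52.0  # ng/mL
    cortisol_baseline_sd: float = 10.3
    cortisol_nadir_time_h: float = 36.0
    cortisol_suppression_max: float = 0.9  # fractional suppression at the nadir
    cortisol_suppression_base: float = 0.65  # sustained suppression away from the nadir
    cortisol_nadir_log_width: float = 0.6  # log-time width of the nadir bump
    cortisol_onset_rate: float = 9.2  # 1/h; onset essentially complete by 30 min
    cortisol_noise_cv: float = 0.10
    electrolyte_effect: bool = True  # False = null mode (post == pre distribution)
    seed: int = 0

    def dose_event(self, bw_kg: float | None = None) -> DoseEvent:
        return DoseEvent(dose_mg=self.dose_mg, bw_kg=bw_kg or self.bw_mean_kg)


def _rng(config: StudyConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _body_weights(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    if config.sample_bw:
        bw = rng.normal(config.bw_mean_kg, config.bw_sd_kg, config.n_horses)
        return np.maximum(bw, 300.0)
    return np.full(config.n_horses, config.bw_mean_kg)


def gen_plasma(config: StudyConfig) -> pd.DataFrame:
    """Plasma drug concentrations, long format with BLQ censoring.

    Per horse: sample individual PK parameters, evaluate the
    one-compartment profile on the plasma schedule, apply multiplicative
    residual error (stdev0) and censor at the plasma LOQ.  Columns:
    subject_id, time_h, conc_ng_ml (NaN when censored), blq.
    """
    rng = _rng(config, 1)
    params = sample_individuals(config.pop, config.n_horses, seed=rng.integers(2**31))
    bws = _body_weights(config, rng)
    times = np.asarray(config.plasma_schedule_h, dtype=float)
    rows = []
    for i, (p, bw) in enumerate(zip(params, bws)):
        conc = predict_concentration(p, config.dose_event(bw), times)
        if config.pop.stdev0 > 0:
            eps = np.maximum(rng.normal(0.0, config.pop.stdev0, times.size), -1.0)
            conc = conc * (1.0 + eps)
        blq = conc < config.plasma_loq
        for t, c, b in zip(times, conc, blq):
            rows.append(
                {
                    "subject_id": f"H{i + 1:02d}",
                    "time_h": t,
                    "conc_ng_ml": np.nan if b else float(c),
                    "blq": bool(b),
                }
            )
    return pd.DataFrame(rows)


def gen_urine(config: StudyConfig) -> pd.DataFrame:
    """Urine drug concentrations: mono-exponential decline, LOQ censoring.

    Per horse U(t) = U24 * exp(-kz (t - 24)) with log-normal U24 and
    Normal kz, multiplied by log-normal noise, censored at the urine
    LOQ.  Same long-format schema as gen_plasma.
    """
    rng = _rng(config, 2)
    times = np.asarray(config.urine_schedule_h, dtype=float)
    rows = []
    for i in range(config.n_horses):
        u24 = config.urine_u24_gm * np.exp(rng.normal(0.0, config.urine_u24_log_sd))
        kz = max(rng.normal(config.urine_kz_mean, config.urine_kz_sd), 1e-4)
        conc = u24 * np.exp(-kz * (times - 24.0))
        if config.urine_noise_log_sd > 0:
            conc = conc * np.exp(rng.normal(0.0, config.urine_noise_log_sd, times.size))
        blq = conc < config.urine_loq
        for t, c, b in zip(times, conc, blq):
            rows.append(
                {
                    "subject_id": f"H{i + 1:02d}",
                    "time_h": t,
                    "conc_ng_ml": np.nan if b else float(c),
                    "blq": bool(b),
                }
            )
    return pd.DataFrame(rows)


def _suppression(config: StudyConfig, t: np.ndarray) -> np.ndarray:
    """Fractional cortisol suppression template S(t) in [0, 1).

    A sustained plateau (base level, reached after a rapid first-order
    onset) plus a log-time Gaussian bump peaked at the nadir time, so
    the template has a genuinely peaked minimum at 36 h while staying
    above 0.6 from 30 min through 312 h (the stated effect size the
    statistics stage is tested against).  Scaling the template scales
    both the plateau and the bump, so ``cortisol_suppression_max = 0``
    is the null (flat) mode.
    """
    t = np.asarray(t, dtype=float)
    smax = config.cortisol_suppression_max
    if smax == 0.0:
        return np.zeros_like(t)
    base = config.cortisol_suppression_base * (smax / 0.9)
    amp = max(smax - base, 0.0)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(t > 0, np.log(np.maximum(t, 1e-12) / config.cortisol_nadir_time_h), -np.inf)
    bump = np.exp(-(log_ratio**2) / (2.0 * config.cortisol_nadir_log_width**2))
    onset = 1.0 - np.exp(-config.cortisol_onset_rate * t)
    return (base + amp * bump) * onset


def gen_cortisol(config: StudyConfig) -> pd.DataFrame:
    """Cortisol time series, long format (subject_id, time_h, value).

    Per horse a Normal baseline B and value(t) = B * (1 - S(t)) with
    proportional noise; the cohort mean curve has its minimum at the
    configured nadir time (36 h).  Sampling starts at 30 min post-dose
    (baseline coded as time 0).
    """
    rng = _rng(config, 3)
    times = np.array([0.0] + [t for t in config.plasma_schedule_h if t >= 0.5])
    supp = _suppression(config, times)
    supp[0] = 0.0  # baseline is pre-dose
    rows = []
    for i in range(config.n_horses):
        base = max(rng.normal(config.cortisol_baseline_mean, config.cortisol_baseline_sd), 1.0)
        values = base * (1.0 - supp)
        if config.cortisol_noise_cv > 0:
            values = values * (1.0 + rng.normal(0.0, config.cortisol_noise_cv, times.size))
        for t, v in zip(times, values):
            rows.append(
                {"subject_id": f"H{i + 1:02d}", "time_h": float(t), "value": max(float(v), 0.0)}
            )
    return pd.DataFrame(rows)


# plasma electrolyte distributions (mean, SD) and FE medians (pre, post);
# mmol/L for K/Na/Cl, mg/dL for Ca/P; FE in percent
_ELECTROLYTES = {
    "potassium": {"plasma": ((3.8, 0.71), (2.7, 0.67)), "fe": (39.0, 69.0)},
    "sodium": {"plasma": ((137.0, 1.2), (140.0, 1.2)), "fe": (2.3, 1.61)},
    "chloride": {"plasma": ((100.1, 1.5), (99.9, 1.0)), "fe": (3.7, 2.2)},
    "calcium": {"plasma": ((11.6, 0.4), (11.8, 0.4)), "fe": (4.7, 12.1)},
    "phosphorus": {"plasma": ((3.3, 0.66), (3.3, 0.71)), "fe": (0.02, 0.02)},
}
_FE_LOG_SD = 0.30  # log-scale spread of individual FE values around the median


def gen_electrolytes(config: StudyConfig) -> pd.DataFrame:
    """Pre/post electrolyte panel with urine values back-computed from FE.

    Per horse and phase: plasma values are Normal draws around the
    target pre/post means; each analyte's FE is a log-normal draw around
    its target median and the urine concentration is solved from the FE
    identity given shared per-horse creatinine values.  In null mode
    (``electrolyte_effect=False``) the post phase re-draws from the pre
    distributions, giving an exchangeable no-effect dataset.
    """
    rng = _rng(config, 4)
    rows = []
    for i in range(config.n_horses):
        sid = f"H{i + 1:02d}"
        for phase_idx, phase in enumerate(("pre", "post")):
            eff = phase_idx if config.electrolyte_effect else 0
            p_cr = max(rng.normal(1.4, 0.15), 0.5)  # mg/dL
            u_cr = 150.0 * np.exp(rng.normal(0.0, 0.3))  # mg/dL
            for analyte, spec_ in _ELECTROLYTES.items():
                mean, sd = spec_["plasma"][eff]
                plasma = max(rng.normal(mean, sd), 0.05 * mean)
                fe = spec_["fe"][eff] * np.exp(rng.normal(0.0, _FE_LOG_SD))
                urine = fe / 100.0 * (u_cr / p_cr) * plasma
                rows.append(
                    {
                        "subject_id": sid,
                        "phase": phase,
                        "analyte": analyte,
                        "plasma_value": float(plasma),
                        "urine_value": float(urine),
                        "plasma_creatinine": float(p_cr),
                        "urine_creatinine": float(u_cr),
                    }
                )
    return pd.DataFrame(rows)


def null_config(config: StudyConfig | None = None, seed: int | None = None) -> StudyConfig:
    """A no-effect variant: flat cortisol, exchangeable electrolytes."""
    cfg = config or StudyConfig()
    updates: dict = {"cortisol_suppression_max": 0.0, "electrolyte_effect": False}
    if seed is not None:
        updates["seed"] = seed
    return replace(cfg, **updates)
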