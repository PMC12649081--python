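"""One-compartment extravascular PK model with closed-form kinetics.

The model describes plasma concentration after a single extravascular
(intramuscular) bolus with first-order absorption and first-order
elimination:

    C(t) = (D/BW) / (V/F) * ka/(ka - ke) * (exp(-ke*t) - exp(-ka*t))

where D is the dose, BW body weight, V/F the apparent volume of
distribution, ka the absorption rate constant and ke = (CL/F)/(V/F) the
elimination rate constant.  Bioavailability F is absorbed into the
apparent parameters (every volume and clearance is "/F").

Units are pinned at the interface and never inferred: time in hours,
concentration in ng/mL, dose in mg, body weight in kg, V/F in L/kg and
CL/F in mL/min/kg (the unit the population model is reported in);
internally clearance is carried in L/h/kg.  Flip-flop kinetics
(ka < ke, terminal slope governed by absorption) is permitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParams",
    "DoseEvent",
    "SecondaryParams",
    "convert_clearance",
    "predict_concentration",
    "derive_secondary",
]

#: relative |ka - ke| / ke below which the degenerate (ka == ke) limit is used
_DEGENERATE_RTOL = 1e-6


@dataclass(frozen=True)
class PKParams:
    """Individual one-compartment extravascular parameters.

    Attributes
    ----------
    ka : float
        First-order absorption rate constant, 1/h.
    cl_f : float
        Apparent clearance CL/F, mL/min/kg.
    v_f : float
        Apparent volume of distribution V/F, L/kg.
    """

    ka: float
    cl_f: float
    v_f: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl_f", "v_f"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")

    @property
    def ke(self) -> float:
        """Elimination rate constant (CL/F)/(V/F), 1/h."""
        return convert_clearance(self.cl_f) / self.v_f


@dataclass(frozen=True)
class DoseEvent:
    """A single extravascular bolus dose.

    Attributes
    ----------
    dose_mg : float
        Administered dose, mg.
    bw_kg : float
        Body weight, kg; the model is parameterized per kg so body
        weight enters only through dose_mg / bw_kg.
    route : str
        Label; only an extravascular bolus ("im") is supported.
    """

    dose_mg: float
    bw_kg: float
    route: str = "im"

    def __post_init__(self) -> None:
        if not (self.dose_mg > 0):
            raise ValueError(f"dose_mg must be > 0, got {self.dose_mg!r}")
        if not (self.bw_kg > 0):
            raise ValueError(f"bw_kg must be > 0, got {self.bw_kg!r}")

    @property
    def dose_ng_per_kg(self) -> float:
        """Dose normalized by body weight, ng/kg."""
        return self.dose_mg / self.bw_kg * 1e6


@dataclass(frozen=True)
class SecondaryParams:
    """Derived (secondary) parameters of the one-compartment model."""

    ke: float  # elimination rate constant, 1/h
    t_half: float  # elimination half-life, h
    tmax_model: float  # model-predicted time of peak, h
    cmax_model: float  # model-predicted peak concentration, ng/mL
    auc_inf_model: float  # model-predicted AUC to infinity, ng*h/mL


def convert_clearance(cl_ml_min_kg: float) -> float:
    """Convert clearance from mL/min/kg (reporting unit) to L/h/kg.

    1 mL/min = 60 mL/h = 0.06 L/h, so the factor is 0.06 exactly.
    """
    if not (cl_ml_min_kg > 0):
        raise ValueError(f"clearance must be > 0, got {cl_ml_min_kg!r}")
    return cl_ml_min_kg * 0.06


def predict_concentration(
    params: PKParams, dose: DoseEvent, times: np.ndarray | list[float]
) -> np.ndarray:
    """Evaluate the closed-form concentration profile at ``times``.

    Parameters
    ----------
    params, dose
        Individual parameters and dosing event.
    times
        Sampling times in hours, nonnegative and sorted ascending.

    Returns
    -------
    numpy.ndarray
        Concentrations in ng/mL; C(0) = 0 and the profile is unimodal.

    Notes
    -----
    When ka and ke coincide to within 1e-6 relative the general formula
    is 0/0; the analytic limit C(t) = (D/BW)/(V/F) * ka * t * exp(-ka*t)
    is used instead, which keeps the model continuous across ka == ke.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and t[0] < 0:
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")

    ka = params.ka
    ke = params.ke
    # (D/BW)/(V/F) in ng/L per kg basis -> ng/mL needs /1000
    c0 = dose.dose_ng_per_kg / params.v_f / 1000.0

    if abs(ka - ke) / ke < _DEGENERATE_RTOL:
        conc = c0 * ka * t * np.exp(-ka * t)
    else:
        conc = c0 * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    # clip tiny negative round-off near t=0
    return np.maximum(conc, 0.0)


def derive_secondary(params: PKParams, dose: DoseEvent) -> SecondaryParams:
    """Derive ke, half-life, tmax, cmax and AUCinf from primary parameters.

    ke = (CL/F)/(V/F); t_half = ln2/ke; tmax = ln(ka/ke)/(ka-ke) (limit
    1/ka when ka == ke); AUCinf = (dose/BW)/(CL/F), returned in ng*h/mL.
    """
    ka = params.ka
    ke = params.ke
    if abs(ka - ke) / ke < _DEGENERATE_RTOL:
        tmax = 1.0 / ka
    else:
        tmax = math.log(ka / ke) / (ka - ke)
    cl_l_h_kg = convert_clearance(params.cl_f)
    auc_inf = dose.dose_ng_per_kg / cl_l_h_kg / 1000.0  # ng*h/mL
    cmax = float(predict_concentration(params, dose, np.array([tmax]))[0])
    return SecondaryParams(
        ke=ke,
        t_half=math.log(2.0) / ke,
        tmax_model=tmax,
        cmax_model=cmax,
        auc_inf_model=auc_inf,
    )
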