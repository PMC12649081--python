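import numpy as np
import pytest

from isoflupk import DoseEvent, PKParams, TABLE_POP
from isoflupk.nca import ConcProfile
from isoflupk.synthetic import PLASMA_SCHEDULE_H


@pytest.fixture(scope="session")
def typical_params() -> PKParams:
    """Published typical one-compartment parameters."""
    return TABLE_POP.tv


@pytest.fixture(scope="session")
def study_dose() -> DoseEvent:
    """20 mg IM to the cohort-mean 556.5 kg horse."""
    return DoseEvent(dose_mg=20.0, bw_kg=556.5)


@pytest.fixture(scope="session")
def paper_schedule() -> np.ndarray:
    return np.asarray(PLASMA_SCHEDULE_H, dtype=float)


@pytest.fixture()
def typical_profile(typical_params, study_dose, paper_schedule) -> ConcProfile:
    """Noise-free typical-horse profile sampled on the study schedule."""
    from isoflupk import predict_concentration

    conc = predict_concentration(typical_params, study_dose, paper_schedule)
    return ConcProfile("typical", paper_schedule, conc, loq=0.01)
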