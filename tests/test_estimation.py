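"""Two-stage estimation: individual log-scale fits and population pooling."""

import numpy as np
import pytest

from isoflupk import (
    ConcProfile,
    PKParams,
    TABLE_POP,
    compare_models,
    default_init,
    detection_time_mc,
    fit_individual,
    predict_concentration,
    two_stage_population,
)
from isoflupk.estimation import IndividualFit, fit_monoexponential
from isoflupk.synthetic import PLASMA_SCHEDULE_H, StudyConfig, gen_plasma
from isoflupk.nca import read_conc_csv


def make_profile(params, dose, times=None, noise_sd=0.0, seed=0):
    t = np.asarray(times if times is not None else PLASMA_SCHEDULE_H, float)
    c = predict_concentration(params, dose, t)
    if noise_sd:
        rng = np.random.default_rng(seed)
        c = c * np.maximum(1.0 + rng.normal(0, noise_sd, t.size), 0.0)
    return ConcProfile("sim", t, c)


class TestFitIndividual:
    def test_recovers_typicals_from_noise_free_data(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose)
        fit = fit_individual(prof, study_dose)
        assert fit.converged
        assert fit.params.ka == pytest.approx(8.34, rel=1e-4)
        assert fit.params.cl_f == pytest.approx(10.1, rel=1e-4)
        assert fit.params.v_f == pytest.approx(27.9, rel=1e-4)

    def test_truth_init_gives_zero_ssr(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose)
        fit = fit_individual(prof, study_dose, init=TABLE_POP.tv)
        assert fit.ssr_log == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose, times=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_individual(prof, study_dose)

    def test_noisy_fit_stays_close(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose, noise_sd=0.187, seed=4)
        fit = fit_individual(prof, study_dose)
        assert fit.params.cl_f == pytest.approx(10.1, rel=0.15)


class TestDefaultInit:
    def test_within_factor_three_of_truth(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose)
        init = default_init(prof, study_dose)
        for got, true in (
            (init.ka, 8.34),
            (init.cl_f, 10.1),
            (init.v_f, 27.9),
        ):
            assert true / 3.0 <= got <= true * 3.0

    def test_flat_profile_falls_back(self, study_dose):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        prof = ConcProfile("flat", t, np.full(5, 2.0))
        init = default_init(prof, study_dose)
        assert init.ka > 0 and init.cl_f > 0 and init.v_f > 0

    def test_ka_capped(self, study_dose):
        # peak at the very first sample implies a huge 1/tmax; cap at 50/h
        t = np.array([0.05, 1.0, 2.0, 4.0, 8.0])
        c = np.array([5.0, *(4.0 * np.exp(-0.5 * t[1:]))])
        init = default_init(ConcProfile("fast", t, c), study_dose)
        assert init.ka <= 50.0


class TestTwoStagePopulation:
    def test_identical_fits_give_zero_omega(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose)
        fit = fit_individual(prof, study_dose, init=TABLE_POP.tv)
        pop = two_stage_population([fit, fit])
        assert pop.omega2_cl == pytest.approx(0.0, abs=1e-12)
        assert pop.tv.cl_f == pytest.approx(fit.params.cl_f)

    def test_hand_arithmetic_two_fits(self):
        fits = []
        for lcl in (0.0, 0.2):
            fits.append(
                IndividualFit(
                    subject_id=f"s{lcl}",
                    params=PKParams(ka=1.0, cl_f=float(np.exp(lcl)), v_f=1.0),
                    ssr_log=0.0,
                    n_obs=10,
                    aic=0.0,
                    converged=True,
                )
            )
        pop = two_stage_population(fits)
        assert pop.tv.cl_f == pytest.approx(np.exp(0.1))
        assert pop.omega2_cl == pytest.approx(0.02)

    def test_needs_two_converged(self, study_dose):
        prof = make_profile(TABLE_POP.tv, study_dose)
        fit = fit_individual(prof, study_dose)
        with pytest.raises(ValueError):
            two_stage_population([fit])


class TestCompareModels:
    def test_single_candidate_first(self):
        f = IndividualFit("s", PKParams(1, 1, 1), 0.1, 10, -5.0, True)
        ranked = compare_models({"only": [f]})
        assert ranked[0][0] == "only" and not ranked[0][2]

    def test_one_compartment_wins_on_absorption_data(self, study_dose):
        # data from the 1-cmt model: the no-absorption candidate cannot
        # describe the rising phase and loses on AIC
        cfg = StudyConfig(seed=21)
        profiles = read_conc_csv_from_df(gen_plasma(cfg))
        one_cmt = [fit_individual(p, study_dose) for p in profiles]
        mono = [fit_monoexponential(p, study_dose) for p in profiles]
        ranked = compare_models({"one_compartment": one_cmt, "monoexponential": mono})
        assert ranked[0][0] == "one_compartment"
        assert ranked[0][1] < ranked[1][1]

    def test_equal_aic_flagged_tied(self):
        f1 = IndividualFit("a", PKParams(1, 1, 1), 0.1, 10, -5.0, True)
        f2 = IndividualFit("b", PKParams(1, 1, 1), 0.1, 10, -5.0, True)
        ranked = compare_models({"m1": [f1], "m2": [f2]})
        assert ranked[0][2] and ranked[1][2]


def read_conc_csv_from_df(df):
    import io as _io

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_conc_csv(buf, loq=0.01)


class TestRecoveryStudy:
    def test_parameter_recovery_median_error(self, study_dose):
        # 5-cohort spot check of the recovery study (the full 20-cohort
        # version runs in the acceptance suite)
        errs_cl = []
        for seed in range(5):
            cfg = StudyConfig(seed=seed)
            profiles = read_conc_csv_from_df(gen_plasma(cfg))
            fits = [fit_individual(p, study_dose) for p in profiles if
                    p.quantifiable.sum() >= 4]
            pop = two_stage_population(fits)
            errs_cl.append(abs(pop.tv.cl_f - 10.1) / 10.1)
        assert np.median(errs_cl) < 0.10

    def test_pipeline_closure_detection_time(self, study_dose):
        # simulate -> fit -> simulate again: the median t99 error across
        # replicate cohorts stays within 15% of the generating model (one
        # 12-horse cohort alone carries ~12% sampling noise on ke)
        from isoflupk import PopulationModel

        t99_gen = detection_time_mc(TABLE_POP, study_dose, n=1000, seed=0).crossing_times[1]
        errors = []
        for seed in range(5):
            profiles = read_conc_csv_from_df(gen_plasma(StudyConfig(seed=seed)))
            pop_fit = two_stage_population(
                [fit_individual(p, study_dose) for p in profiles]
            )
            refit_pop = PopulationModel(
                tv=pop_fit.tv,
                omega2_ka=pop_fit.omega2_ka,
                omega2_v=pop_fit.omega2_v,
                omega2_cl=pop_fit.omega2_cl,
                stdev0=pop_fit.stdev0,
            )
            t99_fit = detection_time_mc(
                refit_pop, study_dose, n=1000, seed=0
            ).crossing_times[1]
            errors.append(abs(t99_fit - t99_gen) / t99_gen)
        assert np.median(errors) < 0.15
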