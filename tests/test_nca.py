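"""Non-compartmental analysis: peak finding, terminal slope, AUC rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoflupk import (
    ConcProfile,
    auc_linuplogdown,
    derive_secondary,
    extrapolate_auc,
    find_cmax_tmax,
    fit_lambda_z,
    nca_cohort_summary,
    predict_concentration,
    run_nca,
)
from isoflupk.nca import (
    NoQuantifiableData,
    TerminalPhaseNotEstimable,
    read_conc_csv,
    write_nca_csv,
)


def profile(times, concs, **kw):
    return ConcProfile("s1", np.asarray(times, float), np.asarray(concs, float), **kw)


class TestCmaxTmax:
    def test_single_point(self):
        assert find_cmax_tmax(profile([1.0], [2.0])) == (2.0, 1.0)

    def test_tie_broken_by_earliest_time(self):
        p = profile([1, 2, 3, 4], [1.0, 5.0, 5.0, 2.0])
        assert find_cmax_tmax(p) == (5.0, 2.0)

    def test_all_blq_raises(self):
        p = profile([1, 2], [0.2, 0.3], blq_flags=[True, True])
        with pytest.raises(NoQuantifiableData):
            find_cmax_tmax(p)

    def test_matches_dense_model_peak(self, typical_params, study_dose, typical_profile):
        # the schedule point nearest the model peak carries the observed Cmax
        dense_t = np.linspace(0.01, 6, 100000)
        dense_c = predict_concentration(typical_params, study_dose, dense_t)
        t_peak = dense_t[np.argmax(dense_c)]
        cmax, tmax = find_cmax_tmax(typical_profile)
        sched = typical_profile.times
        assert tmax == sched[np.argmin(np.abs(sched - t_peak))]
        assert cmax == pytest.approx(dense_c.max(), rel=0.01)


class TestLambdaZ:
    def test_exact_monoexponential(self):
        t = np.array([0.5, 48.0, 72.0, 96.0])
        c = np.concatenate([[5.0], np.exp(-0.02 * t[1:])])
        lz, n, r2 = fit_lambda_z(profile(t, c))
        assert lz == pytest.approx(0.02, rel=1e-9)
        assert n == 3
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_schedule_recovers_ke(
        self, typical_profile, typical_params, study_dose
    ):
        ke = derive_secondary(typical_params, study_dose).ke
        lz, _, _ = fit_lambda_z(typical_profile)
        assert lz == pytest.approx(ke, rel=0.02)

    def test_rising_tail_not_estimable(self):
        p = profile([0.5, 1, 2, 3, 4], [5.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(TerminalPhaseNotEstimable):
            fit_lambda_z(p)

    def test_too_few_points(self):
        p = profile([1, 2, 3], [5.0, 3.0, 2.0])  # only 2 post-peak points
        with pytest.raises(TerminalPhaseNotEstimable):
            fit_lambda_z(p)

    def test_window_excludes_tmax(self):
        # points after tmax are log-linear; including the peak would bend the fit
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        c = np.array([10.0, 8.0 * np.exp(-0.1 * 2), *(8.0 * np.exp(-0.1 * t[2:]))])
        lz, n, _ = fit_lambda_z(profile(t, c))
        assert lz == pytest.approx(0.1, rel=1e-6)
        assert n <= 4


class TestAUC:
    def test_pure_linear(self):
        assert auc_linuplogdown(profile([0, 1, 2], [0, 1, 1])) == pytest.approx(1.5)

    def test_linear_up_log_down(self):
        # up: 0->4 trapezoid = 2; down: (4-2)/ln(4/2) = 2/ln2
        expected = 2.0 + 2.0 / np.log(2.0)
        assert auc_linuplogdown(profile([0, 1, 2], [0, 4, 2])) == pytest.approx(expected)

    def test_anchor_at_zero(self):
        # profile starting at 0.5 h is anchored at (0, 0)
        assert auc_linuplogdown(profile([0.5, 1.0], [2.0, 2.0])) == pytest.approx(
            0.5 + 1.0
        )

    def test_dense_grid_matches_closed_form(self, typical_params, study_dose):
        t = np.arange(0.0, 1200.0, 0.1)
        c = predict_concentration(typical_params, study_dose, t)
        prof = ConcProfile("dense", t, c)
        auc_inf_model = derive_secondary(typical_params, study_dose).auc_inf_model
        assert auc_linuplogdown(prof) == pytest.approx(auc_inf_model, rel=0.005)

    def test_trailing_blq_removed_does_not_change_auc(self, typical_profile):
        base = auc_linuplogdown(typical_profile)
        t = np.append(typical_profile.times, [400.0, 500.0])
        c = np.append(typical_profile.concs, [0.0, 0.0])
        flags = np.append(typical_profile.blq_flags, [True, True])
        extended = ConcProfile("ext", t, c, blq_flags=flags, loq=0.01)
        assert auc_linuplogdown(extended) == pytest.approx(base, rel=1e-12)


class TestExtrapolation:
    def test_hand_example(self):
        auc_inf, pct = extrapolate_auc(50.0, 0.2, 0.02)
        assert auc_inf == pytest.approx(60.0)
        assert pct == pytest.approx(100.0 * 10.0 / 60.0)

    def test_zero_clast(self):
        auc_inf, pct = extrapolate_auc(50.0, 0.0, 0.02)
        assert auc_inf == 50.0 and pct == 0.0

    def test_pct_extrap_decreases_with_longer_sampling(
        self, typical_params, study_dose
    ):
        pcts = []
        for t_end in (120.0, 240.0, 312.0):
            t = np.arange(0.0, t_end + 0.5, 0.5)
            c = predict_concentration(typical_params, study_dose, t)
            pcts.append(run_nca(ConcProfile("x", t, c)).pct_extrap)
        assert pcts[0] > pcts[1] > pcts[2]


class TestNCARoundTrip:
    def test_dense_noise_free_recovers_model(self, typical_params, study_dose):
        # oracle equivalence: NCA vs closed-form secondary parameters
        sec = derive_secondary(typical_params, study_dose)
        t = np.arange(0.0, 1500.0, 0.25)
        c = predict_concentration(typical_params, study_dose, t)
        res = run_nca(ConcProfile("dense", t, c))
        assert res.lambda_z == pytest.approx(sec.ke, rel=0.01)
        assert res.t_half == pytest.approx(sec.t_half, rel=0.01)
        assert res.auc_inf == pytest.approx(sec.auc_inf_model, rel=0.01)

    def test_invariants_hold_on_schedule(self, typical_profile):
        res = run_nca(typical_profile)
        assert res.auc_inf >= res.auc_last
        assert 0.0 <= res.pct_extrap < 100.0
        assert res.n_lambda_points >= 3
        assert res.lambda_z > 0


class TestCohortSummary:
    def test_three_values(self):
        results = []
        for v in (1.0, 2.0, 3.0):
            t = np.array([0.5, 1, 24, 48, 72])
            c = v * np.exp(-0.02 * t)
            c[0] = v * 0.5
            results.append(run_nca(ConcProfile(f"h{v}", t, c)))
        table = nca_cohort_summary(results).set_index("parameter")
        row = table.loc["cmax"]
        assert row["mean"] == pytest.approx(np.mean([r.cmax for r in results]))
        assert row["sd"] == pytest.approx(np.std([r.cmax for r in results], ddof=1))
        assert row["n"] == 3

    def test_single_subject_sd_zero(self, typical_profile):
        table = nca_cohort_summary([run_nca(typical_profile)])
        assert (table["sd"] == 0.0).all()
        assert (table["n"] == 1).all()


class TestCSVIO:
    def test_round_trip(self, tmp_path, typical_profile):
        import pandas as pd

        rows = []
        for t, c, b in zip(
            typical_profile.times, typical_profile.concs, typical_profile.blq_flags
        ):
            rows.append(
                {"subject_id": "typical", "time_h": t,
                 "conc_ng_ml": np.nan if b else c, "blq": b}
            )
        path = tmp_path / "conc.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        profiles = read_conc_csv(path, loq=0.01)
        assert len(profiles) == 1
        np.testing.assert_allclose(profiles[0].concs, typical_profile.concs)
        out = tmp_path / "nca.csv"
        write_nca_csv([run_nca(profiles[0])], out)
        assert out.exists() and "cmax" in out.read_text()

    def test_empty_csv_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("subject_id,time_h,conc_ng_ml,blq\n")
        with pytest.raises(ValueError):
            read_conc_csv(path)


@settings(max_examples=30, deadline=None)
@given(
    concs=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=12)
)
def test_auc_nonnegative_and_bounded_by_rectangles(concs):
    t = np.arange(1.0, len(concs) + 1.0)
    auc = auc_linuplogdown(profile(t, concs))
    upper = max(concs) * t[-1]
    assert 0.0 <= auc <= upper + 1e-9
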