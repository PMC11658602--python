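"""Non-compartmental analysis: trapezoid AUCs, phase rates, half-lives,
clearance, fold ratios and calibration quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depotkit.errors import InvalidSpec, NoDecayPhase, UndefinedPK
from depotkit.phantoms import PlasmaSimSpec, simulate_plasma
from depotkit.pk import (
    CalibrationCurve,
    PlasmaSeries,
    auto_phase_windows,
    cohort_summary,
    fit_calibration,
    fold_ratio,
    half_life,
    nca,
    phase_rates,
    quantify,
    trapezoid_auc,
)

# printed cohort means: Tmax, Cmax, AUC_adm, AUC_post, AUC_total, t1/2a, t1/2b, CL/F
GEL_AUC_ADM, GEL_AUC_POST = 252.4, 599.7
SOLN_AUC_ADM, SOLN_AUC_POST = 1338.7, 944.7


class TestTrapezoidAuc:
    def test_rectangle(self):
        s = PlasmaSeries(np.array([0.0, 30.0, 60.0]), np.array([100.0, 100.0, 100.0]), t_adm=24.0)
        assert trapezoid_auc(s, 0.0, 60.0) == pytest.approx(100.0)

    def test_triangle_rise(self):
        s = PlasmaSeries(np.array([0.0, 24.0, 60.0]), np.array([0.0, 2084.0, 0.0]), t_adm=24.0)
        assert trapezoid_auc(s, 0.0, 24.0) == pytest.approx(2084.0 * 24.0 / 2.0 / 60.0)
        assert trapezoid_auc(s, 0.0, 24.0) == pytest.approx(416.8)

    def test_interpolated_window_endpoint(self):
        s = PlasmaSeries(np.array([0.0, 10.0]), np.array([0.0, 100.0]), t_adm=5.0)
        # closed form for the sub-triangle
        assert trapezoid_auc(s, 0.0, 5.0) == pytest.approx(50.0 * 5.0 / 2.0 / 60.0)

    def test_exact_for_piecewise_linear(self):
        t = np.array([0.0, 5.0, 12.0, 40.0])
        c = np.array([0.0, 80.0, 20.0, 10.0])
        s = PlasmaSeries(t, c, t_adm=12.0)
        hand = sum((c[i] + c[i + 1]) * (t[i + 1] - t[i]) / 2 for i in range(3)) / 60.0
        assert trapezoid_auc(s, 0.0, 40.0) == pytest.approx(hand)

    def test_window_outside_span_rejected(self):
        s = PlasmaSeries(np.array([0.0, 10.0]), np.array([1.0, 1.0]), t_adm=5.0)
        with pytest.raises(InvalidSpec):
            trapezoid_auc(s, 0.0, 20.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1.0, 23.0))
    def test_additivity_over_adjacent_windows(self, split):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 24, 13)
        c = rng.uniform(0, 100, size=t.size)
        s = PlasmaSeries(t, c, t_adm=24.0)
        assert trapezoid_auc(s, 0.0, split) + trapezoid_auc(s, split, 24.0) == pytest.approx(
            trapezoid_auc(s, 0.0, 24.0)
        )


class TestPrintedCohortArithmetic:
    def test_phase_aucs_sum_to_totals(self):
        assert GEL_AUC_ADM + GEL_AUC_POST == pytest.approx(852.1)
        assert SOLN_AUC_ADM + SOLN_AUC_POST == pytest.approx(2283.4)

    def test_fold_ratios(self):
        assert fold_ratio(2283.4, 852.1) == 2.7
        assert fold_ratio(SOLN_AUC_ADM, GEL_AUC_ADM) == 5.3

    def test_apparent_clearance_at_printed_precision(self):
        assert round(40.0 / 852.1, 2) == 0.05
        assert round(40.0 / 2283.4, 2) == 0.02


class TestPhaseRates:
    def test_pure_exponential_rate_and_half_life(self):
        # log10 slope -0.0558/min -> rate 0.1285/min -> t1/2 5.39 min
        t = np.linspace(24, 64, 9)
        c = 1000.0 * 10.0 ** (-0.0558 * (t - 24.0))
        s = PlasmaSeries(t, c, t_adm=24.0)
        a, b = phase_rates(s, (24.0, 44.0), (44.0, 64.0))
        assert a == pytest.approx(0.0558 * 2.303, rel=1e-6)
        assert half_life(a) == pytest.approx(5.39, abs=0.01)

    def test_flat_series_no_decay(self):
        t = np.linspace(24, 264, 10)
        s = PlasmaSeries(t, np.full(10, 50.0), t_adm=24.0)
        with pytest.raises(NoDecayPhase):
            phase_rates(s, (24.0, 100.0), (100.0, 264.0))

    def test_stripped_recovery_on_noiseless_biexponential(self):
        series, truth = simulate_plasma(PlasmaSimSpec())
        a, b = phase_rates(series, (24.0, 44.0), (84.0, 264.0), strip=True)
        assert a == pytest.approx(truth.alpha, rel=0.01)
        assert b == pytest.approx(truth.beta, rel=0.01)

    def test_recovery_with_noise(self):
        """Window regressions on 16-sample noisy series: beta tight, alpha
        looser (the stripped residuals carry most of the noise)."""
        errs_a, errs_b = [], []
        for seed in range(50):
            series, truth = simulate_plasma(PlasmaSimSpec(noise_cv=0.05, seed=seed))
            a, b = phase_rates(series, (24.0, 44.0), (84.0, 264.0), strip=True)
            errs_a.append(abs(1 / a - 1 / truth.alpha) * truth.alpha)
            errs_b.append(abs(1 / b - 1 / truth.beta) * truth.beta)
        assert np.median(errs_b) < 0.10
        assert np.median(errs_a) < 0.20


class TestHalfLife:
    def test_ln2(self):
        assert half_life(0.693) == pytest.approx(1.0, abs=0.001)

    def test_slow_elimination_regime(self):
        assert half_life(0.00549) == pytest.approx(126.3, abs=0.2)

    def test_reciprocal_law(self):
        assert half_life(0.01) == pytest.approx(2 * half_life(0.02))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidSpec):
            half_life(0.0)


class TestNca:
    def test_simulated_series_auc_within_1pct_of_closed_form(self):
        series, truth = simulate_plasma(PlasmaSimSpec(noise_cv=0.0))
        p = nca(series, dose_mg=40.0, phase_windows=None)
        assert p.auc_total == pytest.approx(truth.auc_total, rel=0.01)

    def test_auc_additivity_identity_exact(self):
        series, _ = simulate_plasma(PlasmaSimSpec(noise_cv=0.05, seed=3))
        p = nca(series, dose_mg=40.0, phase_windows=None)
        assert p.auc_total == p.auc_administration + p.auc_post_administration

    def test_clearance_inversion_identity(self):
        series, _ = simulate_plasma(PlasmaSimSpec(noise_cv=0.05, seed=4))
        p = nca(series, dose_mg=40.0, phase_windows=None)
        assert p.cl_f * p.auc_total == pytest.approx(40.0, rel=1e-12)

    def test_doubling_concentrations_doubles_auc_halves_clearance(self):
        series, _ = simulate_plasma(PlasmaSimSpec(noise_cv=0.0))
        doubled = PlasmaSeries(series.times, 2 * series.concentrations, t_adm=series.t_adm)
        p1 = nca(series, dose_mg=40.0, phase_windows=None)
        p2 = nca(doubled, dose_mg=40.0, phase_windows=None)
        assert p2.auc_total == pytest.approx(2 * p1.auc_total)
        assert p2.cl_f == pytest.approx(p1.cl_f / 2)

    def test_tmax_earliest_on_ties(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        c = np.array([0.0, 50.0, 50.0, 10.0])
        p = nca(PlasmaSeries(t, c, t_adm=20.0), dose_mg=40.0, phase_windows=None)
        assert p.tmax_min == 10.0

    def test_all_zero_series_rejected(self):
        t = np.linspace(0, 264, 16)
        with pytest.raises(UndefinedPK):
            nca(PlasmaSeries(t, np.zeros(16)), dose_mg=40.0, phase_windows=None)

    def test_auto_windows_cover_post_administration_span(self):
        series, _ = simulate_plasma(PlasmaSimSpec())
        (a_lo, a_hi), (b_lo, b_hi) = auto_phase_windows(series)
        assert a_lo == 24.0 and b_hi == 264.0 and a_hi == b_lo


class TestCalibration:
    def test_exact_points_recovered(self):
        x = np.array([0.2, 1.0, 5.0, 20.0, 100.0])
        y = 0.04 * x + 0.01
        curve = fit_calibration(x, y)
        assert curve.r_squared == pytest.approx(1.0)
        for xi, yi in zip(x, y):
            conc, clipped = quantify(yi, curve)
            assert conc == pytest.approx(xi)
            assert not clipped

    def test_single_point_proportionality(self):
        curve = fit_calibration([10.0], [0.5], mode="single-point")
        assert quantify(0.25, curve)[0] == pytest.approx(5.0)

    def test_noisy_calibration_back_calculates_within_10pct(self):
        rng = np.random.default_rng(6)
        nominal = np.array([0.2, 0.5, 2.0, 10.0, 25.0, 50.0, 100.0])
        ratios = 0.04 * nominal * rng.normal(1.0, 0.03, size=nominal.size)
        curve = fit_calibration(nominal, ratios)
        for x, y in zip(nominal, ratios):
            assert quantify(y, curve)[0] == pytest.approx(x, rel=0.10)

    def test_negative_back_calculation_clipped(self):
        curve = CalibrationCurve(slope=0.04, intercept=0.5, r_squared=0.99)
        conc, clipped = quantify(0.1, curve)
        assert conc == 0.0 and clipped

    def test_tissue_mass_normalization(self):
        curve = fit_calibration([10.0], [0.5], mode="single-point")
        assert quantify(0.5, curve, tissue_mass_mg=25.0)[0] == pytest.approx(10.0 / 25.0)


class TestFoldRatio:
    def test_equal_inputs(self):
        assert fold_ratio(852.1, 852.1) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(InvalidSpec):
            fold_ratio(1.0, 0.0)


def test_cohort_summary_structure():
    series = [simulate_plasma(PlasmaSimSpec(noise_cv=0.05, seed=s))[0] for s in range(3)]
    params = [nca(s, dose_mg=40.0) for s in series]
    df = cohort_summary(params)
    assert set(df.columns) == {"parameter", "mean", "sd", "n"}
    assert (df.n == 3).all()
    row = df.set_index("parameter").loc["auc_total"]
    vals = [p.auc_total for p in params]
    assert row["mean"] == pytest.approx(np.mean(vals))
    assert row["sd"] == pytest.approx(np.std(vals, ddof=1))
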