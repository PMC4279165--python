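"""Two-state melts: van 't Hoff arithmetic, fit recovery, osmolyte summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chaperokin import (
    InputError,
    MeltCurve,
    NoTransitionError,
    OsmolyteSeries,
    TwoStateFit,
    TwoStateMelt,
    delta_tm,
    dtm_consistency_report,
    fit_melt,
    fraction_unfolded,
    melt_signal,
    reference_osmolyte_series,
    stabilization_trend,
)
from chaperokin.synth import gen_equilibrium_curve, gen_meltcurve


class TestFractionUnfolded:
    @settings(max_examples=50, derandomize=True)
    @given(
        tm=st.floats(min_value=30.0, max_value=80.0),
        dh=st.floats(min_value=5.0, max_value=200.0),
    )
    def test_half_unfolded_at_tm(self, tm, dh):
        assert fraction_unfolded(tm, tm, dh) == pytest.approx(0.5, abs=1e-12)

    def test_direct_evaluation(self):
        # K = exp[(45/R)(1/328.25 - 1/333.25)], R = 1.987e-3 kcal/mol/K
        assert fraction_unfolded(60.1, 55.1, 45.0) == pytest.approx(0.738, abs=1e-3)

    def test_folded_limit(self):
        assert fraction_unfolded(25.1, 55.1, 45.0) < 0.01

    def test_sharpens_with_enthalpy(self):
        """|df_u/dT| at Tm grows with the van 't Hoff enthalpy."""
        eps = 1e-4
        slopes = [
            (fraction_unfolded(55.1 + eps, 55.1, dh) - fraction_unfolded(55.1 - eps, 55.1, dh))
            / (2 * eps)
            for dh in (20.0, 45.0, 90.0)
        ]
        assert slopes[0] < slopes[1] < slopes[2]

    def test_rejects_nonpositive_enthalpy(self):
        from chaperokin import ParameterError

        with pytest.raises(ParameterError):
            fraction_unfolded(50.0, 55.0, 0.0)


class TestMeltSignal:
    FIT = TwoStateFit(tm=50.0, dh_vh=500.0, a_n=1000.0, b_n=1.0,
                      a_u=9000.0, b_u=-4.0, rss=0.0, converged=True)

    def test_baseline_limits_and_midpoint(self):
        # very sharp transition: pure baselines away from Tm
        assert melt_signal(25.0, self.FIT) == pytest.approx(1000.0 + 25.0, rel=1e-6)
        assert melt_signal(75.0, self.FIT) == pytest.approx(9000.0 - 300.0, rel=1e-6)
        mid = 0.5 * ((1000.0 + 50.0) + (9000.0 - 200.0))
        assert melt_signal(50.0, self.FIT) == pytest.approx(mid, rel=1e-9)


class TestFitMelt:
    def test_noiseless_recovery_of_all_parameters(self, d122y):
        curve = gen_meltcurve(d122y, noise_frac=0.0)
        fit = fit_melt(curve)
        assert fit.tm == pytest.approx(48.80, abs=0.05)
        assert fit.dh_vh == pytest.approx(45.0, rel=0.01)
        assert fit.a_n == pytest.approx(1000.0, rel=0.01)
        assert fit.b_n == pytest.approx(1.0, abs=0.05)
        assert fit.a_u == pytest.approx(9000.0, rel=0.01)
        assert fit.b_u == pytest.approx(-4.0, abs=0.05)

    def test_noisy_recovery_wild_type(self, wt):
        curve = gen_meltcurve(wt, noise_frac=0.01, seed=7)
        fit = fit_melt(curve)
        assert fit.tm == pytest.approx(55.1, abs=0.3)
        assert fit.converged

    def test_equilibrium_curve_with_fixed_baselines(self, wt):
        curve = gen_equilibrium_curve(wt, noise_frac=0.0)
        fit = fit_melt(curve, fix_baselines=True)
        assert fit.tm == pytest.approx(66.3, abs=0.05)
        assert (fit.a_n, fit.b_n, fit.a_u, fit.b_u) == (0.0, 0.0, 1.0, 0.0)

    def test_flat_signal_is_no_transition(self):
        temps = np.arange(25.0, 80.5, 0.5)
        with pytest.raises(NoTransitionError):
            fit_melt(MeltCurve(temps=temps, signal=np.full_like(temps, 1000.0)))

    def test_featureless_ramp_is_no_transition(self):
        temps = np.arange(25.0, 80.5, 0.5)
        rng = np.random.default_rng(0)
        signal = 1000.0 + 5.0 * temps + rng.normal(0, 5.0, temps.size)
        with pytest.raises(NoTransitionError):
            fit_melt(MeltCurve(temps=temps, signal=signal))

    def test_short_or_narrow_scans_rejected(self):
        with pytest.raises(InputError):
            fit_melt(MeltCurve(temps=np.arange(25, 30, 0.5),
                               signal=np.zeros(10)))
        temps = np.linspace(40.0, 50.0, 40)
        with pytest.raises(InputError):
            fit_melt(MeltCurve(temps=temps, signal=np.sin(temps)))

    def test_truncate_post_max_still_recovers(self, d122y):
        curve = gen_meltcurve(d122y, noise_frac=0.0)
        fit = fit_melt(curve, truncate_post_max=True)
        assert fit.tm == pytest.approx(48.8, abs=0.1)

    def test_sklearn_surface(self, d122y):
        curve = gen_meltcurve(d122y, noise_frac=0.0)
        est = TwoStateMelt().fit(curve.temps, curve.signal)
        assert est.predict(curve.temps) == pytest.approx(curve.signal, rel=1e-4)
        assert "fix_baselines" in est.get_params()


class TestDeltaTm:
    def test_published_trehalose_shifts(self):
        def as_fit(tm):
            return TwoStateFit(tm=tm, dh_vh=45.0, a_n=0, b_n=0, a_u=1, b_u=0,
                               rss=0.0, converged=True)

        control = as_fit(55.1)
        assert delta_tm(as_fit(60.2), control) == pytest.approx(5.1, abs=1e-9)
        assert delta_tm(as_fit(54.6), control) == pytest.approx(-0.5, abs=1e-9)
        assert delta_tm(control, control) == 0.0

    def test_unconverged_inputs_rejected(self):
        good = TwoStateFit(tm=55.1, dh_vh=45.0, a_n=0, b_n=0, a_u=1, b_u=0,
                           rss=0.0, converged=True)
        bad = TwoStateFit(tm=50.0, dh_vh=45.0, a_n=0, b_n=0, a_u=1, b_u=0,
                          rss=0.0, converged=False)
        with pytest.raises(InputError):
            delta_tm(bad, good)


class TestOsmolyteSeries:
    def test_dtms_computed_from_control(self):
        s = OsmolyteSeries("trehalose", concs=[0.25, 0.5, 0.75],
                           tms=[56.5, 57.8, 60.2], control_tm=55.1)
        assert s.dtms == pytest.approx([1.4, 2.7, 5.1])

    def test_exact_linear_trend(self):
        c = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        s = OsmolyteSeries("tmao", concs=c, tms=50.0 + 6.0 * c, control_tm=50.0)
        trend = stabilization_trend(s)
        assert trend.slope == pytest.approx(6.00, abs=1e-10)
        assert trend.sign == "stabilizing"

    def test_constant_series_is_neutral(self):
        s = OsmolyteSeries("tmao", concs=[0.1, 0.2, 0.3],
                           tms=[50.0, 50.0, 50.0], control_tm=50.0)
        trend = stabilization_trend(s)
        assert trend.slope == 0.0
        assert trend.sign == "neutral"

    def test_reference_wild_type_trehalose_is_stabilizing(self):
        series = reference_osmolyte_series("WT", "trehalose")
        assert stabilization_trend(series).slope > 0

    def test_consistency_report_surfaces_discrepancies(self):
        """The published ΔTm column disagrees with Tm − control for several
        rows (notably D122Y trehalose and low-concentration WT TMAO); the
        report flags them without altering the Tm values."""
        report = dtm_consistency_report()
        wt_trehalose = report.query("variant == 'WT' and osmolyte == 'trehalose'")
        assert wt_trehalose["consistent"].all()
        d122y_trehalose = report.query("variant == 'D122Y' and osmolyte == 'trehalose'")
        assert not d122y_trehalose["consistent"].any()
        # the inconsistent D122Y shifts all point at a common ~46.2 °C reference
        implied = d122y_trehalose["tm_c"] - d122y_trehalose["dtm_printed"]
        assert implied.std() < 0.1
        assert implied.mean() == pytest.approx(46.2, abs=0.1)
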