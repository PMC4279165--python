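"""Synthetic generators: determinism, zero-noise identities, calibration."""

import numpy as np
import pytest

from chaperokin import (
    ExperimentCondition,
    InputError,
    fit_melt,
    fraction_soluble,
    preset,
    simulate_capture,
)
from chaperokin.synth import (
    DEFAULT_EL_CONCS,
    gen_densitometry,
    gen_equilibrium_curve,
    gen_meltcurve,
    gen_spectrum,
    gen_timecourse,
)


class TestPresets:
    def test_dsf_and_equilibrium_melting_temperatures(self):
        assert preset("WT").tm_dsf == 55.1
        assert preset("D122Y").tm_dsf == 48.8
        assert preset("I154F").tm_dsf == 39.1
        assert preset("WT").tm_equilibrium == 66.3
        assert preset("D122Y").tm_equilibrium == 50.4
        assert preset("I154F").tm_equilibrium == 50.7

    def test_capture_rate_constants(self):
        assert preset("I154F").capture.k_u == 0.030
        assert preset("D122Y").capture.k_agg == 0.005

    def test_unknown_variant(self):
        with pytest.raises(InputError):
            preset("T119M")

    def test_wild_type_barely_partitions(self):
        """Kinetically stable control: <2% soluble loss over 60 min at any
        tested chaperonin concentration."""
        v = preset("WT")
        for el in DEFAULT_EL_CONCS:
            traj = simulate_capture(
                v.capture, ExperimentCondition(el, 2.0), np.linspace(0, 60, 61)
            )
            assert traj.soluble_frac[-1] > 0.98

    def test_endpoint_calibration(self):
        """Variant presets reproduce the 60 min partitioning endpoints at
        3 µM chaperonin: ~25% (I154F) and ~55% (D122Y) soluble."""
        grid = np.linspace(0, 60, 61)
        for name, target in [("I154F", 0.25), ("D122Y", 0.55)]:
            traj = simulate_capture(
                preset(name).capture, ExperimentCondition(3.0, 2.0), grid
            )
            assert traj.soluble_frac[-1] == pytest.approx(target, abs=0.01)


class TestTimecourse:
    COND = ExperimentCondition(3.0, 2.0)

    def test_zero_noise_matches_simulation(self, i154f):
        tc = gen_timecourse(i154f, self.COND, noise_sd=0.0)
        traj = simulate_capture(i154f.capture, self.COND, tc.times)
        assert tc.soluble_frac == pytest.approx(traj.soluble_frac, abs=1e-12)

    def test_seed_determinism(self, i154f):
        a = gen_timecourse(i154f, self.COND, seed=5)
        b = gen_timecourse(i154f, self.COND, seed=5)
        c = gen_timecourse(i154f, self.COND, seed=6)
        assert np.array_equal(a.soluble_frac, b.soluble_frac)
        assert not np.array_equal(a.soluble_frac, c.soluble_frac)

    def test_no_chaperonin_control_still_declines(self, i154f):
        """Without chaperonin the aggregation channel alone depletes the
        soluble pool of the aggregation-prone variant."""
        tc = gen_timecourse(i154f, ExperimentCondition(0.0, 2.0), noise_sd=0.0)
        assert tc.soluble_frac[-1] < 0.99
        assert np.all(np.diff(tc.soluble_frac) <= 0)

    def test_aggregate_escape_raises_apparent_solubility(self, i154f):
        cond = ExperimentCondition(0.0, 2.0)
        full_spin = gen_timecourse(i154f, cond, noise_sd=0.0)
        escape = gen_timecourse(i154f, cond, noise_sd=0.0, aggregate_escape_frac=0.5)
        assert escape.soluble_frac[-1] > full_spin.soluble_frac[-1]


class TestMeltCurves:
    def test_zero_noise_roundtrip_identity(self, d122y):
        fit = fit_melt(gen_meltcurve(d122y, noise_frac=0.0))
        assert fit.tm == pytest.approx(48.80, abs=0.05)

    def test_seeds_differ(self, wt):
        a = gen_meltcurve(wt, seed=1)
        b = gen_meltcurve(wt, seed=2)
        assert not np.array_equal(a.signal, b.signal)

    def test_equilibrium_curve_is_fraction_unfolded(self, wt):
        curve = gen_equilibrium_curve(wt, noise_frac=0.0)
        assert curve.signal[0] < 0.01 and curve.signal[-1] > 0.95
        mid = np.interp(wt.tm_equilibrium, curve.temps, curve.signal)
        assert mid == pytest.approx(0.5, abs=0.01)


class TestSpectra:
    def test_no_scatter_means_clean_350(self):
        spec = gen_spectrum(0.30, scatter_a350=0.0)
        assert spec.at(350.0) == pytest.approx(0.0, abs=1e-4)
        from chaperokin import baseline_corrected_a280

        assert baseline_corrected_a280(spec) == pytest.approx(0.30, abs=1e-3)

    def test_scatter_sets_a350(self):
        from chaperokin import aggregation_index

        t0 = gen_spectrum(0.30, scatter_a350=0.0)
        t60 = gen_spectrum(0.30, scatter_a350=0.05)
        assert aggregation_index(t60, t0) == pytest.approx(0.050, abs=1e-6)


class TestDensitometry:
    def test_zero_cv_is_exact(self):
        records = gen_densitometry(0.37, cv=0.0, seed=1)
        assert all(fraction_soluble(r) == pytest.approx(0.37) for r in records)
        assert len(records) == 3

    def test_seeded_reproducibility(self):
        a = gen_densitometry(0.5, seed=9)
        b = gen_densitometry(0.5, seed=9)
        assert [(r.s_band, r.p_band) for r in a] == [(r.s_band, r.p_band) for r in b]

    def test_law_of_large_numbers(self):
        records = gen_densitometry(0.5, n_replicates=3000, cv=0.1, seed=2)
        mean = np.mean([fraction_soluble(r) for r in records])
        assert mean == pytest.approx(0.5, abs=0.01)

    def test_bad_fraction_rejected(self):
        from chaperokin import ParameterError

        with pytest.raises(ParameterError):
            gen_densitometry(1.2)
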