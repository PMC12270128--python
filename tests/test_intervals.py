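"""Interval dynamics: ISIs, bursts, CCDs, grid-search fits, POI, burstiness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microtunnel as mt
from microtunnel.intervals import FitError, intersection_time


def exact_line_ccd(m, c=0.0, t_lo=0.01, t_hi=1.0, n_bins=50):
    """Noise-free CCD lying exactly on log10 P = m log10 t + c (normalized)."""
    t = np.logspace(np.log10(t_lo), np.log10(t_hi), n_bins)
    p = 10.0 ** (m * np.log10(t) + c)
    p = p / p[0]
    return mt.CCD(t=t, p=p, n_intervals=10_000)


class TestIntervalsAndBursts:
    def test_consecutive_differences(self):
        assert np.allclose(mt.compute_intervals([0.0, 0.1, 0.3]), [0.1, 0.2])

    def test_single_spike_no_intervals(self):
        assert mt.compute_intervals([1.0]).size == 0

    def test_periodic_train_constant_intervals(self):
        train = np.arange(50) * 0.02
        assert np.allclose(mt.compute_intervals(train), 0.02)

    def test_eight_fast_spikes_form_one_burst(self):
        train = np.arange(8) * 0.01
        bursts, flags = mt.detect_bursts(train)
        assert len(bursts) == 1 and bursts[0].n_spikes == 8 and flags.all()

    def test_three_fast_spikes_no_burst(self):
        bursts, flags = mt.detect_bursts(np.arange(3) * 0.01)
        assert bursts == [] and not flags.any()

    def test_exactly_50ms_spacing_is_not_a_burst(self):
        """The burst criterion is strict: ISIs must be < 50 ms, not <=."""
        bursts, _ = mt.detect_bursts(np.arange(5) * 0.05)
        assert bursts == []

    def test_mixed_train_burstiness_half(self):
        """4 spikes at 10 ms then 4 at 100 ms: one burst of 4, burstiness 0.5."""
        train = np.concatenate([np.arange(4) * 0.01, 0.2 + np.arange(4) * 0.1])
        bursts, flags = mt.detect_bursts(train)
        assert len(bursts) == 1 and bursts[0].n_spikes == 4
        assert flags.sum() == 4
        assert mt.burstiness(train) == 0.5

    def test_ibi_end_to_start(self):
        train = np.concatenate([np.arange(4) * 0.01, 1.5 + np.arange(4) * 0.01])
        bursts, _ = mt.detect_bursts(train)
        ibis = mt.compute_ibi(train, bursts)
        assert np.allclose(ibis, [1.5 - 0.03])

    def test_ibi_onset_to_onset_mode(self):
        train = np.concatenate([np.arange(4) * 0.01, 1.5 + np.arange(4) * 0.01])
        bursts, _ = mt.detect_bursts(train)
        assert np.allclose(mt.compute_ibi(train, bursts, mode="onset_to_onset"), [1.5])

    def test_single_burst_no_ibi(self):
        train = np.arange(6) * 0.01
        bursts, _ = mt.detect_bursts(train)
        assert mt.compute_ibi(train, bursts).size == 0

    def test_burstiness_extremes(self):
        assert mt.burstiness(np.arange(10) * 0.01) == 1.0
        assert mt.burstiness(np.arange(10) * 0.1) == 0.0
        assert mt.burstiness(np.empty(0)) == 0.0

    def test_fr_burst_counts_per_array(self):
        vals = [0.9, 0.6, 0.4, 0.2]
        assert mt.fr_burst(vals, n_arrays=2) == 1.0  # 2 units above 0.5, 2 arrays


class TestCCD:
    def test_constant_intervals_step_function(self):
        ccd = mt.build_ccd(np.full(100, 0.05), t_range=(0.01, 0.1))
        assert np.all(ccd.p[ccd.t <= 0.05] == 1.0)
        assert np.all(ccd.p[ccd.t > 0.05] == 0.0)

    def test_monotone_and_normalized(self, rng):
        x = rng.uniform(0.01, 1.0, 500)
        ccd = mt.build_ccd(x)
        assert ccd.p[0] == 1.0
        assert np.all(np.diff(ccd.p) <= 0)
        assert np.all((ccd.p >= 0) & (ccd.p <= 1))

    def test_doubling_intervals_shifts_ccd_exactly(self, rng):
        x = rng.uniform(0.01, 1.0, 300)
        c1 = mt.build_ccd(x)
        c2 = mt.build_ccd(2 * x)
        assert np.allclose(np.log10(c2.t) - np.log10(c1.t), np.log10(2))
        assert np.array_equal(c1.p, c2.p)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            mt.build_ccd([0.1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ccd_invariants_hold_for_power_law_samples(self, seed):
        x = mt.sample_loglog_intervals(-1.2, 0.01, 0.5, 200, seed=seed)
        ccd = mt.build_ccd(x)
        assert ccd.p[0] == 1.0
        assert np.all(np.diff(ccd.p) <= 1e-12)


class TestFitLoglog:
    def test_exact_line_recovered_with_full_window(self):
        ccd = exact_line_ccd(-1.5)
        fit = mt.fit_loglog(ccd, nominal_t_range=(0.01, 1.0), prob_range=None)
        assert fit.m == pytest.approx(-1.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        # ties in R² break toward the widest window: the full nominal range
        assert fit.t_range[0] <= 0.01 * 0.5 + 1e-12 or fit.t_range[0] <= 0.01
        assert fit.n_bins >= 50 * 0.6

    def test_probability_range_restricts_bins(self):
        """Only bins with 0.1 <= P <= 1 enter the ISI fit."""
        ccd = exact_line_ccd(-1.0, t_lo=0.01, t_hi=10.0)
        fit = mt.fit_loglog(ccd, nominal_t_range=(0.01, 10.0), prob_range=(1.0, 0.1))
        # for P = (t/0.01)^-1, P >= 0.1 means t <= 0.1: a 3-decade CCD keeps 1 decade
        in_window = (ccd.t >= fit.t_range[0]) & (ccd.t <= fit.t_range[1])
        used_p = ccd.p[in_window & (ccd.p >= 0.1 - 1e-12) & (ccd.p <= 1 + 1e-12)]
        assert used_p.size == fit.n_bins
        assert fit.m == pytest.approx(-1.0, abs=1e-9)

    def test_slope_recovery_at_n_1e4(self):
        x = mt.sample_loglog_intervals(-1.5, 0.01, 0.2, 10_000, seed=13)
        fit = mt.fit_loglog(mt.build_ccd(x), nominal_t_range=(0.01, 0.2))
        assert abs(fit.m + 1.5) <= 0.1

    def test_scale_equivariance_of_slope(self):
        ccd1 = exact_line_ccd(-1.3, t_lo=0.01, t_hi=1.0)
        ccd2 = exact_line_ccd(-1.3, t_lo=0.05, t_hi=5.0)
        f1 = mt.fit_loglog(ccd1, prob_range=None)
        f2 = mt.fit_loglog(ccd2, prob_range=None)
        assert f1.m == pytest.approx(f2.m, abs=1e-9)

    def test_fit_failure_signal(self):
        ccd = exact_line_ccd(-1.0, n_bins=12)
        with pytest.raises(FitError):
            mt.fit_loglog(ccd, nominal_t_range=(1e-6, 2e-6))

    def test_five_tunnel_isi_window_presets(self):
        assert mt.intervals.DEFAULT_ISI_WINDOW == (0.01, 0.2)
        w = mt.intervals.ISI_FIT_WINDOWS_FIVE_TUNNEL
        assert w[(("CA1", "EC"), "feed_forward")] == (0.01, 0.11)
        assert w[(("CA1", "EC"), "feedback")] == (0.01, 0.09)


class TestPiecewise:
    def test_analytic_intersection_at_ten_seconds(self):
        """Lines m=-2,c=0 and m=-0.5,c=-1.5 cross at log10 t = 1, i.e. t = 10 s."""
        fast = mt.LinearFit(m=-2.0, c=0.0, r_squared=1.0, t_range=(0.1, 10),
                            prob_range=None, n_bins=10)
        slow = mt.LinearFit(m=-0.5, c=-1.5, r_squared=1.0, t_range=(10, 100),
                            prob_range=None, n_bins=10)
        poi, stable = intersection_time(fast, slow)
        assert poi == pytest.approx(10.0)
        assert stable

    def test_parallel_lines_poi_undefined(self):
        f = mt.LinearFit(m=-1.0, c=0.0, r_squared=1.0, t_range=(0.1, 1),
                         prob_range=None, n_bins=5)
        s = mt.LinearFit(m=-1.0, c=-0.5, r_squared=1.0, t_range=(1, 10),
                         prob_range=None, n_bins=5)
        poi, stable = intersection_time(f, s)
        assert np.isnan(poi) and not stable

    def test_exact_broken_power_law_recovered(self):
        t = np.logspace(np.log10(0.2), np.log10(20.0), 60)
        tx = 1.0
        p = np.where(t <= tx, (t / 0.2) ** -2.0,
                     (tx / 0.2) ** -2.0 * (t / tx) ** -0.5)
        p = p / p[0]
        ccd = mt.CCD(t=t, p=p, n_intervals=10_000)
        pw = mt.fit_piecewise(ccd, boundary_nominal=tx)
        assert pw.fast.m == pytest.approx(-2.0, abs=1e-6)
        assert pw.slow.m == pytest.approx(-0.5, abs=1e-6)
        assert pw.poi == pytest.approx(tx, rel=1e-6)
        assert pw.poi_stable

    def test_single_regime_degenerate_input_flagged_unstable(self):
        """A pure power law yields equal slopes and an unstable POI."""
        t = np.logspace(np.log10(0.1), np.log10(10.0), 50)
        p = (t / 0.1) ** -1.2
        p = p / p[0]
        ccd = mt.CCD(t=t, p=p, n_intervals=5_000)
        pw = mt.fit_piecewise(ccd)
        assert pw.fast.m == pytest.approx(pw.slow.m, abs=1e-9)
        assert not pw.poi_stable

    def test_two_regime_sampled_recovery(self):
        """Both regime slopes and the crossover survive sampling noise."""
        from microtunnel.synthetic import two_regime_crossover

        fast = mt.IntervalLaw(-1.5, 0.2, 2.0)
        slow = mt.IntervalLaw(-0.6, 2.0, 30.0)
        w = 0.75
        tx = two_regime_crossover(fast, w)
        x = mt.sample_two_regime_intervals(fast, slow, 5000, mixture_weight=w, seed=14)
        pw = mt.fit_piecewise(mt.build_ccd(x), boundary_nominal=tx)
        assert abs(pw.fast.m - fast.m) <= 0.15 * abs(fast.m)
        assert abs(pw.slow.m - slow.m) <= 0.15 * abs(slow.m)
        assert max(pw.poi / tx, tx / pw.poi) <= 1.5
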