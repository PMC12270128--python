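"""Ground-truth generator: interval laws, burst trains, tunnel pairs, rendering."""

import numpy as np
import pytest
from scipy import stats

import microtunnel as mt
from microtunnel.synthetic import (
    loglog_interval_cdf,
    sample_two_regime_intervals,
    truncated_pareto_cdf,
    two_regime_crossover,
)


class TestIntervalSampling:
    def test_degenerate_zero_width_support_returns_constant(self):
        x = mt.sample_loglog_intervals(-1.0, 0.01, 0.01, 25, seed=0)
        assert np.all(x == 0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(m=0.5), dict(m=0.0), dict(t_min=-0.01), dict(t_min=0.2, t_max=0.01),
         dict(n=0)],
    )
    def test_parameter_errors(self, kwargs):
        full = dict(m=-1.0, t_min=0.01, t_max=0.2, n=10)
        full.update(kwargs)
        with pytest.raises(ValueError):
            mt.sample_loglog_intervals(**full)

    def test_same_seed_identical(self):
        a = mt.sample_loglog_intervals(-1.5, 0.01, 0.2, 1000, seed=7)
        b = mt.sample_loglog_intervals(-1.5, 0.01, 0.2, 1000, seed=7)
        assert np.array_equal(a, b)

    def test_samples_within_support(self):
        x = mt.sample_loglog_intervals(-1.5, 0.01, 0.2, 5000, seed=1)
        assert x.min() >= 0.01 and x.max() <= 0.2

    def test_fitted_ccd_slope_recovers_generating_exponent(self):
        x = mt.sample_loglog_intervals(-1.5, 0.01, 0.2, 100_000, seed=3)
        fit = mt.fit_loglog(mt.build_ccd(x), nominal_t_range=(0.01, 0.2))
        assert abs(fit.m + 1.5) <= 0.05

    def test_ks_against_truncated_pareto_cdf(self):
        """The sampler matches its nominal law at n=1e4 (alpha 0.01).

        The continuous ("pareto") variant is tested directly; the default
        atom-truncated law, conditioned below t_max, is by construction the
        same truncated Pareto, so the conditional sample is tested against
        the same CDF, plus a binomial check on the atom mass.
        """
        m, lo, hi, n = -1.5, 0.01, 0.2, 10_000
        x = mt.sample_loglog_intervals(m, lo, hi, n, seed=11, truncation="pareto")
        res = stats.kstest(x, lambda t: truncated_pareto_cdf(t, m, lo, hi))
        assert res.pvalue > 0.01

        y = mt.sample_loglog_intervals(m, lo, hi, n, seed=11)
        cont = y[y < hi]
        res2 = stats.kstest(cont, lambda t: truncated_pareto_cdf(t, m, lo, hi))
        assert res2.pvalue > 0.01
        atom = (hi / lo) ** m
        assert stats.binomtest(int(n - cont.size), n, atom).pvalue > 0.01

    def test_atom_law_cdf_matches_empirical(self):
        x = mt.sample_loglog_intervals(-0.5, 0.01, 0.2, 10_000, seed=2)
        t = np.logspace(-2, np.log10(0.2), 30)
        emp = np.array([(x <= ti).mean() for ti in t])  # right-continuous CDF
        assert np.max(np.abs(emp - loglog_interval_cdf(t, -0.5, 0.01, 0.2))) < 0.02
        # the tail atom carries its nominal mass, exactly at t_max
        assert abs((x == 0.2).mean() - (0.2 / 0.01) ** -0.5) < 0.02


class TestBurstTrain:
    def test_single_burst_span(self):
        bp = mt.BurstParams(spikes_per_burst=4, intra_burst_isi=0.01)
        train = mt.generate_burst_train(bp, duration=0.1, seed=0)
        assert train.size == 4
        assert np.isclose(train[-1] - train[0], 0.03)

    def test_all_spikes_in_bursts_gives_unit_burstiness(self):
        bp = mt.BurstParams(spikes_per_burst=5, intra_burst_isi=0.01)
        train = mt.generate_burst_train(bp, duration=200.0, seed=1)
        bursts, flags = mt.detect_bursts(train)
        assert len(bursts) >= 10
        assert flags.all()
        assert mt.burstiness(train) == 1.0

    def test_generated_bursts_detected_with_defaults_and_gaps_wide(self):
        bp = mt.BurstParams()
        train = mt.generate_burst_train(bp, duration=500.0, seed=2)
        bursts, _ = mt.detect_bursts(train)
        sizes = {b.n_spikes for b in bursts}
        assert sizes == {bp.spikes_per_burst}
        ibis = mt.compute_ibi(train, bursts)
        assert ibis.min() >= 0.05

    def test_too_short_duration_warns_and_returns_empty(self):
        bp = mt.BurstParams(spikes_per_burst=5, intra_burst_isi=0.01)
        with pytest.warns(UserWarning):
            train = mt.generate_burst_train(bp, duration=0.02, seed=0)
        assert train.size == 0

    def test_two_regime_recovery_from_mixture(self):
        """A 70/30 fast/slow gap law is recovered by the two-piece CCD fit."""
        fast = mt.IntervalLaw(-2.0, 0.2, 2.0)
        slow = mt.IntervalLaw(-0.5, 2.0, 20.0)
        tx = two_regime_crossover(fast, 0.7)
        x = sample_two_regime_intervals(fast, slow, 1000, mixture_weight=0.7, seed=3)
        pw = mt.fit_piecewise(mt.build_ccd(x), boundary_nominal=tx)
        assert abs(pw.fast.m - fast.m) <= 0.15 * abs(fast.m)
        assert abs(pw.slow.m - slow.m) <= 0.15 * abs(slow.m)
        assert max(pw.poi / tx, tx / pw.poi) <= 1.5

    def test_invalid_burst_params_rejected(self):
        with pytest.raises(ValueError):
            mt.BurstParams(spikes_per_burst=3)
        with pytest.raises(ValueError):
            mt.BurstParams(intra_burst_isi=0.06)


class TestTunnelPair:
    def test_lossless_noiseless_pair_is_exact_shift(self):
        axon = mt.GroundTruthAxon(axon_id="a", region_pair=("EC", "DG"),
                                  direction="feed_forward", conduction_delay=0.0004,
                                  detect_prob=1.0, jitter_sd=0.0)
        up, down = mt.generate_tunnel_pair(axon, duration=30.0, noise_rate=0.0, seed=5)
        assert up.size == down.size > 50
        assert np.allclose(down - up, 0.0004)

    def test_feedback_axon_shifts_downstream_earlier(self):
        axon = mt.GroundTruthAxon(axon_id="a", region_pair=("EC", "DG"),
                                  direction="feedback", conduction_delay=0.0004,
                                  detect_prob=1.0, jitter_sd=0.0)
        up, down = mt.generate_tunnel_pair(axon, duration=30.0, seed=5)
        assert np.allclose(down - up, -0.0004)

    def test_full_detection_gives_unit_nmi(self):
        axon = mt.GroundTruthAxon(axon_id="a", region_pair=("EC", "DG"),
                                  direction="feed_forward", conduction_delay=0.0004,
                                  detect_prob=1.0, jitter_sd=0.0)
        up, down = mt.generate_tunnel_pair(axon, duration=10.0, seed=6)
        pairing = mt.match_spike_pairs(up, down)
        assert mt.compute_nmi(pairing) == 1.0

    def test_one_sided_dropout_nmi_matches_binomial_expectation(self):
        """Dropping half the downstream spikes halves the NMI (±binomial error)."""
        axon = mt.GroundTruthAxon(axon_id="a", region_pair=("EC", "DG"),
                                  direction="feed_forward", conduction_delay=0.0004,
                                  detect_prob=(1.0, 0.5), jitter_sd=0.0)
        base = np.arange(200) * 0.05 + 0.01
        up, down = mt.generate_tunnel_pair(axon, duration=10.5, seed=7, base_train=base)
        assert up.size == 200
        pairing = mt.match_spike_pairs(up, down)
        nmi = mt.compute_nmi(pairing)
        assert pairing.n_pairs == down.size  # every surviving copy pairs
        # 3-sigma binomial band around 0.5
        assert abs(nmi - 0.5) <= 3 * np.sqrt(0.25 / 200)

    def test_same_seed_identical_pair(self, valid_ff_axon):
        a = mt.generate_tunnel_pair(valid_ff_axon, 20.0, noise_rate=0.5, seed=9)
        b = mt.generate_tunnel_pair(valid_ff_axon, 20.0, noise_rate=0.5, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_spike_times_inside_recording(self, valid_ff_axon):
        up, down = mt.generate_tunnel_pair(valid_ff_axon, 15.0, noise_rate=2.0, seed=8)
        for train in (up, down):
            assert np.all((train >= 0) & (train < 15.0))
            assert np.all(np.diff(train) > 0)


class TestRenderVoltage:
    def test_pure_noise_sd_estimate_within_5pct(self):
        trace = mt.render_voltage_trace([], noise_sd=2e-5, duration=5.0, seed=10)
        assert abs(mt.estimate_noise_sd(trace) - 2e-5) / 2e-5 < 0.05

    def test_single_spike_detected_once_at_right_time(self):
        trace = mt.render_voltage_trace([0.1], amplitude=10.0, noise_sd=1e-5,
                                        duration=0.25, seed=11)
        spikes = mt.detect_spikes(trace)
        assert len(spikes) == 1
        assert abs(spikes[0].time - 0.1) <= 1 / trace.sampling_rate
        assert 5 <= abs(spikes[0].peak_amplitude) <= 50

    def test_overlapping_pair_flagged_complex(self):
        trace = mt.render_voltage_trace([0.1, 0.1005], amplitude=10.0, noise_sd=1e-5,
                                        duration=0.25, seed=12)
        spikes = mt.detect_spikes(trace)
        assert any(s.complex_overlap for s in spikes)


class TestDataset:
    def test_regeneration_is_bitwise_identical(self, five_tunnel_dataset):
        layout, ds = five_tunnel_dataset
        ds2 = mt.generate_dataset(layout, duration=60.0, seed=4)
        assert set(ds.spike_trains) == set(ds2.spike_trains)
        for e in ds.spike_trains:
            assert np.array_equal(ds.spike_trains[e], ds2.spike_trains[e])

    def test_trains_sorted_and_in_range(self, five_tunnel_dataset):
        _, ds = five_tunnel_dataset
        for train in ds.spike_trains.values():
            assert np.all(np.diff(train) > 0)
            if train.size:
                assert train[0] >= 0 and train[-1] < ds.duration

    def test_ground_truth_delays_in_valid_window(self, five_tunnel_dataset):
        _, ds = five_tunnel_dataset
        assert all(ax.has_valid_delay for ax in ds.ground_truth)
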