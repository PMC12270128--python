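"""Self-contained validation experiments on ground-truth synthetic data.

Each experiment regenerates its inputs from a seed, runs the relevant part of
the analysis pipeline, and measures recovery of the known ground truth:
matching optimality, direction/delay recovery on synthetic tunnels, power-law
slope recovery through the grid-search CCD fit, two-regime IBI recovery,
detection performance on rendered traces, and the statistical-test oracles.
They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import intervals, io, pipeline
from .detection import cluster_spikes, detect_spikes
from .directionality import match_spike_pairs, run_tunnel
from .groupstats import ancova_slopes
from .synthetic import (
    BurstParams,
    GroundTruthAxon,
    IntervalLaw,
    generate_burst_train,
    generate_dataset,
    generate_tunnel_pair,
    render_voltage_trace,
    sample_loglog_intervals,
)

__all__ = [
    "dp_max_matching",
    "matching_oracle_agreement",
    "direction_recovery",
    "slope_recovery",
    "piecewise_recovery",
    "detection_performance",
    "ancova_oracle_error",
    "ancova_null_type1",
    "pipeline_determinism",
]


def dp_max_matching(a, b, window: float) -> int:
    """Exhaustive-equivalent maximum one-to-one matching size (independent oracle).

    Dynamic program over the two sorted trains: for points on a line with a
    window constraint there is always a non-crossing maximum matching
    (exchange argument), so ``f[i, j] = max(f[i+1, j], f[i, j+1],
    f[i+1, j+1] + [|a_i - b_j| <= w])`` enumerates the optimum exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    f = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            best = max(f[i + 1, j], f[i, j + 1])
            if abs(a[i] - b[j]) <= window:
                best = max(best, 1 + f[i + 1, j + 1])
            f[i, j] = best
    return int(f[0, 0])


def matching_oracle_agreement(n_instances: int = 500, max_spikes: int = 50,
                              window: float = 0.001, seed: int = 0) -> dict:
    """Pair counts of the matcher vs the DP oracle on dense random instances.

    Instances draw up to ``max_spikes`` spikes per train uniformly over a
    50 ms stretch, far denser than physiological tunnel traffic, so that
    many spikes compete for partners within the window — the adversarial
    regime for one-to-one matching.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        na, nb = rng.integers(0, max_spikes + 1, 2)
        a = np.sort(rng.uniform(0.0, 0.05, na))
        b = np.sort(rng.uniform(0.0, 0.05, nb))
        got = match_spike_pairs(a, b, window).n_pairs
        if got == dp_max_matching(a, b, window):
            agree += 1
    return {"n_instances": n_instances, "n_agree": agree,
            "agreement_pct": 100.0 * agree / n_instances}


def direction_recovery(n_tunnels: int = 200, n_spikes: int = 300, seed: int = 0,
                       jitter_sd: float = 5e-5, detect_prob: float = 0.9,
                       noise_rate: float = 0.5) -> dict:
    """FF/FB classification and delay accuracy over seeded synthetic tunnels.

    Each tunnel gets one axon with conduction delay uniform in the valid
    0.2-1 ms magnitude window, random direction, ``n_spikes`` upstream
    spikes, per-electrode dropout, timing jitter, and Poisson noise spikes.
    """
    rng = np.random.default_rng(seed)
    correct = 0
    errors = []
    for k in range(n_tunnels):
        direction = "feed_forward" if rng.random() < 0.5 else "feedback"
        axon = GroundTruthAxon(
            axon_id=f"ax{k}", region_pair=("EC", "DG"), direction=direction,
            conduction_delay=float(rng.uniform(2e-4, 1e-3)),
            detect_prob=detect_prob, jitter_sd=jitter_sd,
        )
        base = np.cumsum(sample_loglog_intervals(-1.5, 0.01, 0.2, n_spikes, rng=rng))
        duration = float(base[-1]) + 0.05
        up, down = generate_tunnel_pair(axon, duration, noise_rate=noise_rate,
                                        rng=rng, base_train=base)
        res = run_tunnel(up, down, region_pair=("EC", "DG"))
        if res.valid and res.direction == direction:
            correct += 1
            errors.append(abs(res.delay - axon.signed_delay))
    return {
        "n_tunnels": n_tunnels,
        "pct_correct": 100.0 * correct / n_tunnels,
        "median_delay_error_ms": float(np.median(errors)) * 1e3 if errors else float("nan"),
    }


def slope_recovery(ms=(-0.5, -1.0, -1.5, -2.0), n: int = 10_000,
                   t_min: float = 0.01, t_max: float = 0.2, seed: int = 0) -> dict:
    """Grid-search CCD fit bias for power-law interval samples, per true slope."""
    rng = np.random.default_rng(seed)
    bias_pct = {}
    for m in ms:
        x = sample_loglog_intervals(m, t_min, t_max, n, rng=rng)
        fit = intervals.fit_loglog(intervals.build_ccd(x), nominal_t_range=(t_min, t_max))
        bias_pct[m] = 100.0 * (fit.m - m) / abs(m)
    return {
        "n": n,
        "bias_pct": bias_pct,
        "max_abs_bias_pct": max(abs(v) for v in bias_pct.values()),
    }


def piecewise_recovery(n_bursts: int = 1000, seed: int = 0) -> dict:
    """Two-regime IBI recovery end to end: bursts -> IBIs -> piecewise fit.

    A bursty unit with fast-regime slope -2, slow-regime slope -0.5 and 70%
    fast gaps is generated; the recovered slopes are compared to the
    construction and the fitted POI to the construction crossover.
    """
    bp = BurstParams(
        spikes_per_burst=5, intra_burst_isi=0.01,
        ibi_fast_law=IntervalLaw(-2.0, 0.2, 2.0),
        ibi_slow_law=IntervalLaw(-0.5, 2.0, 20.0),
        mixture_weight=0.7,
    )
    rng = np.random.default_rng(seed)
    span = (bp.spikes_per_burst - 1) * bp.intra_burst_isi
    from .synthetic import sample_two_regime_intervals

    mean_gap = float(np.mean(sample_two_regime_intervals(
        bp.ibi_fast_law, bp.ibi_slow_law, 2000, mixture_weight=bp.mixture_weight, rng=rng)))
    duration = (mean_gap + span) * (n_bursts + 5)
    train = generate_burst_train(bp, duration, rng=rng)
    bursts, _ = intervals.detect_bursts(train)
    ibis = intervals.compute_ibi(train, bursts)
    pw = intervals.fit_piecewise(intervals.build_ccd(ibis), boundary_nominal=bp.crossover)
    return {
        "n_bursts": len(bursts),
        "fast_slope": pw.fast.m,
        "slow_slope": pw.slow.m,
        "fast_error_pct": 100.0 * (pw.fast.m - bp.ibi_fast_law.m) / abs(bp.ibi_fast_law.m),
        "slow_error_pct": 100.0 * (pw.slow.m - bp.ibi_slow_law.m) / abs(bp.ibi_slow_law.m),
        "poi_s": pw.poi,
        "crossover_s": bp.crossover,
        "poi_ratio": max(pw.poi / bp.crossover, bp.crossover / pw.poi),
    }


def detection_performance(n_spikes: int = 100, amplitude: float = 10.0,
                          seed: int = 0) -> dict:
    """Recall/precision on a rendered 25 kHz trace plus the overlap discard.

    ``n_spikes`` spikes at ``amplitude`` S.D. with >= 4 ms separation are
    rendered onto Gaussian noise; detections within 1 ms of a true spike are
    hits. A second trace carries an overlapping pair 0.5 ms apart, which must
    be flagged complex and excluded from clusters.
    """
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.05, 4.95, 2 * n_spikes))
    times = times[np.concatenate([[True], np.diff(times) > 0.004])][:n_spikes]
    trace = render_voltage_trace(times, amplitude=amplitude, noise_sd=1e-5,
                                 duration=5.0, rng=rng)
    spikes = detect_spikes(trace)
    det = np.array([s.time for s in spikes])
    recall = float(np.mean([np.min(np.abs(det - t)) < 0.001 for t in times])) if det.size else 0.0
    precision = float(np.mean([np.min(np.abs(times - d)) < 0.001 for d in det])) if det.size else 0.0

    # overlapping pair: clean spikes plus two spikes 0.5 ms apart
    t_overlap = [0.3, 0.3005]
    clean = np.arange(1, 11) * 0.05 + 0.6
    trace2 = render_voltage_trace(np.sort(np.concatenate([t_overlap, clean])),
                                  amplitude=amplitude, noise_sd=1e-5, duration=1.5, rng=rng)
    spikes2 = detect_spikes(trace2)
    flagged = [s for s in spikes2 if s.complex_overlap]
    overlap_flagged = any(abs(s.time - 0.3) < 0.002 for s in flagged)
    clusters, discarded = cluster_spikes(spikes2)
    in_clusters = {i for c in clusters for i in c.member_indices}
    overlap_excluded = all(i not in in_clusters for i, s in enumerate(spikes2)
                           if s.complex_overlap)
    return {
        "n_spikes": int(times.size),
        "recall_pct": 100.0 * recall,
        "precision_pct": 100.0 * precision,
        "overlap_flagged": bool(overlap_flagged),
        "overlap_excluded_from_clusters": bool(overlap_excluded and len(discarded) > 0),
    }


def ancova_oracle_error(n1: int = 15, n2: int = 12, seed: int = 0) -> dict:
    """Relative error of the ANCOVA interaction F vs the squared slope-t oracle.

    For two groups, the interaction F statistic must equal the square of the
    classical two-sample slope t statistic with pooled residual variance.
    """
    rng = np.random.default_rng(seed)
    x1 = np.linspace(-2.0, -0.7, n1)
    x2 = np.linspace(-2.0, -0.7, n2)
    y1 = -1.2 * x1 + 0.3 + rng.normal(0, 0.05, n1)
    y2 = -1.5 * x2 + 0.1 + rng.normal(0, 0.05, n2)
    cmp_ = ancova_slopes({"a": (x1, y1), "b": (x2, y2)})

    def _fit(x, y):
        b = np.polyfit(x, y, 1)
        resid = y - np.polyval(b, x)
        return b[0], float(np.sum(resid**2)), float(np.sum((x - x.mean()) ** 2))

    b1, ss1, sxx1 = _fit(x1, y1)
    b2, ss2, sxx2 = _fit(x2, y2)
    s2 = (ss1 + ss2) / (n1 + n2 - 4)
    t = (b1 - b2) / np.sqrt(s2 * (1 / sxx1 + 1 / sxx2))
    return {
        "interaction_f": cmp_.interaction_f,
        "t_squared": float(t**2),
        "rel_error": abs(cmp_.interaction_f - t**2) / t**2,
    }


def ancova_null_type1(reps: int = 1000, n_points: int = 20, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Empirical type-I rate of the slope-homogeneity test under the null.

    Two groups of independent points from the same line with Gaussian noise;
    the rejection rate at nominal alpha should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(-2.0, -0.7, n_points)
    rejections = 0
    for _ in range(reps):
        y1 = -1.5 * x + 0.2 + rng.normal(0, 0.05, n_points)
        y2 = -1.5 * x + 0.2 + rng.normal(0, 0.05, n_points)
        if ancova_slopes({"a": (x, y1), "b": (x, y2)}).interaction_p < alpha:
            rejections += 1
    return {"reps": reps, "type1_pct": 100.0 * rejections / reps}


def pipeline_determinism(tmp_dir, seed: int = 0, duration: float = 60.0) -> dict:
    """Byte-identity of two full pipeline runs from the same seed."""
    from pathlib import Path

    tmp = Path(tmp_dir)
    layout = io.five_tunnel_layout()
    ds = generate_dataset(layout, duration=duration, seed=seed)
    csv = tmp / "spikes.csv"
    io.write_spike_csv(csv, ds.spike_trains)
    pipeline.run_pipeline(csv, layout, seed=seed, out_dir=tmp / "run1")
    pipeline.run_pipeline(csv, layout, seed=seed, out_dir=tmp / "run2")
    names = sorted(p.name for p in (tmp / "run1").iterdir())
    identical = all(
        (tmp / "run1" / n).read_bytes() == (tmp / "run2" / n).read_bytes() for n in names
    )
    n_valid = sum(
        1 for ax in ds.ground_truth if ax.has_valid_delay
    )
    return {"identical": bool(identical), "n_files": len(names), "n_valid_axons": n_valid}
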