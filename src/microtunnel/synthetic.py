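"""Ground-truth spike-train and voltage-trace generator.

Emulates the statistical structure of axonal traffic in microfluidic tunnels
spanning two electrodes: a single axon fires with heavy-tailed inter-spike
intervals, every spike appears on both tunnel electrodes separated by a fixed
conduction delay (0.2-1 ms for a valid 400 um tunnel) up to small Gaussian
timing jitter, each electrode independently misses spikes (detection
dropout), and uncorrelated Poisson noise events contaminate both electrodes.
Bursting units emit runs of >= 4 spikes at < 50 ms spacing separated by gaps
drawn from a two-regime (fast/slow) heavy-tailed inter-burst-interval law.

Every generator is driven by a ``numpy.random.Generator`` (or an integer
seed); identical seeds and parameters reproduce identical datasets bit for
bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detection import VoltageTrace

__all__ = [
    "IntervalLaw",
    "BurstParams",
    "GroundTruthAxon",
    "SyntheticDataset",
    "sample_loglog_intervals",
    "truncated_pareto_cdf",
    "loglog_interval_cdf",
    "sample_two_regime_intervals",
    "two_regime_crossover",
    "generate_isi_train",
    "generate_burst_train",
    "generate_tunnel_pair",
    "default_spike_template",
    "render_voltage_trace",
    "generate_dataset",
]

REGIONS = ("EC", "DG", "CA3", "CA1")


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class IntervalLaw:
    """Power-law interval law: survival P(T >= t) = (t / t_min)**m on [t_min, t_max].

    ``m`` is the log-log CCD slope (negative). The residual tail mass
    ``(t_max / t_min)**m`` sits as an atom at ``t_max`` — the unique
    construction whose CCD is *exactly* linear in log-log over the whole
    support (a continuous truncation would bend the CCD downward near
    ``t_max``). The conditional truncated Pareto (no atom) is available via
    ``sample_loglog_intervals(..., truncation="pareto")`` for comparison.
    """

    m: float
    t_min: float
    t_max: float

    def __post_init__(self):
        if self.m >= 0:
            raise ValueError("interval-law slope m must be negative")
        if not (0 < self.t_min <= self.t_max):
            raise ValueError("require 0 < t_min <= t_max")

    @property
    def tail_mass(self) -> float:
        """Probability of the atom at t_max."""
        return (self.t_max / self.t_min) ** self.m

    @property
    def mean(self) -> float:
        """Mean interval (closed form, atom included)."""
        m, a, b = self.m, self.t_min, self.t_max
        if a == b:
            return a
        if m == -1.0:
            cont = a * np.log(b / a)
        else:
            cont = -m * (b ** (m + 1) - a ** (m + 1)) / ((m + 1) * a**m)
        return float(cont + b * self.tail_mass)


def sample_loglog_intervals(m: float, t_min: float, t_max: float, n: int,
                            seed=None, rng=None, truncation: str = "atom") -> np.ndarray:
    """Inverse-CDF samples from the power-law interval law with CCD slope ``m``.

    With ``truncation="atom"`` (default) the survival function is exactly
    ``(t/t_min)**m`` up to ``t_max``, so the empirical CCD on log-spaced bins
    is log-log linear with slope ``m`` (up to sampling noise).
    ``truncation="pareto"`` instead renormalizes the continuous law on
    ``[t_min, t_max]`` (classical truncated Pareto, whose CCD bends near the
    upper limit).
    """
    if m >= 0:
        raise ValueError("m must be negative")
    if not (0 < t_min <= t_max):
        raise ValueError("require 0 < t_min <= t_max")
    if n < 1:
        raise ValueError("n must be >= 1")
    if truncation not in ("atom", "pareto"):
        raise ValueError(f"unknown truncation {truncation!r}")
    g = _rng(seed, rng)
    if t_min == t_max:  # zero-width support
        return np.full(n, float(t_min))
    u = np.clip(g.random(n), np.finfo(float).tiny, 1.0)
    if truncation == "atom":
        r = (t_max / t_min) ** m
        cont = np.minimum(t_min * u ** (1.0 / m), t_max)
        return np.where(u <= r, t_max, cont)  # atom placed exactly at t_max
    tm = u * (t_min**m - t_max**m) + t_max**m
    return tm ** (1.0 / m)


def loglog_interval_cdf(t, m: float, t_min: float, t_max: float):
    """CDF of the default (atom-truncated) power-law interval law."""
    t = np.asarray(t, dtype=float)
    f = 1.0 - (np.clip(t, t_min, t_max) / t_min) ** m
    return np.where(t < t_min, 0.0, np.where(t >= t_max, 1.0, f))


def truncated_pareto_cdf(t, m: float, t_min: float, t_max: float):
    """CDF of the continuous truncated Pareto with CCD exponent ``m``."""
    t = np.asarray(t, dtype=float)
    f = (t_min**m - np.clip(t, t_min, t_max) ** m) / (t_min**m - t_max**m)
    return np.where(t < t_min, 0.0, np.where(t > t_max, 1.0, f))


def two_regime_crossover(fast: IntervalLaw, mixture_weight: float | None) -> float:
    """Regime boundary of the two-regime law.

    With ``mixture_weight`` given, the crossover is placed where the fast
    power law has spent exactly that much probability mass:
    ``t_x = t_min * (1 - w) ** (1 / m_fast)``; otherwise the fast law's own
    upper limit is the crossover.
    """
    if mixture_weight is None:
        return fast.t_max
    if not (0 < mixture_weight < 1):
        raise ValueError("mixture_weight must be in (0, 1)")
    return float(fast.t_min * (1.0 - mixture_weight) ** (1.0 / fast.m))


def sample_two_regime_intervals(fast: IntervalLaw, slow: IntervalLaw, n: int,
                                mixture_weight: float | None = None,
                                seed=None, rng=None) -> np.ndarray:
    """Samples from a broken power law: fast slope below the crossover, slow above.

    The survival function is ``(t/t0)**m_fast`` on ``[t0, t_x]`` and
    ``(t_x/t0)**m_fast * (t/t_x)**m_slow`` on ``[t_x, t_max]``, so the CCD is
    exactly piecewise log-log linear with the crossover at ``t_x`` (the POI
    of the two segments). Residual tail mass beyond ``slow.t_max`` sits as an
    atom at ``slow.t_max``. The fast-regime probability mass is
    ``1 - (t_x/t0)**m_fast``, i.e. ``mixture_weight`` when that is supplied.
    """
    g = _rng(seed, rng)
    t0 = fast.t_min
    tx = two_regime_crossover(fast, mixture_weight)
    t1 = slow.t_max
    if not (t0 < tx < t1):
        raise ValueError("regimes must satisfy t_min_fast < crossover < t_max_slow")
    r_fast = (tx / t0) ** fast.m  # survival at the crossover
    u = g.random(n)
    u = np.clip(u, np.finfo(float).tiny, 1.0)
    out = np.empty(n)
    in_fast = u > r_fast
    out[in_fast] = np.minimum(t0 * u[in_fast] ** (1.0 / fast.m), tx)
    atom = r_fast * (t1 / tx) ** slow.m
    in_slow = ~in_fast & (u > atom)
    out[in_slow] = np.minimum(tx * (u[in_slow] / r_fast) ** (1.0 / slow.m), t1)
    out[~in_fast & ~in_slow] = t1  # residual tail mass, exactly at the limit
    return out


@dataclass(frozen=True)
class BurstParams:
    """Burst-structure parameters of a synthetic unit.

    ``spikes_per_burst`` spikes at fixed ``intra_burst_isi`` spacing form each
    burst (satisfying the >= 4 spikes at < 50 ms burst definition by
    construction); gaps between bursts follow the two-regime law built from
    ``ibi_fast_law``/``ibi_slow_law`` (and ``mixture_weight``, if given, which
    relocates the crossover — see :func:`sample_two_regime_intervals`).
    """

    spikes_per_burst: int = 5
    intra_burst_isi: float = 0.01
    ibi_fast_law: IntervalLaw = field(default_factory=lambda: IntervalLaw(-1.5, 0.2, 2.0))
    ibi_slow_law: IntervalLaw = field(default_factory=lambda: IntervalLaw(-0.5, 2.0, 20.0))
    mixture_weight: float | None = None

    def __post_init__(self):
        if self.spikes_per_burst < 4:
            raise ValueError("bursts need at least 4 spikes")
        if not (0 < self.intra_burst_isi < 0.05):
            raise ValueError("intra-burst ISI must be below 0.05 s")
        if self.ibi_fast_law.t_min < 0.05:
            raise ValueError("inter-burst gaps must be >= 0.05 s (fast law t_min too small)")

    @property
    def crossover(self) -> float:
        return two_regime_crossover(self.ibi_fast_law, self.mixture_weight)

    @property
    def fast_weight(self) -> float:
        """Probability mass of the fast regime."""
        return 1.0 - (self.crossover / self.ibi_fast_law.t_min) ** self.ibi_fast_law.m


@dataclass(frozen=True)
class GroundTruthAxon:
    """True parameters of one synthetic tunnel axon (the recovery target)."""

    axon_id: str
    region_pair: tuple[str, str]
    direction: str  # "feed_forward" or "feedback"
    conduction_delay: float  # seconds, positive magnitude
    isi_law: IntervalLaw = field(default_factory=lambda: IntervalLaw(-1.5, 0.01, 0.2))
    burst_params: BurstParams | None = None
    detect_prob: float | tuple[float, float] = 1.0
    jitter_sd: float = 5e-5

    def __post_init__(self):
        if self.direction not in ("feed_forward", "feedback"):
            raise ValueError("direction must be feed_forward or feedback")
        if self.conduction_delay <= 0:
            raise ValueError("conduction_delay is a positive magnitude")
        for p in self.detect_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("detect_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def detect_probs(self) -> tuple[float, float]:
        p = self.detect_prob
        return tuple(p) if isinstance(p, (tuple, list)) else (float(p), float(p))

    @property
    def has_valid_delay(self) -> bool:
        return 0.0002 <= self.conduction_delay <= 0.001

    @property
    def signed_delay(self) -> float:
        """Downstream-minus-upstream delay, positive for feed-forward travel."""
        return self.conduction_delay if self.direction == "feed_forward" else -self.conduction_delay


def generate_isi_train(isi_law: IntervalLaw, duration: float, seed=None, rng=None,
                       t_start: float = 0.0) -> np.ndarray:
    """Renewal spike train with truncated-Pareto ISIs on ``[t_start, duration)``."""
    if duration <= t_start:
        raise ValueError("duration must exceed t_start")
    g = _rng(seed, rng)
    mean = isi_law.mean
    n_guess = max(16, int((duration - t_start) / mean * 1.5) + 8)
    times = []
    t = t_start
    while t < duration:
        isis = sample_loglog_intervals(isi_law.m, isi_law.t_min, isi_law.t_max,
                                       n_guess, rng=g)
        ts = t + np.cumsum(isis)
        times.append(ts[ts < duration])
        t = ts[-1]
    out = np.concatenate(times) if times else np.empty(0)
    return out


def generate_burst_train(burst_params: BurstParams, duration: float,
                         seed=None, rng=None) -> np.ndarray:
    """Spike train of fixed-shape bursts separated by two-regime gaps.

    Every emitted burst satisfies the burst definition (>= 4 spikes at
    < 50 ms) by construction and gaps are >= 50 ms, so downstream burst
    detection with default parameters recovers the bursts exactly. A duration
    too short for one full burst yields an empty train with a warning.
    """
    g = _rng(seed, rng)
    bp = burst_params
    span = (bp.spikes_per_burst - 1) * bp.intra_burst_isi
    if span >= duration:
        warnings.warn("duration too short for a single burst; empty train", stacklevel=2)
        return np.empty(0)
    times = []
    t = 0.0
    while t + span < duration:
        times.append(t + bp.intra_burst_isi * np.arange(bp.spikes_per_burst))
        gap = sample_two_regime_intervals(bp.ibi_fast_law, bp.ibi_slow_law, 1,
                                          mixture_weight=bp.mixture_weight, rng=g)[0]
        t = t + span + gap
    return np.concatenate(times)


def generate_tunnel_pair(axon: GroundTruthAxon, duration: float, noise_rate: float = 0.0,
                         seed=None, rng=None, base_train=None):
    """Upstream/downstream spike trains for one tunnel axon.

    Upstream spikes follow the axon's ISI law (or burst structure when
    ``burst_params`` is set); each is copied downstream shifted by the signed
    conduction delay plus Gaussian jitter, each electrode drops spikes
    independently with probability ``1 - detect_prob``, and homogeneous
    Poisson noise events at ``noise_rate`` Hz are added independently per
    electrode. Returns ``(train_upstream, train_downstream)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_rate < 0:
        raise ValueError("noise_rate must be non-negative")
    g = _rng(seed, rng)
    if base_train is not None:
        base = np.asarray(base_train, dtype=float)
    elif axon.burst_params is not None:
        base = generate_burst_train(axon.burst_params, duration, rng=g)
    else:
        base = generate_isi_train(axon.isi_law, duration, rng=g)

    down = base + axon.signed_delay
    if axon.jitter_sd > 0:
        down = down + g.normal(0.0, axon.jitter_sd, size=down.size)
    p_up, p_down = axon.detect_probs
    up = base[g.random(base.size) < p_up] if p_up < 1.0 else base.copy()
    down = down[g.random(down.size) < p_down] if p_down < 1.0 else down

    def _with_noise(train):
        if noise_rate > 0:
            k = g.poisson(noise_rate * duration)
            train = np.concatenate([train, g.uniform(0.0, duration, k)])
        train = train[(train >= 0.0) & (train < duration)]
        return np.sort(train)

    return _with_noise(up), _with_noise(down)


def default_spike_template(sampling_rate: float = 25000.0, duration: float = 0.0012) -> np.ndarray:
    """Biphasic extracellular spike template, 1.2 ms, peak normalized to 1.

    Negative main lobe followed by a smaller positive rebound, the canonical
    shape of an axonal spike recorded by a substrate electrode.
    """
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    s1, s2 = 0.10e-3, 0.18e-3
    t1, t2 = 0.35e-3, 0.70e-3
    w = -np.exp(-(((t - t1) / s1) ** 2)) + 0.45 * np.exp(-(((t - t2) / s2) ** 2))
    return w / np.max(np.abs(w))


def render_voltage_trace(spike_times, template=None, amplitude: float = 10.0,
                         noise_sd: float = 1e-5, sampling_rate: float = 25000.0,
                         duration: float | None = None, seed=None, rng=None,
                         electrode_id: str = "e0", electrode_role: str = "tunnel") -> VoltageTrace:
    """White Gaussian noise plus ``amplitude * noise_sd`` spike templates.

    Each spike's template is added with its extremum at the nearest sample to
    the spike time; spikes closer than the template length simply sum,
    producing the overlapping (complex) waveforms used to exercise the
    complex-spike discard.
    """
    g = _rng(seed, rng)
    times = np.asarray(spike_times, dtype=float)
    if template is None:
        template = default_spike_template(sampling_rate)
    template = np.asarray(template, dtype=float)
    if duration is None:
        duration = (times.max() if times.size else 0.0) + 0.05
    n = int(round(duration * sampling_rate))
    x = g.normal(0.0, noise_sd, n)
    peak_off = int(np.argmax(np.abs(template)))
    for t in times:
        i0 = int(round(t * sampling_rate)) - peak_off
        a0, a1 = max(i0, 0), min(i0 + template.size, n)
        if a1 <= a0:
            continue
        x[a0:a1] += amplitude * noise_sd * template[a0 - i0 : a1 - i0]
    return VoltageTrace(samples=x, sampling_rate=sampling_rate,
                        electrode_id=electrode_id, electrode_role=electrode_role)


@dataclass
class SyntheticDataset:
    """Spike trains (and optional traces) with the generating ground truth."""

    spike_trains: dict  # electrode_id -> sorted times (s)
    ground_truth: list  # of GroundTruthAxon
    seed: int
    duration: float
    traces: dict | None = None  # electrode_id -> VoltageTrace
    sampling_rate: float = 25000.0


def generate_dataset(layout, duration: float = 120.0, seed: int = 0,
                     noise_rate: float = 0.5, p_feed_forward: float = 0.7,
                     detect_prob: float = 0.9, jitter_sd: float = 5e-5,
                     with_traces: bool = False, well_burst_params: BurstParams | None = None,
                     isi_law: IntervalLaw | None = None) -> SyntheticDataset:
    """Full-array synthetic recording for a layout of wells and tunnels.

    One axon per tunnel: conduction delay uniform in the valid 0.2-1 ms
    window, direction feed-forward with probability ``p_feed_forward``
    (feed-forward axons dominate in these cultures). One bursting unit per
    well electrode. Regenerating with the same seed reproduces the dataset
    exactly.
    """
    g = np.random.default_rng(seed)
    isi_law = isi_law or IntervalLaw(-1.5, 0.01, 0.2)
    well_burst_params = well_burst_params or BurstParams()
    trains: dict[str, np.ndarray] = {}
    truth: list[GroundTruthAxon] = []

    for tun in sorted(layout.tunnels, key=lambda t: t.tunnel_id):
        delay = g.uniform(0.0002, 0.001)
        direction = "feed_forward" if g.random() < p_feed_forward else "feedback"
        axon = GroundTruthAxon(
            axon_id=f"axon_{tun.tunnel_id}",
            region_pair=(tun.region_from, tun.region_to),
            direction=direction,
            conduction_delay=float(delay),
            isi_law=isi_law,
            detect_prob=detect_prob,
            jitter_sd=jitter_sd,
        )
        up, down = generate_tunnel_pair(axon, duration, noise_rate=noise_rate, rng=g)
        trains[tun.electrode_a] = up
        trains[tun.electrode_b] = down
        truth.append(axon)

    for region in sorted(layout.wells):
        for e in layout.wells[region]:
            if e in trains:
                continue
            trains[e] = generate_burst_train(well_burst_params, duration, rng=g)

    traces = None
    if with_traces:
        traces = {}
        for e in sorted(trains):
            role = "tunnel" if any(e in (t.electrode_a, t.electrode_b) for t in layout.tunnels) else "well"
            traces[e] = render_voltage_trace(trains[e], amplitude=10.0, noise_sd=1e-5,
                                             duration=duration, rng=g,
                                             electrode_id=e, electrode_role=role)
    return SyntheticDataset(spike_trains=trains, ground_truth=truth, seed=seed,
                            duration=duration, traces=traces)
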