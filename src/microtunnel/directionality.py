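"""Tunnel directionality: spike pairing, NMI, conduction-delay histograms.

A microfluidic tunnel is monitored by two electrodes; a single axon threading
it produces near-simultaneous spike pairs whose signed time difference
(downstream minus upstream) is the conduction delay. Tunnels are accepted as
single-axon when the normalized matching index

    NMI = (number of paired spikes) / max(n_a, n_b)

exceeds 0.2 (strictly) and the delay-histogram peak lies between 0.2 and
1 ms in magnitude. The delay sign gives the travel direction; travel
following the trisynaptic order EC -> DG -> CA3 -> CA1 -> EC (or the
perforant-path jumps EC -> CA3 and EC -> CA1) is feed-forward, anything else
feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SpikePairing",
    "DelayHistogram",
    "TunnelResult",
    "FEED_FORWARD_PAIRS",
    "match_spike_pairs",
    "compute_nmi",
    "delay_histogram",
    "classify_direction",
    "run_tunnel",
]

#: Travel directions classified feed-forward: the trisynaptic loop plus the
#: perforant-path EC->CA3 and the (excitatory, hence feed-forward by
#: convention) EC->CA1 projection.
FEED_FORWARD_PAIRS = frozenset(
    {("EC", "DG"), ("DG", "CA3"), ("CA3", "CA1"), ("CA1", "EC"), ("EC", "CA3"), ("EC", "CA1")}
)

DEFAULT_MATCHING_WINDOW = 0.001  # s, the maximum valid conduction delay
DEFAULT_BIN_WIDTH = 0.00004  # s, one sample at 25 kHz
DEFAULT_DELAY_WINDOW = (0.0002, 0.001)  # s, valid |delay| range
NMI_THRESHOLD = 0.2


@dataclass(frozen=True)
class SpikePairing:
    """One-to-one matched spike pairs between the two tunnel electrodes."""

    pairs: np.ndarray  # shape (k, 2): (time_upstream, time_downstream)
    n_a: int
    n_b: int
    matching_window: float

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def deltas(self) -> np.ndarray:
        """Signed delays, downstream minus upstream."""
        if self.n_pairs == 0:
            return np.empty(0)
        return self.pairs[:, 1] - self.pairs[:, 0]


@dataclass(frozen=True)
class DelayHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_delay: float | None = None
    peak_prominence: float | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class TunnelResult:
    tunnel_id: str
    region_pair: tuple[str, str]  # declared orientation (from, to)
    travel_pair: tuple[str, str] | None  # inferred travel direction
    nmi: float
    delay: float  # signed seconds (NaN when no peak)
    direction: str  # feed_forward / feedback / invalid
    valid: bool
    histogram: DelayHistogram
    n_pairs: int


def match_spike_pairs(train_a, train_b, window: float = DEFAULT_MATCHING_WINDOW) -> SpikePairing:
    """Optimal one-to-one pairing of two spike trains within a time window.

    Maximum-cardinality matching minimizing the total |time difference|,
    computed exactly per window-connected component (components are split
    wherever consecutive events across both trains are more than ``window``
    apart, so each assignment problem is tiny). Deterministic.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if window <= 0:
        raise ValueError("matching window must be positive")
    if a.size == 0 or b.size == 0:
        return SpikePairing(np.empty((0, 2)), int(a.size), int(b.size), window)

    times = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(a.size, dtype=int), np.ones(b.size, dtype=int)])
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    breaks = np.flatnonzero(np.diff(times) > window) + 1
    pairs = []
    big = 1e9 * window
    for seg_t, seg_l in zip(np.split(times, breaks), np.split(labels, breaks)):
        ta = seg_t[seg_l == 0]
        tb = seg_t[seg_l == 1]
        if ta.size == 0 or tb.size == 0:
            continue
        cost = np.abs(ta[:, None] - tb[None, :])
        cost = np.where(cost <= window, cost, big)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if cost[i, j] <= window:
                pairs.append((ta[i], tb[j]))
    pairs = np.array(sorted(pairs)) if pairs else np.empty((0, 2))
    return SpikePairing(pairs, int(a.size), int(b.size), window)


def compute_nmi(pairing: SpikePairing, n_a: int | None = None, n_b: int | None = None) -> float:
    """Normalized matching index: paired spikes over the larger train's count.

    0 by convention when both trains are empty.
    """
    n_a = pairing.n_a if n_a is None else n_a
    n_b = pairing.n_b if n_b is None else n_b
    denom = max(n_a, n_b)
    if denom == 0:
        return 0.0
    return pairing.n_pairs / denom


def delay_histogram(pairing: SpikePairing, bin_width: float = DEFAULT_BIN_WIDTH,
                    min_peak_count: float = 5.0, prominence_frac: float = 0.2) -> DelayHistogram:
    """Histogram of signed delays over ±window with peak detection.

    The peak must contain at least ``min_peak_count`` pairs and have
    prominence at least ``prominence_frac`` of the pair count; the reported
    delay is the count-weighted centroid of the peak bin ±2 neighbours, for
    sub-bin accuracy.
    """
    w = pairing.matching_window
    n_bins = max(1, int(np.ceil(2 * w / bin_width)))
    edges = np.linspace(-w, w, n_bins + 1)
    if pairing.n_pairs == 0:
        return DelayHistogram(bin_edges=edges, counts=np.zeros(n_bins, dtype=int))
    counts, _ = np.histogram(pairing.deltas, bins=edges)
    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    peaks, props = signal.find_peaks(
        padded, height=min_peak_count, prominence=max(prominence_frac * pairing.n_pairs, 1e-9)
    )
    if peaks.size == 0:
        return DelayHistogram(bin_edges=edges, counts=counts)
    best = peaks[np.argmax(props["peak_heights"])] - 1  # unpad
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo, hi = max(best - 2, 0), min(best + 3, n_bins)
    weight = counts[lo:hi].astype(float)
    delay = float(np.sum(weight * centers[lo:hi]) / np.sum(weight))
    prom = float(props["prominences"][np.argmax(props["peak_heights"])])
    return DelayHistogram(bin_edges=edges, counts=counts, peak_delay=delay,
                          peak_prominence=prom)


def classify_direction(histogram: DelayHistogram, region_pair, nmi: float,
                       delay_window=DEFAULT_DELAY_WINDOW,
                       nmi_threshold: float = NMI_THRESHOLD):
    """Delay sign -> travel direction -> feed-forward/feedback class.

    Returns ``(delay, travel_pair, direction, valid)``. Invalid when there is
    no histogram peak, NMI <= threshold (strict > required), or the peak's
    magnitude lies outside the valid conduction-delay window.
    """
    d = histogram.peak_delay
    if d is None or not (nmi > nmi_threshold) or not (delay_window[0] <= abs(d) <= delay_window[1]):
        return (d if d is not None else float("nan")), None, "invalid", False
    travel = tuple(region_pair) if d > 0 else (region_pair[1], region_pair[0])
    direction = "feed_forward" if travel in FEED_FORWARD_PAIRS else "feedback"
    return float(d), travel, direction, True


def run_tunnel(train_a, train_b, tunnel_id: str = "t0", region_pair=("EC", "DG"),
               window: float = DEFAULT_MATCHING_WINDOW, bin_width: float = DEFAULT_BIN_WIDTH,
               delay_window=DEFAULT_DELAY_WINDOW, nmi_threshold: float = NMI_THRESHOLD) -> TunnelResult:
    """Full per-tunnel analysis: pairing, NMI, delay histogram, direction."""
    pairing = match_spike_pairs(train_a, train_b, window=window)
    nmi = compute_nmi(pairing)
    hist = delay_histogram(pairing, bin_width=bin_width)
    delay, travel, direction, valid = classify_direction(
        hist, region_pair, nmi, delay_window=delay_window, nmi_threshold=nmi_threshold
    )
    return TunnelResult(tunnel_id=tunnel_id, region_pair=tuple(region_pair),
                        travel_pair=travel, nmi=nmi, delay=delay, direction=direction,
                        valid=valid, histogram=hist, n_pairs=pairing.n_pairs)
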