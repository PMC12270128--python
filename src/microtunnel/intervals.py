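"""Interval dynamics: ISI/IBI extraction, burst detection, log-binned CCDs and power-law fits.

Spike-train timing on compartmentalized MEA cultures is heavy-tailed: the
complementary cumulative distribution (CCD) of inter-spike intervals is close
to linear on log-log axes over one to two decades, and inter-burst intervals
show two regimes ("up states" of fast bursting and "down states" of slow
bursting) that are fitted by two separate log-log lines whose intersection
(the POI, position of intersect) marks the regime crossover.

All times are in seconds. Fits are ordinary least squares on
``(log10 t, log10 P)`` restricted to a candidate window; the window itself is
grid-searched (each limit scaled by factors 1 ± 50% in 5% steps) and the
window maximizing Pearson R² wins, ties broken by the widest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CCD",
    "LinearFit",
    "PiecewiseFit",
    "Burst",
    "BurstinessSummary",
    "FitError",
    "compute_intervals",
    "detect_bursts",
    "compute_ibi",
    "build_ccd",
    "fit_loglog",
    "fit_piecewise",
    "intersection_time",
    "burstiness",
    "fr_burst",
    "ISI_FIT_WINDOWS_FIVE_TUNNEL",
    "DEFAULT_ISI_WINDOW",
]

#: Default ISI fit window (seconds); the canonical window for the five-tunnel
#: design, also used as the fallback for the four-tunnel design where no
#: per-tunnel window is configured.
DEFAULT_ISI_WINDOW = (0.01, 0.2)

#: Five-tunnel per-pair overrides: CA1-EC axons are fit over a shorter window
#: to avoid the non-linear tail (feed-forward 0.01-0.11 s, feedback 0.01-0.09 s).
ISI_FIT_WINDOWS_FIVE_TUNNEL = {
    (("CA1", "EC"), "feed_forward"): (0.01, 0.11),
    (("CA1", "EC"), "feedback"): (0.01, 0.09),
}


class FitError(ValueError):
    """No candidate window contained enough bins for a line fit."""


@dataclass(frozen=True)
class CCD:
    """Normalized complementary cumulative distribution on log-spaced bins.

    ``p[i]`` is the fraction of intervals >= ``t[i]``, normalized so that the
    first bin has probability exactly 1.
    """

    t: np.ndarray
    p: np.ndarray
    n_intervals: int

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if t.ndim != 1 or t.shape != p.shape:
            raise ValueError("t and p must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("bin times must be strictly increasing")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("CCD probabilities must be non-increasing")
        if abs(p[0] - 1.0) > 1e-12:
            raise ValueError("CCD must be normalized to start at 1")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class LinearFit:
    """Least-squares line ``log10 P = m log10 t + c`` on a CCD window."""

    m: float
    c: float
    r_squared: float
    t_range: tuple[float, float]
    prob_range: tuple[float, float] | None
    n_bins: int

    def predict(self, t):
        return 10.0 ** (self.m * np.log10(np.asarray(t, dtype=float)) + self.c)


@dataclass(frozen=True)
class PiecewiseFit:
    """Two-piece log-log fit: fast (short-interval) and slow (long-interval) lines.

    ``poi`` is the time at which the two fitted lines intersect,
    ``10 ** ((c_slow - c_fast) / (m_fast - m_slow))``; it is flagged unstable
    when the slopes are too close for the intersection to be meaningful.
    """

    fast: LinearFit
    slow: LinearFit
    poi: float
    poi_stable: bool
    boundary: float


@dataclass(frozen=True)
class Burst:
    """A maximal run of >= ``min_spikes`` spikes with consecutive ISIs < ``max_isi``."""

    start_index: int
    end_index: int  # inclusive

    @property
    def n_spikes(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class BurstinessSummary:
    """Per-unit burstiness values plus the group-level frBurst."""

    unit_burstiness: dict = field(default_factory=dict)
    n_arrays: int = 1

    @property
    def fr_burst(self) -> float:
        return fr_burst(list(self.unit_burstiness.values()), self.n_arrays)


def compute_intervals(train) -> np.ndarray:
    """Consecutive differences of a sorted spike train (n-1 ISIs, seconds)."""
    t = np.asarray(train, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike train must be 1-D")
    if t.size < 2:
        return np.empty(0)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("spike train must be strictly increasing")
    return dt


def detect_bursts(train, max_isi: float = 0.05, min_spikes: int = 4):
    """Max-interval burst detection.

    A burst is a maximal run of consecutive ISIs strictly below ``max_isi``
    containing at least ``min_spikes`` spikes. Returns ``(bursts, flags)``
    where ``flags`` marks, per spike, membership in any burst.
    """
    t = np.asarray(train, dtype=float)
    flags = np.zeros(t.size, dtype=bool)
    bursts: list[Burst] = []
    if t.size < min_spikes:
        return bursts, flags
    fast = np.diff(t) < max_isi
    # maximal runs of consecutive fast ISIs
    i = 0
    n = fast.size
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            # spikes i .. j span j - i + 1 spikes
            if j - i + 1 >= min_spikes:
                bursts.append(Burst(start_index=i, end_index=j))
                flags[i : j + 1] = True
            i = j
        i += 1
    return bursts, flags


def compute_ibi(train, bursts, mode: str = "end_to_start") -> np.ndarray:
    """Inter-burst intervals between adjacent bursts of one train.

    ``end_to_start`` (default): next burst's first spike minus previous
    burst's last spike. ``onset_to_onset``: difference of burst onsets.
    """
    t = np.asarray(train, dtype=float)
    if mode not in ("end_to_start", "onset_to_onset"):
        raise ValueError(f"unknown IBI mode: {mode!r}")
    if len(bursts) < 2:
        return np.empty(0)
    out = np.empty(len(bursts) - 1)
    for k in range(len(bursts) - 1):
        if mode == "end_to_start":
            out[k] = t[bursts[k + 1].start_index] - t[bursts[k].end_index]
        else:
            out[k] = t[bursts[k + 1].start_index] - t[bursts[k].start_index]
    if np.any(out <= 0):
        raise ValueError("bursts must be ordered and non-overlapping")
    return out


def build_ccd(intervals, n_bins: int = 50, t_range=None) -> CCD:
    """Complementary cumulative distribution on logarithmically spaced bins."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals to build a CCD")
    if np.any(x <= 0):
        raise ValueError("intervals must be positive")
    lo, hi = t_range if t_range is not None else (x.min(), x.max())
    if not (0 < lo < hi):
        raise ValueError("t_range must satisfy 0 < lo < hi")
    t = np.logspace(np.log10(lo), np.log10(hi), n_bins)
    t[0], t[-1] = lo, hi  # pin endpoints (logspace rounding must not drop samples)
    xs = np.sort(x)
    ge = x.size - np.searchsorted(xs, t, side="left")
    if ge[0] == 0:
        raise ValueError("no intervals at or above the first bin")
    p = ge / ge[0]  # first-bin normalization
    return CCD(t=t, p=p, n_intervals=int(x.size))


def _ls_line(logt, logp):
    """Least-squares slope/intercept/R² with exact handling of perfect lines."""
    res = stats.linregress(logt, logp)
    r2 = res.rvalue**2
    return float(res.slope), float(res.intercept), float(r2)


def _grid_fit(t, p, lo_candidates, hi_candidates, prob_range, min_bins=3):
    """Best OLS line over candidate (lo, hi) windows, maximizing R².

    Ties (within 1e-10 of R²) are broken by the widest window in log time,
    then by bin count, then by the smaller lower limit.
    """
    logt_all = np.log10(t)
    valid_p = p > 0
    if prob_range is not None:
        pmax, pmin = max(prob_range), min(prob_range)
        valid_p &= (p >= pmin - 1e-12) & (p <= pmax + 1e-12)
    best = None
    best_key = None
    for lo in lo_candidates:
        for hi in hi_candidates:
            if not lo < hi:
                continue
            mask = valid_p & (t >= lo * (1 - 1e-12)) & (t <= hi * (1 + 1e-12))
            n = int(mask.sum())
            if n < min_bins:
                continue
            logt = logt_all[mask]
            if logt[-1] - logt[0] <= 0:
                continue
            m, c, r2 = _ls_line(logt, np.log10(p[mask]))
            key = (round(r2, 10), np.log10(hi / lo), n, -lo)
            if best_key is None or key > best_key:
                best_key = key
                best = LinearFit(
                    m=m,
                    c=c,
                    r_squared=r2,
                    t_range=(float(lo), float(hi)),
                    prob_range=tuple(prob_range) if prob_range is not None else None,
                    n_bins=n,
                )
    if best is None:
        raise FitError("no candidate window with enough bins for a fit")
    return best


def _factors(grid_frac: float, grid_step: float) -> np.ndarray:
    n = int(round(grid_frac / grid_step))
    return 1.0 + grid_step * np.arange(-n, n + 1)


def fit_loglog(
    ccd: CCD,
    nominal_t_range=None,
    prob_range=(1.0, 0.1),
    grid_frac: float = 0.5,
    grid_step: float = 0.05,
) -> LinearFit:
    """Grid-search log-log line fit.

    Each limit of the nominal time window is scaled by factors
    ``1 - grid_frac .. 1 + grid_frac`` in ``grid_step`` increments; among all
    candidate windows (intersected with ``prob_range``, by default
    probability 1 down to 0.1) the one maximizing Pearson R² is returned.
    """
    lo0, hi0 = nominal_t_range if nominal_t_range is not None else (ccd.t[0], ccd.t[-1])
    if not (0 < lo0 < hi0):
        raise ValueError("nominal_t_range must satisfy 0 < lo < hi")
    f = _factors(grid_frac, grid_step)
    return _grid_fit(ccd.t, ccd.p, lo0 * f, hi0 * f, prob_range)


def fit_piecewise(
    ccd: CCD,
    boundary_nominal: float | None = None,
    grid_frac: float = 0.5,
    grid_step: float = 0.05,
    prob_range=None,
    slope_tol: float = 0.05,
) -> PiecewiseFit:
    """Two-piece grid-search fit for two-regime (up/down state) CCDs.

    The fast fit covers bins below a shared boundary, the slow fit bins above
    it; the boundary itself is grid-searched (± ``grid_frac`` in ``grid_step``
    steps around ``boundary_nominal``, default the geometric midpoint of the
    bin range) together with the fast fit's lower and the slow fit's upper
    limit. The boundary maximizing the mean of the two R² values wins.
    """
    t, p = ccd.t, ccd.p
    if boundary_nominal is None:
        boundary_nominal = float(np.sqrt(t[0] * t[-1]))
    f = _factors(grid_frac, grid_step)
    best = None
    best_key = None
    for b in boundary_nominal * f:
        if not (t[0] < b < t[-1]):
            continue
        try:
            fast = _grid_fit(t, p, t[0] * f, [b], prob_range)
            slow = _grid_fit(t, p, [b], t[-1] * f, prob_range)
        except FitError:
            continue
        score = 0.5 * (fast.r_squared + slow.r_squared)
        key = (round(score, 10), fast.n_bins + slow.n_bins)
        if best_key is None or key > best_key:
            best_key = key
            best = (fast, slow, float(b))
    if best is None:
        raise FitError("no boundary admitted fits on both sides")
    fast, slow, b = best
    poi, stable = intersection_time(fast, slow, slope_tol=slope_tol)
    return PiecewiseFit(fast=fast, slow=slow, poi=poi, poi_stable=stable, boundary=b)


def intersection_time(fast: LinearFit, slow: LinearFit, slope_tol: float = 0.05):
    """Time at which two log-log lines intersect: ``10**((c_s - c_f)/(m_f - m_s))``.

    Returns ``(poi_seconds, stable)``; ``stable`` is False (and the POI NaN
    for exactly parallel lines) when the slopes differ by less than
    ``slope_tol``, where the intersection is numerically meaningless.
    """
    dm = fast.m - slow.m
    if dm == 0:
        return float("nan"), False
    poi = 10.0 ** ((slow.c - fast.c) / dm)
    return float(poi), bool(abs(dm) > slope_tol)


def burstiness(train, max_isi: float = 0.05, min_spikes: int = 4) -> float:
    """Fraction of a unit's spikes that belong to bursts (0 for empty trains)."""
    t = np.asarray(train, dtype=float)
    if t.size == 0:
        return 0.0
    _, flags = detect_bursts(t, max_isi=max_isi, min_spikes=min_spikes)
    return float(flags.mean())


def fr_burst(burstiness_values, n_arrays: int = 1, threshold: float = 0.5) -> float:
    """Number of units with burstiness above ``threshold``, per array.

    Group-level summary: units whose fraction of spikes in bursts exceeds 50%
    are counted and normalized by the number of arrays contributing to the
    group.
    """
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    v = np.asarray(list(burstiness_values), dtype=float)
    return float((v > threshold).sum() / n_arrays)
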