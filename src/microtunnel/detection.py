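"""Spike detection and waveform clustering for extracellular traces.

Thresholds are expressed in multiples of the noise standard deviation (S.D.),
estimated robustly with the median-absolute-deviation estimator standard in
extracellular sorting. Tunnel electrodes use two amplitude bands (5-50 S.D.
and 50.1-500 S.D., the second catching very large axonal spikes); well
electrodes use a single ±3.5 S.D. threshold to accommodate their lower SNR.
A 1.5 ms refractory period is enforced per electrode, and detections whose
waveform windows overlap in time are flagged as complex (multiple axons
superimposed) so clustering can discard them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "VoltageTrace",
    "DetectedSpike",
    "SpikeCluster",
    "TUNNEL_BANDS",
    "WELL_BANDS",
    "estimate_noise_sd",
    "bandpass_filter",
    "detect_spikes",
    "cluster_spikes",
]

#: Dual amplitude bands (in noise S.D.) for tunnel electrodes.
TUNNEL_BANDS = ((5.0, 50.0), (50.1, 500.0))
#: Single ±3.5 S.D. threshold band for well electrodes.
WELL_BANDS = ((3.5, np.inf),)

#: Waveform extraction window around the peak (seconds).
DEFAULT_PRE_S = 0.0006
DEFAULT_POST_S = 0.0010


@dataclass
class VoltageTrace:
    """A single-electrode voltage trace (volts) sampled at ``sampling_rate`` Hz."""

    samples: np.ndarray
    sampling_rate: float
    electrode_id: str = "e0"
    electrode_role: str = "tunnel"  # "tunnel" or "well"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class DetectedSpike:
    """One detected event, time-stamped at the extremum.

    ``peak_amplitude`` is signed and in multiples of the noise S.D.; the
    ``waveform`` window is likewise stored in S.D. units so cluster distances
    are noise-scaled.
    """

    time: float
    sample_index: int
    peak_amplitude: float
    waveform: np.ndarray
    complex_overlap: bool = False


@dataclass
class SpikeCluster:
    cluster_id: int
    member_indices: list[int]
    mean_waveform: np.ndarray
    waveform_sd: np.ndarray


def _samples_of(trace) -> np.ndarray:
    return trace.samples if isinstance(trace, VoltageTrace) else np.asarray(trace, dtype=float)


def estimate_noise_sd(trace) -> float:
    """Robust noise S.D.: ``median(|x|) / 0.6745``, insensitive to spikes."""
    x = _samples_of(trace)
    sd = float(np.median(np.abs(x)) / 0.6745)
    if sd == 0.0:
        warnings.warn("constant trace: noise S.D. estimate is 0", stacklevel=2)
    return sd


def bandpass_filter(trace: VoltageTrace, low_hz: float = 300.0, high_hz: float = 3000.0,
                    order: int = 4) -> VoltageTrace:
    """Zero-phase Butterworth band-pass (no spike-time shift)."""
    nyq = trace.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for Nyquist {nyq}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trace.sampling_rate,
                        output="sos")
    y = signal.sosfiltfilt(sos, trace.samples)
    return VoltageTrace(samples=y, sampling_rate=trace.sampling_rate,
                        electrode_id=trace.electrode_id, electrode_role=trace.electrode_role)


def detect_spikes(
    trace: VoltageTrace,
    bands=TUNNEL_BANDS,
    refractory_s: float = 0.0015,
    noise_sd: float | None = None,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
) -> list[DetectedSpike]:
    """Amplitude-band threshold detection with refractory enforcement.

    Peaks of ``|x|`` above the lowest band threshold are detected at either
    polarity and kept if their amplitude falls inside one of the declared
    bands. Within the refractory period the larger-amplitude event survives.
    A surviving event is flagged ``complex_overlap`` when a distinct
    same-polarity detection was suppressed inside its refractory window (two
    axonal spikes summed): "distinct" requires the smaller of the two peaks
    to rise by at least the detection threshold above the inter-peak valley
    of ``|x|``, i.e. to be a threshold-worthy excursion in its own right.
    This separates genuine event pairs from noise ripples riding on one
    waveform's flank, while opposite-polarity sub-refractory peaks (the two
    lobes of one biphasic waveform) are never flagged. Kept detections whose
    waveform windows overlap are also both flagged.
    """
    x = _samples_of(trace)
    fs = trace.sampling_rate
    if x.size == 0:
        return []
    sd = estimate_noise_sd(x) if noise_sd is None else float(noise_sd)
    if sd <= 0:
        return []
    kmin = min(lo for lo, _ in bands)
    idx, _ = signal.find_peaks(np.abs(x), height=kmin * sd)
    if idx.size == 0:
        return []
    amps = x[idx] / sd
    inband = np.zeros(idx.size, dtype=bool)
    for lo, hi in bands:
        inband |= (np.abs(amps) >= lo) & (np.abs(amps) <= hi)
    idx, amps = idx[inband], amps[inband]

    refractory = refractory_s * fs
    kept_idx: list[int] = []
    kept_amp: list[float] = []
    flagged: list[bool] = []
    for i, a in zip(idx, amps):
        if kept_idx and i - kept_idx[-1] < refractory:
            j = kept_idx[-1]
            valley = np.min(np.abs(x[j : i + 1])) / sd
            smaller = min(abs(a), abs(kept_amp[-1]))
            distinct = (np.sign(a) == np.sign(kept_amp[-1])
                        and smaller - valley >= kmin)
            if abs(a) > abs(kept_amp[-1]):
                kept_idx[-1], kept_amp[-1] = int(i), float(a)
            flagged[-1] = flagged[-1] or bool(distinct)
        else:
            kept_idx.append(int(i))
            kept_amp.append(float(a))
            flagged.append(False)

    pre_n = int(round(pre_s * fs))
    post_n = int(round(post_s * fs))
    win_len = pre_n + post_n
    # kept detections whose waveform windows overlap are both complex
    for k in range(len(kept_idx) - 1):
        if kept_idx[k + 1] - kept_idx[k] < win_len:
            flagged[k] = True
            flagged[k + 1] = True

    padded = np.pad(x, (pre_n, post_n), mode="edge") / sd
    spikes = []
    for i, a, fl in zip(kept_idx, kept_amp, flagged):
        wf = padded[i : i + win_len + 1].copy()
        spikes.append(
            DetectedSpike(time=i / fs, sample_index=i, peak_amplitude=a,
                          waveform=wf, complex_overlap=fl)
        )
    return spikes


def cluster_spikes(spikes, inclusion_sd: float = 3.0):
    """Leader-follower template clustering with a 3-S.D. inclusion rule.

    Waveforms (in noise-S.D. units) are assigned in time order to the nearest
    existing cluster whose running mean is within ``inclusion_sd`` RMS
    distance; otherwise they seed a new cluster. The wide tolerance
    accommodates variable axon-electrode coupling of a single axon. Spikes
    flagged ``complex_overlap`` are excluded from all clusters and returned
    separately so multi-axon overlaps do not contaminate templates.

    Returns ``(clusters, discarded_indices)``.
    """
    if len(spikes) == 0:
        raise ValueError("need at least one spike to cluster")
    discarded = [i for i, s in enumerate(spikes) if s.complex_overlap]
    live = [(i, s) for i, s in enumerate(spikes) if not s.complex_overlap]
    if not live:
        warnings.warn("all spikes flagged complex; no clusters formed", stacklevel=2)
        return [], discarded

    means: list[np.ndarray] = []
    members: list[list[int]] = []
    for i, s in live:
        wf = np.asarray(s.waveform, dtype=float)
        if means:
            d = [np.sqrt(np.mean((wf - m) ** 2)) for m in means]
            j = int(np.argmin(d))
            if d[j] <= inclusion_sd:
                n = len(members[j])
                means[j] = (means[j] * n + wf) / (n + 1)
                members[j].append(i)
                continue
        means.append(wf.copy())
        members.append([i])

    clusters = []
    for cid, (m, idxs) in enumerate(zip(means, members)):
        wfs = np.stack([np.asarray(spikes[i].waveform, dtype=float) for i in idxs])
        clusters.append(
            SpikeCluster(cluster_id=cid, member_indices=idxs,
                         mean_waveform=wfs.mean(axis=0), waveform_sd=wfs.std(axis=0))
        )
    return clusters, discarded
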