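"""End-to-end orchestration: input -> tunnel results -> interval dynamics -> statistics.

``run_pipeline`` accepts either a spike-time CSV (the primary path) or a
rendered-trace container (detection is then run per electrode with the
tunnel/well preset from the layout), analyses every tunnel for NMI, delay and
direction, fits ISI CCDs and burst statistics per unit, fits IBI CCDs
piecewise where enough bursts exist, and compares slope and burstiness groups.
All outputs are plain CSV/JSON tables; a parameter snapshot is written next to
every results bundle, and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, directionality, groupstats, intervals, io

__all__ = ["PipelineResult", "run_pipeline", "detect_all", "analyse_tunnels",
           "analyse_dynamics", "analyse_groups"]

DEFAULT_PARAMS = {
    "matching_window_s": directionality.DEFAULT_MATCHING_WINDOW,
    "delay_bin_width_s": directionality.DEFAULT_BIN_WIDTH,
    "delay_window_s": list(directionality.DEFAULT_DELAY_WINDOW),
    "nmi_threshold": directionality.NMI_THRESHOLD,
    "refractory_s": 0.0015,
    "burst_max_isi_s": 0.05,
    "burst_min_spikes": 4,
    "isi_window_s": list(intervals.DEFAULT_ISI_WINDOW),
    "ccd_bins": 50,
    "min_isi_for_fit": 30,
    "min_ibi_for_fit": 10,
    "bandpass_hz": [300.0, 3000.0],
    "n_arrays": 1,
}


@dataclass
class PipelineResult:
    tunnels: pd.DataFrame
    dynamics: pd.DataFrame
    ccd_points: pd.DataFrame
    stats: dict
    params: dict


def detect_all(traces: dict, layout: io.LayoutConfig, params: dict) -> dict:
    """Band-pass + threshold detection per electrode; returns spike trains."""
    lo, hi = params["bandpass_hz"]
    trains = {}
    for e in sorted(traces):
        tr = traces[e]
        role = layout.role_of(e)
        filtered = detection.bandpass_filter(tr, lo, hi)
        bands = detection.TUNNEL_BANDS if role == "tunnel" else detection.WELL_BANDS
        spikes = detection.detect_spikes(filtered, bands=bands,
                                         refractory_s=params["refractory_s"])
        trains[e] = np.array([s.time for s in spikes if not s.complex_overlap])
    return trains


def analyse_tunnels(trains: dict, layout: io.LayoutConfig, params: dict) -> pd.DataFrame:
    rows = []
    for tun in sorted(layout.tunnels, key=lambda t: t.tunnel_id):
        a = trains.get(tun.electrode_a, np.empty(0))
        b = trains.get(tun.electrode_b, np.empty(0))
        res = directionality.run_tunnel(
            a, b, tunnel_id=tun.tunnel_id,
            region_pair=(tun.region_from, tun.region_to),
            window=params["matching_window_s"],
            bin_width=params["delay_bin_width_s"],
            delay_window=tuple(params["delay_window_s"]),
            nmi_threshold=params["nmi_threshold"],
        )
        rows.append({
            "tunnel_id": res.tunnel_id,
            "region_from": tun.region_from, "region_to": tun.region_to,
            "travel_pair": "-".join(res.travel_pair) if res.travel_pair else "",
            "nmi": res.nmi, "n_pairs": res.n_pairs,
            "delay_ms": res.delay * 1e3 if np.isfinite(res.delay) else np.nan,
            "direction": res.direction, "valid": res.valid,
        })
    cols = ["tunnel_id", "region_from", "region_to", "travel_pair", "nmi",
            "n_pairs", "delay_ms", "direction", "valid"]
    return pd.DataFrame(rows, columns=cols)


def _isi_window(travel_pair: str, direction: str, params: dict):
    key = (tuple(travel_pair.split("-")), direction) if travel_pair else None
    override = intervals.ISI_FIT_WINDOWS_FIVE_TUNNEL.get(key)
    for label, window in (params.get("isi_windows") or {}).items():
        if label == f"{travel_pair}:{direction}":
            override = tuple(window)
    return override or tuple(params["isi_window_s"])


def analyse_dynamics(trains: dict, layout: io.LayoutConfig, params: dict,
                     tunnels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit ISI fit, burst statistics and piecewise IBI fit.

    Units are per-electrode merged trains; tunnel electrodes inherit the
    travel pair and direction of their tunnel's result.
    """
    tun_meta = {}
    for _, r in tunnels.iterrows():
        for tun in layout.tunnels:
            if tun.tunnel_id == r["tunnel_id"]:
                meta = (r["travel_pair"], r["direction"], r["valid"])
                tun_meta[tun.electrode_a] = meta
                tun_meta[tun.electrode_b] = meta
    rows, pts = [], []
    region_of = {e: r for r, es in layout.wells.items() for e in es}
    for e in sorted(trains):
        train = np.asarray(trains[e], dtype=float)
        travel, direction, valid = tun_meta.get(e, ("", "", False))
        group = travel if travel else region_of.get(e, "")
        row = {"electrode_id": e, "group": group, "direction": direction,
               "n_spikes": int(train.size), "n_intervals": 0,
               "m": np.nan, "c": np.nan, "r2": np.nan,
               "t_lo": np.nan, "t_hi": np.nan,
               "m_ibi_fast": np.nan, "m_ibi_slow": np.nan, "poi_s": np.nan,
               "n_bursts": 0, "burstiness": 0.0}
        if train.size >= 2:
            isis = intervals.compute_intervals(train)
            row["n_intervals"] = int(isis.size)
            if isis.size >= params["min_isi_for_fit"]:
                window = _isi_window(travel, direction, params)
                try:
                    ccd = intervals.build_ccd(isis, n_bins=params["ccd_bins"])
                    fit = intervals.fit_loglog(ccd, nominal_t_range=window)
                    row.update(m=fit.m, c=fit.c, r2=fit.r_squared,
                               t_lo=fit.t_range[0], t_hi=fit.t_range[1])
                    mask = ((ccd.t >= fit.t_range[0]) & (ccd.t <= fit.t_range[1])
                            & (ccd.p > 0) & (ccd.p >= 0.1 - 1e-12))
                    for t, p in zip(ccd.t[mask], ccd.p[mask]):
                        pts.append({"electrode_id": e, "group": group,
                                    "direction": direction,
                                    "log10_t": np.log10(t), "log10_p": np.log10(p)})
                except (intervals.FitError, ValueError):
                    pass
            bursts, _ = intervals.detect_bursts(
                train, max_isi=params["burst_max_isi_s"],
                min_spikes=params["burst_min_spikes"])
            row["n_bursts"] = len(bursts)
            row["burstiness"] = intervals.burstiness(
                train, max_isi=params["burst_max_isi_s"],
                min_spikes=params["burst_min_spikes"])
            if len(bursts) >= params["min_ibi_for_fit"]:
                ibis = intervals.compute_ibi(train, bursts)
                try:
                    ccd = intervals.build_ccd(ibis, n_bins=params["ccd_bins"])
                    pw = intervals.fit_piecewise(ccd)
                    row.update(m_ibi_fast=pw.fast.m, m_ibi_slow=pw.slow.m,
                               poi_s=pw.poi if pw.poi_stable else np.nan)
                except (intervals.FitError, ValueError):
                    pass
        rows.append(row)
    cols = ["electrode_id", "group", "direction", "n_spikes", "n_intervals",
            "m", "c", "r2", "t_lo", "t_hi", "m_ibi_fast", "m_ibi_slow",
            "poi_s", "n_bursts", "burstiness"]
    pt_cols = ["electrode_id", "group", "direction", "log10_t", "log10_p"]
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(pts, columns=pt_cols))


def analyse_groups(dynamics: pd.DataFrame, ccd_points: pd.DataFrame, params: dict) -> dict:
    """ANCOVA on pooled CCD points by group; Kruskal-Wallis on burstiness."""
    stats: dict = {"ancova": None, "kruskal_wallis": None, "fr_burst": {}}
    groups = {}
    for g, sub in ccd_points.groupby("group"):
        if g and len(sub) >= 3 and sub["log10_t"].nunique() >= 3:
            groups[g] = (sub["log10_t"].to_numpy(), sub["log10_p"].to_numpy())
    if len(groups) >= 2:
        try:
            cmp_ = groupstats.ancova_slopes(groups)
            stats["ancova"] = {
                "interaction_f": cmp_.interaction_f,
                "interaction_p": cmp_.interaction_p,
                "group_slopes": cmp_.group_slopes,
                "partial_eta_squared": cmp_.partial_eta_squared,
                "tukey": cmp_.tukey.to_dict(orient="records"),
            }
        except ValueError as err:
            warnings.warn(f"ANCOVA skipped: {err}", stacklevel=2)
    burst_groups = {g: sub["burstiness"].to_numpy()
                    for g, sub in dynamics.groupby("group") if g}
    burst_groups = {g: v for g, v in burst_groups.items() if v.size > 0}
    if len(burst_groups) >= 2:
        kw = groupstats.kruskal_wallis(burst_groups)
        stats["kruskal_wallis"] = {"h": kw.h_statistic, "p": kw.p_value}
    stats["fr_burst"] = {
        g: intervals.fr_burst(v, n_arrays=params["n_arrays"])
        for g, v in sorted(burst_groups.items())
    }
    return stats


def run_pipeline(input_path, layout, params=None, seed: int = 0,
                 out_dir=None) -> PipelineResult:
    """Full analysis of one recording; optionally writes a results bundle.

    ``input_path`` is either a spike CSV or a trace-container prefix (a path
    whose ``.json`` sidecar exists). Deterministic given inputs, params, seed.
    """
    if isinstance(layout, (str, Path)):
        layout = io.read_layout_json(layout)
    p = dict(DEFAULT_PARAMS)
    p.update(layout.params or {})
    p.update(params or {})
    p["seed"] = seed

    input_path = Path(input_path)
    if input_path.suffix == ".csv":
        table = io.read_spike_csv(input_path)
        trains = io.spike_trains_from_table(table)
    elif input_path.with_suffix(".json").exists():
        traces = io.read_traces(input_path)
        trains = detect_all(traces, layout, p)
    else:
        raise ValueError(f"cannot read input {input_path}: not a spike CSV or trace container")

    if not trains or all(v.size == 0 for v in trains.values()):
        warnings.warn("empty recording: producing empty result tables", stacklevel=2)
    tunnels = analyse_tunnels(trains, layout, p)
    dynamics, ccd_points = analyse_dynamics(trains, layout, p, tunnels)
    stats = analyse_groups(dynamics, ccd_points, p)
    result = PipelineResult(tunnels=tunnels, dynamics=dynamics,
                            ccd_points=ccd_points, stats=stats, params=p)
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in (("tunnels", result.tunnels), ("dynamics", result.dynamics),
                     ("ccd_points", result.ccd_points)):
        df.to_csv(out / f"{name}.csv", index=False)
    io.write_json(out / "stats.json", result.stats)
    io.write_json(out / "params.json", result.params)
    return out
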