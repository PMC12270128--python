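"""File formats and layout configuration.

Formats are deliberately plain: spike tables are CSV with columns
``electrode_id, unit_id, time_s`` (times in seconds as decimal text, exact
round trip); layouts and parameter snapshots are JSON; voltage traces are a
raw little-endian float32 binary per recording with a JSON sidecar carrying
electrode ids, per-electrode sample offsets, the sampling rate and the
volts-per-unit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import VoltageTrace

__all__ = [
    "TunnelSpec",
    "LayoutConfig",
    "four_tunnel_layout",
    "five_tunnel_layout",
    "write_spike_csv",
    "read_spike_csv",
    "write_layout_json",
    "read_layout_json",
    "write_traces",
    "read_traces",
    "write_json",
    "read_json",
]

REGIONS = ("EC", "DG", "CA3", "CA1")
SPIKE_COLUMNS = ("electrode_id", "unit_id", "time_s")


@dataclass(frozen=True)
class TunnelSpec:
    """One tunnel: two electrodes, the declared region orientation, length."""

    tunnel_id: str
    electrode_a: str  # region_from side (upstream in the declared orientation)
    electrode_b: str  # region_to side
    region_from: str
    region_to: str
    length_um: float = 400.0


@dataclass
class LayoutConfig:
    """Electrode layout: wells per region, tunnels, architecture tag, parameters."""

    wells: dict = field(default_factory=dict)  # region -> [electrode ids]
    tunnels: list = field(default_factory=list)  # of TunnelSpec
    architecture: str = "five_tunnel"
    params: dict = field(default_factory=dict)  # analysis-parameter overrides

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.architecture not in ("four_tunnel", "five_tunnel"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        seen: set[str] = set()
        for region, electrodes in self.wells.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region label {region!r}")
            for e in electrodes:
                if e in seen:
                    raise ValueError(f"electrode {e!r} assigned to multiple roles")
                seen.add(e)
        for t in self.tunnels:
            for r in (t.region_from, t.region_to):
                if r not in REGIONS:
                    raise ValueError(f"unknown region label {r!r} in tunnel {t.tunnel_id}")
            for e in (t.electrode_a, t.electrode_b):
                if e in seen:
                    raise ValueError(f"electrode {e!r} assigned to multiple roles")
                seen.add(e)

    @property
    def tunnel_electrodes(self) -> set:
        return {e for t in self.tunnels for e in (t.electrode_a, t.electrode_b)}

    def role_of(self, electrode_id: str) -> str:
        return "tunnel" if electrode_id in self.tunnel_electrodes else "well"


def _pairs_layout(pairs, architecture, tunnels_per_pair=1, wells_per_region=2, params=None):
    wells = {}
    eid = 0
    for region in REGIONS:
        wells[region] = [f"w_{region}_{i}" for i in range(wells_per_region)]
    tunnels = []
    for region_from, region_to, length in pairs:
        for k in range(tunnels_per_pair):
            tid = f"{region_from}-{region_to}_{k}"
            tunnels.append(TunnelSpec(
                tunnel_id=tid,
                electrode_a=f"t_{tid}_a", electrode_b=f"t_{tid}_b",
                region_from=region_from, region_to=region_to, length_um=length,
            ))
    return LayoutConfig(wells=wells, tunnels=tunnels, architecture=architecture,
                        params=params or {})


def four_tunnel_layout(tunnels_per_pair: int = 1, wells_per_region: int = 2,
                       params=None) -> LayoutConfig:
    """Trisynaptic-loop layout: EC->DG, DG->CA3, CA3->CA1, CA1->EC tunnel sets."""
    pairs = [("EC", "DG", 400.0), ("DG", "CA3", 400.0),
             ("CA3", "CA1", 400.0), ("CA1", "EC", 400.0)]
    return _pairs_layout(pairs, "four_tunnel", tunnels_per_pair, wells_per_region, params)


def five_tunnel_layout(tunnels_per_pair: int = 1, wells_per_region: int = 2,
                       params=None) -> LayoutConfig:
    """Four-tunnel layout plus the diagonal EC->CA3 perforant-path tunnels (400-600 um)."""
    layout = four_tunnel_layout(tunnels_per_pair, wells_per_region, params)
    tunnels = list(layout.tunnels)
    for k in range(tunnels_per_pair):
        tid = f"EC-CA3_{k}"
        tunnels.append(TunnelSpec(tunnel_id=tid, electrode_a=f"t_{tid}_a",
                                  electrode_b=f"t_{tid}_b", region_from="EC",
                                  region_to="CA3", length_um=500.0))
    return LayoutConfig(wells=layout.wells, tunnels=tunnels,
                        architecture="five_tunnel", params=layout.params)


# ---------------------------------------------------------------------------
# spike CSV

def write_spike_csv(path, table):
    """Write a spike table (DataFrame or electrode->times mapping) as CSV.

    Times are written with Python's shortest-exact float representation, so a
    read-back reproduces the in-memory values bit for bit (well beyond the
    microsecond precision a 25 kHz recording requires).
    """
    if isinstance(table, dict):
        rows = []
        for e in sorted(table):
            times = np.asarray(table[e], dtype=float)
            rows.append(pd.DataFrame({"electrode_id": e, "unit_id": 0, "time_s": times}))
        df = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=list(SPIKE_COLUMNS)))
    else:
        df = table.loc[:, list(SPIKE_COLUMNS)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(SPIKE_COLUMNS) + "\n")
        for e, u, t in df.itertuples(index=False):
            fh.write(f"{e},{u},{t!r}\n")
    return path


def read_spike_csv(path) -> pd.DataFrame:
    """Read a spike CSV, raising a descriptive error naming the bad line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != list(SPIKE_COLUMNS):
            raise ValueError(f"{path}: line 1: expected header {','.join(SPIKE_COLUMNS)}")
        electrode, unit, time = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                unit.append(int(parts[1]))
                time.append(float(parts[2]))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed row {line!r}") from None
            electrode.append(parts[0])
    return pd.DataFrame({"electrode_id": electrode, "unit_id": unit, "time_s": time})


def spike_trains_from_table(df: pd.DataFrame) -> dict:
    """Electrode -> sorted spike-time array (units merged per electrode)."""
    return {e: np.sort(g["time_s"].to_numpy())
            for e, g in df.groupby("electrode_id", sort=True)}


# ---------------------------------------------------------------------------
# layout JSON

def write_layout_json(path, layout: LayoutConfig):
    obj = {
        "architecture": layout.architecture,
        "wells": {r: list(v) for r, v in sorted(layout.wells.items())},
        "tunnels": [asdict(t) for t in layout.tunnels],
        "params": layout.params,
    }
    return write_json(path, obj)


def read_layout_json(path) -> LayoutConfig:
    obj = read_json(path)
    tunnels = [TunnelSpec(**t) for t in obj.get("tunnels", [])]
    return LayoutConfig(wells=obj.get("wells", {}), tunnels=tunnels,
                        architecture=obj.get("architecture", "five_tunnel"),
                        params=obj.get("params", {}))


# ---------------------------------------------------------------------------
# trace container: one float32 .bin + JSON sidecar

def write_traces(prefix, traces: dict, volts_per_unit: float = 1.0):
    """Write traces as ``<prefix>.bin`` (concatenated float32) + ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    order = sorted(traces)
    sidecar = {"electrodes": [], "volts_per_unit": volts_per_unit}
    offset = 0
    with open(prefix.with_suffix(".bin"), "wb") as fh:
        for e in order:
            tr = traces[e]
            x = (tr.samples / volts_per_unit).astype("<f4")
            x.tofile(fh)
            sidecar["electrodes"].append({
                "electrode_id": e, "offset": offset, "n_samples": int(x.size),
                "sampling_rate": tr.sampling_rate, "electrode_role": tr.electrode_role,
            })
            offset += int(x.size)
    write_json(prefix.with_suffix(".json"), sidecar)
    return prefix


def read_traces(prefix) -> dict:
    prefix = Path(prefix)
    sidecar = read_json(prefix.with_suffix(".json"))
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype="<f4")
    vpu = sidecar["volts_per_unit"]
    out = {}
    for rec in sidecar["electrodes"]:
        x = raw[rec["offset"]: rec["offset"] + rec["n_samples"]].astype(float) * vpu
        out[rec["electrode_id"]] = VoltageTrace(
            samples=x, sampling_rate=rec["sampling_rate"],
            electrode_id=rec["electrode_id"], electrode_role=rec["electrode_role"],
        )
    return out


# ---------------------------------------------------------------------------
# JSON helpers

def write_json(path, obj):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
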