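"""File I/O: HDF5 / CSV trace sets, YAML/JSON configs, metrics tables.

HDF5 layout: one group per unique label combination (protocol phase /
background / delay / location), each holding a trial x time ``data`` dataset,
the protocol and labels as JSON attributes, and optional noiseless component
datasets.  Round trips preserve sample values bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import (BarPattern, Flash, PerPhotonGain, ResponseTrace,
                       SimulationConfig, StimulusProtocol, TraceSet, WeberGain)

__all__ = [
    "write_traces", "read_traces", "write_traces_csv",
    "write_table", "read_table",
    "config_to_dict", "config_from_dict", "load_config", "save_config",
]


# --------------------------------------------------------------------------
# config serialization (field names mirror SimulationConfig / StimulusProtocol)
# --------------------------------------------------------------------------

def _gain_law_to_dict(law):
    if law is None:
        return "none"
    if isinstance(law, WeberGain):
        return {"weber": {"G_D": law.G_D, "I_0": law.I_0}}
    if isinstance(law, PerPhotonGain):
        return {"per_photon": {"alpha": law.alpha,
                               "tau_recovery": law.tau_recovery,
                               "recovery": law.recovery}}
    raise TypeError(f"unknown gain law {law!r}")


def _gain_law_from_dict(d):
    if d in (None, "none"):
        return None
    if not isinstance(d, dict) or len(d) != 1:
        raise ValueError(f"malformed gain_law entry: {d!r}")
    (name, kw), = d.items()
    if name == "weber":
        return WeberGain(**kw)
    if name == "per_photon":
        return PerPhotonGain(**kw)
    raise ValueError(f"unknown gain_law {name!r}; valid: weber, per_photon, none")


def config_to_dict(config: SimulationConfig) -> dict:
    d = {k: getattr(config, k) for k in
         ("n_rods", "sampling_rate", "trial_duration", "spr_amplitude",
          "spr_time_to_peak", "continuous_noise_sd", "noise_cutoff_hz", "seed")}
    d["gain_law"] = _gain_law_to_dict(config.gain_law)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["gain_law"] = _gain_law_from_dict(d.get("gain_law"))
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return SimulationConfig(**d)


def load_config(path) -> dict:
    """Load a YAML or JSON experiment config into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


# --------------------------------------------------------------------------
# protocol serialization
# --------------------------------------------------------------------------

def _protocol_to_dict(p: StimulusProtocol) -> dict:
    d = {"background_segments": [list(s) for s in p.background_segments],
         "flashes": [[f.time, f.strength, f.location_id] for f in p.flashes],
         "channel": p.channel}
    if p.spatial_pattern is not None:
        sp = p.spatial_pattern
        d["spatial_pattern"] = {"bar_width": sp.bar_width,
                                "intensity": sp.intensity, "phase": sp.phase}
    return d


def _protocol_from_dict(d: dict) -> StimulusProtocol:
    sp = d.get("spatial_pattern")
    return StimulusProtocol(
        [tuple(s) for s in d["background_segments"]],
        [Flash(*f) for f in d.get("flashes", [])],
        BarPattern(**sp) if sp else None,
        d.get("channel", "short_wavelength"))


# --------------------------------------------------------------------------
# trace sets
# --------------------------------------------------------------------------

def _group_key(labels: dict) -> str:
    return json.dumps(labels, sort_keys=True, default=str)


def write_traces(traceset: TraceSet, path) -> None:
    """Write a trace set to HDF5 (one group per unique label combination)."""
    groups: dict[str, list[ResponseTrace]] = {}
    for tr in traceset.traces:
        groups.setdefault(_group_key(tr.labels), []).append(tr)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = traceset.kind
        f.attrs["params"] = json.dumps(traceset.params)
        if traceset.seed is not None:
            f.attrs["seed"] = int(traceset.seed)
        for i, (key, trs) in enumerate(sorted(groups.items())):
            g = f.create_group(f"group_{i:04d}")
            g.attrs["labels"] = key
            g.attrs["dt"] = trs[0].dt
            g.attrs["protocol"] = json.dumps(_protocol_to_dict(trs[0].protocol))
            if trs[0].ground_truth is not None:
                cfg = config_to_dict(trs[0].ground_truth)
                g.attrs["ground_truth"] = json.dumps(cfg)
            g.create_dataset("data", data=np.stack([t.samples for t in trs]))
            g.create_dataset("trial_index",
                             data=np.array([t.trial_index for t in trs]))
            for name, comp in trs[0].components.items():
                g.create_dataset(f"component_{name}", data=comp)


def read_traces(path) -> TraceSet:
    """Read a trace set written by :func:`write_traces`."""
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise ValueError(f"cannot parse {path} as an HDF5 trace file: {err}") from None
    with f:
        traces = []
        for name in sorted(k for k in f.keys() if k.startswith("group_")):
            g = f[name]
            labels = json.loads(g.attrs["labels"])
            proto = _protocol_from_dict(json.loads(g.attrs["protocol"]))
            gt = (config_from_dict(json.loads(g.attrs["ground_truth"]))
                  if "ground_truth" in g.attrs else None)
            data = g["data"][...]
            idx = g["trial_index"][...]
            comps = {k.removeprefix("component_"): g[k][...]
                     for k in g.keys() if k.startswith("component_")}
            for row, ti in zip(data, idx):
                traces.append(ResponseTrace(row, float(g.attrs["dt"]), proto,
                                            int(ti), gt, dict(labels),
                                            dict(comps)))
        return TraceSet(str(f.attrs["kind"]), traces,
                        json.loads(f.attrs["params"]),
                        int(f.attrs["seed"]) if "seed" in f.attrs else None)


def write_traces_csv(traceset: TraceSet, path) -> None:
    """Long-format CSV export: one row per (trial, sample)."""
    frames = []
    for j, tr in enumerate(traceset.traces):
        frames.append(pd.DataFrame({
            "trace": j, "trial": tr.trial_index, "t": tr.time,
            "value": tr.samples,
            "labels": json.dumps(tr.labels, sort_keys=True, default=str)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

METRICS_COLUMNS = ["background", "gain", "gain_sd", "noise_sd", "threshold",
                   "n_trials"]


def write_table(records: pd.DataFrame, path, columns=None) -> None:
    """Write a metrics table as CSV with 12 significant digits."""
    if columns is not None:
        missing = set(columns) - set(records.columns)
        if missing:
            raise ValueError(f"records missing required columns: {sorted(missing)}")
        records = records[list(columns)]
    records.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"cannot parse {path} as a CSV table: {err}") from None
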