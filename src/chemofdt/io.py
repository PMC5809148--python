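"""File-format plumbing: trace CSVs, ensemble manifests, result tables.

Everything is plain CSV + JSON so runs diff cleanly and tests can inspect
outputs; each written artifact carries a JSON sidecar (or embedded fields)
with the seed, a config hash and the package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .synthetic_data import Ensemble, FRETTrace, StimulusProtocol

__all__ = [
    "config_hash",
    "write_ensemble",
    "read_ensemble",
    "write_activity_trace",
    "write_psd_csv",
    "write_json",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(seed, config) -> dict:
    return {"seed": seed, "config_hash": config_hash(config or {}),
            "version": __version__}


def write_ensemble(ensemble: Ensemble, outdir, config=None) -> Path:
    """Write per-cell trace CSVs (time_s, cfp, yfp, ratio) plus a JSON
    manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, tr in enumerate(ensemble.traces):
        name = f"{ensemble.fixture_name or 'trace'}_{i:04d}.csv"
        df = pd.DataFrame({"time_s": tr.time, "ratio": tr.ratio})
        if tr.cfp is not None:
            df.insert(1, "cfp", tr.cfp)
            df.insert(2, "yfp", tr.yfp)
        df.to_csv(outdir / name, index=False, float_format="%.10g")
        files.append(name)
    manifest = {
        "fixture": ensemble.fixture_name,
        "seed": ensemble.seed,
        "n_cells": len(ensemble.traces),
        "duration_s": ensemble.duration,
        "protocol": (
            {"events": [[t, lvl] for t, lvl in ensemble.protocol.events],
             "flow_delay_s": ensemble.protocol.flow_delay_s}
            if ensemble.protocol else None),
        "activity_map": ensemble.activity_map,
        "params": ensemble.params,
        "files": files,
        "provenance": _provenance(ensemble.seed, config),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path


def read_ensemble(manifest_path) -> Ensemble:
    manifest_path = Path(manifest_path)
    m = json.loads(manifest_path.read_text())
    traces = []
    for name in m["files"]:
        df = pd.read_csv(manifest_path.parent / name)
        traces.append(FRETTrace(
            time=df["time_s"].to_numpy(float),
            ratio=df["ratio"].to_numpy(float),
            cfp=df["cfp"].to_numpy(float) if "cfp" in df else None,
            yfp=df["yfp"].to_numpy(float) if "yfp" in df else None,
            cell_id=Path(name).stem, fixture_name=m.get("fixture", "")))
    protocol = None
    if m.get("protocol"):
        protocol = StimulusProtocol(
            events=[tuple(e) for e in m["protocol"]["events"]],
            flow_delay_s=m["protocol"].get("flow_delay_s", 0.0))
    return Ensemble(traces=traces, fixture_name=m.get("fixture", ""),
                    seed=m.get("seed"), protocol=protocol,
                    activity_map=m.get("activity_map"),
                    duration=m.get("duration_s", 0.0),
                    params=m.get("params", {}))


def write_activity_trace(trace, path, params=None, seed=None) -> None:
    """ActivityTrace CSV (time_s, activity, n_bound_R, n_bound_B) with a
    JSON sidecar of the array-model parameters and seed."""
    path = Path(path)
    pd.DataFrame({
        "time_s": trace.time, "activity": trace.A,
        "n_bound_R": trace.n_bound_R, "n_bound_B": trace.n_bound_B,
    }).to_csv(path, index=False, float_format="%.10g")
    side = {"seed": seed if seed is not None else trace.seed,
            "params": (params.to_dict() if params is not None
                       else (trace.params.to_dict() if trace.params else None))}
    path.with_suffix(".json").write_text(json.dumps(side, indent=1, default=str))


def write_psd_csv(psd, path) -> None:
    pd.DataFrame({"freq_hz": psd.freq, "psd": psd.s, "sem": psd.sem}).to_csv(
        Path(path), index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
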