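"""Artifact readers/writers: rasters, trial-result tables, run manifests.

Everything is plain delimited text or JSON so runs remain diffable and
portable; a manifest captures the resolved configuration and per-trial
seeds, which is sufficient to bit-reproduce any trial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoding import TrialResult
from .simulator import SpikeRaster

RESULT_COLUMNS = ("trial_index", "theta_S", "theta_D", "theta_R", "modulus_C",
                  "precue_modulus", "outcome", "flagged")


def write_raster(path, raster: SpikeRaster) -> None:
    """Raster as CSV with columns time_ms, neuron, population."""
    df = pd.DataFrame({"time_ms": raster.times, "neuron": raster.neuron,
                       "population": raster.population})
    df.to_csv(path, index=False, float_format="%.2f")


def read_raster(path) -> SpikeRaster:
    try:
        df = pd.read_csv(path)
        return SpikeRaster(times=df["time_ms"].to_numpy(dtype=float),
                           neuron=df["neuron"].to_numpy(dtype=int),
                           population=df["population"].to_numpy(dtype="U1"))
    except (KeyError, ValueError) as err:
        raise ValueError(f"malformed raster file {path}: {err}") from err


def write_results(path, results: list[TrialResult]) -> None:
    """Trial results, one row per trial (delay rates are not serialized)."""
    rows = []
    for r in results:
        rows.append({c: getattr(r, c) for c in RESULT_COLUMNS})
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, index=False)


def read_results(path) -> list[TrialResult]:
    try:
        df = pd.read_csv(path)
        out = []
        for _, row in df.iterrows():
            theta_d = row["theta_D"]
            out.append(TrialResult(
                trial_index=int(row["trial_index"]),
                theta_S=float(row["theta_S"]),
                theta_D=None if pd.isna(theta_d) else float(theta_d),
                theta_R=float(row["theta_R"]),
                modulus_C=float(row["modulus_C"]),
                precue_modulus=float(row["precue_modulus"]),
                outcome=str(row["outcome"]),
                flagged=bool(row["flagged"])))
        return out
    except (KeyError, ValueError) as err:
        raise ValueError(f"malformed results file {path}: {err}") from err


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path, *, config: dict, master_seed: int, trial_indices,
                   artifact_hashes: dict | None = None) -> dict:
    """Run manifest: resolved config, seed bookkeeping, artifact checksums."""
    manifest = {
        "package_version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "master_seed": int(master_seed),
        "trial_indices": [int(t) for t in np.asarray(trial_indices)],
        "seed_scheme": "numpy SeedSequence((master_seed, trial_index))",
        "config": _jsonable(config),
        "artifacts": artifact_hashes or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def verify_manifest(path) -> bool:
    """Recompute artifact checksums; False if any file was tampered with."""
    manifest = read_manifest(path)
    base = Path(path).parent
    for name, digest in manifest.get("artifacts", {}).items():
        target = base / name
        if not target.exists() or file_sha256(target) != digest:
            return False
    return True
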