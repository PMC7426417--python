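"""CSV/JSON/YAML serialization for trajectories, configs and reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit_model import CircuitSpec, KineticParams, Trajectory
from .errors import ValidationError

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_yaml",
    "read_yaml",
    "file_sha256",
]


def write_trajectory_csv(path, traj: Trajectory, sidecar: bool = True) -> None:
    """Trajectory table plus a JSON sidecar with the spec and parameters."""
    traj.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "circuit": {k: (v.value if hasattr(v, "value") else v)
                        for k, v in dataclasses.asdict(traj.spec).items()},
            "params": traj.params.to_dict(),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"time_min", "erk", "damage", "Z", "mRNA", "protein"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trajectory CSV must have columns {sorted(required)}")
    site_cols = sorted((c for c in df.columns if c.startswith("T_site")),
                       key=lambda c: int(c.removeprefix("T_site")))
    if not site_cols:
        raise ValidationError("trajectory CSV has no T_site columns")
    meta_path = Path(str(path) + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        spec = CircuitSpec(**meta["circuit"])
        params = KineticParams.from_dict(meta["params"])
    else:
        spec = CircuitSpec(n_sites=len(site_cols))
        params = KineticParams()
    return Trajectory(
        time_grid=df["time_min"].to_numpy(float),
        erk=df["erk"].to_numpy(float),
        damage=df["damage"].to_numpy(float),
        repressor=df["Z"].to_numpy(float),
        tx_rates=np.vstack([df[c].to_numpy(float) for c in site_cols]),
        mrna=df["mRNA"].to_numpy(float),
        protein=df["protein"].to_numpy(float),
        spec=spec,
        params=params,
    )


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValidationError(f"{path} does not contain a mapping")
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
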