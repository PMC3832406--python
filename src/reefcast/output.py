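"""Result serialisation: delimited tables, forcing audit logs, manifests.

Every run writes a deterministic tree of delimited text files plus a
manifest listing each file with its SHA-256 content digest, so a rerun
from the same configuration and seed is byte-identical and any corruption
is detectable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import STATE_VARIABLES, Trajectory
from .scenarios import EnsembleResult

__all__ = [
    "trajectory_frame",
    "ensemble_frame",
    "forcing_audit",
    "write_results",
    "verify_manifest",
]


def trajectory_frame(traj: Trajectory, replicate: int = 0,
                     every_days: int = 1) -> pd.DataFrame:
    """Long-format (replicate, day, variable, value) table of one run."""
    days = np.asarray(traj.days)[::every_days]
    states = traj.states[::every_days]
    if states.ndim != 2:
        raise ValueError("expected a single-run trajectory (days x variables)")
    return pd.DataFrame({
        "replicate": np.repeat(replicate, len(days) * len(STATE_VARIABLES)),
        "day": np.repeat(days, len(STATE_VARIABLES)),
        "variable": np.tile(STATE_VARIABLES, len(days)),
        "value": states.ravel(),
    })


def ensemble_frame(ensemble: EnsembleResult, every_days: int = 365) -> pd.DataFrame:
    """Long-format table of all replicates of an ensemble (default: one
    record per variable per year)."""
    frames = [
        trajectory_frame(ensemble.replicate(i), replicate=i, every_days=every_days)
        for i in range(ensemble.n_replicates)
    ]
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "scenario", ensemble.scenario.label)
    out.insert(1, "site", ensemble.site_label)
    return out


def forcing_audit(ensemble: EnsembleResult) -> pd.DataFrame:
    """Realised forcing draws per replicate: seeds, scalars, schedules."""
    rows = []
    for i, fs in enumerate(ensemble.forcing_sets):
        row = {
            "scenario": ensemble.scenario.label,
            "site": ensemble.site_label,
            "replicate": i,
            "seed": ensemble.replicate_seeds[i],
            "fishing_total": fs.fishing_total,
            "water_quality_poor": fs.water_quality_poor,
            "turf_growth_scale": fs.nutrient.turf_growth_scale if fs.nutrient else "",
            "macroalgae_growth_scale":
                fs.nutrient.macroalgae_growth_scale if fs.nutrient else "",
            "coral_growth_reduction":
                fs.sediment.coral_growth_reduction if fs.sediment else "",
            "coral_recruit_reduction":
                fs.sediment.coral_recruit_reduction if fs.sediment else "",
            "coral_mortality_increase":
                fs.sediment.coral_mortality_increase if fs.sediment else "",
            "bleaching_schedule": ";".join(
                f"{y}:{s:.6f}" for y, s in fs.bleaching_schedule
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(outputs: dict[str, pd.DataFrame | str], directory: str | Path) -> dict:
    """Write named outputs under ``directory`` and return the manifest.

    DataFrames are written as CSV (name.csv); strings as text (name.txt).
    The manifest (manifest.json) lists every file with its SHA-256 digest;
    identical runs produce identical digests.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {directory} is not writable: {exc}") from exc

    manifest: dict[str, dict] = {"files": {}}
    for name in sorted(outputs):
        value = outputs[name]
        if isinstance(value, pd.DataFrame):
            path = directory / f"{name}.csv"
            value.to_csv(path, index=False, lineterminator="\n")
        else:
            path = directory / f"{name}.txt"
            path.write_text(str(value))
        manifest["files"][path.name] = {
            "sha256": _digest(path),
            "bytes": path.stat().st_size,
        }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def verify_manifest(directory: str | Path) -> list[str]:
    """Return the names of files whose content digest no longer matches."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bad = []
    for name, meta in manifest["files"].items():
        path = directory / name
        if not path.exists() or _digest(path) != meta["sha256"]:
            bad.append(name)
    return bad
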