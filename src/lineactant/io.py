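"""Output management: CSV series, HDF5 snapshots, run manifests."""

from __future__ import annotations

import hashlib
import json
import pathlib
from datetime import datetime, timezone

import h5py
import numpy as np

from .engine import ReplicateSet, Trajectory

__all__ = ["write_outputs", "write_snapshots", "read_snapshots"]

SERIES_COLUMNS = [
    "L", "phi", "frac_tiles_at_line", "n_domains_minority",
    "n_domains_minority_unfiltered", "n_up", "n_down",
]


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def write_snapshots(traj: Trajectory, path: pathlib.Path) -> None:
    """Spin snapshots (frames x sites, int8) and cycle indices to HDF5."""
    if traj.snapshots is None:
        raise ValueError("trajectory was run without record_snapshots")
    with h5py.File(path, "w") as f:
        f.create_dataset("spins", data=traj.snapshots, compression="gzip")
        f.create_dataset("cycles", data=np.asarray(traj.cycles))
        f.attrs["width"] = traj.spec.width
        f.attrs["height"] = traj.spec.height
        f.attrs["layout"] = traj.layout_name or "none"
        f.attrs["j"] = traj.params.j
        f.attrs["ratio"] = traj.params.ratio
        f.attrs["sigma"] = traj.params.sigma


def read_snapshots(path: pathlib.Path):
    """Snapshots, cycles and box shape from a simulate HDF5 file."""
    with h5py.File(path, "r") as f:
        spins = f["spins"][...]
        cycles = f["cycles"][...]
        shape = (int(f.attrs["width"]), int(f.attrs["height"]))
    return spins, cycles, shape


def write_outputs(
    result: ReplicateSet | Trajectory,
    out_dir: str | pathlib.Path,
    config_text: str = "",
) -> dict:
    """Write trajectory CSVs (and snapshots, when recorded) plus a manifest.

    The manifest records input hash, seeds and file list; re-running the
    same configuration reproduces byte-identical CSV/JSON (the manifest
    timestamp aside).
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajectories = (
        result.trajectories if isinstance(result, ReplicateSet) else [result]
    )
    files: list[str] = []
    for i, traj in enumerate(trajectories):
        name = f"trajectory_{i:03d}.csv"
        frame = traj.frame.reset_index()[["cycle"] + SERIES_COLUMNS]
        frame.to_csv(out / name, index=False)
        files.append(name)
        if traj.snapshots is not None:
            sname = f"snapshots_{i:03d}.h5"
            write_snapshots(traj, out / sname)
            files.append(sname)
    if isinstance(result, ReplicateSet):
        result.aggregate.reset_index().to_csv(out / "aggregate.csv", index=False)
        files.append("aggregate.csv")
    meta = {
        "n_replicates": len(trajectories),
        "seeds": [t.seed_entropy for t in trajectories],
        "layout": trajectories[0].layout_name,
        "lattice": [trajectories[0].spec.width, trajectories[0].spec.height],
        "params": {
            "j": trajectories[0].params.j,
            "j_st": trajectories[0].params.j_st,
            "j_dc": trajectories[0].params.j_dc,
            "ratio": trajectories[0].params.ratio,
            "sigma": trajectories[0].params.sigma,
        },
        "schedule": {
            "t_mc": trajectories[0].schedule.t_mc,
            "stride": trajectories[0].schedule.stride,
            "deactivate_at": trajectories[0].schedule.deactivate_at,
        },
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    files.append("run_meta.json")
    manifest = {
        "config_sha256": _sha256(config_text),
        "files": files,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
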