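"""Reading and writing session directories.

A session lives in one directory:

    <session>/
      meta.json            arena size, duration, sampling rates, label
      position.csv         columns t, x, y  (s, cm, cm)
      spikes/unit_<id>.csv column t         (s)
      waveforms/unit_<id>.csv  column uv    (µV, mean waveform; optional)
      lfp/ch<k>.csv        columns t, uv   (s, µV)

All files are plain text; re-writing the same in-memory objects reproduces
byte-identical output, which the pipeline relies on for determinism checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ExperimentConfig, LdlExperiment, SessionData
from .types import ArenaSpec, InputError, LfpTrace, SpikeTrain, Trajectory

__all__ = [
    "write_session",
    "load_session",
    "write_experiment",
    "load_manifest",
    "export_rate_map_csv",
    "export_rate_map_png",
]

_FLOAT_FMT = "%.6f"


def write_session(session: SessionData, out_dir: str | Path) -> Path:
    """Write one session to ``out_dir`` in the standard layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spikes").mkdir(exist_ok=True)
    (out / "lfp").mkdir(exist_ok=True)

    meta = {
        "label": session.label,
        "arena": {"width": session.arena.width, "height": session.arena.height},
        "duration": session.duration,
        "position_fs": float(
            1.0 / np.median(np.diff(session.trajectory.t))
        ),
        "lfp_fs": {name: trace.fs for name, trace in sorted(session.lfp.items())},
        "waveform_fs": {
            uid: train.waveform_fs
            for uid, train in sorted(session.spikes.items())
            if train.waveform is not None
        },
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")

    traj = session.trajectory
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        out / "position.csv", index=False, float_format=_FLOAT_FMT
    )
    for uid, train in sorted(session.spikes.items()):
        pd.DataFrame({"t": train.times}).to_csv(
            out / "spikes" / f"unit_{uid}.csv", index=False, float_format=_FLOAT_FMT
        )
        if train.waveform is not None:
            (out / "waveforms").mkdir(exist_ok=True)
            pd.DataFrame({"uv": train.waveform}).to_csv(
                out / "waveforms" / f"unit_{uid}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )
    for name, trace in sorted(session.lfp.items()):
        t = np.arange(trace.samples.size) / trace.fs
        pd.DataFrame({"t": t, "uv": trace.samples}).to_csv(
            out / "lfp" / f"{name}.csv", index=False, float_format="%.4f"
        )
    return out


def load_session(session_dir: str | Path) -> SessionData:
    """Load a session directory written by :func:`write_session`.

    Spike times beyond the trajectory span are clipped (they cannot be
    assigned a position); an empty spike file yields a unit with no spikes.
    """
    d = Path(session_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise InputError(f"missing meta.json in {d}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"ill-formed {meta_path}: {exc}") from exc

    pos_path = d / "position.csv"
    if not pos_path.exists():
        raise InputError(f"missing position.csv in {d}")
    pos = pd.read_csv(pos_path)
    for col in ("t", "x", "y"):
        if col not in pos.columns:
            raise InputError(f"{pos_path}: missing column {col!r}")
    traj = Trajectory(pos["t"].to_numpy(), pos["x"].to_numpy(), pos["y"].to_numpy())

    arena = ArenaSpec(**meta["arena"])
    waveform_fs = meta.get("waveform_fs", {})

    spikes: dict[str, SpikeTrain] = {}
    spikes_dir = d / "spikes"
    if spikes_dir.exists():
        for path in sorted(spikes_dir.glob("unit_*.csv")):
            uid = path.stem.removeprefix("unit_")
            frame = pd.read_csv(path)
            times = frame["t"].to_numpy() if "t" in frame.columns else np.empty(0)
            times = times[(times >= traj.t[0]) & (times <= traj.t[-1])]
            waveform = None
            wf_path = d / "waveforms" / path.name
            if wf_path.exists():
                waveform = pd.read_csv(wf_path)["uv"].to_numpy()
            spikes[uid] = SpikeTrain(
                times=np.sort(times),
                waveform=waveform,
                waveform_fs=waveform_fs.get(uid),
                unit_id=uid,
            )

    lfp: dict[str, LfpTrace] = {}
    lfp_dir = d / "lfp"
    if lfp_dir.exists():
        fs_map = meta.get("lfp_fs", {})
        for path in sorted(lfp_dir.glob("ch*.csv")):
            frame = pd.read_csv(path)
            name = path.stem
            fs = fs_map.get(name)
            if fs is None:
                dt = np.median(np.diff(frame["t"].to_numpy()))
                fs = 1.0 / dt
            lfp[name] = LfpTrace(samples=frame["uv"].to_numpy(), fs=float(fs))

    return SessionData(
        label=meta.get("label", d.name),
        arena=arena,
        duration=float(meta["duration"]),
        trajectory=traj,
        spikes=spikes,
        lfp=lfp,
    )


def write_experiment(experiment: LdlExperiment, out_dir: str | Path) -> Path:
    """Write all three sessions plus a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, session in experiment.sessions.items():
        write_session(session, out / label)
    manifest = {
        "seed": experiment.seed,
        "config": _config_dict(experiment.config),
        "true_coms": {
            uid: {lab: list(com) for lab, com in coms.items()}
            for uid, coms in sorted(experiment.true_coms.items())
        },
        "unit_kinds": dict(sorted(experiment.unit_kinds.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d


def export_rate_map_csv(rate_map, path: str | Path, grid: str = "rate_smooth") -> Path:
    """Write one grid of a rate map (``rate_smooth`` by default) as CSV.

    Rows run south to north (row i is the bins centred at y = (i+0.5)*bin),
    columns west to east; invalid bins are empty cells.
    """
    values = getattr(rate_map, grid)
    path = Path(path)
    pd.DataFrame(values).to_csv(path, index=False, header=False, float_format="%.6f")
    return path


def export_rate_map_png(rate_map, path: str | Path, grid: str = "rate_smooth") -> Path:
    """Render a rate-map grid as a heatmap PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = getattr(rate_map, grid)
    fig, ax = plt.subplots(figsize=(4, 4))
    ny, nx = values.shape
    extent = (
        rate_map.origin[0],
        rate_map.origin[0] + nx * rate_map.bin_size,
        rate_map.origin[1],
        rate_map.origin[1] + ny * rate_map.bin_size,
    )
    im = ax.imshow(values, origin="lower", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, label="rate (Hz)")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    path = Path(path)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def load_manifest(exp_dir: str | Path) -> dict:
    path = Path(exp_dir) / "manifest.json"
    if not path.exists():
        raise InputError(f"missing manifest.json in {exp_dir}")
    return json.loads(path.read_text())
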