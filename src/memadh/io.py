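"""Configuration files and trajectory containers.

Run configuration is one YAML document with two sections, ``model`` and
``schedule``, whose keys mirror :class:`~memadh.model.ModelParams` and
:class:`~memadh.mc.McSchedule`. Omitted keys take the package defaults;
unknown keys are rejected so that typos fail loudly.

Trajectories are stored one-per-file in HDF5: all parameters and the seed
in root attributes, scalar series, snapshots and the event trace as named
datasets. A ``complete`` attribute written last marks a fully flushed file,
so truncated files from crashed runs are detected on read. The event trace
can additionally be exported to flat CSV (columns ``time_cycles``,
``n_after``) for analysis outside the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .mc import McSchedule, Trajectory
from .model import ModelParams, SystemState

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "export_events_csv",
    "import_events_csv",
]

FORMAT_VERSION = "1"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated model + schedule pair loaded from one config file."""

    params: ModelParams
    schedule: McSchedule

    def to_dict(self) -> dict:
        return {
            "model": dataclasses.asdict(self.params),
            "schedule": dataclasses.asdict(self.schedule),
        }


def _build(section: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}' section: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid '{section}' configuration: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file = all defaults."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"cannot read config file {path}: {exc}") from exc
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"model", "schedule"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    params = _build("model", ModelParams, data.get("model") or {})
    schedule = _build("schedule", McSchedule, data.get("schedule") or {})
    return RunConfig(params=params, schedule=schedule)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Persist a run losslessly to HDF5; the ``complete`` flag is written last."""
    with h5py.File(path, "w") as f:
        from . import __version__

        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        f.attrs["nb_initial"] = traj.nb_initial
        for key, val in dataclasses.asdict(traj.params).items():
            f.attrs[f"model/{key}"] = "none" if val is None else val
        for key, val in dataclasses.asdict(traj.schedule).items():
            f.attrs[f"schedule/{key}"] = val
        for key, val in traj.acceptance.items():
            f.attrs[f"acceptance/{key}"] = val
        for name in (
            "sample_cycles", "sample_nb", "sample_mean_l", "sample_mean_l2",
            "snapshot_cycles", "snapshot_counts", "snapshot_sites",
            "event_times", "event_nb", "event_channel",
        ):
            f.create_dataset(name, data=getattr(traj, name))
        if traj.final_state is not None:
            f.create_dataset("final_l", data=traj.final_state.l)
            f.create_dataset("final_n", data=traj.final_state.n)
        f.attrs["complete"] = True


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory container; refuses truncated or mismatched files."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"trajectory format version {version!r} != supported {FORMAT_VERSION!r}"
            )
        if not f.attrs.get("complete", False):
            raise ValueError(f"truncated trajectory file (incomplete run): {path}")
        model_kwargs = {}
        schedule_kwargs = {}
        acceptance = {}
        for key, val in f.attrs.items():
            if key.startswith("model/"):
                name = key.split("/", 1)[1]
                if isinstance(val, str) and val == "none":
                    val = None
                elif isinstance(val, np.bool_):
                    val = bool(val)
                elif isinstance(val, np.integer):
                    val = int(val)
                elif isinstance(val, np.floating):
                    val = float(val)
                model_kwargs[name] = val
            elif key.startswith("schedule/"):
                name = key.split("/", 1)[1]
                schedule_kwargs[name] = (
                    float(val) if isinstance(val, np.floating) else int(val)
                )
            elif key.startswith("acceptance/"):
                acceptance[key.split("/", 1)[1]] = (
                    float(val) if isinstance(val, np.floating) else int(val)
                )
        arrays = {
            name: f[name][()]
            for name in (
                "sample_cycles", "sample_nb", "sample_mean_l", "sample_mean_l2",
                "snapshot_cycles", "snapshot_counts", "snapshot_sites",
                "event_times", "event_nb", "event_channel",
            )
        }
        final = None
        if "final_l" in f:
            final = SystemState(l=f["final_l"][()], n=f["final_n"][()])
        return Trajectory(
            params=ModelParams(**model_kwargs),
            schedule=McSchedule(**schedule_kwargs),
            nb_initial=int(f.attrs["nb_initial"]),
            acceptance=acceptance,
            final_state=final,
            **arrays,
        )


def export_events_csv(traj: Trajectory, path: str | Path) -> None:
    """Flat CSV of the bond-change event trace: time_cycles, n_after, channel."""
    pd.DataFrame(
        {
            "time_cycles": traj.event_times,
            "n_after": traj.event_nb,
            "channel": traj.event_channel,
        }
    ).to_csv(path, index=False)


def import_events_csv(path: str | Path):
    """Read an exported event CSV back as (times, n_after, channel) arrays."""
    df = pd.read_csv(path)
    channel = (
        df["channel"].to_numpy(np.int8) if "channel" in df.columns else None
    )
    return (
        df["time_cycles"].to_numpy(np.float64),
        df["n_after"].to_numpy(np.int64),
        channel,
    )
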