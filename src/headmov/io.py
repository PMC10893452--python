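"""Readers and writers for trace, marker, event and config files.

All formats are delimited text (CSV with a header row); times are seconds
with 6 decimal places, angles degrees.  Trace files carry either
quaternion columns (``time_s, qw, qx, qy, qz``) or engine Euler columns
(``time_s, rx_deg, ry_deg, rz_deg``), auto-detected from the header.
Event files use one schema for every producer — algorithms and human
raters alike: ``subject, block, algorithm, onset_s, offset_s, direction,
amplitude_deg, peak_velocity_deg_s``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import (
    BmatConfig,
    CwConfig,
    DizcoConfig,
    MovementEvent,
    SvtConfig,
    TreeConfig,
)
from .kinematics import OrientationTrace, euler_to_quat, quat_to_euler

__all__ = [
    "read_trace",
    "write_trace",
    "read_markers",
    "write_markers",
    "read_events",
    "write_events",
    "events_to_frame",
    "frame_to_events",
    "load_config",
    "save_config",
    "write_manifest",
    "CONFIG_TYPES",
]

_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_EULER_COLS = ["rx_deg", "ry_deg", "rz_deg"]
EVENT_COLS = ["subject", "block", "algorithm", "onset_s", "offset_s",
              "direction", "amplitude_deg", "peak_velocity_deg_s"]

CONFIG_TYPES = {
    "bmat": BmatConfig, "svt": SvtConfig, "cw": CwConfig,
    "dizco": DizcoConfig, "tree": TreeConfig,
}


def _read_numeric(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column "
                f"{c!r} at data row {row + 1}"
            )
        df[c] = coerced
    return df


def read_trace(path: str | Path) -> OrientationTrace:
    """Read a trace file (quaternion or Euler dialect, auto-detected)."""
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns
    if all(c in header for c in _QUAT_COLS):
        df = _read_numeric(path, ["time_s", *_QUAT_COLS])
        quat = df[["qx", "qy", "qz", "qw"]].to_numpy()  # scipy scalar-last
    elif all(c in header for c in _EULER_COLS):
        df = _read_numeric(path, ["time_s", *_EULER_COLS])
        quat = euler_to_quat(df["rx_deg"], df["ry_deg"], df["rz_deg"])
    else:
        raise ValueError(
            f"{path}: header must contain either {_QUAT_COLS} or {_EULER_COLS}"
        )
    return OrientationTrace(timestamps=df["time_s"].to_numpy(), quat=quat)


def write_trace(trace: OrientationTrace, path: str | Path,
                dialect: str = "quat") -> None:
    """Write a trace; ``dialect`` is ``'quat'`` (default) or ``'euler'``."""
    path = Path(path)
    if dialect == "quat":
        q = trace.quat
        df = pd.DataFrame({
            "time_s": trace.timestamps,
            "qw": q[:, 3], "qx": q[:, 0], "qy": q[:, 1], "qz": q[:, 2],
        })
        float_format = "%.12g"
    elif dialect == "euler":
        eul = quat_to_euler(trace.quat)
        df = pd.DataFrame({
            "time_s": trace.timestamps,
            "rx_deg": eul[:, 0], "ry_deg": eul[:, 1], "rz_deg": eul[:, 2],
        })
        float_format = "%.9f"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["time_s"] = df["time_s"].map(lambda t: f"{t:.6f}")
    df.to_csv(path, index=False, float_format=float_format)


def read_markers(path: str | Path) -> list[tuple[float, str]]:
    df = _read_numeric(Path(path), ["time_s"])
    if "kind" not in df.columns:
        raise ValueError(f"{path}: missing 'kind' column")
    return [(float(t), str(k)) for t, k in zip(df["time_s"], df["kind"])]


def write_markers(markers: list[tuple[float, str]], path: str | Path) -> None:
    df = pd.DataFrame(markers, columns=["time_s", "kind"])
    df["time_s"] = df["time_s"].map(lambda t: f"{t:.6f}")
    df.to_csv(path, index=False)


def events_to_frame(events: list[MovementEvent], subject: str = "",
                    block: str = "", algorithm: str = "") -> pd.DataFrame:
    rows = [{
        "subject": subject, "block": block, "algorithm": algorithm,
        "onset_s": e.onset, "offset_s": e.offset,
        "direction": e.direction if e.direction is not None else "",
        "amplitude_deg": e.amplitude if e.amplitude is not None else np.nan,
        "peak_velocity_deg_s": e.peak_velocity if e.peak_velocity is not None else np.nan,
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLS)


def frame_to_events(df: pd.DataFrame) -> list[MovementEvent]:
    events = []
    for _, row in df.iterrows():
        direction = row.get("direction", "")
        amp = row.get("amplitude_deg", np.nan)
        vel = row.get("peak_velocity_deg_s", np.nan)
        events.append(MovementEvent(
            onset=float(row["onset_s"]), offset=float(row["offset_s"]),
            direction=None if (pd.isna(direction) or direction == "") else str(direction),
            amplitude=None if pd.isna(amp) else float(amp),
            peak_velocity=None if pd.isna(vel) else float(vel),
        ))
    return events


def write_events(events: list[MovementEvent], path: str | Path, *,
                 subject: str = "", block: str = "", algorithm: str = "") -> None:
    df = events_to_frame(events, subject=subject, block=block, algorithm=algorithm)
    for col in ("onset_s", "offset_s"):
        df[col] = df[col].map(lambda t: f"{t:.6f}")
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[MovementEvent]:
    df = _read_numeric(Path(path), ["onset_s", "offset_s"])
    return frame_to_events(df)


def load_config(path: str | Path) -> dict[str, object]:
    """Load per-algorithm configs from a YAML file.

    Top-level keys name algorithms (``bmat``, ``svt``, ``cw``, ``dizco``,
    ``tree``); each maps to that algorithm's config fields.  Missing keys
    keep their defaults; unknown fields are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, object] = {}
    for name, cls in CONFIG_TYPES.items():
        fields = raw.get(name, {}) or {}
        if not isinstance(fields, dict):
            raise ValueError(f"{path}: section {name!r} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(fields) - known
        if unknown:
            raise ValueError(f"{path}: unknown {name} fields {sorted(unknown)}")
        # YAML lists -> tuples where the dataclass default is a tuple
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in fields.items()
        }
        out[name] = cls(**coerced)
    return out


def save_config(configs: dict[str, object], path: str | Path) -> None:
    data = {name: asdict(cfg) for name, cfg in configs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(path: str | Path, *, config: dict | None = None,
                   inputs: list[str | Path] | None = None,
                   seed: int | None = None) -> dict:
    """Write a run manifest: version, config hash, input digests, seed.

    The manifest hash is stable for equal config + inputs + seed; the
    timestamp is informational and excluded from the hash.
    """
    config = config or {}
    payload = {
        "tool": "headmov",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "inputs": {str(p): _digest(Path(p)) for p in (inputs or [])},
        "seed": seed,
    }
    payload["manifest_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return payload
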