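"""Reading and writing marker trajectories.

The native on-disk dialect is a long-format CSV with a comment header:

.. code-block:: text

    # pmsway-markers v1
    # subject_id: S01
    # sample_rate: 240.0
    # height: 1.70
    # mass: 70.0
    # age_group: young
    # gender: female
    # front_foot: right
    frame,label,x,y,z
    0,LFHD,0.07,0.06,1.63
    ...

Coordinates are meters in the lab frame; missing samples are empty/NaN
cells.  C3D is not currently supported — convert recordings to this CSV
dialect first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MarkerTrajectorySet
from .errors import FormatError

__all__ = ["read_markers", "write_markers"]

_MAGIC = "# pmsway-markers v1"
_FLOAT_META = ("sample_rate", "height", "mass")
_STR_META = ("subject_id", "age_group", "gender", "front_foot")


def write_markers(traj: MarkerTrajectorySet, path: str | Path) -> Path:
    """Write a trajectory set to the long-format CSV dialect."""
    path = Path(path)
    T, M = traj.n_frames, traj.n_markers
    pos = traj.positions.copy()
    pos[traj.missing] = np.nan
    frame = np.repeat(np.arange(T), M)
    label = np.tile(np.asarray(traj.marker_labels, dtype=object), T)
    flat = pos.reshape(T * M, 3)
    df = pd.DataFrame(
        {"frame": frame, "label": label,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        for key in _STR_META:
            fh.write(f"# {key}: {getattr(traj, key)}\n")
        for key in _FLOAT_META:
            fh.write(f"# {key}: {getattr(traj, key)!r}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def _parse_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_markers(path: str | Path, format: str = "csv") -> MarkerTrajectorySet:
    """Read a marker trajectory set from disk.

    Parameters
    ----------
    path : path to the file.
    format : {"csv"}
        Only the native CSV dialect is supported; ``"c3d"`` raises a
        :class:`~pmsway.errors.FormatError`.
    """
    path = Path(path)
    if format != "csv":
        raise FormatError(
            f"unsupported format {format!r}; convert to the pmsway CSV dialect"
        )
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    meta = _parse_header(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"unparseable CSV: {exc}") from exc
    required = {"frame", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"CSV must have columns {sorted(required)}")

    labels = list(dict.fromkeys(df["label"]))  # first-appearance order
    frames = np.sort(df["frame"].unique())
    T, M = len(frames), len(labels)
    if not np.array_equal(frames, np.arange(T)):
        raise FormatError("frames must be consecutive integers starting at 0")
    if len(df) != T * M:
        raise FormatError("every frame must list every marker exactly once")

    lab_idx = pd.Categorical(df["label"], categories=labels).codes
    positions = np.full((T, M, 3), np.nan)
    positions[df["frame"].to_numpy(), lab_idx] = df[["x", "y", "z"]].to_numpy()
    missing = ~np.isfinite(positions).all(axis=2)
    # a marker exactly at the lab origin is an unreconstructed sample
    missing |= (positions == 0.0).all(axis=2)
    positions[missing] = np.nan

    kwargs: dict = {}
    for key in _STR_META:
        if key in meta:
            kwargs[key] = meta[key]
    for key in _FLOAT_META:
        if key in meta:
            try:
                kwargs[key] = float(meta[key])
            except ValueError as exc:
                raise FormatError(f"bad header value for {key}: {meta[key]!r}") from exc
    kwargs.setdefault("subject_id", path.stem)

    try:
        return MarkerTrajectorySet(
            marker_labels=labels,
            positions=np.where(np.isfinite(positions), positions, 0.0),
            missing=missing,
            **kwargs,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
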