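"""Containers and operations for 3D swarm trajectory data.

The pipeline starts from tracked 3D trajectories: per-track time series of
positions sampled on a common frame clock (100 Hz in the laboratory setup
this package targets).  Positions are in mm, time in s; velocities (mm/s)
and accelerations (mm/s^2) are derived by finite differences.  Midge mass
is taken as 1 throughout, so all energies and the pressure are per unit
mass.

Tracks are split, never interpolated, across frame gaps: no gap-filling
procedure is assumed.  The vertical (gravity) axis is z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError, TrajectoryParseError

__all__ = [
    "MidgeTrack",
    "SwarmRecording",
    "FrameSnapshot",
    "read_trajectories",
    "write_trajectories",
    "differentiate",
    "flight_filter",
    "snapshot",
]

_REQUIRED_COLUMNS = ("track_id", "frame", "x", "y", "z")
_DERIV_COLUMNS = ("vx", "vy", "vz", "ax", "ay", "az")


@dataclass
class MidgeTrack:
    """A single midge's contiguous trajectory segment.

    Parameters
    ----------
    track_id : str
        Opaque identifier (unique within a recording).
    start_frame : int
        Frame index of the first sample; frames are contiguous thereafter.
    positions : (n, 3) ndarray
        Positions in mm.
    velocities, accelerations : (n, 3) ndarray or None
        Derived kinematics in mm/s and mm/s^2; absent until differentiated.
    """

    track_id: str
    start_frame: int
    positions: np.ndarray
    velocities: np.ndarray | None = None
    accelerations: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if not np.isfinite(self.positions).all():
            raise ValueError(f"track {self.track_id!r}: non-finite positions")
        for name in ("velocities", "accelerations"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.positions.shape:
                    raise ValueError(
                        f"track {self.track_id!r}: {name} shape {arr.shape} "
                        f"!= positions shape {self.positions.shape}"
                    )
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def frames(self) -> np.ndarray:
        """Integer frame indices covered by this track (contiguous)."""
        return np.arange(self.start_frame, self.start_frame + len(self))

    @property
    def end_frame(self) -> int:
        """One past the last frame index."""
        return self.start_frame + len(self)


@dataclass
class SwarmRecording:
    """A set of midge tracks sharing one frame clock.

    ``frame_rate`` is in Hz (default 100, the camera rate of the laboratory
    system).  ``schedule`` optionally records the perturbation protocol the
    recording was taken under; ``meta`` is free-form provenance.
    """

    frame_rate: float = 100.0
    tracks: list[MidgeTrack] = field(default_factory=list)
    schedule: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def frame_range(self) -> tuple[int, int]:
        """(first frame, one past last frame) over all tracks."""
        if not self.tracks:
            raise ValueError("empty recording has no frame range")
        return (
            min(t.start_frame for t in self.tracks),
            max(t.end_frame for t in self.tracks),
        )

    @property
    def n_frames(self) -> int:
        lo, hi = self.frame_range
        return hi - lo

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy table sorted by (track_id, frame)."""
        parts = []
        for tr in self.tracks:
            d = {
                "track_id": tr.track_id,
                "frame": tr.frames,
                "x": tr.positions[:, 0],
                "y": tr.positions[:, 1],
                "z": tr.positions[:, 2],
            }
            if tr.velocities is not None:
                d["vx"], d["vy"], d["vz"] = tr.velocities.T
            if tr.accelerations is not None:
                d["ax"], d["ay"], d["az"] = tr.accelerations.T
            parts.append(pd.DataFrame(d))
        df = pd.concat(parts, ignore_index=True)
        return df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


@dataclass
class FrameSnapshot:
    """All flying midges at one time step.

    ``positions`` etc. are (N, 3); N may be 0.  Swarm averages are taken
    over the rows of a snapshot.
    """

    time: float
    positions: np.ndarray
    velocities: np.ndarray | None
    accelerations: np.ndarray | None
    ids: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        n = self.positions.shape[0]
        for name in ("velocities", "accelerations"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.size == 0:
                    arr = arr.reshape(0, 3)
                if arr.shape[0] != n:
                    raise ValueError(f"{name} length != positions length")
                setattr(self, name, arr)
        self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != n:
            raise ValueError("ids length != positions length")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# I/O


def _split_contiguous(track_id: str, frames: np.ndarray, arrays: dict) -> list[MidgeTrack]:
    """Split one id's rows into gap-free MidgeTracks (suffixed if split)."""
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    arrays = {k: v[order] for k, v in arrays.items()}
    breaks = np.flatnonzero(np.diff(frames) != 1) + 1
    segments = np.split(np.arange(len(frames)), breaks)
    out = []
    for i, seg in enumerate(segments):
        tid = track_id if len(segments) == 1 else f"{track_id}#{i}"
        pos = np.column_stack([arrays["x"][seg], arrays["y"][seg], arrays["z"][seg]])
        vel = acc = None
        if "vx" in arrays:
            vel = np.column_stack([arrays["vx"][seg], arrays["vy"][seg], arrays["vz"][seg]])
        if "ax" in arrays:
            acc = np.column_stack([arrays["ax"][seg], arrays["ay"][seg], arrays["az"][seg]])
        out.append(
            MidgeTrack(tid, int(frames[seg[0]]), pos, velocities=vel, accelerations=acc)
        )
    return out


def read_trajectories(
    path, frame_rate: float = 100.0, delimiter: str = ","
) -> SwarmRecording:
    """Read a delimited trajectory table into a :class:`SwarmRecording`.

    The file must have a header row with columns ``track_id, frame, x, y, z``
    (coordinates in mm, ``frame`` integer); optional ``vx,vy,vz,ax,ay,az``
    columns are accepted.  Ids whose frames are non-contiguous are split
    into contiguous segments with ``#<i>`` suffixes.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing column(s) {missing}")
    numeric_cols = [c for c in df.columns if c != "track_id"]
    for col in numeric_cols:
        raw = df[col].to_numpy(dtype=object)
        try:
            # numpy's parser is correctly rounded, so round-trips are exact
            df[col] = np.asarray(raw, dtype=float)
        except (ValueError, TypeError):
            for row, item in enumerate(raw):
                try:
                    float(item)
                except (ValueError, TypeError):
                    raise TrajectoryParseError(
                        f"{path}: non-numeric value {item!r} in column "
                        f"{col!r} at data row {row + 1}",
                        row=row + 1,
                    ) from None
            raise
    tracks: list[MidgeTrack] = []
    has_vel = all(c in df.columns for c in ("vx", "vy", "vz"))
    has_acc = all(c in df.columns for c in ("ax", "ay", "az"))
    cols = ["x", "y", "z"]
    if has_vel:
        cols += ["vx", "vy", "vz"]
    if has_acc:
        cols += ["ax", "ay", "az"]
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy().astype(int)
        arrays = {c: grp[c].to_numpy(dtype=float) for c in cols}
        tracks.extend(_split_contiguous(str(tid), frames, arrays))
    return SwarmRecording(frame_rate=frame_rate, tracks=tracks, meta={"source": str(path)})


def write_trajectories(recording: SwarmRecording, path, delimiter: str = ",") -> None:
    """Write a recording as the delimited table read by :func:`read_trajectories`.

    Rows are sorted by (track_id, frame).  Raises on an empty recording.
    """
    if not recording.tracks:
        raise ValueError("cannot write an empty recording")
    df = recording.to_frame()
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Kinematics


def _boxcar(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0, truncated at the ends."""
    window = min(window, arr.shape[0])
    if window <= 1:
        return arr
    kernel = np.ones(window)
    counts = np.convolve(np.ones(arr.shape[0]), kernel, mode="same")
    if arr.ndim == 1:
        return np.convolve(arr, kernel, mode="same") / counts
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        out[:, j] = np.convolve(arr[:, j], kernel, mode="same") / counts
    return out


def differentiate(recording: SwarmRecording, smooth_window: int = 0) -> SwarmRecording:
    """Derive velocities and accelerations by finite differences in time.

    Central differences at interior frames, second-order one-sided
    differences at track endpoints (exact on quadratic trajectories).
    ``smooth_window`` > 1 applies a centered boxcar to positions first
    (default: no smoothing).  Tracks shorter than 3 frames are dropped
    with a warning.
    """
    dt = recording.dt
    new_tracks = []
    for tr in recording.tracks:
        if len(tr) < 3:
            warnings.warn(
                f"dropping track {tr.track_id!r}: too short to differentiate "
                f"({len(tr)} frames)",
                stacklevel=2,
            )
            continue
        pos = _boxcar(tr.positions, smooth_window)
        vel = np.gradient(pos, dt, axis=0, edge_order=2)
        acc = np.gradient(vel, dt, axis=0, edge_order=2)
        new_tracks.append(
            MidgeTrack(tr.track_id, tr.start_frame, tr.positions, vel, acc)
        )
    return replace(recording, tracks=new_tracks)


def _moving_average_speed(speed: np.ndarray, window: int) -> np.ndarray:
    return _boxcar(speed, window)


def flight_filter(
    recording: SwarmRecording, window: int = 100, threshold: float = 60.0
) -> SwarmRecording:
    """Remove non-flying midges (sitting/walking) time step by time step.

    For each midge the speed is averaged over a centered ``window``-frame
    moving window (truncated at track ends); the midge is discarded at time
    steps where that average falls below ``threshold`` (mm/s, default 60).
    Tracks may be split into multiple segments by removals.
    """
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    new_tracks = []
    for tr in recording.tracks:
        if tr.velocities is None:
            raise ValueError("flight_filter requires velocities; differentiate first")
        speed = np.linalg.norm(tr.velocities, axis=1)
        keep = _moving_average_speed(speed, window) >= threshold
        if keep.all():
            new_tracks.append(tr)
            continue
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        segments = np.split(idx, breaks)
        whole = len(segments) == 1 and idx.size == len(tr)
        for i, seg in enumerate(segments):
            tid = tr.track_id if whole else f"{tr.track_id}~{i}"
            new_tracks.append(
                MidgeTrack(
                    tid,
                    tr.start_frame + int(seg[0]),
                    tr.positions[seg],
                    tr.velocities[seg],
                    None if tr.accelerations is None else tr.accelerations[seg],
                )
            )
    return replace(recording, tracks=new_tracks)


def snapshot(recording: SwarmRecording, frame: int) -> FrameSnapshot:
    """Gather all midges present at one frame into a :class:`FrameSnapshot`."""
    lo, hi = recording.frame_range
    if not (lo <= frame < hi):
        raise IndexError(f"frame {frame} outside recording range [{lo}, {hi})")
    pos, vel, acc, ids = [], [], [], []
    any_vel = any_acc = True
    for tr in recording.tracks:
        if tr.start_frame <= frame < tr.end_frame:
            i = frame - tr.start_frame
            pos.append(tr.positions[i])
            ids.append(tr.track_id)
            if tr.velocities is None:
                any_vel = False
            else:
                vel.append(tr.velocities[i])
            if tr.accelerations is None:
                any_acc = False
            else:
                acc.append(tr.accelerations[i])
    n = len(pos)
    return FrameSnapshot(
        time=frame / recording.frame_rate,
        positions=np.array(pos).reshape(n, 3),
        velocities=np.array(vel).reshape(n, 3) if any_vel else None,
        accelerations=np.array(acc).reshape(n, 3) if any_acc else None,
        ids=np.array(ids, dtype=object),
    )
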