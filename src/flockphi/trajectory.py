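"""Multi-agent 2-D trajectory containers, loading, resampling and headings.

Trajectories are per-individual position series on a common frame grid
(coordinates in mm, e.g. a 3000 × 2500 mm arena with the origin at a
corner).  Headings are backward finite differences of position: the unit
heading at step ``t`` is the direction of ``x(t) − x(t−1)``, which is also
the step over which turning rates are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default CSV column names; pass a ``dialect`` mapping to override.
DEFAULT_DIALECT = {"frame": "frame", "id": "id", "x": "x", "y": "y"}


@dataclass
class Trajectory:
    """Positions of N individuals over T frames.

    ``positions`` has shape (T, N, 2) in mm; ``ids`` are the individual
    labels (sorted ascending), ``frames`` the integer frame index and
    ``frame_rate`` the sampling rate in Hz.
    """

    frames: np.ndarray
    positions: np.ndarray
    frame_rate: float
    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, N, 2)")
        if self.positions.shape[0] != self.frames.shape[0]:
            raise ValueError("frames and positions disagree on T")
        if self.positions.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.positions.shape[1] != len(self.ids):
            raise ValueError("ids and positions disagree on N")
        if not np.all(np.isfinite(self.positions)):
            t, i, _ = np.argwhere(~np.isfinite(self.positions))[0]
            raise ValueError(
                f"non-finite coordinate at frame {self.frames[t]} for individual {self.ids[i]}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class HeadingSeries:
    """Per-step unit headings and speeds derived from a trajectory.

    ``unit_heading`` has shape (T−1, N, 2): entry ``t`` is the direction of
    motion over the step ending at frame ``t+1``.  ``defined`` flags steps
    before an individual's first displacement, where no heading exists yet.
    ``carried`` counts zero-displacement steps whose heading was carried
    forward from the previous step.
    """

    unit_heading: np.ndarray
    speed: np.ndarray
    step_dt: float
    defined: np.ndarray
    carried: int = 0


def load_trajectory(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    frame_rate: float = 120.0,
) -> Trajectory:
    """Read a long-format trajectory CSV (one row per individual per frame).

    ``dialect`` maps the canonical column roles (frame, id, x, y) to the
    file's actual column names.  Individuals are sorted by id; per-individual
    series must cover exactly the same frames.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    ids = sorted(df["id"].unique())
    frames = np.sort(df["frame"].unique())
    lengths = df.groupby("id").size()
    if lengths.nunique() != 1:
        raise ValueError(f"ragged per-individual lengths: {dict(lengths)}")
    positions = np.full((len(frames), len(ids), 2), np.nan)
    frame_index = {f: t for t, f in enumerate(frames)}
    id_index = {v: i for i, v in enumerate(ids)}
    rows = df[["frame", "id", "x", "y"]].to_numpy()
    for f, ind, x, y in rows:
        positions[frame_index[f], id_index[ind]] = (x, y)
    bad = np.argwhere(~np.isfinite(positions))
    if bad.size:
        t, i, _ = bad[0]
        raise ValueError(
            f"non-finite or missing coordinate at frame {frames[t]} for individual {ids[i]}"
        )
    return Trajectory(
        frames=frames,
        positions=positions,
        frame_rate=frame_rate,
        ids=tuple(int(v) for v in ids),
    )


def resample(traj: Trajectory, dt: float) -> Trajectory:
    """Keep every stride-th frame so the step becomes ``dt`` seconds.

    ``dt`` must be an integer multiple of the native frame period
    (e.g. 120 fps and dt = 0.05 s give stride 6).
    """
    stride_f = dt * traj.frame_rate
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        below = max(1, int(np.floor(stride_f))) / traj.frame_rate
        above = max(1, int(np.ceil(stride_f))) / traj.frame_rate
        raise ValueError(
            f"dt={dt} is not an integer multiple of the frame period "
            f"1/{traj.frame_rate}; nearest valid values are {below:.6g} s and {above:.6g} s"
        )
    return Trajectory(
        frames=traj.frames[::stride],
        positions=traj.positions[::stride],
        frame_rate=traj.frame_rate / stride,
        ids=traj.ids,
    )


def derive_headings(traj: Trajectory) -> HeadingSeries:
    """Backward finite-difference unit headings and speeds.

    Zero-displacement steps carry the previous heading forward (counted in
    ``carried``); steps before an individual's first displacement are
    flagged undefined.  An individual that never moves is an error.
    """
    disp = np.diff(traj.positions, axis=0)  # (T-1, N, 2)
    norms = np.linalg.norm(disp, axis=2)
    moving = norms > 0.0
    if not moving.any(axis=0).all():
        idle = [traj.ids[i] for i in np.flatnonzero(~moving.any(axis=0))]
        raise ValueError(f"individual(s) {idle} never move; headings undefined")
    nsteps, n = norms.shape
    unit = np.zeros_like(disp)
    defined = np.zeros((nsteps, n), dtype=bool)
    carried = 0
    for i in range(n):
        last = np.array([np.nan, np.nan])
        have = False
        for t in range(nsteps):
            if moving[t, i]:
                last = disp[t, i] / norms[t, i]
                have = True
            elif have:
                carried += 1
            if have:
                unit[t, i] = last
                defined[t, i] = True
    if carried:
        logger.info("carried forward %d zero-displacement headings", carried)
    dt = traj.dt
    return HeadingSeries(
        unit_heading=unit,
        speed=norms / dt,
        step_dt=dt,
        defined=defined,
        carried=carried,
    )


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the standard long-format CSV (`frame,id,x,y`)."""
    t_idx, i_idx = np.meshgrid(
        np.arange(traj.n_frames), np.arange(traj.n), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "frame": traj.frames[t_idx.ravel()],
            "id": np.asarray(traj.ids)[i_idx.ravel()],
            "x": traj.positions[..., 0].ravel(),
            "y": traj.positions[..., 1].ravel(),
        }
    )
    df.to_csv(path, index=False)
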