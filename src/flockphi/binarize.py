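"""Binarize trajectories into collective ON/OFF states.

Each individual's state at a step is the conjunction (AND) of three binary
interaction functions evaluated on the school's geometry:

* **distance** — ON iff any other individual is strictly within ζ mm,
* **visual field** — ON iff any other individual lies strictly within an
  angle η of the focal individual's heading (η = VF/2, so a visual field of
  2π makes this function identically ON and values below 2π open a rear
  blind spot),
* **turning rate** — ON iff the angle between consecutive headings is at
  least δ (so δ = 0 makes this function identically ON).

States are defined from the second heading step onward, since the turning
rate needs two consecutive headings; the first step is dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .trajectory import Trajectory, HeadingSeries, derive_headings


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in [0, π] between vectors along the last axis."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = np.where(nu * nv > 0, nu * nv, 1.0)
    cos = np.clip(np.sum(u * v, axis=-1) / denom, -1.0, 1.0)
    return np.arccos(cos)


@dataclass
class BinarizationParams:
    """Threshold triple (ζ, η, δ) plus the time step.

    ``visual_field`` is the full field-of-view in rad (the heat-map axis,
    up to 2π); the half-angle threshold η = visual_field / 2 is what the
    visual-field function compares against.  ``delta`` is in rad per step;
    use ``from_rate`` to convert a rad/s threshold.  ``visual_vector``
    selects the direction convention: ``to_neighbour`` (default; a field
    below 2π is a rear blind spot) or ``as_printed`` (focal-to-neighbour
    vector negated).
    """

    zeta: float
    visual_field: float = 2.0 * math.pi
    delta: float = 0.0
    dt: float = 0.05
    visual_vector: str = "to_neighbour"

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if not 0.0 <= self.visual_field <= 2.0 * math.pi + 1e-12:
            raise ValueError("visual_field must be in [0, 2*pi]")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.visual_vector not in ("to_neighbour", "as_printed"):
            raise ValueError("visual_vector must be 'to_neighbour' or 'as_printed'")

    @property
    def eta(self) -> float:
        """Half-angle threshold η ∈ [0, π]."""
        return self.visual_field / 2.0

    @classmethod
    def from_rate(cls, zeta: float, visual_field: float, delta_rate: float, dt: float, **kw):
        """Build params from a turning threshold expressed in rad/s."""
        return cls(zeta=zeta, visual_field=visual_field, delta=delta_rate * dt, dt=dt, **kw)


@dataclass
class StateSeries:
    """T×N matrix of conjunct ON/OFF bits with the parameters that made it."""

    states: np.ndarray
    params: BinarizationParams | None = None
    n: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise ValueError("states must be a (T, N) matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")
        if self.n == 0:
            self.n = self.states.shape[1]

    def __len__(self) -> int:
        return self.states.shape[0]

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        header = "t," + ",".join(f"s{i + 1}" for i in range(self.n))
        data = np.column_stack([np.arange(len(self)), self.states])
        np.savetxt(path, data, fmt="%d", delimiter=",", header=header, comments="")
        if sidecar and self.params is not None:
            Path(str(path) + ".json").write_text(json.dumps(asdict(self.params), indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StateSeries":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2, dtype=np.int64)
        params = None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            params = BinarizationParams(**json.loads(sidecar.read_text()))
        return cls(states=data[:, 1:], params=params)


def distance_state(positions: np.ndarray, i: int, zeta: float) -> int:
    """1 iff some other individual is strictly within ζ of individual ``i``."""
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions - positions[i], axis=-1)
    d[i] = np.inf
    return int((d < zeta).any())


def visual_state(
    positions: np.ndarray,
    headings: np.ndarray,
    i: int,
    eta: float,
    visual_vector: str = "to_neighbour",
) -> int:
    """1 iff some other individual lies strictly within angle η of i's heading.

    With ``to_neighbour`` the angle is between the focal heading and the
    vector from the focal individual to the neighbour; ``as_printed`` negates
    that vector (turning the blind spot to the front).  An undefined focal
    heading yields 0.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    h = headings[i]
    if not np.all(np.isfinite(h)) or np.linalg.norm(h) == 0.0:
        return 0
    rel = positions - positions[i]
    if visual_vector == "as_printed":
        rel = -rel
    mask = np.arange(len(positions)) != i
    nonzero = np.linalg.norm(rel, axis=-1) > 0
    mask &= nonzero
    if not mask.any():
        return 0
    angles = _angle_between(np.broadcast_to(h, rel[mask].shape), rel[mask])
    return int((angles < eta).any())


#: Absolute slack on the non-strict turning comparison; arccos round-off can
#: land an exact-threshold turn one ulp below delta.
_ANGLE_TOL = 1e-12


def turning_state(heading_t: np.ndarray, heading_prev: np.ndarray, delta: float) -> int:
    """1 iff the angle between consecutive headings is at least δ (non-strict)."""
    ang = _angle_between(np.asarray(heading_t), np.asarray(heading_prev))
    return int(ang >= delta - _ANGLE_TOL)


def binarize(
    traj: Trajectory,
    params: BinarizationParams,
    headings: HeadingSeries | None = None,
) -> StateSeries:
    """Conjunct per-individual states over the whole trajectory.

    The trajectory must already be sampled at ``params.dt``.  Headings are
    derived if not supplied.  The state at step ``t`` uses positions and
    headings at ``t`` and the heading at ``t − 1``; undefined headings make
    the visual and turning functions OFF.
    """
    if abs(traj.dt - params.dt) > 1e-9:
        raise ValueError(
            f"trajectory step {traj.dt:.6g}s does not match params.dt={params.dt:.6g}s; "
            "resample first"
        )
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames (two heading steps) to binarize")
    hs = headings if headings is not None else derive_headings(traj)
    pos = traj.positions[1:]  # align with heading steps
    unit = hs.unit_heading
    defined = hs.defined
    nsteps, n = unit.shape[:2]
    eta = params.eta

    # distance: pairwise, strict <
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dists = np.linalg.norm(diff, axis=-1)
    idx = np.arange(n)
    dists[:, idx, idx] = np.inf
    d_on = (dists < params.zeta).any(axis=2)

    # visual field: angle(heading_i, x_j - x_i) < eta, strict <
    # diff[t, i, j] = pos_i - pos_j; the vector to the neighbour is -diff
    rel = -diff if params.visual_vector == "to_neighbour" else diff
    with np.errstate(invalid="ignore", divide="ignore"):
        relnorm = np.linalg.norm(rel, axis=-1)
        cos = np.einsum("tid,tijd->tij", unit, rel)
        denom = np.where(relnorm > 0, relnorm, 1.0)
        ang = np.arccos(np.clip(cos / denom, -1.0, 1.0))
    ang[:, idx, idx] = np.inf
    ang[relnorm == 0] = np.inf  # coincident individuals carry no bearing
    b_on = (ang < eta).any(axis=2) & defined

    # turning rate: non-strict >= delta between consecutive headings
    turn = _angle_between(unit[1:], unit[:-1])
    t_on = (turn >= params.delta - _ANGLE_TOL) & defined[1:] & defined[:-1]

    states = (d_on[1:] & b_on[1:] & t_on).astype(np.uint8)
    return StateSeries(states=states, params=params, n=n)
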