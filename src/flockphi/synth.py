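"""Synthetic inputs: Boids trajectories, random Markov chains and fixtures.

The Boids simulator emulates the empirical recording conditions the rest of
the pipeline expects: a 3000 × 2500 mm arena, a 0.05 s step, small schools
(N = 2..5) with zone-based repulsion / alignment / attraction rules whose
radii and speeds were matched to observed schools (repulsion radius 10 mm ≈
body length, alignment radius 120 mm ≈ typical neighbour distance,
attraction unbounded, per-step displacements of ~8-12 mm ≈ 200-250 mm/s).

Random state-by-node TPMs (every conditional ON-probability independent
Uniform(0, 1)) provide the size-effect baseline: integrated information of
generic time-homogeneous Markov chains as a function of the number of
nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .phi import _cut_masks, _sorted_cuts, cut_one_cuts
from .tpm import StateByNodeTPM
from .trajectory import Trajectory

#: Per-step displacement (mm per Δt) and heading-noise SD (rad) by group
#: size, matching the observed average speeds (Δt = 0.05 s).
TABLE_SPEEDS = {2: 11.1, 3: 12.4, 4: 8.47, 5: 10.2}
TABLE_NOISE = {2: 0.20, 3: 0.17, 4: 0.21, 5: 0.23}


@dataclass
class BoidsParams:
    """Zone-model parameters.

    ``v`` is the displacement per time step in mm (≈ speed × Δt); ``C``
    scales all three interaction rules; ``noise_sd`` is the SD of the
    Gaussian heading perturbation in rad, applied after the rules are
    averaged.
    """

    n: int
    R: float = 10.0
    O: float = 120.0
    A: float = math.inf
    v: float | None = None
    C: float = 1.0
    noise_sd: float | None = None
    dt: float = 0.05
    arena: tuple[float, float] = (3000.0, 2500.0)
    seed: int = 0
    boundary: str = "reflective"  # or "periodic"

    def __post_init__(self) -> None:
        if not 0 < self.R <= self.O <= self.A:
            raise ValueError("need 0 < R <= O <= A")
        if self.v is None:
            self.v = TABLE_SPEEDS.get(self.n, 10.0)
        if self.noise_sd is None:
            self.noise_sd = TABLE_NOISE.get(self.n, 0.2)
        if self.v <= 0:
            raise ValueError("v must be positive")
        if self.C < 0:
            raise ValueError("C must be nonnegative")
        if self.boundary not in ("reflective", "periodic"):
            raise ValueError("boundary must be 'reflective' or 'periodic'")


def _rotate(vectors: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    return np.stack(
        [c * vectors[:, 0] - s * vectors[:, 1], s * vectors[:, 0] + c * vectors[:, 1]],
        axis=1,
    )


def simulate_boids(
    params: BoidsParams,
    steps: int,
    init_positions: np.ndarray | None = None,
    init_headings: np.ndarray | None = None,
) -> Trajectory:
    """Synchronous zone-model simulation; returns a standard Trajectory.

    Per step and agent: repulsion away from neighbours within R, alignment
    with the headings of agents within O (self included, giving heading
    persistence), attraction toward neighbours in the O..A shell; the three
    rule vectors are each scaled by C, summed and averaged, the heading is
    rotated by Gaussian noise, and the position advances by v along it.
    A zero rule sum keeps the previous heading.  Agents starting coincident
    get a random repulsion direction.

    By default agents start at random positions within the alignment radius
    of the arena centre with random headings; explicit ``init_positions`` /
    ``init_headings`` override this (useful for controlled experiments).
    """
    if steps < 2:
        raise ValueError("need at least 2 steps")
    rng = np.random.default_rng(params.seed)
    n = params.n
    w, h = params.arena
    if init_positions is None:
        center = np.array([w / 2, h / 2])
        pos = center + rng.uniform(-params.O, params.O, size=(n, 2))
    else:
        pos = np.asarray(init_positions, dtype=float).copy()
    if init_headings is None:
        theta = rng.uniform(0, 2 * math.pi, size=n)
        vel = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    else:
        vel = np.asarray(init_headings, dtype=float).copy()
        vel /= np.linalg.norm(vel, axis=1, keepdims=True)
    out = np.empty((steps, n, 2))
    out[0] = pos
    for t in range(1, steps):
        diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = x_j - x_i
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = diff / np.where(dist[..., None] > 0, dist[..., None], 1.0)
        coincident = np.argwhere(dist == 0)
        for i, j in coincident:
            ang = rng.uniform(0, 2 * math.pi)
            unit[i, j] = (math.cos(ang), math.sin(ang))
            dist[i, j] = 1e-9
        rep = -params.C * np.einsum("ij,ijd->id", (dist <= params.R).astype(float), unit)
        align_mask = dist <= params.O
        np.fill_diagonal(align_mask, True)  # own heading counts
        ali = params.C * np.einsum("ij,jd->id", align_mask.astype(float), vel)
        att_mask = (dist >= params.O) & (dist <= params.A)
        att = params.C * np.einsum("ij,ijd->id", att_mask.astype(float), unit)
        desired = (rep + ali + att) / 3.0
        norms = np.linalg.norm(desired, axis=1)
        keep = norms < 1e-12
        direction = np.where(keep[:, None], vel, desired / np.where(norms[:, None] > 0, norms[:, None], 1.0))
        direction = _rotate(direction, rng.normal(0.0, params.noise_sd, size=n))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        pos = pos + params.v * direction
        vel = direction
        if params.boundary == "reflective":
            for d, lim in ((0, w), (1, h)):
                low = pos[:, d] < 0
                pos[low, d] = -pos[low, d]
                vel[low, d] = -vel[low, d]
                high = pos[:, d] > lim
                pos[high, d] = 2 * lim - pos[high, d]
                vel[high, d] = -vel[high, d]
        else:
            pos[:, 0] %= w
            pos[:, 1] %= h
        out[t] = pos
    return Trajectory(
        frames=np.arange(steps),
        positions=out,
        frame_rate=1.0 / params.dt,
        ids=tuple(range(1, n + 1)),
    )


# ---------------------------------------------------------------------------
# random Markov chains
# ---------------------------------------------------------------------------


def random_tpm(n: int, seed: int | np.random.Generator = 0) -> StateByNodeTPM:
    """Random state-by-node TPM: every entry independent Uniform(0, 1)."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return StateByNodeTPM(probs=rng.random((1 << n, n)), n=n)


@dataclass
class MarkovBaseline:
    """Per-replicate and aggregate Phi statistics of random Markov chains."""

    n: int
    per_rep: pd.DataFrame  # columns: mean, sd, max, min (across the 2^n states)
    aggregates: dict[str, float]


def markov_phi_baseline(n: int, reps: int = 100, seed: int = 0) -> MarkovBaseline:
    """Phi statistics of ``reps`` random TPMs (cut-one MIP search).

    For each random TPM, Phi is computed at every one of the 2**n collective
    states; the per-replicate summary is the mean/sd/max/min across states,
    and the aggregates are means ± sd of those summaries across replicates
    (``sigma_phi`` is the cross-replicate mean of the per-TPM sd).
    """
    rng = np.random.default_rng(seed)
    cuts = _sorted_cuts(cut_one_cuts(n))
    fm, tm = _cut_masks(cuts, tuple(range(1, n + 1)))
    rows = []
    for _ in range(reps):
        probs = rng.random((1 << n, n))
        phis = np.array([K._big_phi(probs, n, s, fm, tm)[0] for s in range(1 << n)])
        rows.append(
            {"mean": phis.mean(), "sd": phis.std(), "max": phis.max(), "min": phis.min()}
        )
    per_rep = pd.DataFrame(rows)
    agg = {
        "sigma_phi": float(per_rep["sd"].mean()),
        "sigma_phi_sd": float(per_rep["sd"].std(ddof=0)),
        "mean_phi": float(per_rep["mean"].mean()),
        "mean_phi_sd": float(per_rep["mean"].std(ddof=0)),
        "max_phi": float(per_rep["max"].mean()),
        "max_phi_sd": float(per_rep["max"].std(ddof=0)),
        "min_phi": float(per_rep["min"].mean()),
        "min_phi_sd": float(per_rep["min"].std(ddof=0)),
    }
    return MarkovBaseline(n=n, per_rep=per_rep, aggregates=agg)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("copy_pair", "independent_pair", "leader_chain", "and_gate_triple", "leader_school")


def make_fixture(name: str):
    """Small deterministic objects with documented ground-truth properties.

    * ``copy_pair`` — 2-node TPM where each node copies the other's past
      state; irreducible, Phi > 0, major complex {1, 2}.
    * ``independent_pair`` — 2-node TPM where each node depends only on its
      own past; factorizes across every cut, Phi = 0 at every state.
    * ``leader_chain`` — trajectory of 4 agents in single file moving along
      +x with agent 1 at the front: agent 1 is the positional leader at
      every step.
    * ``and_gate_triple`` — 3-node TPM: nodes 1 and 2 are fair coins, node 3
      is the AND of their past states; purely feedforward, so cutting the
      output node's outgoing edges costs nothing and Phi = 0.
    * ``leader_school`` — synthetic 5-node TPM estimated from a seeded Boids
      school pushed through the standard binarization (ζ = 700 mm, visual
      field 1.6π, δ = 0, Δt = 0.05 s); a deterministic stand-in worked
      example for leadership analysis on a school of five.  Its ground
      truth, verified by construction: Phi at the all-ON state exceeds Phi
      at every single-OFF state, and the MIP at each single-OFF state
      isolates the OFF individual.
    """
    if name == "copy_pair":
        # p(node1 ON | s) = bit2(s); p(node2 ON | s) = bit1(s)
        probs = np.array(
            [[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]], dtype=float
        )
        return StateByNodeTPM(probs=probs, n=2)
    if name == "independent_pair":
        codes = np.arange(4)
        probs = np.stack(
            [
                np.where((codes >> 0) & 1 == 1, 0.8, 0.3),
                np.where((codes >> 1) & 1 == 1, 0.7, 0.2),
            ],
            axis=1,
        ).astype(float)
        return StateByNodeTPM(probs=probs, n=2)
    if name == "leader_chain":
        steps, n, speed = 50, 4, 10.0
        t = np.arange(steps, dtype=float)
        positions = np.empty((steps, n, 2))
        for i in range(n):
            positions[:, i, 0] = 500.0 - 60.0 * i + speed * t  # agent 1 in front
            positions[:, i, 1] = 1000.0 + 15.0 * i
        return Trajectory(
            frames=np.arange(steps),
            positions=positions,
            frame_rate=20.0,
            ids=tuple(range(1, n + 1)),
        )
    if name == "and_gate_triple":
        codes = np.arange(8)
        probs = np.stack(
            [
                np.full(8, 0.5),
                np.full(8, 0.5),
                (((codes >> 0) & 1) & ((codes >> 1) & 1)).astype(float),
            ],
            axis=1,
        )
        return StateByNodeTPM(probs=probs, n=3)
    if name == "leader_school":
        from .binarize import BinarizationParams, binarize
        from .tpm import estimate_tpm

        traj = simulate_boids(BoidsParams(n=5, seed=11), steps=20000)
        params = BinarizationParams(
            zeta=700.0, visual_field=1.6 * math.pi, delta=0.0, dt=0.05
        )
        return estimate_tpm(binarize(traj, params))
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
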