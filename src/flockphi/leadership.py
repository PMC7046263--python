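"""Leadership detection from single-OFF states and the system MIP.

A collective state with exactly one OFF individual defines a candidate
leader.  Two diagnostics quantify how real that leadership is:

* the **matching rate** — how often the single-OFF individual is also the
  positional leader (the individual whose position projects furthest along
  the school's mean heading), and
* the **MIP match rate** — how often the system-level minimum information
  partition isolates the OFF individual ({off} -/-> rest or rest -/-> {off}).

When the MIP does isolate the OFF individual, the cut direction classifies
the leadership: cutting the flow *out of* the leader ({off} -/-> rest)
costs little, meaning information mostly flows from the group to the leader
(**passive**); cutting the flow *into* the leader (rest -/-> {off}) means
information mostly flows from the leader outward (**active**).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarize import BinarizationParams, StateSeries, binarize
from .phi import PhiSummary, SystemCut, phi_over_series
from .tpm import estimate_tpm
from .trajectory import Trajectory, derive_headings

logger = logging.getLogger(__name__)


@dataclass
class LeadershipRecord:
    t: int
    state: tuple[int, ...]
    phi: float
    single_off: int  # 1..N, or 0 when the state is not single-OFF
    positional_leader: int  # 1..N, or 0 when the group direction is undefined
    mip: SystemCut | None
    classification: str = "none"


def single_off_index(state) -> int:
    """Index (1-based) of the unique OFF individual, or 0 otherwise."""
    bits = tuple(int(b) for b in state)
    off = [i + 1 for i, b in enumerate(bits) if b == 0]
    return off[0] if len(off) == 1 else 0


def positional_leader(positions, headings) -> int:
    """Individual furthest along the normalised mean heading (1-based).

    Returns 0 when the mean heading vanishes (group direction undefined).
    Ties take the smallest index.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    mean = headings.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        return 0
    direction = mean / norm
    proj = positions @ direction
    return int(np.argmax(proj)) + 1  # argmax takes the first (smallest) index on ties


def classify_leadership(record: LeadershipRecord) -> str:
    """``passive`` / ``active`` / ``none`` from the MIP cut direction.

    Passive: MIP = {off} -/-> rest (information flows from the group toward
    the leader).  Active: MIP = rest -/-> {off} (information flows from the
    leader outward).  Anything else — including states that are not
    single-OFF — is ``none``.
    """
    off = record.single_off
    mip = record.mip
    if off == 0 or mip is None or not mip.isolates(off):
        return "none"
    return "passive" if mip.from_part == (off,) else "active"


def matching_rate(records) -> float | None:
    """Percent of single-OFF steps whose OFF individual is the positional leader.

    Steps with an undefined positional leader are excluded (and logged).
    None when no valid single-OFF step exists.
    """
    valid = [r for r in records if r.single_off != 0 and r.positional_leader != 0]
    excluded = sum(1 for r in records if r.single_off != 0 and r.positional_leader == 0)
    if excluded:
        logger.info("excluded %d single-OFF steps with undefined group direction", excluded)
    if not valid:
        return None
    hits = sum(1 for r in valid if r.single_off == r.positional_leader)
    return 100.0 * hits / len(valid)


def mip_single_off_match_rate(records) -> float | None:
    """Percent of single-OFF steps whose MIP isolates the OFF individual."""
    valid = [r for r in records if r.single_off != 0 and r.mip is not None]
    if not valid:
        return None
    hits = sum(1 for r in valid if r.mip.isolates(r.single_off))
    return 100.0 * hits / len(valid)


def leadership_records(
    traj: Trajectory,
    params: BinarizationParams,
    cut_strategy: str = "cut_one",
    summary: PhiSummary | None = None,
) -> list[LeadershipRecord]:
    """Per-step leadership table for a trajectory.

    Binarizes, estimates the TPM, computes per-state Phi and MIPs once, then
    walks the series.  The state at record ``t`` is aligned with the
    positions and headings of the step it was computed from (binarization
    drops the first heading step).
    """
    hs = derive_headings(traj)
    series = binarize(traj, params, headings=hs)
    if summary is None:
        tpm = estimate_tpm(series)
        summary = phi_over_series(tpm, series=series, cut_strategy=cut_strategy)
    records = []
    for t in range(len(series)):
        state = tuple(int(b) for b in series.states[t])
        # series step t <-> heading step t+1 <-> trajectory frame t+2
        pos = traj.positions[t + 2]
        head = hs.unit_heading[t + 1]
        rec = LeadershipRecord(
            t=t,
            state=state,
            phi=summary.per_state[state],
            single_off=single_off_index(state),
            positional_leader=positional_leader(pos, head),
            mip=summary.mips.get(state),
        )
        rec.classification = classify_leadership(rec)
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": [r.t for r in records],
            "state": ["".join(str(b) for b in r.state) for r in records],
            "phi": [r.phi for r in records],
            "single_off": [r.single_off for r in records],
            "positional_leader": [r.positional_leader for r in records],
            "mip": ["" if r.mip is None else str(r.mip) for r in records],
            "classification": [r.classification for r in records],
        }
    )
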