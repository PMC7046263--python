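"""Parameter-grid sweeps (heat maps) and cross-group comparisons.

A sweep runs the full pipeline — binarize, estimate the TPM, evaluate a
measure — over a grid of (distance ζ, visual field) values at a fixed
turning threshold.  Heat maps across group sizes are compared by a
baseline-adjusted matrix distance; samples are compared with standard
two-sided tests.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .binarize import BinarizationParams, binarize
from .info import mutual_information, transfer_entropy_sum
from .phi import phi_over_series
from .tpm import estimate_tpm
from .trajectory import Trajectory, derive_headings

logger = logging.getLogger(__name__)

#: Default grid mirroring the analysis: ζ 100..1000 mm by 100, visual field
#: 1.0π..2.0π by 0.2π plus 1.9π, turning threshold 0.
DEFAULT_ZETAS = tuple(range(100, 1001, 100))
DEFAULT_VISUAL_FIELDS = tuple(
    round(v, 10) for v in sorted({(1.0 + 0.2 * k) * math.pi for k in range(6)} | {1.9 * math.pi})
)


@dataclass
class HeatMap:
    """Rectangular grid of a summary measure over (visual field, distance)."""

    rows: tuple[float, ...]  # visual-field values (rad)
    cols: tuple[float, ...]  # distance values (mm)
    cells: np.ndarray  # shape (len(rows), len(cols))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.rows), len(self.cols)):
            raise ValueError("cells shape does not match axes")

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write("vf_rad\\zeta_mm," + ",".join(f"{z:g}" for z in self.cols) + "\n")
            for vf, row in zip(self.rows, self.cells):
                fh.write(f"{vf:.10g}," + ",".join(f"{v:.12g}" for v in row) + "\n")
        if sidecar:
            Path(str(path) + ".json").write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeatMap":
        raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        with open(path) as fh:
            cols = tuple(float(v) for v in fh.readline().strip().split(",")[1:])
        meta = {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(rows=tuple(raw[:, 0]), cols=cols, cells=raw[:, 1:], meta=meta)


def _measure_value(measure, series, weighting, cut_strategy):
    if measure == "phi":
        tpm = estimate_tpm(series)
        return phi_over_series(tpm, series=series, weighting=weighting, cut_strategy=cut_strategy).mean
    if measure == "mi":
        return mutual_information(series)
    if measure == "te":
        return transfer_entropy_sum(series)
    raise ValueError("measure must be 'phi', 'mi' or 'te'")


def sweep(
    traj: Trajectory,
    measure: str = "phi",
    zetas=DEFAULT_ZETAS,
    visual_fields=DEFAULT_VISUAL_FIELDS,
    dt: float | None = None,
    delta: float = 0.0,
    weighting: str = "by_state",
    cut_strategy: str = "cut_one",
) -> HeatMap:
    """Heat map of a measure over the (ζ, visual field) grid.

    The trajectory must already be at the analysis time step (``dt`` only
    validates).  Cells that fail are set to NaN and recorded in the metadata;
    identical binarizations (e.g. saturated cells) are computed once.
    """
    dt = traj.dt if dt is None else dt
    if abs(dt - traj.dt) > 1e-9:
        raise ValueError("resample the trajectory to dt before sweeping")
    hs = derive_headings(traj)
    cells = np.full((len(visual_fields), len(zetas)), np.nan)
    failures = []
    cache: dict[bytes, float] = {}
    for (r, vf), (c, zeta) in itertools.product(enumerate(visual_fields), enumerate(zetas)):
        try:
            params = BinarizationParams(zeta=zeta, visual_field=vf, delta=delta, dt=dt)
            series = binarize(traj, params, headings=hs)
            key = series.states.tobytes()
            if key not in cache:
                cache[key] = _measure_value(measure, series, weighting, cut_strategy)
            cells[r, c] = cache[key]
        except Exception as exc:  # pragma: no cover - defensive per-cell guard
            failures.append({"zeta": zeta, "visual_field": vf, "error": str(exc)})
            logger.warning("cell (zeta=%s, vf=%.3f) failed: %s", zeta, vf, exc)
    meta = {
        "measure": measure,
        "n": traj.n,
        "dt": dt,
        "delta": delta,
        "weighting": weighting,
        "cut_strategy": cut_strategy,
        "failures": failures,
    }
    return HeatMap(rows=tuple(visual_fields), cols=tuple(zetas), cells=cells, meta=meta)


def matrix_distance(a: HeatMap, b: HeatMap, kind: str = "frobenius") -> float:
    """Distance between two heat maps on identical grids.

    ``frobenius``: Frobenius norm of the difference divided by the square
    root of the cell count (so a uniform offset of c gives |c|);
    ``mean_abs``: mean absolute difference.
    """
    if a.rows != b.rows or a.cols != b.cols:
        raise ValueError("heat maps are on different grids")
    diff = a.cells - b.cells
    if kind == "frobenius":
        return float(np.linalg.norm(diff) / math.sqrt(diff.size))
    if kind == "mean_abs":
        return float(np.abs(diff).mean())
    raise ValueError("kind must be 'frobenius' or 'mean_abs'")


def baseline_adjusted_md(groups: dict[int, list[HeatMap]], kind: str = "frobenius") -> dict[tuple[int, int], float]:
    """Mean inter-group matrix distance minus the pooled intra-group baseline.

    The baseline is the mean over all within-group pairwise distances, pooled
    over every group with at least two samples.  Returned per adjacent group
    pair (N, N+1); values can be negative when groups overlap more than
    samples within a group do.
    """
    intra = []
    for n, maps in groups.items():
        if len(maps) < 2:
            logger.warning("group N=%d has a single sample; excluded from the baseline", n)
            continue
        intra.extend(
            matrix_distance(x, y, kind) for x, y in itertools.combinations(maps, 2)
        )
    if not intra:
        raise ValueError("no group has two or more samples; baseline undefined")
    baseline = float(np.mean(intra))
    sizes = sorted(groups)
    out = {}
    for n1, n2 in zip(sizes[:-1], sizes[1:]):
        inter = [
            matrix_distance(x, y, kind)
            for x, y in itertools.product(groups[n1], groups[n2])
        ]
        out[(n1, n2)] = float(np.mean(inter) - baseline)
    return out


def compare_groups(x, y, test: str = "welch_t"):
    """Standard two-sided test between two samples: (statistic, p-value).

    ``welch_t`` (unequal-variance t), ``wilcoxon_signed`` (paired) or
    ``mann_whitney_u``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "welch_t":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif test == "wilcoxon_signed":
        if len(x) != len(y):
            raise ValueError("wilcoxon_signed requires paired samples of equal length")
        res = stats.wilcoxon(x, y)
    elif test == "mann_whitney_u":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError("unknown test " + test)
    return float(res.statistic), float(res.pvalue)
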