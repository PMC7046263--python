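"""Comparison measures: mutual information and summed transfer entropy.

Both are plug-in (maximum-likelihood) estimates on the empirical joint
distributions of the binary collective process, in bits (log base 2), with
0·log 0 := 0 and no bias correction.  MI is between the collective state and
its lag; TE sums the pairwise node-level transfer entropies with history
length 1.
"""

from __future__ import annotations

import numpy as np

from .binarize import StateSeries
from .tpm import states_to_codes


def _states_of(series) -> np.ndarray:
    return series.states if isinstance(series, StateSeries) else np.asarray(series)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_counts(*columns: np.ndarray) -> np.ndarray:
    """Contingency counts over tuples of integer columns."""
    stacked = np.stack(columns, axis=1)
    _, counts = np.unique(stacked, axis=0, return_counts=True)
    return counts


def mutual_information(series, lag_steps: int = 1) -> float:
    """I(X(t); X(t−lag)) between collective states, in bits.

    Plug-in estimate H(X(t)) + H(X(t−lag)) − H(X(t), X(t−lag)).
    """
    states = _states_of(series)
    codes = states_to_codes(states)
    if len(codes) <= lag_steps:
        raise ValueError("series shorter than the lag")
    past = codes[:-lag_steps]
    pres = codes[lag_steps:]
    h_pres = _entropy(np.bincount(pres))
    h_past = _entropy(np.bincount(past))
    h_joint = _entropy(_joint_counts(past, pres))
    return max(h_pres + h_past - h_joint, 0.0)


def transfer_entropy(series, source: int, target: int, lag_steps: int = 1) -> float:
    """Pairwise transfer entropy T_{source→target} in bits (1-based node ids).

    H(x_j(t) | x_j(t−1)) − H(x_j(t) | x_i(t−1), x_j(t−1)) by plug-in counts.
    """
    states = _states_of(series)
    xi = states[:, source - 1].astype(np.int64)
    xj = states[:, target - 1].astype(np.int64)
    jp, jn = xj[:-lag_steps], xj[lag_steps:]
    ip = xi[:-lag_steps]
    # H(jn | jp) = H(jn, jp) - H(jp)
    h1 = _entropy(_joint_counts(jp, jn)) - _entropy(np.bincount(jp))
    # H(jn | ip, jp) = H(jn, ip, jp) - H(ip, jp)
    h2 = _entropy(_joint_counts(ip, jp, jn)) - _entropy(_joint_counts(ip, jp))
    return max(h1 - h2, 0.0)


def transfer_entropy_sum(series, lag_steps: int = 1) -> float:
    """Sum of pairwise transfer entropies over all ordered node pairs (bits)."""
    states = _states_of(series)
    n = states.shape[1]
    if n < 2:
        raise ValueError("transfer entropy needs at least 2 nodes")
    total = 0.0
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i != j:
                total += transfer_entropy(states, i, j, lag_steps)
    return total
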