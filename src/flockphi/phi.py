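"""IIT 3.0 quantities: repertoires, concepts, system Phi and the major complex.

The quantities computed here follow the standard IIT 3.0 formulation on a
binary state-by-node TPM:

* **cause/effect repertoires** — distributions over a purview's past/future
  states induced by clamping a mechanism to its current state and
  marginalising everything unconstrained with the uniform (maximum-entropy)
  distribution; mechanism nodes act as independent virtual elements.
* **small phi** — earth mover's distance (Hamming ground metric) between a
  repertoire and its minimum-information partition, maximised over purviews;
  a mechanism whose cause and effect sides are both irreducible specifies a
  concept.
* **big Phi** — the extended EMD between the intact cause-effect structure
  and the structure after the least-destructive unidirectional system cut
  (the system MIP), searched either over all directed bipartitions or over
  the 2N single-node "cut one" bipartitions.

Node ids are 1-based in the public API (matching trajectory individual
labels); collective states are tuples of bits ordered by node id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .tpm import StateByNodeTPM

__all__ = [
    "Repertoire",
    "MaximallyIrreducible",
    "Concept",
    "CauseEffectStructure",
    "SystemCut",
    "PhiResult",
    "PhiSummary",
    "effect_repertoire",
    "cause_repertoire",
    "emd",
    "small_phi",
    "cause_effect_structure",
    "apply_cut",
    "cut_one_cuts",
    "exhaustive_cuts",
    "ces_distance",
    "big_phi",
    "major_complex",
    "phi_over_series",
]


# ---------------------------------------------------------------------------
# helpers: public 1-based node tuples <-> internal bitmasks
# ---------------------------------------------------------------------------


def _as_probs(tpm) -> tuple[np.ndarray, int]:
    if isinstance(tpm, StateByNodeTPM):
        return np.ascontiguousarray(tpm.probs), tpm.n
    arr = np.ascontiguousarray(np.asarray(tpm, dtype=np.float64))
    n = arr.shape[1]
    if arr.shape[0] != 1 << n:
        raise ValueError("TPM must have shape (2**n, n)")
    return arr, n


def _state_to_int(state, n: int) -> int:
    if isinstance(state, (int, np.integer)):
        s = int(state)
        if not 0 <= s < (1 << n):
            raise ValueError(f"state {s} out of range for n={n}")
        return s
    bits = tuple(int(b) for b in state)
    if len(bits) != n or any(b not in (0, 1) for b in bits):
        raise ValueError(f"state {state!r} is not a length-{n} bit vector")
    return sum(b << i for i, b in enumerate(bits))


def _int_to_state(s: int, n: int) -> tuple[int, ...]:
    return tuple((s >> i) & 1 for i in range(n))


def _nodes_to_mask(nodes) -> int:
    return sum(1 << (int(v) - 1) for v in nodes)


def _mask_to_nodes(mask: int) -> tuple[int, ...]:
    return tuple(i + 1 for i in range(mask.bit_length()) if (mask >> i) & 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Repertoire:
    """Probability distribution over a purview's states.

    ``distribution[z]`` is the probability of the purview state with code
    ``z`` (little-endian over the purview nodes in ascending id order).
    """

    purview: tuple[int, ...]
    distribution: np.ndarray
    direction: str  # "cause" | "effect"

    def __post_init__(self):
        d = np.asarray(self.distribution, dtype=float)
        if d.ndim != 1 or d.shape[0] != 1 << len(self.purview):
            raise ValueError("distribution length must be 2**|purview|")
        if d.min() < -1e-12 or abs(d.sum() - 1.0) > 1e-10:
            raise ValueError("repertoire must be a probability distribution")
        object.__setattr__(self, "distribution", d)


@dataclass(frozen=True)
class MaximallyIrreducible:
    """One side (cause or effect) of a concept."""

    purview: tuple[int, ...]
    repertoire: Repertoire
    phi: float


@dataclass(frozen=True)
class Concept:
    mechanism: tuple[int, ...]
    phi: float
    cause: MaximallyIrreducible
    effect: MaximallyIrreducible


@dataclass
class CauseEffectStructure:
    """All concepts of a subsystem in a state (phi > 0 only)."""

    concepts: tuple[Concept, ...]
    state: tuple[int, ...]
    subsystem: tuple[int, ...]
    # kernel-layout views used by ces_distance
    _phis: np.ndarray = field(repr=False, default=None)
    _cause_full: np.ndarray = field(repr=False, default=None)
    _effect_full: np.ndarray = field(repr=False, default=None)
    _zc: np.ndarray = field(repr=False, default=None)
    _crep: np.ndarray = field(repr=False, default=None)
    _emarg: np.ndarray = field(repr=False, default=None)
    _e0: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def total_phi(self) -> float:
        return float(sum(c.phi for c in self.concepts))


@dataclass(frozen=True)
class SystemCut:
    """Unidirectional bipartition: edges from ``from_part`` to ``to_part`` severed."""

    from_part: tuple[int, ...]
    to_part: tuple[int, ...]

    def __post_init__(self):
        if not self.from_part or not self.to_part:
            raise ValueError("cut parts must be non-empty")
        if set(self.from_part) & set(self.to_part):
            raise ValueError("cut parts must be disjoint")

    def isolates(self, node: int) -> bool:
        """True when this cut severs exactly one node from the rest."""
        return self.from_part == (node,) or self.to_part == (node,)

    def __str__(self) -> str:
        fmt = lambda part: "{" + ",".join(str(v) for v in part) + "}"
        return f"{fmt(self.from_part)} -/-> {fmt(self.to_part)}"


@dataclass
class PhiResult:
    state: tuple[int, ...]
    subsystem: tuple[int, ...]
    Phi: float
    mip: SystemCut | None
    ces_intact: CauseEffectStructure | None = None
    ces_cut: CauseEffectStructure | None = None
    reachable: bool = True


@dataclass
class PhiSummary:
    """Aggregates of per-state Phi over a state series or state space."""

    mean: float
    sd: float
    max: float
    min: float
    per_state: dict[tuple[int, ...], float]
    weighting: str
    mips: dict[tuple[int, ...], SystemCut | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# repertoires and EMD
# ---------------------------------------------------------------------------


def effect_repertoire(tpm, state, mechanism, purview) -> Repertoire:
    """Distribution over the purview's next states given the mechanism's state.

    Factorises over purview nodes; unconstrained inputs are marginalised
    uniformly.  The empty purview gives the scalar distribution.
    """
    probs, n = _as_probs(tpm)
    s = _state_to_int(state, n)
    M = _nodes_to_mask(mechanism)
    Z = _nodes_to_mask(purview)
    E = K._effect_table(probs, n, s)
    pv = tuple(sorted(purview))
    k = len(pv)
    dist = np.ones(1 << k)
    for pos, node in enumerate(pv):
        p_on = E[M, node - 1]
        codes = (np.arange(1 << k) >> pos) & 1
        dist *= np.where(codes == 1, p_on, 1.0 - p_on)
    return Repertoire(purview=pv, distribution=dist, direction="effect")


def cause_repertoire(tpm, state, mechanism, purview) -> Repertoire | None:
    """Bayesian-inverted distribution over the purview's past states.

    Mechanism nodes contribute independent likelihoods (virtual elements)
    multiplied and renormalised; a uniform prior is placed on past purview
    states.  Returns None when the mechanism's state is impossible under
    every past purview state (the repertoire is undefined).
    """
    probs, n = _as_probs(tpm)
    s = _state_to_int(state, n)
    Mp = _nodes_to_mask(mechanism)
    Z = _nodes_to_mask(purview)
    gflat, goff = K._cause_tables(probs, n, s)
    pv = tuple(sorted(purview))
    sz = 1 << len(pv)
    out = np.empty(1 << n)
    mass = K._cause_block(gflat, goff, n, Mp, Z, out)
    if Mp != 0 and mass <= 0.0:
        return None
    return Repertoire(purview=pv, distribution=out[:sz].copy(), direction="cause")


def emd(p: Repertoire, q: Repertoire) -> float:
    """Exact earth mover's distance with the Hamming ground metric."""
    if p.purview != q.purview:
        raise ValueError("repertoires are over different purviews")
    H = K.hamming_matrix(len(p.purview))
    return float(K._emd(p.distribution, q.distribution, H))


# ---------------------------------------------------------------------------
# concepts and structures
# ---------------------------------------------------------------------------


def _subsystem_probs(tpm, subsystem):
    """Reduce to a subsystem (or pass through) and return internal pieces."""
    probs, n = _as_probs(tpm)
    if subsystem is None:
        return probs, n, tuple(range(1, n + 1))
    sub = tuple(sorted(int(v) for v in subsystem))
    if not sub:
        raise ValueError("subsystem must be non-empty")
    if sub == tuple(range(1, n + 1)):
        return probs, n, sub
    mask = _nodes_to_mask(sub)
    reduced = K._reduce_tpm(probs, n, mask)
    return np.ascontiguousarray(reduced), len(sub), sub


def _restrict_state(state, n, subsystem_nodes):
    """Compress a full-system state onto subsystem nodes."""
    if isinstance(state, (int, np.integer)):
        bits = _int_to_state(int(state), n)
    else:
        bits = tuple(int(b) for b in state)
    return tuple(bits[v - 1] for v in subsystem_nodes)


def small_phi(tpm, state, mechanism) -> Concept | None:
    """The concept specified by a mechanism, or None when reducible.

    phi is the minimum of the maximally-irreducible cause and effect values;
    purview ties keep the smallest purview bitmask (ascending node order).
    """
    probs, n = _as_probs(tpm)
    s = _state_to_int(state, n)
    M = _nodes_to_mask(mechanism)
    if M == 0:
        raise ValueError("mechanism must be non-empty")
    E = K._effect_table(probs, n, s)
    gflat, goff = K._cause_tables(probs, n, s)
    H = K.hamming_matrix(n)
    phi_e, Ze = K._phi_effect_max(E, n, M)
    if phi_e <= K.EPS:
        return None
    phi_c, Zc, crep = K._phi_cause_max(gflat, goff, n, M, H)
    if phi_c <= K.EPS:
        return None
    mech = tuple(sorted(mechanism))
    cause_pv = _mask_to_nodes(Zc)
    effect_pv = _mask_to_nodes(Ze)
    cause_rep = Repertoire(
        purview=cause_pv,
        distribution=crep[: 1 << len(cause_pv)].copy(),
        direction="cause",
    )
    effect_rep = effect_repertoire(probs, s, mech, effect_pv)
    return Concept(
        mechanism=mech,
        phi=float(min(phi_c, phi_e)),
        cause=MaximallyIrreducible(cause_pv, cause_rep, float(phi_c)),
        effect=MaximallyIrreducible(effect_pv, effect_rep, float(phi_e)),
    )


def cause_effect_structure(tpm, state, subsystem=None) -> CauseEffectStructure:
    """All concepts (phi > 0) over every non-empty mechanism of the subsystem."""
    probs, nfull = _as_probs(tpm)
    sub_probs, n, sub_nodes = _subsystem_probs(tpm, subsystem)
    sub_state = _restrict_state(state, nfull, sub_nodes)
    s = _state_to_int(sub_state, n)
    mechs, phis, zc, ze, creps, emargs, cfull, efull, cnt, E = K._ces(sub_probs, n, s)
    gflat, goff = K._cause_tables(sub_probs, n, s)
    concepts = []
    for idx in range(cnt):
        M = int(mechs[idx])
        mech_local = _mask_to_nodes(M)
        mech = tuple(sub_nodes[v - 1] for v in mech_local)
        cause_pv_local = _mask_to_nodes(int(zc[idx]))
        effect_pv_local = _mask_to_nodes(int(ze[idx]))
        out = np.empty(1 << n)
        K._cause_block(gflat, goff, n, M, int(zc[idx]), out)
        cause_rep = Repertoire(
            purview=tuple(sub_nodes[v - 1] for v in cause_pv_local),
            distribution=out[: 1 << len(cause_pv_local)].copy(),
            direction="cause",
        )
        e_rep = effect_repertoire(sub_probs, s, mech_local, effect_pv_local)
        e_rep = Repertoire(
            purview=tuple(sub_nodes[v - 1] for v in effect_pv_local),
            distribution=e_rep.distribution,
            direction="effect",
        )
        phi_c, _, _ = K._phi_cause_max(gflat, goff, n, M, K.hamming_matrix(n))
        phi_e, _ = K._phi_effect_max(E, n, M)
        concepts.append(
            Concept(
                mechanism=mech,
                phi=float(phis[idx]),
                cause=MaximallyIrreducible(cause_rep.purview, cause_rep, float(phi_c)),
                effect=MaximallyIrreducible(e_rep.purview, e_rep, float(phi_e)),
            )
        )
    return CauseEffectStructure(
        concepts=tuple(concepts),
        state=sub_state,
        subsystem=sub_nodes,
        _phis=phis[:cnt].copy(),
        _cause_full=cfull[:cnt].copy(),
        _effect_full=efull[:cnt].copy(),
        _zc=zc[:cnt].copy(),
        _crep=creps[:cnt].copy(),
        _emarg=emargs[:cnt].copy(),
        _e0=E[0].copy(),
    )


def ces_distance(a: CauseEffectStructure, b: CauseEffectStructure) -> float:
    """Extended EMD between cause-effect structures (intact → cut orientation).

    Each of ``a``'s concepts transports its phi mass onto ``b``'s concepts or
    the null concept (unconstrained repertoires of ``a``'s subsystem); the
    ground cost is the sum of cause- and effect-repertoire EMDs over the full
    subsystem space.
    """
    if a.subsystem != b.subsystem or a.state != b.state:
        raise ValueError("structures must share subsystem and state")
    n = len(a.subsystem)
    H = K.hamming_matrix(n)
    return float(
        K._ces_distance(
            a._phis, a._zc, a._crep, a._emarg, len(a.concepts),
            b._phis, b._zc, b._crep, b._emarg, len(b.concepts),
            a._e0, n, H,
        )
    )


# ---------------------------------------------------------------------------
# system cuts and Phi
# ---------------------------------------------------------------------------


def cut_one_cuts(n: int, nodes: tuple[int, ...] | None = None) -> list[SystemCut]:
    """The 2n single-node bipartitions: {i} -/-> rest and rest -/-> {i}."""
    if n < 2:
        raise ValueError("cut-one needs at least 2 nodes")
    nodes = nodes or tuple(range(1, n + 1))
    cuts = []
    for v in nodes:
        rest = tuple(w for w in nodes if w != v)
        cuts.append(SystemCut(from_part=(v,), to_part=rest))
        cuts.append(SystemCut(from_part=rest, to_part=(v,)))
    return cuts


def exhaustive_cuts(n: int, nodes: tuple[int, ...] | None = None) -> list[SystemCut]:
    """Every unidirectional bipartition (both directions of each split)."""
    if n < 2:
        raise ValueError("cuts need at least 2 nodes")
    nodes = nodes or tuple(range(1, n + 1))
    cuts = []
    for r in range(1, n):
        for part in itertools.combinations(nodes, r):
            rest = tuple(w for w in nodes if w not in part)
            cuts.append(SystemCut(from_part=part, to_part=rest))
    return cuts


def apply_cut(tpm, cut: SystemCut) -> StateByNodeTPM:
    """TPM with the cut's from→to inputs replaced by maximum-entropy noise."""
    probs, n = _as_probs(tpm)
    fm = _nodes_to_mask(cut.from_part)
    tm = _nodes_to_mask(cut.to_part)
    out = K._cut_tpm(probs, n, fm, tm)
    return StateByNodeTPM(probs=out, n=n)


def _cut_masks(cuts: list[SystemCut], node_order: tuple[int, ...]):
    pos = {v: i for i, v in enumerate(node_order)}
    fm = np.array([sum(1 << pos[v] for v in c.from_part) for c in cuts], dtype=np.int64)
    tm = np.array([sum(1 << pos[v] for v in c.to_part) for c in cuts], dtype=np.int64)
    return fm, tm


def _sorted_cuts(cuts: list[SystemCut]) -> list[SystemCut]:
    """Deterministic search order: smallest from-part, then lexicographic."""
    return sorted(
        dict.fromkeys(cuts),
        key=lambda c: (len(c.from_part), c.from_part, c.to_part),
    )


def big_phi(
    tpm,
    state,
    subsystem=None,
    cut_strategy: str = "cut_one",
    keep_ces: bool = True,
) -> PhiResult:
    """System-level integrated information Phi under a MIP search.

    ``cut_strategy`` is ``"cut_one"`` (the 2N single-node cuts) or
    ``"exhaustive"`` (all directed bipartitions).  States unreachable under
    the TPM have Phi defined as 0 and are flagged.  MIP ties keep the
    smallest cut in the deterministic search order.
    """
    probs, nfull = _as_probs(tpm)
    sub_probs, n, sub_nodes = _subsystem_probs(tpm, subsystem)
    sub_state = _restrict_state(state, nfull, sub_nodes)
    s = _state_to_int(sub_state, n)
    if n < 2:
        return PhiResult(state=sub_state, subsystem=sub_nodes, Phi=0.0, mip=None)
    if cut_strategy == "cut_one":
        cuts = _sorted_cuts(cut_one_cuts(n, sub_nodes))
    elif cut_strategy == "exhaustive":
        cuts = _sorted_cuts(exhaustive_cuts(n, sub_nodes))
    else:
        raise ValueError("cut_strategy must be 'cut_one' or 'exhaustive'")
    fm, tm = _cut_masks(cuts, sub_nodes)
    phi, mip_idx, reachable = K._big_phi(sub_probs, n, s, fm, tm)
    mip = cuts[mip_idx] if mip_idx >= 0 else None
    result = PhiResult(
        state=sub_state,
        subsystem=sub_nodes,
        Phi=float(phi),
        mip=mip,
        reachable=bool(reachable),
    )
    if keep_ces and reachable:
        result.ces_intact = cause_effect_structure(sub_probs, s)
        if mip is not None:
            local = SystemCut(
                from_part=tuple(sub_nodes.index(v) + 1 for v in mip.from_part),
                to_part=tuple(sub_nodes.index(v) + 1 for v in mip.to_part),
            )
            fm1, tm1 = _cut_masks([local], tuple(range(1, n + 1)))
            cut_probs = K._cut_tpm(sub_probs, n, int(fm1[0]), int(tm1[0]))
            result.ces_cut = cause_effect_structure(cut_probs, s)
    return result


def major_complex(tpm, state, cut_strategy: str = "cut_one") -> tuple[tuple[int, ...], PhiResult]:
    """The node subset maximising Phi (singletons score 0 by definition).

    Ties keep the smaller subset (by size, then lexicographic order).
    """
    probs, n = _as_probs(tpm)
    if n > 8:
        raise ValueError("major complex search is limited to n <= 8")
    best_sub: tuple[int, ...] = (1,)
    bits = _int_to_state(_state_to_int(state, n), n)
    best = PhiResult(state=(bits[0],), subsystem=(1,), Phi=0.0, mip=None)
    for size in range(2, n + 1):
        for sub in itertools.combinations(range(1, n + 1), size):
            res = big_phi(probs, state, subsystem=sub, cut_strategy=cut_strategy, keep_ces=False)
            if res.Phi > best.Phi + 1e-12:
                best = res
                best_sub = sub
    return best_sub, best


def phi_over_series(
    tpm,
    series=None,
    weighting: str = "by_state",
    cut_strategy: str = "cut_one",
) -> PhiSummary:
    """Per-state Phi table with mean, sd, max and min aggregates.

    ``by_state`` weights the 2**n collective states equally (the heat-map
    convention); ``by_time`` weights each state by its occupancy in the
    series (requires either a series or a TPM with recorded occupancy).
    Each state's Phi is computed once and reused.
    """
    from .tpm import estimate_tpm, states_to_codes  # local import, no cycle

    if tpm is None:
        if series is None:
            raise ValueError("need a TPM or a series")
        tpm = estimate_tpm(series)
    probs, n = _as_probs(tpm)
    if cut_strategy == "cut_one":
        cuts = _sorted_cuts(cut_one_cuts(n))
    else:
        cuts = _sorted_cuts(exhaustive_cuts(n))
    fm, tm = _cut_masks(cuts, tuple(range(1, n + 1)))
    nstates = 1 << n
    phis = np.zeros(nstates)
    mips: dict[tuple[int, ...], SystemCut | None] = {}
    for s in range(nstates):
        phi, mip_idx, _ = K._big_phi(probs, n, s, fm, tm)
        phis[s] = phi
        mips[_int_to_state(s, n)] = cuts[mip_idx] if mip_idx >= 0 else None
    if weighting == "by_state":
        weights = np.full(nstates, 1.0 / nstates)
    elif weighting == "by_time":
        if series is not None:
            states = series.states if hasattr(series, "states") else np.asarray(series)
            occ = np.bincount(states_to_codes(states), minlength=nstates).astype(float)
        elif isinstance(tpm, StateByNodeTPM) and tpm.occupancy is not None:
            occ = tpm.occupancy.astype(float)
        else:
            raise ValueError("by_time weighting needs a series or TPM occupancy")
        if occ.sum() <= 0:
            raise ValueError("empty occupancy")
        weights = occ / occ.sum()
    else:
        raise ValueError("weighting must be 'by_state' or 'by_time'")
    mean = float(np.sum(weights * phis))
    var = float(np.sum(weights * (phis - mean) ** 2))
    observed = weights > 0
    return PhiSummary(
        mean=mean,
        sd=float(np.sqrt(var)),
        max=float(phis[observed].max()),
        min=float(phis[observed].min()),
        per_state={_int_to_state(s, n): float(phis[s]) for s in range(nstates)},
        weighting=weighting,
        mips=mips,
    )
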