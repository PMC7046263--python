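"""Independent brute-force reference implementation of the IIT 3.0 quantities.

Everything here is deliberately naive: explicit enumeration over states,
subsets and partitions, dictionaries keyed by node tuples, and EMD solved as
an explicit linear program with scipy.  It shares no code with the package
implementation and exists to cross-check it on small systems (n <= 3-4).

Conventions mirror the package (they are part of the method's definition):
little-endian state codes, strict/non-strict thresholds, EMD with a Hamming
ground metric, mechanism partitions into two parts where a part may lack a
mechanism or a purview but not both, unidirectional system cuts replaced by
uniform noise, and null-concept padding in the structure distance.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

EPS = 1e-10


def bits_of(code, n):
    return tuple((code >> i) & 1 for i in range(n))


def code_of(bits):
    return sum(b << i for i, b in enumerate(bits))


def hamming(a, b):
    return bin(a ^ b).count("1")


def emd_lp(p, q, cost):
    """Earth mover's distance via an explicit transport LP."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    ns, nd = len(p), len(q)
    c = np.asarray(cost, dtype=float)[:ns, :nd].ravel()
    A_eq = []
    b_eq = []
    for i in range(ns):
        row = np.zeros(ns * nd)
        row[i * nd : (i + 1) * nd] = 1.0
        A_eq.append(row)
        b_eq.append(p[i])
    for j in range(nd):
        row = np.zeros(ns * nd)
        row[j::nd] = 1.0
        A_eq.append(row)
        b_eq.append(q[j])
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success, res.message
    return res.fun


def hamming_cost(k):
    size = 1 << k
    return np.array([[hamming(i, j) for j in range(size)] for i in range(size)], float)


# --- repertoires -----------------------------------------------------------


def effect_marginal(tpm, n, state_code, mech, node):
    """P(node ON next | mechanism clamped, other inputs uniform)."""
    vals = []
    for p in range(1 << n):
        if all(((p >> m) & 1) == ((state_code >> m) & 1) for m in mech):
            vals.append(tpm[p, node])
    return float(np.mean(vals))


def effect_rep(tpm, n, state_code, mech, purview):
    """Product over purview nodes of their mechanism-conditioned marginals."""
    k = len(purview)
    dist = np.ones(1 << k)
    for pos, node in enumerate(sorted(purview)):
        m = effect_marginal(tpm, n, state_code, mech, node)
        for z in range(1 << k):
            dist[z] *= m if (z >> pos) & 1 else 1.0 - m
    return dist


def cause_rep(tpm, n, state_code, mech, purview):
    """Virtual-element Bayesian inversion; None when undefined (zero mass)."""
    purview = sorted(purview)
    k = len(purview)
    dist = np.ones(1 << k)
    for i in mech:
        on = (state_code >> i) & 1
        g = np.zeros(1 << k)
        for z in range(1 << k):
            vals = []
            for p in range(1 << n):
                if all(((p >> node) & 1) == ((z >> pos) & 1) for pos, node in enumerate(purview)):
                    like = tpm[p, i] if on else 1.0 - tpm[p, i]
                    vals.append(like)
            g[z] = np.mean(vals)
        dist = dist * g
    if mech:
        s = dist.sum()
        if s <= 0:
            return None
        dist = dist / s
    else:
        dist = np.full(1 << k, 1.0 / (1 << k))
    return dist


# --- mechanism-level phi ---------------------------------------------------


def mechanism_partitions(mech, purview):
    """Unordered pairs ((M1, Z1), (M2, Z2)); a part may not be (∅, ∅)."""
    mech = tuple(sorted(mech))
    purview = tuple(sorted(purview))
    seen = set()
    out = []
    msets = [tuple(sorted(c)) for r in range(len(mech) + 1) for c in itertools.combinations(mech, r)]
    zsets = [tuple(sorted(c)) for r in range(len(purview) + 1) for c in itertools.combinations(purview, r)]
    for m1 in msets:
        m2 = tuple(v for v in mech if v not in m1)
        for z1 in zsets:
            z2 = tuple(v for v in purview if v not in z1)
            if (not m1 and not z1) or (not m2 and not z2):
                continue
            key = frozenset([(m1, z1), (m2, z2)])
            if key in seen:
                continue
            seen.add(key)
            out.append(((m1, z1), (m2, z2)))
    return out


def partitioned_rep(tpm, n, state_code, parts, direction):
    """Tensor product of the two parts' repertoires over the joint purview."""
    (m1, z1), (m2, z2) = parts
    purview = tuple(sorted(z1 + z2))
    k = len(purview)
    if direction == "effect":
        r1 = effect_rep(tpm, n, state_code, m1, z1)
        r2 = effect_rep(tpm, n, state_code, m2, z2)
    else:
        r1 = cause_rep(tpm, n, state_code, m1, z1)
        r2 = cause_rep(tpm, n, state_code, m2, z2)
        if r1 is None or r2 is None:
            return None
    pos1 = [purview.index(v) for v in sorted(z1)]
    pos2 = [purview.index(v) for v in sorted(z2)]
    dist = np.zeros(1 << k)
    for z in range(1 << k):
        i1 = sum(((z >> p) & 1) << j for j, p in enumerate(pos1))
        i2 = sum(((z >> p) & 1) << j for j, p in enumerate(pos2))
        dist[z] = r1[i1] * r2[i2]
    return dist


def phi_one_side(tpm, n, state_code, mech, purview, direction):
    """phi of mechanism over one purview: EMD to the best partition."""
    if direction == "effect":
        whole = effect_rep(tpm, n, state_code, mech, purview)
    else:
        whole = cause_rep(tpm, n, state_code, mech, purview)
        if whole is None:
            return 0.0
    cost = hamming_cost(len(purview))
    best = np.inf
    for parts in mechanism_partitions(mech, purview):
        cut = partitioned_rep(tpm, n, state_code, parts, direction)
        if cut is None:
            continue
        best = min(best, emd_lp(whole, cut, cost))
        if best <= EPS:
            return 0.0
    return best


def phi_max(tpm, n, state_code, mech, direction):
    """Maximally irreducible phi over purviews; ties keep smallest mask."""
    nodes = range(n)
    best_phi = -1.0
    best_purview = None
    purviews = sorted(
        (tuple(sorted(c)) for r in range(1, n + 1) for c in itertools.combinations(nodes, r)),
        key=lambda pv: sum(1 << v for v in pv),
    )
    for pv in purviews:
        val = phi_one_side(tpm, n, state_code, mech, pv, direction)
        if val > best_phi + EPS:
            best_phi = val
            best_purview = pv
    return best_phi, best_purview


def concept(tpm, n, state_code, mech):
    """(phi, cause side, effect side) or None when reducible."""
    phi_e, pv_e = phi_max(tpm, n, state_code, mech, "effect")
    if phi_e <= EPS:
        return None
    phi_c, pv_c = phi_max(tpm, n, state_code, mech, "cause")
    if phi_c <= EPS:
        return None
    return {
        "mechanism": tuple(sorted(mech)),
        "phi": min(phi_c, phi_e),
        "cause": (pv_c, cause_rep(tpm, n, state_code, mech, pv_c), phi_c),
        "effect": (pv_e, effect_rep(tpm, n, state_code, mech, pv_e), phi_e),
    }


# --- structures and big phi ------------------------------------------------


def unconstrained_effect(tpm, n):
    dist = np.ones(1 << n)
    for s in range(1 << n):
        for i in range(n):
            m = float(np.mean(tpm[:, i]))
            dist[s] *= m if (s >> i) & 1 else 1.0 - m
    return dist


def expand_full(tpm, n, state_code, con):
    """Expand a concept's repertoires over the full state space."""
    pv_c, rep_c, _ = con["cause"]
    pv_e, rep_e, _ = con["effect"]
    full_c = np.zeros(1 << n)
    comp = [v for v in range(n) if v not in pv_c]
    for s in range(1 << n):
        zc = sum(((s >> v) & 1) << j for j, v in enumerate(sorted(pv_c)))
        full_c[s] = rep_c[zc] / (1 << len(comp))
    full_e = np.ones(1 << n)
    for s in range(1 << n):
        v = 1.0
        for i in range(n):
            if i in pv_e:
                m = effect_marginal(tpm, n, state_code, con["mechanism"], i)
            else:
                m = float(np.mean(tpm[:, i]))
            v *= m if (s >> i) & 1 else 1.0 - m
        full_e[s] = v
    return full_c, full_e


def ces(tpm, n, state_code):
    out = []
    for r in range(1, n + 1):
        for mech in itertools.combinations(range(n), r):
            con = concept(tpm, n, state_code, mech)
            if con is not None:
                con["cause_full"], con["effect_full"] = expand_full(tpm, n, state_code, con)
                out.append(con)
    return out


def ces_distance(tpm, n, A, B):
    """Extended EMD between structures, null concept from the intact system."""
    null_c = np.full(1 << n, 1.0 / (1 << n))
    null_e = unconstrained_effect(tpm, n)
    H = hamming_cost(n)
    locsA = [(c["cause_full"], c["effect_full"], c["phi"]) for c in A]
    locsB = [(c["cause_full"], c["effect_full"], c["phi"]) for c in B]
    nA, nB = len(locsA), len(locsB)
    D = np.zeros((nA + 1, nB + 1))
    for i, (ca, ea, _) in enumerate(locsA):
        for j, (cb, eb, _) in enumerate(locsB):
            D[i, j] = emd_lp(ca, cb, H) + emd_lp(ea, eb, H)
        D[i, nB] = emd_lp(ca, null_c, H) + emd_lp(ea, null_e, H)
    for j, (cb, eb, _) in enumerate(locsB):
        D[nA, j] = emd_lp(null_c, cb, H) + emd_lp(null_e, eb, H)
    P = np.array([c[2] for c in locsA] + [0.0])
    Q = np.array([c[2] for c in locsB] + [0.0])
    if P.sum() >= Q.sum():
        Q[nB] = P.sum() - Q[nB:].sum() - Q[:nB].sum()
    else:
        P[nA] = Q.sum() - P.sum()
    if P.sum() <= 1e-15:
        return 0.0
    return emd_lp(P, Q, D)


def cut_tpm(tpm, n, from_part, to_part):
    out = tpm.copy()
    from_bits = list(from_part)
    for i in to_part:
        for s in range(1 << n):
            vals = []
            for pattern in itertools.product([0, 1], repeat=len(from_bits)):
                p = s
                for b, v in zip(from_bits, pattern):
                    p = (p & ~(1 << b)) | (v << b)
                vals.append(tpm[p, i])
            out[s, i] = np.mean(vals)
    return out


def reachable(tpm, n, state_code):
    for p in range(1 << n):
        prob = 1.0
        for i in range(n):
            t = tpm[p, i]
            prob *= t if (state_code >> i) & 1 else 1.0 - t
        if prob > 0:
            return True
    return False


def all_cuts(n):
    """All unidirectional bipartitions of 0..n-1 (0-based node indices)."""
    out = []
    nodes = list(range(n))
    for r in range(1, n):
        for part in itertools.combinations(nodes, r):
            rest = tuple(v for v in nodes if v not in part)
            out.append((part, rest))
    return out


def cut_one(n):
    out = []
    for v in range(n):
        rest = tuple(w for w in range(n) if w != v)
        out.append(((v,), rest))
        out.append((rest, (v,)))
    return out


def big_phi(tpm, n, state_code, cuts):
    if not reachable(tpm, n, state_code):
        return 0.0
    A = ces(tpm, n, state_code)
    best = np.inf
    for from_part, to_part in cuts:
        ct = cut_tpm(tpm, n, from_part, to_part)
        B = ces(ct, n, state_code)
        best = min(best, ces_distance(tpm, n, A, B))
    return max(best, 0.0)
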