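"""Numba kernels for IIT 3.0 quantities on binary state-by-node TPMs.

Everything here works on plain arrays so it can be jitted:

* collective states are integers with little-endian node bits
  (node ``i``'s state is ``(s >> i) & 1``),
* a TPM is a ``(2**n, n)`` float array of conditional ON-probabilities,
* node subsets (mechanisms, purviews, cut parts) are bitmasks.

The public API in :mod:`flockphi.phi` wraps these kernels in dataclasses.

Conventions (fixed throughout the package):

* Effect repertoires factorise over purview nodes (virtual-element /
  conditional-independence construction), so the earth mover's distance
  between two effect repertoires with the Hamming ground metric reduces to
  the sum of per-node marginal differences.  Cause repertoires do not
  factorise and require an exact transport solve.
* Mechanism-level partitions are unordered pairs ((M1, Z1), (M2, Z2)) with
  M1/M2 partitioning the mechanism and Z1/Z2 the purview; a part may have an
  empty mechanism or an empty purview but not both.
* System-level cuts sever the inputs from one part to the other; severed
  inputs are replaced by independent maximum-entropy noise (uniform
  marginalisation over the severed past bits).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Small-phi values at or below this are treated as zero (reducible).
EPS = 1e-10

_INF = 1e18


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        c += x & 1
        x >>= 1
    return c


@njit(cache=True)
def _compress(p, mask):
    """Extract the bits of ``p`` at the positions set in ``mask``."""
    z = 0
    bit = 0
    while mask:
        if mask & 1:
            z |= (p & 1) << bit
            bit += 1
        mask >>= 1
        p >>= 1
    return z


def hamming_matrix(n_bits: int) -> np.ndarray:
    """Hamming ground-cost matrix between the ``2**n_bits`` binary states."""
    size = 1 << n_bits
    idx = np.arange(size)
    xor = idx[:, None] ^ idx[None, :]
    return np.vectorize(lambda v: bin(v).count("1"))(xor).astype(np.float64)


# ---------------------------------------------------------------------------
# Exact earth mover's distance (transportation problem)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _emd(a0, b0, C):
    """Exact EMD between nonnegative vectors of equal mass.

    Successive-shortest-path min-cost flow on the dense bipartite transport
    graph, with Johnson potentials so Dijkstra applies throughout.  Sizes
    here are tiny (<= 64 points a side), so dense scans are fine.
    """
    ns = a0.shape[0]
    nd = b0.shape[0]
    a = a0.copy()
    b = b0.copy()
    total = 0.0
    for i in range(ns):
        total += a[i]
    if total <= 1e-15:
        return 0.0
    tol = 1e-12 * max(total, 1.0)
    x = np.zeros((ns, nd))
    pot_s = np.zeros(ns)
    pot_t = np.zeros(nd)
    dist_s = np.empty(ns)
    dist_t = np.empty(nd)
    vis_s = np.empty(ns, np.bool_)
    vis_t = np.empty(nd, np.bool_)
    par_t = np.empty(nd, np.int64)  # source feeding sink j on the path
    par_s = np.empty(ns, np.int64)  # sink feeding source i (residual arc)
    remaining = total
    while remaining > tol:
        for i in range(ns):
            dist_s[i] = 0.0 if a[i] > tol else _INF
            vis_s[i] = False
            par_s[i] = -1
        for j in range(nd):
            dist_t[j] = _INF
            vis_t[j] = False
            par_t[j] = -1
        while True:
            best = _INF
            side = -1
            idx = -1
            for i in range(ns):
                if not vis_s[i] and dist_s[i] < best:
                    best = dist_s[i]
                    side = 0
                    idx = i
            for j in range(nd):
                if not vis_t[j] and dist_t[j] < best:
                    best = dist_t[j]
                    side = 1
                    idx = j
            if side < 0:
                break
            if side == 0:
                vis_s[idx] = True
                for j in range(nd):
                    if not vis_t[j]:
                        nd_ = best + (C[idx, j] + pot_s[idx] - pot_t[j])
                        if nd_ < dist_t[j] - 1e-15:
                            dist_t[j] = nd_
                            par_t[j] = idx
            else:
                vis_t[idx] = True
                for i in range(ns):
                    if not vis_s[i] and x[i, idx] > tol:
                        nd_ = best + (-C[i, idx] + pot_t[idx] - pot_s[i])
                        if nd_ < dist_s[i] - 1e-15:
                            dist_s[i] = nd_
                            par_s[i] = idx
        # cheapest reachable sink with unmet demand
        tgt = -1
        dbest = _INF
        for j in range(nd):
            if b[j] > tol and dist_t[j] < dbest:
                dbest = dist_t[j]
                tgt = j
        if tgt < 0:
            break  # mass mismatch below tolerance
        # update potentials
        for i in range(ns):
            d = dist_s[i]
            if d > dbest:
                d = dbest
            pot_s[i] += d
        for j in range(nd):
            d = dist_t[j]
            if d > dbest:
                d = dbest
            pot_t[j] += d
        # trace path and find bottleneck
        flow = b[tgt]
        j = tgt
        while True:
            i = par_t[j]
            if a[i] < flow and par_s[i] < 0:
                flow = a[i]
            jprev = par_s[i]
            if jprev < 0:
                break
            if x[i, jprev] < flow:
                flow = x[i, jprev]
            j = jprev
        # apply flow
        j = tgt
        while True:
            i = par_t[j]
            x[i, j] += flow
            jprev = par_s[i]
            if jprev < 0:
                a[i] -= flow
                break
            x[i, jprev] -= flow
            j = jprev
        b[tgt] -= flow
        remaining -= flow
    cost = 0.0
    for i in range(ns):
        for j in range(nd):
            if x[i, j] > 0.0:
                cost += x[i, j] * C[i, j]
    return cost


# ---------------------------------------------------------------------------
# Repertoire building blocks
# ---------------------------------------------------------------------------


@njit(cache=True)
def _effect_table(tpm, n, state):
    """E[M, i] = P(node i ON next | past mechanism M clamped to ``state``).

    Non-mechanism past nodes are marginalised with the uniform distribution.
    Row 0 (empty mechanism) is the unconstrained effect marginal.
    """
    nstates = 1 << n
    E = np.zeros((nstates, n))
    for M in range(nstates):
        sm = state & M
        cnt = 0
        for p in range(nstates):
            if (p & M) == sm:
                for i in range(n):
                    E[M, i] += tpm[p, i]
                cnt += 1
        for i in range(n):
            E[M, i] /= cnt
    return E


@njit(cache=True)
def _cause_tables(tpm, n, state):
    """Per-node likelihoods of the current state, marginalised per purview.

    Returns ``(gflat, goff)`` where for purview mask Z,
    ``gflat[i, goff[Z] + z]`` is the mean over past states ``p`` consistent
    with purview pattern ``z`` of P(node i's observed state | p).
    """
    nstates = 1 << n
    goff = np.zeros(nstates + 1, np.int64)
    for Z in range(nstates):
        goff[Z + 1] = goff[Z] + (1 << _popcount(Z))
    gflat = np.zeros((n, goff[nstates]))
    L = np.empty((n, nstates))
    for i in range(n):
        on = (state >> i) & 1
        for p in range(nstates):
            L[i, p] = tpm[p, i] if on else 1.0 - tpm[p, i]
    for Z in range(nstates):
        k = _popcount(Z)
        for p in range(nstates):
            z = _compress(p, Z)
            for i in range(n):
                gflat[i, goff[Z] + z] += L[i, p]
        norm = 1 << (n - k)
        for z in range(1 << k):
            for i in range(n):
                gflat[i, goff[Z] + z] /= norm
    return gflat, goff


# ---------------------------------------------------------------------------
# Mechanism-level phi
# ---------------------------------------------------------------------------


@njit(cache=True)
def _phi_effect_max(E, n, M):
    """Maximally-irreducible effect of mechanism M.

    Both the intact and any partitioned effect repertoire are products over
    purview nodes, so the Hamming EMD equals the sum of per-node marginal
    differences; the partition minimum is found per node.
    Returns (phi_max, best_purview_mask).  Ties take the first (lowest)
    purview mask.
    """
    nstates = 1 << n
    best_phi = -1.0
    best_Z = 0
    for Z in range(1, nstates):
        phi_z = _INF
        # M1 iterates over non-empty submasks of M (M1 = M handled specially;
        # M1 = 0 is the mirror of M1 = M).
        M1 = M
        while M1 > 0:
            M2 = M ^ M1
            if M1 == M:
                # one part is (M, Z1), the other (0, Z2) with Z2 nonempty
                val = _INF
                for i in range(n):
                    if (Z >> i) & 1:
                        d = abs(E[M, i] - E[0, i])
                        if d < val:
                            val = d
            else:
                val = 0.0
                for i in range(n):
                    if (Z >> i) & 1:
                        d1 = abs(E[M, i] - E[M1, i])
                        d2 = abs(E[M, i] - E[M2, i])
                        val += d1 if d1 < d2 else d2
            if val < phi_z:
                phi_z = val
            if phi_z <= EPS:
                break
            M1 = (M1 - 1) & M
        if phi_z > best_phi + EPS:
            best_phi = phi_z
            best_Z = Z
    return best_phi, best_Z


@njit(cache=True)
def _combine_blocks(b1, b2, Z, Z1, sz, out):
    """out[z] = b1[z restricted to Z1] * b2[z restricted to Z2] over purview Z."""
    for z in range(sz):
        z1 = 0
        z2 = 0
        bit1 = 0
        bit2 = 0
        zz = Z
        zpart = Z1
        zv = z
        while zz:
            if zz & 1:
                if zpart & 1:
                    z1 |= (zv & 1) << bit1
                    bit1 += 1
                else:
                    z2 |= (zv & 1) << bit2
                    bit2 += 1
                zv >>= 1
            zz >>= 1
            zpart >>= 1
        out[z] = b1[z1] * b2[z2]


@njit(cache=True)
def _cause_block(gflat, goff, n, Mpart, Z, out):
    """Cause repertoire of mechanism part ``Mpart`` over purview ``Z``.

    Product over mechanism nodes of their marginalised likelihoods,
    normalised.  Empty mechanism gives the uniform (unconstrained) cause
    repertoire.  Returns the repertoire's pre-normalisation mass.
    """
    sz = 1 << _popcount(Z)
    if Mpart == 0:
        u = 1.0 / sz
        for z in range(sz):
            out[z] = u
        return 1.0
    for z in range(sz):
        out[z] = 1.0
    for i in range(n):
        if (Mpart >> i) & 1:
            for z in range(sz):
                out[z] *= gflat[i, goff[Z] + z]
    s = 0.0
    for z in range(sz):
        s += out[z]
    if s > 0.0:
        for z in range(sz):
            out[z] /= s
    return s


@njit(cache=True)
def _phi_cause_max(gflat, goff, n, M, H):
    """Maximally-irreducible cause of mechanism M.

    Returns (phi_max, best_purview_mask, repertoire) where the repertoire is
    the intact cause repertoire over the best purview (length ``2**n`` buffer,
    first ``2**|Z|`` entries used).  If the mechanism state is impossible
    under every purview, phi is 0.

    Partitioned repertoires are first collected with their L1 distance to the
    intact repertoire, then transported in ascending-L1 order: EMD is bounded
    below by half the L1 distance, so the scan stops as soon as that bound
    exceeds the best partition found.
    """
    nstates = 1 << n
    uc = np.empty(nstates)
    b1 = np.empty(nstates)
    b2 = np.empty(nstates)
    # worst case: 2**|M| * 2**|Z| / 2 partitions
    maxparts = (nstates * nstates) // 2 + 1
    preps = np.empty((maxparts, nstates))
    pl1 = np.empty(maxparts)
    best_rep = np.zeros(nstates)
    best_phi = -1.0
    best_Z = 0
    for Z in range(1, nstates):
        sz = 1 << _popcount(Z)
        mass = _cause_block(gflat, goff, n, M, Z, uc)
        if mass <= 0.0:
            phi_z = 0.0
        else:
            # pass 1: build all partitioned repertoires and their L1 gaps
            nparts = 0
            zero_gap = False
            M1 = 0
            while True:
                M2 = M ^ M1
                if M1 < M2:  # unordered pairs once; Z1 free over subsets
                    Z1 = Z
                    while True:
                        if not (M1 == 0 and Z1 == 0):
                            _cause_block(gflat, goff, n, M1, Z1, b1)
                            _cause_block(gflat, goff, n, M2, Z ^ Z1, b2)
                            _combine_blocks(b1, b2, Z, Z1, sz, preps[nparts])
                            l1 = 0.0
                            for z in range(sz):
                                l1 += abs(uc[z] - preps[nparts, z])
                            if l1 < 1e-12:
                                zero_gap = True
                                break
                            pl1[nparts] = l1
                            nparts += 1
                        if Z1 == 0:
                            break
                        Z1 = (Z1 - 1) & Z
                if zero_gap or M1 == M:
                    break
                M1 = ((M1 | ~M) + 1) & M
            if zero_gap:
                phi_z = 0.0
            else:
                # pass 2: EMD in ascending-L1 order with lower-bound cutoff
                order = np.argsort(pl1[:nparts])
                phi_z = _INF
                for oi in range(nparts):
                    pi = order[oi]
                    if 0.5 * pl1[pi] >= phi_z:
                        break
                    d = _emd(uc[:sz], preps[pi, :sz], H)
                    if d < phi_z:
                        phi_z = d
                        if phi_z <= EPS:
                            break
                if phi_z <= EPS:
                    phi_z = 0.0
        if phi_z > best_phi + EPS:
            best_phi = phi_z
            best_Z = Z
            sz = 1 << _popcount(Z)
            if mass > 0.0:
                for z in range(sz):
                    best_rep[z] = uc[z]
    return best_phi, best_Z, best_rep


# ---------------------------------------------------------------------------
# Cause-effect structure and system-level Phi
# ---------------------------------------------------------------------------


@njit(cache=True)
def _expand_cause(rep, Z, n, out):
    """Expand a cause repertoire over purview Z to the full state space.

    Non-purview past nodes carry the unconstrained (uniform) cause
    distribution.
    """
    nstates = 1 << n
    k = _popcount(Z)
    u = 1.0 / (1 << (n - k))
    for s in range(nstates):
        out[s] = rep[_compress(s, Z)] * u


@njit(cache=True)
def _expand_effect(E, M, Z, n, out):
    """Expand the effect repertoire of mechanism M over purview Z.

    Purview nodes carry the mechanism-conditioned marginal, non-purview
    nodes the unconstrained effect marginal.
    """
    nstates = 1 << n
    for s in range(nstates):
        v = 1.0
        for i in range(n):
            m = E[M, i] if (Z >> i) & 1 else E[0, i]
            v *= m if (s >> i) & 1 else 1.0 - m
        out[s] = v


@njit(cache=True)
def _ces(tpm, n, state):
    """Cause-effect structure: all concepts (phi > 0) of the full system.

    Returns (mechanisms, phis, cause purview masks, effect purview masks,
    cause repertoires compressed over their purview, effect marginals over
    all nodes, expanded cause repertoires, expanded effect repertoires,
    count, effect table).
    """
    nstates = 1 << n
    H = np.empty((nstates, nstates))
    for i in range(nstates):
        for j in range(nstates):
            H[i, j] = _popcount(i ^ j)
    E = _effect_table(tpm, n, state)
    gflat, goff = _cause_tables(tpm, n, state)
    maxc = nstates - 1
    mechs = np.zeros(maxc, np.int64)
    phis = np.zeros(maxc)
    zc = np.zeros(maxc, np.int64)
    ze = np.zeros(maxc, np.int64)
    creps = np.zeros((maxc, nstates))
    emargs = np.zeros((maxc, n))
    cfull = np.zeros((maxc, nstates))
    efull = np.zeros((maxc, nstates))
    cnt = 0
    for M in range(1, nstates):
        phi_e, Ze = _phi_effect_max(E, n, M)
        if phi_e <= EPS:
            continue
        phi_c, Zc, crep = _phi_cause_max(gflat, goff, n, M, H)
        if phi_c <= EPS:
            continue
        mechs[cnt] = M
        phis[cnt] = phi_c if phi_c < phi_e else phi_e
        zc[cnt] = Zc
        ze[cnt] = Ze
        for z in range(1 << _popcount(Zc)):
            creps[cnt, z] = crep[z]
        for i in range(n):
            emargs[cnt, i] = E[M, i] if (Ze >> i) & 1 else E[0, i]
        _expand_cause(crep, Zc, n, cfull[cnt])
        _expand_effect(E, M, Ze, n, efull[cnt])
        cnt += 1
    return mechs, phis, zc, ze, creps, emargs, cfull, efull, cnt, E


@njit(cache=True)
def _project(v, V, S):
    """Re-index bits: v is compressed over mask V; keep only the bits in S ⊆ V."""
    out = 0
    bit = 0
    while V:
        if V & 1:
            if S & 1:
                out |= (v & 1) << bit
                bit += 1
            v >>= 1
        V >>= 1
        S >>= 1
    return out


@njit(cache=True)
def _cause_ground(repA, ZA, repB, ZB, H, buf1, buf2):
    """EMD between two expanded cause repertoires.

    An expanded cause repertoire is rep ⊗ uniform over the purview
    complement; the shared uniform factor outside the purview union
    transports at zero cost, so the EMD reduces to the union space.
    """
    if ZA == ZB:
        szA = 1 << _popcount(ZA)
        return _emd(repA[:szA], repB[:szA], H)
    V = ZA | ZB
    kV = _popcount(V)
    szV = 1 << kV
    uA = 1.0 / (1 << (kV - _popcount(ZA)))
    uB = 1.0 / (1 << (kV - _popcount(ZB)))
    for v in range(szV):
        buf1[v] = repA[_project(v, V, ZA)] * uA
        buf2[v] = repB[_project(v, V, ZB)] * uB
    return _emd(buf1[:szV], buf2[:szV], H)


@njit(cache=True)
def _ces_distance(phiA, zcA, crA, emA, nA, phiB, zcB, crB, emB, nB, e0, n, H):
    """Extended EMD between two cause-effect structures.

    phi mass of the first structure is transported onto the second; surplus
    mass on either side is matched to the null concept (uniform cause,
    unconstrained effect marginals ``e0``).  Ground distance between two
    concepts is the cause-repertoire EMD plus the effect-repertoire EMD;
    effect repertoires are products, so their EMD is the sum of per-node
    marginal differences.
    """
    resA = phiA[:nA].copy()
    resB = phiB[:nB].copy()
    # cancel identical concept mass (zero ground distance is optimal)
    for i in range(nA):
        for j in range(nB):
            if resA[i] > 0.0 and resB[j] > 0.0 and zcA[i] == zcB[j]:
                same = True
                for k in range(n):
                    if abs(emA[i, k] - emB[j, k]) > 1e-12:
                        same = False
                        break
                if same:
                    for z in range(1 << _popcount(zcA[i])):
                        if abs(crA[i, z] - crB[j, z]) > 1e-12:
                            same = False
                            break
                if same:
                    m = resA[i] if resA[i] < resB[j] else resB[j]
                    resA[i] -= m
                    resB[j] -= m
    nstates = 1 << n
    buf1 = np.empty(nstates)
    buf2 = np.empty(nstates)
    D = np.zeros((nA + 1, nB + 1))
    for i in range(nA):
        if resA[i] <= 0.0:
            continue
        for j in range(nB):
            if resB[j] > 0.0:
                de = 0.0
                for k in range(n):
                    de += abs(emA[i, k] - emB[j, k])
                D[i, j] = de + _cause_ground(crA[i], zcA[i], crB[j], zcB[j], H, buf1, buf2)
        # to the null concept: uniform cause, unconstrained effect
        szA = 1 << _popcount(zcA[i])
        u = 1.0 / szA
        for z in range(szA):
            buf1[z] = u
        de = 0.0
        for k in range(n):
            de += abs(emA[i, k] - e0[k])
        D[i, nB] = de + _emd(crA[i, :szA], buf1[:szA], H)
    for j in range(nB):
        if resB[j] <= 0.0:
            continue
        szB = 1 << _popcount(zcB[j])
        u = 1.0 / szB
        for z in range(szB):
            buf1[z] = u
        de = 0.0
        for k in range(n):
            de += abs(emB[j, k] - e0[k])
        D[nA, j] = de + _emd(buf1[:szB], crB[j, :szB], H)
    P = np.zeros(nA + 1)
    Q = np.zeros(nB + 1)
    SA = 0.0
    SB = 0.0
    for i in range(nA):
        P[i] = resA[i]
        SA += resA[i]
    for j in range(nB):
        Q[j] = resB[j]
        SB += resB[j]
    if SA <= 1e-15 and SB <= 1e-15:
        return 0.0
    if SA >= SB:
        Q[nB] = SA - SB
    else:
        P[nA] = SB - SA
    return _emd(P, Q, D)


@njit(cache=True)
def _cut_tpm(tpm, n, from_mask, to_mask):
    """Sever inputs from ``from_mask`` into ``to_mask`` (replace with noise).

    Each target node's conditional is averaged uniformly over the severed
    past bits; all other dependencies are untouched.
    """
    nstates = 1 << n
    out = tpm.copy()
    nsub = 1 << _popcount(from_mask)
    for i in range(n):
        if (to_mask >> i) & 1:
            for s in range(nstates):
                base = s & ~from_mask
                acc = 0.0
                # iterate submasks of from_mask (including 0)
                b = from_mask
                while True:
                    acc += tpm[base | b, i]
                    if b == 0:
                        break
                    b = (b - 1) & from_mask
                out[s, i] = acc / nsub
    return out


@njit(cache=True)
def _state_reachable(tpm, n, state):
    nstates = 1 << n
    for p in range(nstates):
        prob = 1.0
        for i in range(n):
            t = tpm[p, i]
            prob *= t if (state >> i) & 1 else 1.0 - t
        if prob > 0.0:
            return True
    return False


@njit(cache=True)
def _big_phi(tpm, n, state, cuts_from, cuts_to):
    """System Phi: minimum CES distance over the supplied cuts.

    Returns (Phi, index of the minimising cut, reachable flag).  Ties keep
    the earliest cut in the supplied order.
    """
    if not _state_reachable(tpm, n, state):
        return 0.0, -1, False
    nstates = 1 << n
    H = np.empty((nstates, nstates))
    for i in range(nstates):
        for j in range(nstates):
            H[i, j] = _popcount(i ^ j)
    mA, pA, zcA, zeA, crA, emA, cfA, efA, nA, E = _ces(tpm, n, state)
    e0 = E[0].copy()
    best = _INF
    besti = -1
    for c in range(cuts_from.shape[0]):
        ct = _cut_tpm(tpm, n, cuts_from[c], cuts_to[c])
        mB, pB, zcB, zeB, crB, emB, cfB, efB, nB, _EB = _ces(ct, n, state)
        d = _ces_distance(pA, zcA, crA, emA, nA, pB, zcB, crB, emB, nB, e0, n, H)
        if d < best - 1e-12:
            best = d
            besti = c
        if best <= EPS:
            # cannot go below zero; keep earliest zero cut
            break
    if best < 0.0:
        best = 0.0
    return best, besti, True


@njit(cache=True)
def _reduce_tpm(tpm, n, submask):
    """Marginalise a TPM onto a node subset.

    External past nodes are averaged uniformly; external future nodes are
    dropped.  Rows of the result are indexed by the compressed past state of
    the subset, columns by the compressed node index.
    """
    k = _popcount(submask)
    nstates = 1 << n
    ksub = 1 << k
    out = np.zeros((ksub, k))
    counts = np.zeros(ksub)
    for p in range(nstates):
        z = _compress(p, submask)
        counts[z] += 1.0
        col = 0
        for i in range(n):
            if (submask >> i) & 1:
                out[z, col] += tpm[p, i]
                col += 1
    for z in range(ksub):
        for col in range(k):
            out[z, col] /= counts[z]
    return out
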