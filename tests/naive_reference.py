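"""Deliberately naive nested-loop reference implementations.

Plain Python loops and scalar arithmetic only — no vectorization, no
code shared with the package — so agreement with the library is a real
two-route check, not a tautology.
"""

from __future__ import annotations

import math


def naive_d0(L: int) -> float:
    L = max(int(L), 19)
    return 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8


def naive_kernel(d: float, d0: float) -> float:
    return 1.0 / (1.0 + (d / d0) ** 2)


def naive_pair_tm(probs, edges, d0: float):
    """Expected TM contribution per pair: triple loop over i, j, bins."""
    N = len(probs)
    B = len(edges) - 1
    mids = [(edges[b] + edges[b + 1]) / 2.0 for b in range(B)]
    g = [[0.0] * N for _ in range(N)]
    for i in range(N):
        for j in range(N):
            total = 0.0
            for b in range(B):
                total += probs[i][j][b] * naive_kernel(mids[b], d0)
            g[i][j] = total
    return g


def naive_ptm(g) -> float:
    N = len(g)
    best = -1.0
    for i in range(N):
        s = sum(g[i][j] for j in range(N)) / N
        best = max(best, s)
    return best


def naive_iptm(g, asym) -> float:
    N = len(g)
    best = None
    for i in range(N):
        partners = [j for j in range(N) if asym[j] != asym[i]]
        if not partners:
            continue
        s = sum(g[i][j] for j in partners) / len(partners)
        best = s if best is None else max(best, s)
    if best is None:
        raise ValueError("single chain")
    return best


def naive_actifptm(g, q, asym):
    """Contact-weighted interchain score; returns (score, no_interface)."""
    N = len(g)
    qs = [[(q[i][j] + q[j][i]) / 2.0 for j in range(N)] for i in range(N)]
    best = None
    for i in range(N):
        weights = [qs[i][j] if asym[j] != asym[i] else 0.0 for j in range(N)]
        wsum = sum(weights)
        if wsum <= 0.0:
            continue
        s = sum(weights[j] / wsum * g[i][j] for j in range(N))
        best = s if best is None else max(best, s)
    if best is None:
        return 0.0, True
    return best, False


def naive_contact_probs(probs, edges, threshold: float):
    """P(d < threshold) per pair, straddling bin linearly interpolated,
    then symmetrized."""
    N = len(probs)
    B = len(edges) - 1
    q = [[0.0] * N for _ in range(N)]
    for i in range(N):
        for j in range(N):
            total = 0.0
            for b in range(B):
                lo, hi = edges[b], edges[b + 1]
                if hi <= threshold:
                    total += probs[i][j][b]
                elif lo < threshold < hi:
                    total += probs[i][j][b] * (threshold - lo) / (hi - lo)
            q[i][j] = total
    return [[(q[i][j] + q[j][i]) / 2.0 for j in range(N)] for i in range(N)]


def naive_pairwise(probs, edges, q, asym, fixed_d0=None):
    """Per-chain-pair ipTM/actifpTM and per-chain pTM by explicit
    restriction and recomputation."""
    order: list = []
    for a in asym:
        if a not in order:
            order.append(a)
    pw_iptm: dict = {}
    pw_actif: dict = {}
    per_chain: dict = {}
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            a, b = order[ai], order[bi]
            idx = [k for k, lab in enumerate(asym) if lab == a]
            idx += [k for k, lab in enumerate(asym) if lab == b]
            sub_probs = [[probs[i][j] for j in idx] for i in idx]
            sub_q = [[q[i][j] for j in idx] for i in idx]
            sub_asym = [asym[i] for i in idx]
            d0 = fixed_d0 if fixed_d0 is not None else naive_d0(len(idx))
            g = naive_pair_tm(sub_probs, edges, d0)
            key = f"{a}:{b}"
            pw_iptm[key] = naive_iptm(g, sub_asym)
            pw_actif[key] = naive_actifptm(g, sub_q, sub_asym)[0]
    for a in order:
        idx = [k for k, lab in enumerate(asym) if lab == a]
        sub_probs = [[probs[i][j] for j in idx] for i in idx]
        d0 = fixed_d0 if fixed_d0 is not None else naive_d0(len(idx))
        per_chain[a] = naive_ptm(naive_pair_tm(sub_probs, edges, d0))
    return pw_actif, pw_iptm, per_chain


def naive_interface_mask(q, asym, call_threshold: float):
    N = len(q)
    qs = [[(q[i][j] + q[j][i]) / 2.0 for j in range(N)] for i in range(N)]
    return [
        [qs[i][j] >= call_threshold and asym[i] != asym[j] for j in range(N)]
        for i in range(N)
    ]


def naive_ipae(pae, mask) -> float:
    N = len(pae)
    vals = sorted(
        pae[i][j] for i in range(N) for j in range(N) if mask[i][j] or mask[j][i]
    )
    if not vals:
        raise ValueError("no interface")
    mid = len(vals) // 2
    if len(vals) % 2:
        return vals[mid]
    return 0.5 * (vals[mid - 1] + vals[mid])


def naive_interface_plddt(plddt, q, asym, focus, call_threshold: float) -> float:
    mask = naive_interface_mask(q, asym, call_threshold)
    vals = [
        plddt[i]
        for i in range(len(plddt))
        if asym[i] == focus and any(mask[i])
    ]
    if not vals:
        raise ValueError("no interface residues on focus chain")
    return sum(vals) / len(vals)


def naive_expected_pae(probs, edges):
    """Expected distance per pair from a binned distribution."""
    N = len(probs)
    B = len(edges) - 1
    mids = [(edges[b] + edges[b + 1]) / 2.0 for b in range(B)]
    return [
        [sum(probs[i][j][b] * mids[b] for b in range(B)) for j in range(N)]
        for i in range(N)
    ]


def naive_direct_tm(dist, d0: float) -> float:
    """Direct geometric TM-score formula from a distance matrix."""
    N = len(dist)
    best = -1.0
    for i in range(N):
        s = sum(naive_kernel(dist[i][j], d0) for j in range(N)) / N
        best = max(best, s)
    return best
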