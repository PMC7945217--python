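"""Deliberately naive reference implementations used as oracles in tests.

Everything here is written as explicit per-leaf, per-control-point Python
loops straight from the score definitions, with none of the vectorization or
caching of the production code.  It must stay independent of
``vmatcx.complexity`` / ``vmatcx.stats`` internals.
"""

from __future__ import annotations

import itertools


def _rankdata_abs(values):
    """Midranks of |values| by hand (average rank within ties)."""
    order = sorted(range(len(values)), key=lambda i: abs(values[i]))
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and abs(values[order[j + 1]]) == abs(values[order[i]]):
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_wilcoxon_p(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = [x for x in diffs if x != 0.0]
    if not d:
        return 1.0
    ranks = _rankdata_abs(d)
    n = len(d)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    total = 2**n
    le = ge = 0
    for mask in itertools.product((0, 1), repeat=n):
        w = sum(r for r, bit in zip(ranks, mask) if bit)
        if w <= w_obs + 1e-12:
            le += 1
        if w >= w_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def naive_arc_scores(arc, closed_gap_threshold: float = 0.05) -> dict:
    """Per-CP SW/SA/LSV/AAV and the arc MCS by explicit double loops."""
    m = arc.machine
    widths = list(m.leaf_widths)
    edges = list(m.leaf_boundaries)
    cps = arc.cps

    infield = []
    for cp in cps:
        idx = []
        for n in range(m.n_pairs):
            gap = float(cp.leaf_pos_b[n]) - float(cp.leaf_pos_a[n])
            inside = edges[n] < cp.jaw_y[1] and edges[n + 1] > cp.jaw_y[0]
            if gap > closed_gap_threshold and inside:
                idx.append(n)
        infield.append(idx)

    # maximal aperture over the arc, per pair, on CPs where the pair is in-field
    denom = 0.0
    for n in range(m.n_pairs):
        max_b, min_a, ever = -1e30, 1e30, False
        for i, cp in enumerate(cps):
            if n in infield[i]:
                ever = True
                max_b = max(max_b, float(cp.leaf_pos_b[n]))
                min_a = min(min_a, float(cp.leaf_pos_a[n]))
        if ever:
            denom += (max_b - min_a) * widths[n]

    def bank_factor(positions):
        if len(positions) <= 1:
            return 1.0
        pmax = max(positions) - min(positions)
        if pmax == 0.0:
            return 1.0
        s = 0.0
        for k in range(len(positions) - 1):
            s += pmax - abs(positions[k] - positions[k + 1])
        return s / ((len(positions) - 1) * pmax)

    sw, sa, lsvs, aavs = [], [], [], []
    for i, cp in enumerate(cps):
        idx = infield[i]
        gaps = [float(cp.leaf_pos_b[n]) - float(cp.leaf_pos_a[n]) for n in idx]
        sw.append(max(gaps) if gaps else 0.0)
        sa.append(sum(g * widths[n] for g, n in zip(gaps, idx)))
        left = [float(cp.leaf_pos_b[n]) for n in idx]
        right = [float(cp.leaf_pos_a[n]) for n in idx]
        lsvs.append(bank_factor(left) * bank_factor(right))
        aavs.append(sa[-1] / denom)

    weights = [
        float(cps[i + 1].cum_weight) - float(cps[i].cum_weight)
        for i in range(len(cps) - 1)
    ]
    mcs = 0.0
    for i in range(len(weights)):
        mcs += (
            (lsvs[i] + lsvs[i + 1]) / 2.0
            * (aavs[i] + aavs[i + 1]) / 2.0
            * weights[i]
        )
    return {"sw": sw, "sa": sa, "lsv": lsvs, "aav": aavs, "mcs": mcs}
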