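"""Independent reference implementations used only by the tests.

Everything here is written as plain nested loops over dicts, transcribed
directly from the method definitions, and deliberately shares no code
with the package: the package's vectorized linear algebra is checked
against these loops on small instances.
"""

from __future__ import annotations

import math


def oracle_huff(cell, hospitals, S, d, f):
    """Huff probabilities for one cell over its reachable hospitals."""
    reachable = [y for y in hospitals if (cell, y) in d]
    denom = sum(S[z] * f(d[(cell, z)]) for z in reachable)
    if denom <= 0:
        raise ValueError("degenerate cell")
    return {y: S[y] * f(d[(cell, y)]) / denom for y in reachable}


def oracle_ifca(cells, hospitals, S, P, d, f):
    """iFCA weights and visits: W = f(d_xy) * Huff(x)[y]; V_y = sum_x W P_x."""
    W = {}
    for x in cells:
        reachable = [y for y in hospitals if (x, y) in d]
        denom = sum(S[z] * f(d[(x, z)]) for z in reachable)
        for y in reachable:
            if denom > 0:
                W[(x, y)] = f(d[(x, y)]) * (S[y] * f(d[(x, y)]) / denom)
            else:
                W[(x, y)] = 0.0
    V = {y: sum(W.get((x, y), 0.0) * P[x] for x in cells) for y in hospitals}
    return W, V


def oracle_two_step(cells, hospitals, S, P, d, f, method, variant):
    """AI, partial AI, weights and visits for M2SFCA / E2SFCA.

    ``method`` is "m2sfca" (decay squared in the AI numerator) or
    "e2sfca"; ``variant`` selects the published partial formulas
    ("as_printed") or the exact AI summand ("decay_consistent").
    """
    D = {
        y: sum(P[x] * f(d[(x, y)]) for x in cells if (x, y) in d)
        for y in hospitals
    }
    ai = {}
    partial = {}
    for x in cells:
        total = 0.0
        for y in hospitals:
            if (x, y) not in d or D[y] <= 0:
                continue
            fv = f(d[(x, y)])
            if method == "m2sfca":
                summand = S[y] * fv * fv / D[y]
                printed = S[y] * fv / D[y]
            else:
                summand = S[y] * fv / D[y]
                printed = S[y] / D[y]
            total += summand
            partial[(x, y)] = summand if variant == "decay_consistent" else printed
        ai[x] = total
    W = {}
    for (x, y), p in partial.items():
        W[(x, y)] = p / ai[x] if ai[x] > 0 else 0.0
    V = {y: sum(W.get((x, y), 0.0) * P[x] for x in cells) for y in hospitals}
    return ai, partial, W, V


def oracle_closest(cells, hospitals, P, d):
    """Closest-provider visits; ties go to the lowest hospital id."""
    V = {y: 0.0 for y in hospitals}
    for x in cells:
        reachable = sorted(y for y in hospitals if (x, y) in d)
        if not reachable:
            continue
        best = min(reachable, key=lambda y: (d[(x, y)], y))
        V[best] += P[x]
    return V


# --- textbook statistics, written from the defining formulas ----------


def average_ranks(values):
    """Ranks 1..n with average ranks for ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def oracle_spearman(x, y):
    """Spearman's rho as the Pearson correlation of average ranks."""
    return oracle_pearson(average_ranks(list(x)), average_ranks(list(y)))


def oracle_ols(x, y):
    """Slope, intercept and R² from the normal equations."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(x, y))
    ss_tot = sum((b - my) ** 2 for b in y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def oracle_kruskal(groups):
    """Tie-corrected Kruskal–Wallis H."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[idx : idx + len(g)])
        idx += len(g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    from collections import Counter

    counts = Counter(pooled)
    correction = 1.0 - sum(t**3 - t for t in counts.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0
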