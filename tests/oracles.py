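"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, literal rule
transcriptions, grid searches) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def naive_morans_i(values, coords, band):
    """O(n^2) double-loop Moran's I with binary distance-band weights."""
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    n = len(values)
    z = values - values.mean()
    d_lo, d_hi = band
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(coords[i] - coords[j]))
            if d_lo < d <= d_hi:
                num += z[i] * z[j]
                s0 += 1.0
    return (n / s0) * num / (z @ z)


def naive_buffer_means(loss, usable, coords, radius):
    """O(n^2) mean loss of usable cells within (0, radius] of each cell."""
    loss = np.asarray(loss, float)
    usable = np.asarray(usable, bool)
    coords = np.asarray(coords, float)
    n = len(loss)
    out = np.full(n, np.nan)
    for i in range(n):
        acc = []
        for j in range(n):
            if j == i or not usable[j]:
                continue
            if np.hypot(*(coords[i] - coords[j])) <= radius:
                acc.append(loss[j])
        if acc:
            out[i] = np.mean(acc)
    return out


def reference_greedy_match(treated, controls, caliper):
    """Literal transcription of the stated greedy matching rule.

    ``treated`` and ``controls`` are lists of (cell_id, score).  Returns a
    list of (treated_id, control_id, distance) in processing order.
    """
    used = set()
    pairs = []
    for tid, ts in sorted(treated, key=lambda t: (-t[1], t[0])):
        best = None  # (distance, control_id)
        for cid, cs in controls:
            if cid in used:
                continue
            d = abs(ts - cs)
            if best is None or d < best[0] or (d == best[0] and cid < best[1]):
                best = (d, cid)
        if best is not None and best[0] <= caliper:
            used.add(best[1])
            pairs.append((tid, best[1], best[0]))
    return pairs


def naive_normalized_difference(t, c):
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    vt = t.var(ddof=1) if len(t) > 1 else 0.0
    vc = c.var(ddof=1) if len(c) > 1 else 0.0
    return 100.0 * (t.mean() - c.mean()) / np.sqrt((vt + vc) / 2.0)


def logit_mle_gridsearch(x, y, span=6.0, coarse=0.1):
    """Two-stage grid-search MLE for a 1-covariate logistic regression.

    Coarse grid over (b0, b1) followed by Nelder-Mead polish of the
    hand-written negative log-likelihood.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(p):
        eta = p[0] + p[1] * x
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    grid = np.arange(-span, span + coarse, coarse)
    best = None
    for b0 in grid:
        for b1 in grid:
            v = nll((b0, b1))
            if best is None or v < best[0]:
                best = (v, b0, b1)
    res = optimize.minimize(nll, [best[1], best[2]], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return res.x


def naive_group_mean(values):
    total = 0.0
    for v in values:
        total += v
    return total / len(values)


def naive_aggregate_block(block):
    """Forest fraction of one coarse block from a fine classification array."""
    flat = [v for v in np.asarray(block).ravel()]
    obs = [v for v in flat if v != -1]
    if not obs:
        return np.nan
    return sum(1 for v in obs if v == 1) / len(obs)
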