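"""Naive double-loop reference implementations used as independent oracles.

Deliberately plain Python (no vectorisation, no imports from the package's
numeric internals beyond the data containers) so that agreement with the
library is a meaningful cross-check.
"""

from __future__ import annotations

import math


def oracle_entropy_weights(x, cost_mask, scale_min, scale_max, reverse_score=True):
    """Entropy weighting by explicit loops.

    ``x`` is a list of rows; returns (weights, e, d) as plain lists.
    """
    m = len(x)
    n = len(x[0])
    work = [row[:] for row in x]
    if reverse_score:
        for j in range(n):
            if cost_mask[j]:
                for i in range(m):
                    work[i][j] = scale_max[j] + scale_min[j] - work[i][j]
    e = []
    for j in range(n):
        col_sum = sum(work[i][j] for i in range(m))
        acc = 0.0
        for i in range(m):
            p = work[i][j] / col_sum
            if p > 0:
                acc += p * math.log(p)
        e.append(-acc / math.log(m))
    d = [abs(1.0 - ej) for ej in e]
    total = sum(d)
    if total <= 1e-12:
        raise ZeroDivisionError("degenerate matrix")
    w = [dj / total for dj in d]
    return w, e, d


def oracle_aras(x, cost_mask, weights):
    """ARAS by explicit loops: returns (S list incl. ideal row first, K list)."""
    m = len(x)
    n = len(x[0])
    ideal = []
    for j in range(n):
        col = [x[i][j] for i in range(m)]
        ideal.append(min(col) if cost_mask[j] else max(col))
    rows = [ideal] + [row[:] for row in x]
    # reciprocal transform for cost columns
    for j in range(n):
        if cost_mask[j]:
            for r in rows:
                r[j] = 1.0 / r[j]
    S = []
    for r in rows:
        acc = 0.0
        for j in range(n):
            col_sum = sum(rows[i][j] for i in range(m + 1))
            acc += weights[j] * (r[j] / col_sum)
        S.append(acc)
    K = [S[i] / S[0] for i in range(1, m + 1)]
    return S, K
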