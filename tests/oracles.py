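"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written step by step, with plain loops and
its own rank/trim/weight code, sharing nothing with the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def oracle_select_reference(counts) -> str:
    """Exhaustive upper-quartile reference choice."""
    best_name, best_dist = None, None
    q75 = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        q75[sample] = float(np.percentile(col / col.sum() * 1e6, 75))
    mean_q75 = sum(q75.values()) / len(q75)
    for sample in counts.columns:
        dist = abs(q75[sample] - mean_q75)
        if best_dist is None or dist < best_dist:
            best_name, best_dist = sample, dist
    return best_name


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """1-based average ranks, computed by explicit tie grouping."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # mean of 1-based positions i+1..j+1
        for pos in range(i, j + 1):
            ranks[order[pos]] = avg
        i = j + 1
    return ranks


def oracle_tmm_factor_pair(yk, nk, yr, nr, trim_m, trim_a) -> float:
    """One sample-vs-reference TMM factor, separate trim/weight/average steps."""
    m_vals, a_vals, weights = [], [], []
    for g in range(len(yk)):
        if yk[g] > 0 and yr[g] > 0:
            pk, pr = yk[g] / nk, yr[g] / nr
            m_vals.append(np.log2(pk / pr))
            a_vals.append(0.5 * np.log2(pk * pr))
            var = (nk - yk[g]) / (nk * yk[g]) + (nr - yr[g]) / (nr * yr[g])
            weights.append(1.0 / var)
    m_vals = np.array(m_vals)
    a_vals = np.array(a_vals)
    weights = np.array(weights)
    n = len(m_vals)
    rank_m = _average_ranks(m_vals)
    rank_a = _average_ranks(a_vals)
    lo_m = np.floor(n * trim_m) + 1
    lo_a = np.floor(n * trim_a) + 1
    num = den = 0.0
    for g in range(n):
        if lo_m <= rank_m[g] <= n - lo_m + 1 and lo_a <= rank_a[g] <= n - lo_a + 1:
            num += weights[g] * m_vals[g]
            den += weights[g]
    return 2.0 ** (num / den)


def oracle_tmm(counts, trim_m=0.30, trim_a=0.05, reference=None):
    """Full TMM factor vector with geometric-mean rescaling."""
    if reference is None:
        reference = oracle_select_reference(counts)
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    r = list(counts.columns).index(reference)
    raw = []
    for k in range(y.shape[1]):
        if k == r:
            raw.append(1.0)
        else:
            raw.append(
                oracle_tmm_factor_pair(y[:, k], lib[k], y[:, r], lib[r],
                                       trim_m, trim_a)
            )
    raw = np.array(raw)
    geo = np.exp(np.mean([np.log(f) for f in raw]))
    return raw / geo


def oracle_ols(y, x):
    """Explicit normal-equations OLS with the slope t test.

    Returns (beta, se_beta1, t, df, pvalue).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    gram = np.zeros((p, p))
    xty = np.zeros(p)
    for i in range(n):
        for a in range(p):
            xty[a] += x[i, a] * y[i]
            for b in range(p):
                gram[a, b] += x[i, a] * x[i, b]
    gram_inv = np.linalg.inv(gram)
    beta = gram_inv @ xty
    rss = 0.0
    for i in range(n):
        pred = sum(x[i, a] * beta[a] for a in range(p))
        rss += (y[i] - pred) ** 2
    df = n - p
    s2 = rss / df
    se = np.sqrt(s2 * gram_inv[1, 1])
    t = beta[1] / se
    pvalue = 2 * stats.t.sf(abs(t), df)
    return beta, se, t, df, pvalue


def oracle_bh(pvalues):
    """Quadratic-time step-up adjustment: min over the tail at every index."""
    p = np.asarray(pvalues, dtype=float)
    finite = [i for i in range(len(p)) if not np.isnan(p[i])]
    m = len(finite)
    order = sorted(finite, key=lambda i: p[i])
    out = np.full(len(p), np.nan)
    for pos, idx in enumerate(order):
        candidates = []
        for later_pos in range(pos, m):
            j = order[later_pos]
            candidates.append(min(1.0, p[j] * m / (later_pos + 1)))
        out[idx] = min(candidates)
    return out


def oracle_overlap_patterns(sig_sets: dict, universe) -> dict:
    """Brute-force intersection-pattern counts over a gene universe."""
    counts: dict[str, int] = {}
    for gene in universe:
        label = "+".join(name for name, s in sig_sets.items() if gene in s)
        label = label or "none"
        counts[label] = counts.get(label, 0) + 1
    return counts
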