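"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity from its definition by a different route
than the package (exact rational arithmetic, explicit loops, dense grids)
so that agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by definitional hypergeometric enumeration.

    Exact rational arithmetic over the column-margin parameterization
    pmf(k) = C(c1, k) C(n - c1, r1 - k) / C(n, r1); sums the probabilities
    of all tables no more probable than the observed one.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, r1)
    p_obs = Fraction(comb(c1, a) * comb(n - c1, r1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        p_k = Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


def bh_stepup(p_values) -> np.ndarray:
    """Definitional Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def smic_grid_max(n_cgs: int, n_dgs: int, n_grid: int = 100001) -> float:
    """Maximize L(theta) = n_cgs*theta + n_dgs*(1-theta) on a dense theta grid."""
    thetas = np.linspace(0.5, 1.0, n_grid)
    return float(np.max(n_cgs * thetas + n_dgs * (1.0 - thetas)))


def greedy_order_literal(vectors, start_seed, sim) -> tuple[list, list]:
    """Accumulating clustering re-implemented straight from its four steps.

    Maintains an explicit seed list and candidate dict; at every step
    recomputes each candidate's average similarity to *all* seeds from
    scratch and moves the argmax (ties: lexicographically smallest id).
    """
    seeds = [np.asarray(start_seed, dtype=float)]
    candidates = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
    order, trace = [], []
    while candidates:
        scored = {
            cid: float(np.mean([sim(vec, s) for s in seeds]))
            for cid, vec in candidates.items()
        }
        best = max(scored.values())
        winner = min(cid for cid, sc in scored.items() if sc == best)
        order.append(winner)
        trace.append(best)
        seeds.append(candidates.pop(winner))
    return order, trace


def smic_mle_scalar(u, v) -> float:
    """SMIC for the literal greedy oracle, written from the sign definition."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n_cgs = sum(1 for a, b in zip(u, v) if (a > 0 and b > 0) or (a < 0 and b < 0))
    n_dgs = sum(1 for a, b in zip(u, v) if (a > 0 and b < 0) or (a < 0 and b > 0))
    best = -np.inf
    for theta in np.linspace(0.5, 1.0, 501):
        best = max(best, n_cgs * theta + n_dgs * (1 - theta))
    return float(best)


def set_score_loops(norm_values, gene_ids, sample_ids, genes):
    """Gene-set score by explicit per-sample loop over member genes."""
    out = []
    for j, _ in enumerate(sample_ids):
        vals = [norm_values[gene_ids.index(g)][j] for g in genes if g in gene_ids]
        out.append(sum(vals) / len(vals))
    return np.array(out)
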