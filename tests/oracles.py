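"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are checking: plain combinatorics for the exact tests, per-position
loops for region counting, and a direct double loop for residue-level HDX
aggregation.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        total += comb(K, j) * comb(N - K, n - j)
    return total / denom


def fisher_two_sided(a: int, b: int, total_a: int, total_b: int) -> float:
    """Two-sided Fisher exact p on [[a, total_a-a], [b, total_b-b]].

    Sums, over the hypergeometric support of the first cell given fixed
    margins, the probabilities not exceeding that of the observed table.
    """
    m = a + b                      # successes margin
    N = total_a + total_b

    def pmf(x: int) -> float:
        return comb(total_a, x) * comb(total_b, m - x) / comb(N, m)

    lo = max(0, m - total_b)
    hi = min(m, total_a)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-12))


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recursion."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def region_counts_by_position(profile, model, offset_table=None):
    """Per-position recount of region assignment (P-site if offsets given)."""
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    for L, vec in profile.counts.items():
        for pos, c in enumerate(vec):
            if c == 0:
                continue
            p = pos + (offset_table.get(L) if offset_table is not None else 0)
            if p >= model.length:
                continue
            counts[model.region_of(p)] += int(c)
    return counts


def residue_map_brute_force(peptide_deltas, protein, column):
    """Unsmoothed residue means recomputed with an explicit double loop."""
    n = len(protein)
    vals = [[] for _ in range(n)]
    sub = peptide_deltas[peptide_deltas["exposure_s"] == column]
    for _, row in sub.iterrows():
        for r in range(int(row["peptide_start"]) + 2, int(row["peptide_end"]) + 1):
            if protein[r - 1] != "P":
                vals[r - 1].append(float(row["delta_da"]))
    return np.array([np.mean(v) if v else np.nan for v in vals])
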