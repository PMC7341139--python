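"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths: the HWE oracle works by
direct enumeration with exact integer factorials, the pruner is a plain
O(m^2)-per-window re-reading of the documented rule, and the Hudson FST
estimator follows the textbook ratio-of-averages formula.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value by full enumeration of heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0
    weights = {}
    for h in range(n_a % 2, min(n_a, n_A) + 1, 2):
        aa = (n_a - h) // 2
        AA = (n_A - h) // 2
        weights[h] = (factorial(n) // (factorial(AA) * factorial(h) * factorial(aa))
                      ) * 2 ** h
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs * (1.0 + 1e-12))


def naive_window_pruner(dosages: np.ndarray, maf: np.ndarray, window: int,
                        step: int, r2_max: float) -> np.ndarray:
    """Reference greedy pruner: boolean keep mask over SNP columns.

    Within each window, repeatedly find the first (lexicographic) retained
    pair with r^2 > r2_max and drop the lower-MAF member (tie: the later
    SNP); slide by `step`.
    """
    n, m = dosages.shape
    x = dosages.astype(float)
    x[dosages < 0] = np.nan
    keep = np.ones(m, dtype=bool)

    def r2(a: int, b: int) -> float:
        va, vb = x[:, a].copy(), x[:, b].copy()
        va[np.isnan(va)] = np.nanmean(va)
        vb[np.isnan(vb)] = np.nanmean(vb)
        if va.std() == 0 or vb.std() == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1] ** 2)

    for start in range(0, m, step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        changed = True
        while changed:
            changed = False
            for ii in range(len(idx)):
                for jj in range(ii + 1, len(idx)):
                    a, b = idx[ii], idx[jj]
                    if r2(a, b) > r2_max:
                        drop = a if maf[a] < maf[b] else b
                        keep[drop] = False
                        idx.remove(drop)
                        changed = True
                        break
                if changed:
                    break
    return keep


def hudson_fst(counts1: np.ndarray, n1: int, counts2: np.ndarray,
               n2: int) -> float:
    """Hudson-type FST (ratio of averages) from allele counts per SNP.

    counts are minor/reference allele counts out of 2*n alleles per
    subpopulation.
    """
    p1 = counts1 / (2 * n1)
    p2 = counts2 / (2 * n2)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (2 * n1 - 1)
           - p2 * (1 - p2) / (2 * n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


def apply_relatedness_rule(pairs, call_rates: dict) -> list:
    """Exhaustive application of the documented relatedness-removal rule."""
    removed = []
    for (a, b), pihat in pairs:
        if a in removed or b in removed:
            continue
        if pihat <= 0.2:
            continue
        removed.append(b if call_rates[a] >= call_rates[b] else a)
    return removed
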