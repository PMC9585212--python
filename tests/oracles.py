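"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a different route than the
implementation: exact rational enumeration for the HWE test, textbook
normal equations for OLS, rank-then-Pearson for Spearman, and an
all-pairs connected-components construction for clumping.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_pvalues(n: int, n_minor: int):
    """Exact HWE p-value for every possible heterozygote count.

    Enumerates all genotype tables with ``n`` individuals and ``n_minor``
    minor-allele copies using exact integer weights
    ``multinomial(n; hom_minor, het, hom_major) * 2^het`` and returns
    ``{het: Fraction p}`` with p = (sum of weights <= observed) / total.
    """
    lo = max(0, n_minor - n)
    hi = min(n_minor, 2 * n - n_minor)
    hets = [h for h in range(lo, hi + 1) if (h - n_minor) % 2 == 0]
    weights = {}
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        w = comb(n, h) * comb(n - h, hom_minor) * (2**h)
        weights[h] = w
    total = sum(weights.values())
    return {h: Fraction(sum(w2 for w2 in weights.values() if w2 <= w), total)
            for h, w in weights.items()}


def hwe_enumeration_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    allele_a = 2 * n_aa + n_ab
    n_minor = min(allele_a, 2 * n - allele_a)
    return float(hwe_enumeration_pvalues(n, n_minor)[n_ab])


def ols_normal_equations(y, X):
    """Textbook OLS: beta = (X'X)^-1 X'y, SE from sigma^2 diag((X'X)^-1)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return beta, se, df


def spearman_rank_then_pearson(x, y) -> float:
    """Average ranks by hand, then Pearson correlation of the ranks."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # average rank, 1-based
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def clump_by_components(diff_table, genotypes, p_threshold, r2_threshold, merge_window):
    """Exhaustive clumping oracle for planted-block fixtures.

    Builds the graph over significant variants with an edge wherever
    r^2 >= r2_threshold or the two variants share a chromosome and lie
    within merge_window, takes connected components, and represents each
    by its smallest-p variant. On fixtures whose blocks are mutually
    separated in both LD and distance this equals the greedy two-stage
    procedure.
    """
    sig = diff_table[diff_table["P_DIFF"] < p_threshold]
    ids = list(sig["SNP"])
    if not ids:
        return []
    p_of = dict(zip(sig["SNP"], sig["P_DIFF"]))
    pos_of = {v.id: v.pos for v in genotypes.variants}
    chrom_of = {v.id: v.chrom for v in genotypes.variants}
    col = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    parent = {v: v for v in ids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a, b):
        parent[find(a)] = find(b)

    G = genotypes.dosages.astype(float)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ga, gb = G[:, col[a]], G[:, col[b]]
            ok = (ga >= 0) & (gb >= 0)
            r2 = 0.0
            if ok.sum() >= 3 and ga[ok].std() > 0 and gb[ok].std() > 0:
                r2 = float(np.corrcoef(ga[ok], gb[ok])[0, 1] ** 2)
            close = chrom_of[a] == chrom_of[b] and abs(pos_of[a] - pos_of[b]) <= merge_window
            if r2 >= r2_threshold or close:
                union(a, b)

    comps = {}
    for v in ids:
        comps.setdefault(find(v), set()).add(v)
    out = []
    for members in comps.values():
        lead = min(members, key=lambda v: (p_of[v], v))
        out.append((lead, frozenset(members)))
    out.sort(key=lambda t: (p_of[t[0]], t[0]))
    return out
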