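"""Diversity and differentiation statistics.

Per-population allelic diversity (mean alleles per locus A, rarefied
allelic richness A_r, private alleles A_p), multilocus pairwise
Weir-Cockerham F_ST, its Slatkin linearization F/(1-F) used as the response
distance in the landscape-genetics stage, and the PCA of ancestry
coefficients whose first two scores (anc1, anc2) serve as the colonization
-history predictor block.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import AncestryMatrix, DistMatrix, GenotypeTable

__all__ = ["diversity", "default_rarefaction_size", "pairwise_fst",
           "slatkin_linearize", "ancestry_pca", "expected_heterozygosity"]


# ---------------------------------------------------------------------------
# allelic diversity
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) \
        - gammaln(np.asarray(n) - np.asarray(k) + 1)


def default_rarefaction_size(gt: GenotypeTable) -> int:
    """Smallest number of non-missing gene copies over all (pop, locus) cells."""
    g = min(gt.gene_copies(l, p) for p in gt.pops for l in range(gt.n_loci))
    if g < 1:
        raise ValueError("a population has no scored copies at some locus")
    return g


def _rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Expected number of distinct alleles among g gene copies
    (hypergeometric rarefaction)."""
    n = sum(counts.values())
    ni = np.array(list(counts.values()), dtype=float)
    with np.errstate(invalid="ignore"):
        miss = np.where(n - ni >= g,
                        np.exp(_log_comb(n - ni, g) - _log_comb(n, g)), 0.0)
    return float(np.sum(1.0 - miss))


def diversity(gt: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Per-population A (mean alleles/locus), A_r (rarefied to ``g`` gene
    copies) and A_p (alleles private to the population over the full
    dataset).

    ``g`` defaults to the smallest per-(population, locus) number of scored
    gene copies, the largest size every cell supports.
    """
    pops = gt.pops
    g_max = default_rarefaction_size(gt)
    if g is None:
        g = g_max
    if g < 1:
        raise ValueError("rarefaction size must be >= 1")
    if g > g_max:
        offender = min(((gt.gene_copies(l, p), gt.loci[l], p)
                        for p in pops for l in range(gt.n_loci)))
        raise ValueError(
            f"rarefaction size g={g} exceeds the {offender[0]} scored copies "
            f"at locus {offender[1]!r} in population {offender[2]!r}")

    # which populations carry each (locus, allele) — for private alleles
    carriers: dict[tuple[int, int], set[str]] = {}
    for p in pops:
        for l in range(gt.n_loci):
            for a in gt.allele_counts(l, p):
                carriers.setdefault((l, a), set()).add(p)

    records = []
    for p in pops:
        per_locus_k, per_locus_ar = [], []
        for l in range(gt.n_loci):
            counts = gt.allele_counts(l, p)
            per_locus_k.append(len(counts))
            per_locus_ar.append(_rarefied_richness(counts, g))
        a_p = sum(1 for (l, a), who in carriers.items() if who == {p})
        records.append({"pop": p, "A": float(np.mean(per_locus_k)),
                        "A_r": float(np.mean(per_locus_ar)), "A_p": int(a_p)})
    return pd.DataFrame(records).set_index("pop")


def expected_heterozygosity(gt: GenotypeTable, pop: str) -> float:
    """Unbiased multilocus expected heterozygosity (Nei), mean over loci."""
    hs = []
    for l in range(gt.n_loci):
        counts = gt.allele_counts(l, pop)
        n = sum(counts.values())
        if n < 2:
            continue
        p2 = sum((c / n) ** 2 for c in counts.values())
        hs.append((1.0 - p2) * n / (n - 1))
    if not hs:
        raise ValueError(f"no scored loci in population {pop!r}")
    return float(np.mean(hs))


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(gt: GenotypeTable, pop_a: str, pop_b: str
                   ) -> tuple[float, float]:
    """Sum of Weir-Cockerham (1984) variance components over loci and alleles
    for one population pair: returns (sum_a, sum_a+b+c)."""
    sum_a = 0.0
    sum_abc = 0.0
    r = 2
    for l in range(gt.n_loci):
        j = l
        stats = []
        for p in (pop_a, pop_b):
            a = gt.alleles[gt.pop_mask(p), j, :]
            ok = (a != 0).all(axis=1)          # pairwise-complete individuals
            a = a[ok]
            if len(a) < 2:
                stats = []
                break
            stats.append(a)
        if not stats:
            continue                            # locus skipped for this pair
        alleles = np.unique(np.concatenate([s.ravel() for s in stats]))
        if len(alleles) < 2:
            continue                            # monomorphic for the pair
        n_i = np.array([len(s) for s in stats], dtype=float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        for u in alleles:
            p_i = np.array([np.mean(s == u) for s in stats])
            h_i = np.array([np.mean((s == u).sum(axis=1) == 1) for s in stats])
            pbar = float((n_i * p_i).sum() / (r * nbar))
            s2 = float((n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((n_i * h_i).sum() / (r * nbar))
            a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                       - s2 * (r - 1) / r
                                       - hbar / 4.0) / (nbar - 1))
            b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                         - s2 * (r - 1) / r
                                         - hbar * (2 * nbar - 1) / (4 * nbar))
            c_c = hbar / 2.0
            sum_a += a_c
            sum_abc += a_c + b_c + c_c
    return sum_a, sum_abc


def pairwise_fst(gt: GenotypeTable) -> DistMatrix:
    """Multilocus Weir-Cockerham theta for every population pair
    (ratio of summed variance components; negative estimates preserved)."""
    pops = gt.pops
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num, den = _wc_components(gt, pops[i], pops[j])
            if den == 0.0:
                raise ValueError(
                    f"all loci monomorphic for pair ({pops[i]}, {pops[j]}); "
                    "theta undefined")
            out[i, j] = out[j, i] = num / den
    return DistMatrix(list(pops), out, kind="fst")


def slatkin_linearize(d: DistMatrix, eps: float = 1e-6) -> DistMatrix:
    """Elementwise F/(1-F).  Negative estimates clamp to 0; values at or
    above 1-eps clamp to (1-eps)/eps with a warning."""
    if d.kind != "fst":
        raise ValueError("input must be an F_ST matrix")
    v = d.values.copy()
    v[v < 0] = 0.0
    high = v >= 1.0 - eps
    high &= ~np.eye(d.n, dtype=bool)
    if high.any():
        warnings.warn("F_ST values at or above 1 - eps were clamped",
                      RuntimeWarning, stacklevel=2)
        v[high] = 1.0 - eps
    out = v / (1.0 - v)
    np.fill_diagonal(out, 0.0)
    return DistMatrix(list(d.labels), out, kind="linearized_fst")


# ---------------------------------------------------------------------------
# ancestry PCA
# ---------------------------------------------------------------------------

def ancestry_pca(q: AncestryMatrix, n_components: int = 2) -> pd.DataFrame:
    """Centered PCA of the Q matrix; returns the first two score columns
    (anc1, anc2) with a fixed sign convention (the largest-magnitude loading
    of each component is positive).  Also cached on ``q.scores``."""
    if q.K < 2:
        raise ValueError("ancestry PCA needs K >= 2 clusters")
    X = q.Q - q.Q.mean(axis=0)
    # SVD of the centered matrix == eigendecomposition of its covariance
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, Vt.shape[0])
    scores = np.zeros((X.shape[0], n_components))
    for c in range(k):
        load = Vt[c]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        scores[:, c] = sign * U[:, c] * s[c]
    df = pd.DataFrame(scores, index=q.labels,
                      columns=[f"anc{c + 1}" for c in range(n_components)])
    q.scores = df
    return df
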