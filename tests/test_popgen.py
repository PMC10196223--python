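"""Diversity and differentiation metrics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genoscape.containers import AncestryMatrix, DistMatrix, GenotypeTable
from genoscape.popgen import (ancestry_pca, default_rarefaction_size,
                              diversity, pairwise_fst, slatkin_linearize)


def _table(pop_alleles: dict[str, list[list[tuple[int, int]]]],
           loci: list[str]) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [per-individual [(a1, a2) per locus]]}."""
    rows, inds, pops = [], [], []
    for pop, individuals in pop_alleles.items():
        for i, genos in enumerate(individuals):
            rows.append([a for pair in genos for a in pair])
            inds.append(f"{pop}_{i + 1}")
            pops.append(pop)
    arr = np.array(rows).reshape(len(rows), len(loci), 2)
    return GenotypeTable(arr, inds, np.array(pops, dtype=object), loci)


# ---------------------------------------------------------------------------
# diversity / rarefaction
# ---------------------------------------------------------------------------

def test_monomorphic_population():
    gt = _table({
        "A": [[(100, 100)], [(100, 100)]],
        "B": [[(102, 104)], [(102, 106)]],
    }, ["L1"])
    div = diversity(gt, g=4)
    assert div.loc["A", "A"] == 1 and div.loc["A", "A_r"] == 1.0
    assert div.loc["A", "A_p"] == 1      # allele 100 private to A
    assert div.loc["B", "A_p"] == 3


def test_rarefaction_at_full_sample_equals_count():
    gt = _table({"A": [[(100, 102)], [(104, 106)]],
                 "B": [[(100, 100)], [(100, 100)]]}, ["L1"])
    div = diversity(gt, g=4)
    assert div.loc["A", "A_r"] == pytest.approx(4.0)


def test_rarefaction_matches_exhaustive_enumeration():
    """A_r equals the mean distinct-allele count over all C(2n, g) gene-copy
    subsets (brute-force oracle on a 3-population toy)."""
    gt = _table({
        "A": [[(100, 100)], [(100, 102)], [(104, 102)]],
        "B": [[(100, 104)], [(104, 104)], [(106, 100)]],
        "C": [[(102, 102)], [(102, 102)], [(100, 106)]],
    }, ["L1"])
    g = 4
    div = diversity(gt, g=g)
    for pop in ("A", "B", "C"):
        copies = gt.alleles[gt.pop_mask(pop), 0, :].ravel()
        counts = [len(set(sub)) for sub in itertools.combinations(copies, g)]
        assert div.loc[pop, "A_r"] == pytest.approx(np.mean(counts), abs=1e-12)


def test_rarefaction_monotone_in_g(small_genotypes):
    sizes = [2, 6, 12, 20]
    prev = None
    for g in sizes:
        cur = diversity(small_genotypes, g=g)["A_r"]
        if prev is not None:
            assert (cur >= prev - 1e-9).all()
        prev = cur


def test_g_too_large_names_offender(small_genotypes):
    gmax = default_rarefaction_size(small_genotypes)
    with pytest.raises(ValueError, match="locus"):
        diversity(small_genotypes, g=gmax + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_oracle(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Direct single-locus evaluation of the Weir-Cockerham (1984) variance
    components, written independently with explicit per-allele loops."""
    r = 2
    samples = [pop_a, pop_b]
    n_i = np.array([len(s) for s in samples], float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted(set(pop_a.ravel()) | set(pop_b.ravel()))
    num = den = 0.0
    for u in alleles:
        p_i, h_i = [], []
        for s in samples:
            p_i.append((s == u).sum() / (2 * len(s)))
            h_i.append(np.mean([(a == u) ^ (b == u) for a, b in s]))
        p_i, h_i = np.array(p_i), np.array(h_i)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def test_fixed_populations_theta_one():
    gt = _table({"A": [[(100, 100)]] * 4, "B": [[(102, 102)]] * 4}, ["L1"])
    assert pairwise_fst(gt).values[0, 1] == pytest.approx(1.0)


def test_duplicated_population_theta_nonpositive():
    inds = [[(100, 102)], [(100, 100)], [(102, 104)], [(104, 104)]]
    gt = _table({"A": inds, "B": inds}, ["L1"])
    assert pairwise_fst(gt).values[0, 1] <= 0.0


def test_theta_matches_handworked_oracle(rng):
    """2 pops x 4 diploids x 1 locus: theta equals the independent
    per-allele variance-component evaluation."""
    for _ in range(10):
        a = rng.choice([100, 102, 104, 106], size=(4, 2))
        b = rng.choice([100, 102, 104, 106], size=(4, 2))
        if len(set(a.ravel()) | set(b.ravel())) < 2:
            continue
        gt = _table({"A": [[tuple(x)] for x in a],
                     "B": [[tuple(x)] for x in b]}, ["L1"])
        expected = _wc_oracle(a, b)
        assert pairwise_fst(gt).values[0, 1] == pytest.approx(expected,
                                                              abs=1e-12)


def test_theta_invariant_to_locus_order_and_relabeling(small_genotypes):
    gt = small_genotypes
    base = pairwise_fst(gt)
    perm = np.arange(gt.n_loci)[::-1]
    gt_perm = GenotypeTable(gt.alleles[:, perm, :], gt.individuals,
                            gt.populations, [gt.loci[j] for j in perm])
    np.testing.assert_allclose(pairwise_fst(gt_perm).values, base.values,
                               atol=1e-12)
    # allele relabeling: any injective map of sizes leaves theta unchanged
    relabeled = gt.alleles * 3 + 7
    gt_re = GenotypeTable(relabeled, gt.individuals, gt.populations, gt.loci)
    np.testing.assert_allclose(pairwise_fst(gt_re).values, base.values,
                               atol=1e-12)


def test_monomorphic_dataset_raises():
    gt = _table({"A": [[(100, 100)]] * 3, "B": [[(100, 100)]] * 3}, ["L1"])
    with pytest.raises(ValueError, match="monomorphic"):
        pairwise_fst(gt)


# ---------------------------------------------------------------------------
# Slatkin linearization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fst,expected", [(0.0, 0.0), (0.5, 1.0),
                                          (0.2, 0.25)])
def test_slatkin_closed_form(fst, expected):
    d = DistMatrix(["a", "b"], np.array([[0.0, fst], [fst, 0.0]]), "fst")
    out = slatkin_linearize(d)
    assert out.values[0, 1] == pytest.approx(expected)
    assert out.kind == "linearized_fst"


def test_slatkin_clamps_and_warns():
    d = DistMatrix(["a", "b", "c"],
                   np.array([[0.0, -0.05, 1.0], [-0.05, 0.0, 0.3],
                             [1.0, 0.3, 0.0]]), "fst")
    with pytest.warns(RuntimeWarning):
        out = slatkin_linearize(d)
    assert out.values[0, 1] == 0.0
    assert np.isfinite(out.values[0, 2])
    assert (out.values >= 0).all()


@given(st.floats(min_value=0.0, max_value=0.999))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_slatkin_strictly_increasing(f):
    d = lambda x: DistMatrix(["a", "b"], np.array([[0, x], [x, 0.0]]), "fst")
    lo = slatkin_linearize(d(f)).values[0, 1]
    hi = slatkin_linearize(d(min(f + 1e-4, 0.9991))).values[0, 1]
    assert hi > lo


# ---------------------------------------------------------------------------
# ancestry PCA
# ---------------------------------------------------------------------------

def test_ancestry_pca_mirror_symmetry():
    q = AncestryMatrix(["a", "b"], np.array([[0.8, 0.2], [0.2, 0.8]]))
    sc = ancestry_pca(q)
    assert sc["anc1"].iloc[0] == pytest.approx(-sc["anc1"].iloc[1])


def test_ancestry_pca_constant_rows_zero_scores():
    q = AncestryMatrix(["a", "b", "c"], np.full((3, 4), 0.25))
    sc = ancestry_pca(q)
    np.testing.assert_allclose(sc.to_numpy(), 0.0, atol=1e-12)


def test_ancestry_pca_matches_eigen_oracle():
    Q = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1],
                  [0.3, 0.3, 0.4], [0.05, 0.15, 0.8]])
    q = AncestryMatrix(list("abcd"), Q)
    sc = ancestry_pca(q)
    # independent route: eigendecomposition of the covariance matrix
    X = Q - Q.mean(axis=0)
    lam, V = np.linalg.eigh(X.T @ X)
    order = np.argsort(lam)[::-1]
    V = V[:, order]
    for c in range(2):
        v = V[:, c]
        proj = X @ v
        assert (np.allclose(sc.iloc[:, c], proj, atol=1e-9)
                or np.allclose(sc.iloc[:, c], -proj, atol=1e-9))


def test_ancestry_pca_rejects_k1():
    q = AncestryMatrix(["a", "b"], np.ones((2, 1)))
    with pytest.raises(ValueError):
        ancestry_pca(q)
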