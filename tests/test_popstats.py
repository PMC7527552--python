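import numpy as np
import pytest

from zanthopop import MISSING
from zanthopop.popstats import (diversity_table, expected_heterozygosity,
                                heterozygosity, nucleotide_diversity,
                                weir_cockerham_fst)

from conftest import make_matrix


def brute_force_pi(copies):
    """Average pairwise difference among allele copies (0/1 list)."""
    n = len(copies)
    diffs = sum(copies[i] != copies[j] for i in range(n) for j in range(i + 1, n))
    return diffs / (n * (n - 1) / 2)


def wc_oracle(p_counts, n_dip, het_counts):
    """Independently coded Weir-Cockerham (1984) variance components for one
    biallelic site; returns (a, b, c)."""
    r = len(n_dip)
    n = np.asarray(n_dip, dtype=float)
    p = np.asarray(p_counts, dtype=float) / (2 * n)
    h = np.asarray(het_counts, dtype=float) / n
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n * p) / (r * nbar)
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_pi_brute_force_example():
    """4 diploids with 4 copies of each allele: pi = 16/28."""
    m = make_matrix([[1], [1], [0], [2]], pop_map={f"acc{i}": "P" for i in range(4)})
    pi, mean = nucleotide_diversity(m, "P")
    assert mean == pytest.approx(brute_force_pi([0, 1] * 2 + [0, 0, 1, 1]))
    assert mean == pytest.approx(16 / 28)


def test_pi_edge_cases():
    m = make_matrix([[0, 1], [0, MISSING]],
                    pop_map={"acc0": "P", "acc1": "P"})
    pi, _ = nucleotide_diversity(m, "P")
    assert pi[0] == 0.0                       # monomorphic
    assert pi[1] == pytest.approx(1.0)        # single het pair of copies
    with pytest.raises(KeyError):
        nucleotide_diversity(m, "nope")


def test_observed_heterozygosity():
    m = make_matrix([[0, 1, 2, 1], [0, 0, 2, 2]])
    het = heterozygosity(m)
    assert het.iloc[0] == pytest.approx(0.5)
    assert het.iloc[1] == 0.0


def test_heterozygosity_unbiased_under_masking(island4):
    rng = np.random.default_rng(5)
    full = heterozygosity(island4)
    g = island4.genotypes.copy()
    mask = rng.random(g.shape) < 0.3
    g[mask] = MISSING
    from conftest import make_matrix as mk
    m2 = mk(g, stack_ids=list(island4.stack_ids))
    masked = heterozygosity(m2)
    # binomial sampling error on ~0.7 * n_sites observations
    n_eff = 0.7 * island4.n_sites
    tol = 3 * np.sqrt(full.mean() * (1 - full.mean()) / n_eff)
    assert np.abs(masked.to_numpy() - full.to_numpy()).max() < 3 * tol


def test_wc_fst_fixed_difference_limit():
    g = np.array([[2] * 3] * 6 + [[0] * 3] * 6, dtype=np.int8)
    m = make_matrix(g, pop_map={f"acc{i}": ("P" if i < 6 else "Q")
                                for i in range(12)})
    assert weir_cockerham_fst(m, ["P", "Q"]).fst > 0.9


def test_wc_fst_identical_pops_near_zero(island4):
    """Randomly splitting one deme yields F_ST indistinguishable from 0."""
    rng = np.random.default_rng(0)
    accs = [a for a in island4.accession_ids if island4.pop_map[a] == "W"]
    half = set(rng.choice(accs, size=len(accs) // 2, replace=False))
    pm = dict(island4.pop_map)
    for a in accs:
        pm[a] = "W1" if a in half else "W2"
    from dataclasses import replace
    m2 = replace(island4, pop_map=pm)
    assert abs(weir_cockerham_fst(m2, ["W1", "W2"]).fst) < 0.02


def test_wc_fst_matches_independent_oracle():
    """2 pops x 5 diploids, alt copies 7/10 vs 2/10 with chosen hets."""
    p_geno = [2, 2, 1, 1, 1]   # 7 alt copies, 3 hets
    q_geno = [1, 1, 0, 0, 0]   # 2 alt copies, 2 hets
    g = np.array(p_geno + q_geno, dtype=np.int8).reshape(10, 1)
    m = make_matrix(g, pop_map={f"acc{i}": ("P" if i < 5 else "Q")
                                for i in range(10)})
    res = weir_cockerham_fst(m, ["P", "Q"])
    a, b, c = wc_oracle([7, 2], [5, 5], [3, 2])
    assert res.fst == pytest.approx(a / (a + b + c), rel=1e-12)
    np.testing.assert_allclose(res.components[:, 0], [a, b, c], rtol=1e-12)


def test_label_swap_invariance(island4):
    """Recoding 0<->2 at every site leaves pi and F_ST unchanged."""
    g = island4.genotypes.copy()
    swapped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
    from dataclasses import replace
    m2 = replace(island4, genotypes=swapped)
    _, pi1 = nucleotide_diversity(island4, "W")
    _, pi2 = nucleotide_diversity(m2, "W")
    assert pi1 == pytest.approx(pi2, rel=1e-12)
    f1 = weir_cockerham_fst(island4, ["W", "X"]).fst
    f2 = weir_cockerham_fst(m2, ["W", "X"]).fst
    assert f1 == pytest.approx(f2, rel=1e-12)


def test_diversity_table_shape(island4):
    tab = diversity_table(island4)
    assert (tab["kind"] == "population").sum() == 4
    assert (tab["kind"] == "pair").sum() == 6
    with pytest.raises(ValueError):
        weir_cockerham_fst(island4, ["W"])
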