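import numpy as np
import pytest

from zanthopop import (Deme, Demography, SimConfig, expected_sfs_mc,
                       island_model, simulate_genotypes)
from zanthopop.popstats import weir_cockerham_fst
from zanthopop.simulate import pairwise_tmrca


def constant_folded_expectation(n):
    """Folded standard-coalescent expectation: 1/i + 1/(n-i), normalized."""
    f = np.zeros(n // 2 + 1)
    for i in range(1, n):
        f[min(i, n - i)] += 1.0 / i
    return f / f.sum()


def test_pairwise_tmrca_matches_2n():
    """E[T2] for two lineages in a constant deme of N diploids is 2N."""
    d = Demography([Deme("A", 1000.0)])
    t = pairwise_tmrca(d, "A", 20000, seed=3)
    se = t.std() / np.sqrt(len(t))
    assert abs(t.mean() - 2000.0) < 3 * se


def test_constant_size_folded_sfs_closed_form():
    d = Demography([Deme("A", 5000.0)])
    sfs = expected_sfs_mc(d, {"A": 5}, 40000, seed=7)
    n = 10
    expect = constant_folded_expectation(n)
    obs = sfs.counts.ravel()[: n // 2 + 1]
    # Monte-Carlo SE per folded class, conservative binomial bound
    se = np.sqrt(expect * (1 - expect) / 40000) * 3.5
    assert np.all(np.abs(obs[1:] - expect[1:]) < 3 * se[1:] + 0.004)


def test_split_at_time_zero_equals_panmixia():
    """Two demes joined at t=0 behave as one panmictic deme."""
    one = Demography([Deme("A", 2000.0)])
    split = Demography([Deme("A", 2000.0), Deme("B", 2000.0)],
                       [("join", 0.0, "B", "A")])
    s1 = expected_sfs_mc(one, {"A": 8}, 20000, seed=5, haploid=True)
    s2 = expected_sfs_mc(split, {"A": 4, "B": 4}, 20000, seed=6, haploid=True)
    m1 = s1.counts.ravel()[:5]
    # pool the two demes of the split spectrum into a 1-D folded SFS
    from zanthopop.sfs import fold_joint
    dims = s2.counts.shape
    pooled = np.zeros(9)
    for i in range(dims[0]):
        for j in range(dims[1]):
            pooled[i + j] += s2.counts[i, j]
    pooled = fold_joint(pooled, (8,)).ravel()[:5]
    assert np.abs(m1[1:] - pooled[1:]).max() < 0.01


def test_island_model_fst_matches_wright():
    """WC F_ST on island-model genotypes tracks 1/(1 + 4Nm (d/(d-1))^2)."""
    d_demes, nm = 4, 4.0
    demo = island_model(d_demes, 2000.0, nm / 2000.0)
    cfg = SimConfig(n_loci=4000,
                    samples_per_deme={f"deme{i}": 10 for i in range(d_demes)},
                    seed=11)
    m = simulate_genotypes(demo, cfg)
    fst = weir_cockerham_fst(m, [f"deme{i}" for i in range(d_demes)]).fst
    expect = 1.0 / (1.0 + 4 * nm * (d_demes / (d_demes - 1.0)) ** 2)
    assert abs(fst - expect) < 0.015


def test_exchangeability_within_deme():
    """Permuting accessions within a deme leaves summary statistics alone."""
    demo = island_model(2, 1000.0, 0.001, labels=["A", "B"])
    cfg = SimConfig(n_loci=500, samples_per_deme={"A": 6, "B": 6}, seed=4)
    m = simulate_genotypes(demo, cfg)
    rng = np.random.default_rng(0)
    idx_a = np.flatnonzero([m.pop_map[a] == "A" for a in m.accession_ids])
    perm = rng.permutation(idx_a)
    g = m.genotypes.copy()
    g[idx_a] = g[perm]
    from conftest import make_matrix
    m2 = make_matrix(g, stack_ids=list(m.stack_ids))
    m2.pop_map = {f"acc{i}": m.pop_map[m.accession_ids[i]]
                  for i in range(m.n_accessions)}
    f1 = weir_cockerham_fst(m, ["A", "B"]).fst
    f2 = weir_cockerham_fst(m2, ["A", "B"]).fst
    assert f1 == pytest.approx(f2, abs=1e-12)


def test_simulator_determinism_and_missingness():
    demo = Demography([Deme("A", 1000.0)])
    cfg = SimConfig(n_loci=300, samples_per_deme={"A": 5}, missing_rate=0.3,
                    seed=42)
    m1 = simulate_genotypes(demo, cfg)
    m2 = simulate_genotypes(demo, cfg)
    np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
    miss = (m1.genotypes == -1).mean()
    assert abs(miss - 0.3) < 0.03


def test_never_coalescing_demography_rejected():
    d = Demography([Deme("A", 100.0), Deme("B", 100.0)])
    with pytest.raises(ValueError, match="never coalesces"):
        d.compile()


def test_migration_rate_bound():
    d = island_model(2, 100.0, 1.5)
    with pytest.raises(ValueError, match="migration"):
        d.compile()


def test_expected_sfs_against_msprime_two_pop_split():
    """Cross-validate the branch-length SFS engine against msprime on a
    two-deme split demography."""
    import msprime

    t_split, n1, n2, nanc = 800.0, 1500.0, 700.0, 1200.0
    ours = Demography([Deme("A", n1), Deme("B", n2)],
                      [("join", t_split, "B", "A"),
                       ("size", t_split, "A", nanc, 0.0)])
    sfs = expected_sfs_mc(ours, {"A": 6, "B": 6}, 60000, seed=13,
                          haploid=True)

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=n1)
    dem.add_population(name="B", initial_size=n2)
    dem.add_population(name="ANC", initial_size=nanc)
    dem.add_population_split(time=t_split, derived=["A", "B"], ancestral="ANC")
    reps = msprime.sim_ancestry(samples={"A": 3, "B": 3}, demography=dem,
                                num_replicates=3000, random_seed=5, ploidy=2)
    acc = np.zeros((7, 7))
    for ts in reps:
        a = ts.allele_frequency_spectrum(
            sample_sets=[list(range(0, 6)), list(range(6, 12))],
            mode="branch", polarised=True, span_normalise=False)
        acc += a
    from zanthopop.sfs import fold_joint
    acc[0, 0] = acc[6, 6] = 0.0
    folded = fold_joint(acc, (6, 6))
    folded[0, 0] = 0.0
    folded /= folded.sum()
    ours_arr = sfs.counts
    assert np.abs(ours_arr - folded).max() < 0.012
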