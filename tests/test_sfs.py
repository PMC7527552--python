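import numpy as np
import pytest
from scipy.stats import hypergeom

from zanthopop import MISSING, FoldedSFS, bootstrap_sfs, folded_sfs
from zanthopop.sfs import fold_joint, read_sfs, write_sfs

from conftest import make_matrix


def full_panel(n_dip, alt_copies, n_sites=1, stack_ids=None):
    """n_dip diploids, one population, each site with alt_copies alt alleles
    spread as homozygotes/heterozygote."""
    g = np.zeros((n_dip, n_sites), dtype=np.int8)
    for s in range(n_sites):
        c = alt_copies
        i = 0
        while c >= 2:
            g[i, s] = 2
            c -= 2
            i += 1
        if c:
            g[i, s] = 1
    return make_matrix(g, stack_ids=stack_ids,
                       pop_map={f"acc{i}": "P" for i in range(n_dip)})


def test_full_projection_single_bin():
    """Fully genotyped site with 3 alt copies lands wholly in bin 3."""
    m = full_panel(10, 3)
    s = folded_sfs(m, ["P"], [20])
    assert s.counts[3] == pytest.approx(1.0)
    assert s.counts.sum() == pytest.approx(1.0)
    assert s.n_sites_used == 1


def test_hypergeometric_projection_masses():
    """2 of 10 diploids missing (16 observed copies), projection 16: the
    bins follow the hypergeometric pmf of drawing alt copies in 16 draws."""
    m = full_panel(10, 5)
    g = m.genotypes.copy()
    g[[8, 9], 0] = MISSING  # remove homozygous-ref diploids: 16 copies, 5 alt
    m2 = make_matrix(g, pop_map=m.pop_map)
    s = folded_sfs(m2, ["P"], [14])
    expect = hypergeom.pmf(np.arange(8), 16, 5, 14)
    # folded: classes beyond 7 fold back
    full = hypergeom.pmf(np.arange(15), 16, 5, 14)
    folded = fold_joint(full, (14,)).ravel()
    np.testing.assert_allclose(s.counts.ravel(), folded, atol=1e-12)


def test_half_frequency_folding_single_count():
    """A site at exactly half the projected copies increments its bin once."""
    m = full_panel(10, 10)
    s = folded_sfs(m, ["P"], [20])
    assert s.counts[10] == pytest.approx(1.0)
    assert s.counts.sum() == pytest.approx(1.0)


def test_sites_below_projection_skipped():
    m = full_panel(10, 3)
    g = m.genotypes.copy()
    g[:6, 0] = MISSING       # 8 observed copies < projection 16
    m2 = make_matrix(g, pop_map=m.pop_map)
    s = folded_sfs(m2, ["P"], [16])
    assert s.n_sites_used == 0


def test_mass_conservation(island4):
    s = folded_sfs(island4, ["W", "X"], [12, 12])
    assert s.counts.sum() == pytest.approx(s.n_sites_used, rel=1e-9)


def test_refolding_is_identity(island4):
    s = folded_sfs(island4, ["W", "X"], [10, 10])
    refolded = fold_joint(s.counts, s.sample_sizes)
    np.testing.assert_allclose(refolded, s.counts, atol=1e-12)


def test_marginalization_matches_1d(island4):
    joint = folded_sfs(island4, ["W", "X"], [12, 12])
    marg = joint.marginalize(0)
    solo = folded_sfs(island4, ["W"], [12])
    # same usable-site set is not guaranteed (joint requires both pops), so
    # compare normalized shapes loosely
    a = marg.counts.ravel() / marg.counts.sum()
    b = solo.counts.ravel() / solo.counts.sum()
    assert np.abs(a - b).max() < 0.03


def test_bootstrap_identity_hook(island4):
    s = folded_sfs(island4, ["W"], [12])
    b = bootstrap_sfs(island4, ["W"], [12], 1, seed=0, _identity=True)[0]
    np.testing.assert_allclose(b.counts, s.counts, atol=1e-12)


def test_bootstrap_consistency_and_determinism(island4):
    s = folded_sfs(island4, ["W"], [10])
    boots = bootstrap_sfs(island4, ["W"], [10], 30, seed=7)
    mean = np.mean([b.counts for b in boots], axis=0)
    se = np.std([b.counts for b in boots], axis=0) / np.sqrt(30)
    assert np.all(np.abs(mean - s.counts) < 4 * se + 1e-9)
    again = bootstrap_sfs(island4, ["W"], [10], 2, seed=7)
    np.testing.assert_allclose(again[0].counts, boots[0].counts)
    assert not np.allclose(boots[0].counts, boots[1].counts)


def test_projection_validation(island4):
    with pytest.raises(ValueError):
        folded_sfs(island4, ["W"], [0])
    with pytest.raises(ValueError):
        folded_sfs(island4, ["W"], [99])


def test_sfs_file_round_trip(tmp_path, island4):
    s = folded_sfs(island4, ["W", "X"], [8, 8])
    path = tmp_path / "sfs.txt"
    write_sfs(s, path)
    s2 = read_sfs(path)
    np.testing.assert_allclose(s2.counts, s.counts, rtol=1e-9)
    assert s2.sample_sizes == s.sample_sizes
    assert s2.pop_labels == s.pop_labels


def test_probability_normalization(island4):
    s = folded_sfs(island4, ["W"], [10]).normalized()
    assert s.segregating_values().sum() == pytest.approx(1.0)
    assert s.is_probability
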