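import numpy as np
import pytest

from zanthopop.fstats import (FreqMatrix, FStatResult, block_jackknife, d_stat,
                              f2, f3, f3_scan, f4, outgroup_f3)

from conftest import make_matrix


def freq_matrix_from_freqs(freqs, counts=None, n_blocks=4):
    freqs = np.asarray(freqs, dtype=float)
    P, S = freqs.shape
    counts = (np.full((P, S), 1000) if counts is None
              else np.asarray(counts))
    block_ids = np.repeat(np.arange(n_blocks), int(np.ceil(S / n_blocks)))[:S]
    return FreqMatrix(freqs, counts, [f"P{i}" for i in range(P)],
                      np.sort(block_ids))


def brute_force_f3(c, a, b, kc, corrected=True):
    vals = (c - a) * (c - b)
    if corrected:
        vals = vals - c * (1 - c) / (kc - 1)
    return vals.mean()


def test_f3_intermediate_target_negative():
    """Target exactly intermediate between the sources gives negative f3."""
    S = 40
    a = np.tile([1.0, 0.0], S // 2)
    b = 1.0 - a
    c = np.full(S, 0.5)
    fm = freq_matrix_from_freqs([c, a, b])
    res = f3("P0", "P1", "P2", fm)
    expect = brute_force_f3(c, a, b, np.full(S, 1000.0))
    assert res.estimate == pytest.approx(expect, abs=1e-9)
    assert res.estimate < 0
    assert res.estimate == pytest.approx(-0.25, abs=0.001)


def test_f3_target_equals_source_is_zero():
    rng = np.random.default_rng(1)
    a = rng.uniform(0.1, 0.9, 60)
    b = rng.uniform(0.1, 0.9, 60)
    fm = freq_matrix_from_freqs([a, a.copy(), b])
    res = f3("P0", "P1", "P2", fm, corrected=False)
    assert res.estimate == pytest.approx(0.0, abs=1e-12)


def test_f3_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    freqs = rng.uniform(0.05, 0.95, (3, 6))
    counts = rng.integers(10, 40, (3, 6))
    fm = freq_matrix_from_freqs(freqs, counts, n_blocks=2)
    res = f3("P0", "P1", "P2", fm)
    expect = np.mean((freqs[0] - freqs[1]) * (freqs[0] - freqs[2])
                     - freqs[0] * (1 - freqs[0]) / (counts[0] - 1))
    assert res.estimate == pytest.approx(expect, rel=1e-12)


def test_f3_rejects_duplicate_target():
    fm = freq_matrix_from_freqs(np.random.default_rng(0).random((3, 8)))
    with pytest.raises(ValueError):
        f3("P0", "P0", "P1", fm)


def test_f3_symmetric_in_sources():
    rng = np.random.default_rng(3)
    fm = freq_matrix_from_freqs(rng.uniform(0.1, 0.9, (3, 30)))
    r1 = f3("P0", "P1", "P2", fm)
    r2 = f3("P0", "P2", "P1", fm)
    assert r1.estimate == pytest.approx(r2.estimate, rel=1e-12)
    assert r1.se == pytest.approx(r2.se, rel=1e-12)


def test_outgroup_f3_ranks_clone_highest():
    rng = np.random.default_rng(5)
    og = rng.uniform(0.2, 0.8, 200)
    x = np.clip(og + rng.normal(0, 0.15, 200), 0.01, 0.99)
    clone = x.copy()
    far = rng.uniform(0.2, 0.8, 200)
    fm = FreqMatrix(np.vstack([og, x, clone, far]),
                    np.full((4, 200), 1000), ["og", "x", "clone", "far"],
                    np.repeat(np.arange(4), 50))
    r_clone = outgroup_f3("og", "x", "clone", fm)
    r_far = outgroup_f3("og", "x", "far", fm)
    assert r_clone.estimate > r_far.estimate


def test_d_zero_when_sister_frequencies_equal():
    rng = np.random.default_rng(2)
    w, x = rng.uniform(0.1, 0.9, (2, 40))
    y = rng.uniform(0.1, 0.9, 40)
    fm = freq_matrix_from_freqs([w, x, y, y.copy()])
    res = d_stat("P0", "P1", "P2", "P3", fm)
    assert res.estimate == pytest.approx(0.0, abs=1e-12)


def test_d_single_fixed_site_is_one():
    """w=1, x=0, y=1, z=0 gives D = 1 in the normalized form."""
    fm = freq_matrix_from_freqs([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0],
                                 [0.0, 0.0]], n_blocks=2)
    res = d_stat("P0", "P1", "P2", "P3", fm)
    assert res.estimate == pytest.approx(1.0, abs=1e-12)


def test_d_brute_force_and_symmetries():
    rng = np.random.default_rng(11)
    fr = rng.uniform(0.05, 0.95, (4, 24))
    fm = freq_matrix_from_freqs(fr, n_blocks=3)
    w, x, y, z = fr
    expect = np.sum((w - x) * (y - z)) / np.sum(
        (w + x - 2 * w * x) * (y + z - 2 * y * z))
    r = d_stat("P0", "P1", "P2", "P3", fm)
    assert r.estimate == pytest.approx(expect, abs=1e-12)
    assert d_stat("P1", "P0", "P2", "P3", fm).estimate == pytest.approx(
        -r.estimate, abs=1e-12)
    assert d_stat("P0", "P1", "P3", "P2", fm).estimate == pytest.approx(
        -r.estimate, abs=1e-12)


def test_global_allele_relabel_invariance():
    rng = np.random.default_rng(4)
    fr = rng.uniform(0.05, 0.95, (4, 30))
    fm1 = freq_matrix_from_freqs(fr)
    fm2 = freq_matrix_from_freqs(1.0 - fr)
    for func, args in [(f2, ("P0", "P1")), (f3, ("P0", "P1", "P2")),
                       (d_stat, ("P0", "P1", "P2", "P3"))]:
        assert func(*args, fm1).estimate == pytest.approx(
            func(*args, fm2).estimate, rel=1e-10)


def test_f4_additivity_identity():
    """f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) for any frequency table."""
    rng = np.random.default_rng(9)
    fr = rng.uniform(0.02, 0.98, (5, 50))
    fm = freq_matrix_from_freqs(fr)
    lhs = f4("P0", "P1", "P2", "P3", fm).estimate
    rhs = (f4("P0", "P1", "P2", "P4", fm).estimate
           + f4("P0", "P1", "P4", "P3", fm).estimate)
    assert lhs == pytest.approx(rhs, abs=1e-10)


def test_jackknife_identical_blocks_zero_se():
    num = np.tile([1.0, 2.0], 10)
    den = np.ones(20)
    ids = np.repeat(np.arange(10), 2)
    est, se = block_jackknife(num, den, ids)
    assert est == pytest.approx(1.5)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_jackknife_matches_textbook_equal_blocks():
    """Equal-size blocks, simple mean: matches the classic delete-one
    jackknife variance."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 40)
    ids = np.repeat(np.arange(8), 5)
    est, se = block_jackknife(x, np.ones(40), ids)
    G = 8
    block_means = x.reshape(8, 5).mean(axis=1)
    theta_j = np.array([(x.sum() - x[ids == b].sum()) / 35 for b in range(8)])
    var = (G - 1) / G * np.sum((theta_j - theta_j.mean()) ** 2)
    assert est == pytest.approx(x.mean())
    assert se == pytest.approx(np.sqrt(var), rel=1e-9)


def test_jackknife_block_size_robustness():
    rng = np.random.default_rng(6)
    x = rng.normal(0.0, 1.0, 4000)
    se_small = block_jackknife(x, np.ones(4000),
                               np.repeat(np.arange(40), 100))[1]
    se_half = block_jackknife(x, np.ones(4000),
                              np.repeat(np.arange(80), 50))[1]
    assert abs(se_small - se_half) / se_small < 0.2


def test_jackknife_single_block_error():
    with pytest.raises(ValueError):
        block_jackknife(np.ones(5), np.ones(5), np.zeros(5, dtype=int))


def test_f3_scan_counts_and_planted_admixture():
    """One planted 50/50 admixed target is flagged; pure drift targets are
    not; 3 populations give exactly 3 tests."""
    rng = np.random.default_rng(8)
    S = 4000
    anc = rng.uniform(0.1, 0.9, S)
    drift = 0.06
    a = np.clip(anc + rng.normal(0, drift, S), 0.001, 0.999)
    b = np.clip(anc + rng.normal(0, drift, S), 0.001, 0.999)
    c = np.clip(anc + rng.normal(0, drift, S), 0.001, 0.999)
    mix = 0.5 * a + 0.5 * b + rng.normal(0, 0.01, S)
    fm = FreqMatrix(np.vstack([a, b, c, np.clip(mix, 0.001, 0.999)]),
                    np.full((4, S), 2000), ["A", "B", "C", "MIX"],
                    np.repeat(np.arange(20), S // 20))
    scan = f3_scan(fm)
    assert len(scan) == 4 * 3  # 4 targets x C(3,2) source pairs
    sig = scan[scan["significant"]]
    assert set(sig["target"]) == {"MIX"}
    best = scan.loc[scan["f3"].idxmin()]
    assert best["target"] == "MIX" and best["significant"]
    three = f3_scan(FreqMatrix(np.vstack([a, b, c]), np.full((3, S), 2000),
                               ["A", "B", "C"],
                               np.repeat(np.arange(20), S // 20)))
    assert len(three) == 3


def test_fstat_result_validation():
    with pytest.raises(ValueError):
        FStatResult("f2", ("a", "b"), 0.1, -0.5, 1.0, 10)
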