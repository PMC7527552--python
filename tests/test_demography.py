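import numpy as np
import pytest

from zanthopop import Deme, Demography, SimConfig, expected_sfs_mc
from zanthopop.demography import (FitConfig, ModelFit, Param, compare_models,
                                  fit_model, generations_to_years,
                                  model_9, model_11, model_12, model_13,
                                  model_isolation)


def test_rescaling_generations_to_years():
    assert generations_to_years(1360.0) == pytest.approx(5440.0)


def test_param_validation():
    with pytest.raises(ValueError):
        Param("bad", 5.0, 1.0)
    with pytest.raises(ValueError):
        Param("bad", 0.0, 1.0, log=True)


def test_model_fit_aic_consistency_enforced():
    with pytest.raises(ValueError):
        ModelFit("m", {}, -100.0, 2, aic=123.0, n_sites=10,
                 sample_sizes=(8, 8))


def test_akaike_weights_closed_form():
    """Delta-AIC (0, 2) gives weights (0.731, 0.269)."""
    f1 = ModelFit("a", {}, -100.0, 1, 2 * 1 - 2 * -100.0, 10.0, (8, 8))
    f2 = ModelFit("b", {}, -100.0, 2, 2 * 2 - 2 * -100.0, 10.0, (8, 8))
    ranked = compare_models([f1, f2])
    assert ranked[0].weight == pytest.approx(
        np.exp(0) / (np.exp(0) + np.exp(-1)), abs=1e-4)
    assert ranked[0].weight == pytest.approx(0.731, abs=0.001)
    assert ranked[1].weight == pytest.approx(0.269, abs=0.001)
    assert sum(f.weight for f in ranked) == pytest.approx(1.0)


def test_equal_aic_equal_weights():
    f1 = ModelFit("a", {}, -50.0, 1, 102.0, 10.0, (8,))
    f2 = ModelFit("b", {}, -50.0, 1, 102.0, 10.0, (8,))
    ranked = compare_models([f1, f2])
    assert ranked[0].weight == pytest.approx(ranked[1].weight)


def test_extra_unused_parameter_costs_two_aic():
    """Identical lnL with one extra free parameter -> AIC larger by 2."""
    f1 = ModelFit("a", {}, -80.0, 2, 2 * 2 + 160.0, 10.0, (8, 8))
    f2 = ModelFit("b", {}, -80.0, 3, 2 * 3 + 160.0, 10.0, (8, 8))
    assert f2.aic - f1.aic == pytest.approx(2.0)


def test_compare_models_rejects_mixed_data():
    f1 = ModelFit("a", {}, -50.0, 1, 102.0, 10.0, (8,))
    f2 = ModelFit("b", {}, -50.0, 1, 102.0, 20.0, (8,))
    with pytest.raises(ValueError):
        compare_models([f1, f2])


def test_coalescent_scaling_invariance():
    """Scaling all sizes and times by c leaves the conditioned SFS shape
    unchanged (coalescent scaling identity)."""
    base = Demography([Deme("A", 2000.0), Deme("B", 2000.0)],
                      [("join", 1000.0, "B", "A")])
    scaled = Demography([Deme("A", 6000.0), Deme("B", 6000.0)],
                        [("join", 3000.0, "B", "A")])
    s1 = expected_sfs_mc(base, {"A": 6, "B": 6}, 30000, seed=3, haploid=True)
    s2 = expected_sfs_mc(scaled, {"A": 6, "B": 6}, 30000, seed=4, haploid=True)
    assert np.abs(s1.counts - s2.counts).max() < 0.012


def test_fit_model_dimension_check():
    obs = expected_sfs_mc(Demography([Deme("A", 1000.0)]), {"A": 8}, 2000,
                          seed=1, haploid=True)
    with pytest.raises(ValueError, match="populations"):
        fit_model(obs, model_9(), FitConfig(n_starts=1))


def test_degenerate_sfs_rejected():
    from zanthopop.sfs import FoldedSFS

    flat = np.zeros(9)
    flat[1] = 100.0
    obs = FoldedSFS(flat, (8,), ("A",), 100.0)
    mod = model_isolation(1e3, 1e3, 1e3, (10.0, 1e4))
    with pytest.raises(ValueError, match="degenerate|populations"):
        fit_model(obs, mod, FitConfig(n_starts=1))


def test_model_builders_produce_valid_demographies():
    for mod, vals in [
        (model_9(), {"T_split": 1360.0, "cult_drift": 27.2}),
        (model_11(), {"T_split": 1360.0, "cult_drift": 27.2,
                      "m12": 1e-4, "m21": 1e-5}),
        (model_12(), {"T_split": 1360.0, "cult_drift": 27.2,
                      "wild_drift": 0.2}),
        (model_13(), {"T_old": 55250.0, "frac_young": 0.99}),
    ]:
        demo = mod.builder(vals)
        demo.compile()   # raises on invalid structure
        assert mod.k == len(mod.params)


def test_model9_derived_quantities():
    mod = model_9(n_anc=10_000.0)
    d = mod.derived({"T_split": 1360.0, "cult_drift": 27.2})
    assert d["N_cult_present"] == pytest.approx(50.0)
    assert d["fold_decline"] == pytest.approx(200.0)
    assert d["T_split_years"] == pytest.approx(5440.0)


def test_multinomial_mle_property():
    """When the expected SFS equals the observed proportions, lnL equals the
    multinomial log-mass at the MLE (maximum over probability vectors)."""
    probs = np.array([0.5, 0.3, 0.2])
    counts = probs * 1000
    lnl = float(np.dot(counts, np.log(probs)))
    for q in [np.array([0.4, 0.35, 0.25]), np.array([0.6, 0.2, 0.2])]:
        assert float(np.dot(counts, np.log(q))) < lnl
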