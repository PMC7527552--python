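import numpy as np
import pandas as pd
import pytest

from zanthopop import SNPMatrix, SimConfig, island_model, simulate_genotypes


def make_matrix(genotypes, stack_ids=None, pop_map=None, positions=None):
    """Build a small SNPMatrix from a genotype array (accessions x sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_acc, n_sites = g.shape
    acc = [f"acc{i}" for i in range(n_acc)]
    meta = pd.DataFrame({
        "stack_id": stack_ids if stack_ids is not None
        else [f"s{j}" for j in range(n_sites)],
        "pos": positions if positions is not None else list(range(1, n_sites + 1)),
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    })
    return SNPMatrix(g, meta, acc, pop_map or {})


@pytest.fixture(scope="session")
def island4():
    """Neutral 4-deme island-model panel reused across calibration tests
    (N = 2000 diploids, total out-migration 0.002 per generation, so
    Nm = 4 and Wright's expected F_ST is ~0.034)."""
    demo = island_model(4, 2000.0, 0.002, labels=["W", "X", "Y", "Z"])
    cfg = SimConfig(n_loci=3000, samples_per_deme={p: 8 for p in "WXYZ"},
                    seed=2)
    return simulate_genotypes(demo, cfg)


@pytest.fixture(scope="session")
def study_panel():
    """Reduced-size version of the 112-accession six-clade study fixture."""
    import tempfile

    from zanthopop import make_study_fixture, read_popmap, read_vcf

    with tempfile.TemporaryDirectory() as td:
        vcf, pm = make_study_fixture(123, td, n_snps=1200)
        return read_vcf(vcf, read_popmap(pm))
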