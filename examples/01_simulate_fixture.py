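"""Generate a reduced study-scale synthetic panel and inspect its design.

Emulates the 112-accession, six-clade sampling design (four Z. bungeanum
clades, wild and cultivated Z. armatum) with GBS stacks and missing calls,
then prints panel dimensions and the species-level vs within-species
differentiation — the deep split should dominate.
"""

import tempfile

from zanthopop import make_study_fixture, read_popmap, read_vcf
from zanthopop.popstats import weir_cockerham_fst

with tempfile.TemporaryDirectory() as td:
    vcf, popmap = make_study_fixture(seed=1, out_dir=td, n_snps=3000)
    panel = read_vcf(vcf, read_popmap(popmap))

print(f"accessions: {panel.n_accessions}, SNPs: {panel.n_sites}, "
      f"populations: {panel.populations()}")
fst_species = weir_cockerham_fst(panel, ["CladeI", "CladeV"]).fst
fst_within = weir_cockerham_fst(panel, ["CladeI", "CladeII"]).fst
print(f"F_ST Z. bungeanum Clade I vs wild Z. armatum (between species): "
      f"{fst_species:.3f}")
print(f"F_ST Clade I vs Clade II (within species):                     "
      f"{fst_within:.3f}")
print("The between-species value is far larger: the 12 Mya-equivalent split "
      "has fixed most variation between species.")
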