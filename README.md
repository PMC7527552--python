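# zanthopop

Population-genomic inference for reduced-representation (GBS) SNP panels,
built around the analysis stack used to resolve the diversity, demographic
history, cultivar relationships and selection signals of Chinese pepper
(*Zanthoxylum bungeanum* and *Z. armatum*): 112 accessions in six genetic
clades genotyped at ~38,000 biallelic SNPs.

For researchers working on non-model (often polyploid-adjacent, unmapped)
crop or tree genomes, the package provides, from a VCF + population map:

- **Genotype I/O and filtering** — biallelic/missingness site filters,
  one-SNP-per-locus LD thinning on GBS stacks;
- **Diversity and differentiation** — per-site nucleotide diversity
  π = (k/(k−1))·2p̂(1−p̂), observed/expected heterozygosity, and
  Weir–Cockerham F_ST from per-site variance components (Σa / Σ(a+b+c));
- **Folded site-frequency spectra** — 1-D and joint 2-D/3-D, folded over
  the pooled minor allele, with hypergeometric projection for missing data
  and stack-level bootstrap;
- **Demographic inference** — stairway-style piecewise-constant Ne(t) from
  the folded SFS (exact expected spectra via the pure-death lineage chain),
  and multi-population composite-likelihood model fitting: multinomial
  likelihood over SFS entries, Monte-Carlo expected spectra, cyclic Brent
  optimization, AIC/Akaike-weight model comparison, parametric bootstrap;
- **f-statistics** — admixture-f3 (bias-corrected), outgroup-f3, f4 and
  D = Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz), all with weighted block-jackknife
  standard errors and an FDR-adjusted f3 scan;
- **Admixture graphs** — prediction of every f2/f3/f4 from drift edges and
  mixture proportions (f2(A,B) = Σ_e d_e (w_A(e)−w_B(e))²), least-squares
  fitting, max|Z| scoring over the full statistic basis, and the
  incremental skeleton-tree search;
- **Selection scans** — FLK (tree-derived kinship, χ²_{P−1}) and an
  Fdist-style island-model simulation null, combined by the all-tests
  consensus rule;
- **A structured-coalescent simulator** (numba-accelerated) generating
  genotype matrices and expected spectra under multi-deme demographies with
  growth, migration and splits — every inference stage above is validated
  by parameter recovery against it, including a full study-scale fixture
  emulating the 112-accession design.

Times are rescaled to years with generation time g = 4 yr and mutation rate
μ = 2.6 × 10⁻⁹ per site per year, the calibration used for this system.

## Worked example

Fit the isolation-with-exponential-shrinkage model to a wild/cultivated
pair simulated at a 5,440-year split with a 200-fold cultivated decline
(`examples/04_fit_demographic_model.py`, ~1 minute):

```
$ python examples/04_fit_demographic_model.py
model_9    lnL= -10973.5 AIC=  21951.1 weight=1.000
isolation  lnL= -13159.3 AIC=  26320.6 weight=0.000

best-fit split: 5358 yr (truth 5440); fold-decline 200 (truth 200)
The shrinkage model should carry essentially all Akaike weight.
```

The shrinkage model wins the AIC comparison decisively, and the recovered
split time and fold-decline sit within a few percent of the generating
truth — the same experiment design, at larger size, underlies the
reproduction script below.  The other examples cover the synthetic study
fixture, diversity/F_ST tables, stairway trajectories (a planted twofold
post-glacial decline comes back as a 0.50 size ratio), the f3 admixture
scan, admixture-graph fitting (14,706 statistics for 19 populations), and
the outlier consensus.

A thin CLI wraps the pipeline stages
(`zanthopop simulate | filter | stats | sfs | stairway | fitmodels |
fstats | graph | outliers | run-all`), driven by a YAML/JSON config with a
single master seed; `zanthopop run-all -c config.yaml` writes TSV/JSON/VCF
artifacts plus a machine-readable run report.

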