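# Methods

`zanthopop` reimplements, as a tested library, the population-genomic
analysis stack used to study the diversity, demography, admixture and
selection history of Chinese pepper (*Zanthoxylum bungeanum* and
*Z. armatum*) from a genome-wide GBS SNP panel.  Because the deposited
sequencing reads are not required (or available offline), every inference
stage is validated by parameter recovery on data from the package's own
structured-coalescent simulator, with the published point estimates serving
as the simulation truths.

## The coalescent simulator

Genealogies are simulated backward in time under the structured coalescent:
demes have diploid sizes with optional exponential growth within epochs,
backward migration rates per epoch, and join events (a deme merges into
another, looking back).  Times are in generations; the pairwise coalescence
rate in a deme of size `N` is `1/(2N)`.  Waiting times under exponential
size change are drawn exactly by inverting the integrated hazard; competing
events (per-deme coalescence, migration) are resampled after every event.
The kernels are numba-compiled; an independent coalescent library (msprime)
is used in the test suite only, as a cross-validation oracle.

**Segregating-site ascertainment.** SNPs are placed uniformly on branch
length, one or more per GBS stack, *conditioned on segregating*.  Under
low-rate infinite-sites mutation, a locus carrying `s` SNPs has its
genealogy weighted by `(total branch length)^s`; the generator therefore
importance-resamples stack genealogies by that weight from a pool
(`pool_factor` × the number of stacks, default 3).  This matters: without
the length weighting the simulated spectra are inconsistent with
mutational ascertainment and demographic fits are systematically biased.
Because SNP counts are fixed by conditioning, no mutation rate enters the
simulator; rates enter only when rescaling results to years
(`g = 4` yr/generation, `mu = 2.6e-9` /site/yr).

**Study fixture.** `make_study_fixture` emits a 112-accession, six-clade
panel (30/20/20/17 accessions in *Z. bungeanum* Clades I–IV; 12 wild and 13
cultivated *Z. armatum*) with ~38,395 SNPs in stacks of 1–4 SNPs
(probabilities 0.5/0.3/0.15/0.05), 10% genotypes missing completely at
random, under a composite demography: species split 3e6 generations ago
(12 Mya-equivalent), clade splits at 55,250/54,750 generations (221/219
kya), Clade IV attached at 75,000 generations, and a wild/cultivated
*Z. armatum* split 1,360 generations ago (5,440 yr) with a 200-fold
exponential decline in the cultivated deme.  Absolute sizes are declared
assumptions, not published values: 20,000 diploids per *Z. bungeanum* clade
(so their diversity exceeds *Z. armatum*'s), 10,000 for wild/ancestral
*Z. armatum*, 50 for present-day cultivated.  All are overridable.

What the generator does **not** emulate: read-level error and depth,
within-stack recombination (stacks are grouping metadata only; loci are
unlinked), non-random missingness, and selection (outlier tests get planted
loci by post-hoc genotype perturbation).  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data artifacts.

## Filters and spectra

Matrix-level site filtering retains biallelic sites genotyped in at least
`1 - max_missing_fraction` of accessions (default threshold 0.4, i.e. a
site must be genotyped in ≥60% of accessions); non-biallelic removal takes
priority over missingness in the report so the counts are well defined.
Monomorphic-within-panel sites are retained by default (they carry SFS
projection mass) with a flag to drop them.  LD thinning keeps one uniform
random SNP per stack, deterministically per seed.

Folded spectra (1-D and joint 2-D/3-D) index the *pooled* minor allele;
cell pairs `(c, n - c)` merge onto a canonical representative, exact-half
cells counted once.  Missing data are handled by hypergeometric projection
(fractional mass, deterministic) to a per-population haploid size; sites
with fewer observed copies than the projection are skipped.  Monomorphic
classes are recorded but excluded from likelihoods, since a SNP-only panel
has no invariant-site count.  The bootstrap resamples whole stacks with
replacement (the exchangeable unit under within-stack linkage).

## Diversity and differentiation

Per-site nucleotide diversity is `(k/(k-1)) · 2p(1-p)` over observed copies
(equal to the average pairwise difference), reported per variant site —
GBS panels have no callable-site denominator, so between-study comparisons
need an external total.  Observed heterozygosity is per accession; expected
heterozygosity per population.  F_ST is Weir & Cockerham's theta from
per-site variance components `(a, b, c)` with per-site sample sizes,
combined as a ratio of sums; negative per-site components are retained.

## Demographic inference

**Stairway-style Ne(t).**  The expected folded SFS under piecewise-constant
Ne is computed exactly: the ancestral-lineage count is a pure-death chain,
epoch occupancy times come from matrix exponentials of the bidiagonal rate
matrix, and `E[xi_i] = sum_k k E[T_k] C(n-i-1,k-2)/C(n-1,k-1)`.  The fit
maximizes the multinomial likelihood of the folded SFS over per-epoch sizes
on a fixed log time grid (12 intervals spanning 0.02–8 coalescent units);
the number of free epochs (1–6, contiguous groupings) is chosen by a 50/50
train/validation split of the site counts, taking the *smallest* epoch
count within 2 lnL units of the best held-out score — the SFS shape cannot
anchor the absolute size scale, and unpenalized extra epochs wander along
the size/time ridge.  Bootstrap spectra are refit with the chosen epoch
count to form median/75%/95% envelopes.  Only size *ratios* and relative
timings are well identified from a SNP-only SFS; absolute scaling requires
either a callable-site total (Watterson anchor with `mu` and `g`) or an
explicit reference size.

**Multi-population model fitting.**  The composite likelihood is
multinomial over segregating folded-SFS entries; the expected spectrum is
the Monte-Carlo branch-length SFS (10,000 genealogies per evaluation by
default — a desk-scale setting; production fits should raise it) under
common random numbers per optimization run, so the surface is smooth.
Optimization is cyclic coordinate-wise Brent line search (bounded, up to 50
cycles, stopping once a full cycle gains < 0.01 lnL), from independent
random starts, followed by a polish pass at 10× the simulation budget in a
narrowed bracket — this damps Monte-Carlo bias along weakly identified
directions.  Sizes and times are optimized in log10 space.  Empty expected
classes are floored at 1e-6 and renormalized.

The shrinkage models are parameterized by the split time `T` and the
cultivated *drift* `T / N_cult_present` rather than `(T, N)`: the
cultivated deme's differentiation is governed almost entirely by that
ratio, so these coordinates keep the likelihood ridge axis-aligned for the
coordinate search (the familiar `(T, N)` quantities and the fold-decline
are reported as derived values).  The three-clade model fits `T_old` and
the ratio `T_young/T_old` ∈ (0.2, 0.999).  Model comparison uses
`AIC = 2k − 2 lnL` and Akaike weights; note that under this standard
definition a model with extra parameters at equal likelihood has a
*higher* (worse) AIC.  Parametric bootstrap refits multinomial resamples
of the fitted spectrum, warm-started at the MLE.

## f-statistics and admixture graphs

Frequencies and copy counts per population feed f2/f3/f4/D estimators:
admixture-f3 subtracts the target's heterozygosity bias term
`c(1-c)/(k_c - 1)` (needed for unbiasedness at finite samples); outgroup-f3
is the plain ranking statistic; D uses the normalized ABBA–BABA form.
Standard errors are weighted delete-one-block jackknives (Busing's
formulas) over contiguous blocks of ~200 SNPs cut on stack boundaries — no
chromosome map exists for this genome, so stack order stands in for
physical order.  The f3 scan tests every target against every unordered
source pair, with one-sided p-values in the negative (admixture) direction
and Benjamini–Hochberg adjustment; "significant" means the adjusted p
corresponds to Z ≤ −1.96.

Admixture graphs use the linearized drift model: leaf frequencies are the
root frequency plus independent edge increments, admixture nodes mix
parental frequencies by their proportions, so
`f2(A,B) = sum_e d_e (w_A(e) − w_B(e))^2` with `w` the expected edge usage,
and f3/f4 follow by linear identities.  Fitting minimizes SE-weighted
squared residuals on the pairwise-f2 basis (box constraints: drifts ≥ 0,
proportions in (0,1); multi-start trust-region least squares); the fit is
then scored by residual Z over the *full* enumerated f2/f3/f4 basis, whose
SEs come from block-level f2 sums combined linearly (a block-diagonal
approximation to the joint jackknife covariance).  Identifiability is
probed by the rank of the prediction Jacobian; deficiencies (e.g. the two
root edges, which only ever appear summed) are warned about, not fatal.
The incremental search starts from the best four-leaf skeleton (first
population on the outgroup side), adds each remaining population to every
edge — and optionally as a two-parent admixture of every edge pair — and
keeps the minimal max|Z| solution, breaking ties by fewer admixture events
then lexicographic attachment.  Drift lengths are reported in
1000 × F_ST units.

## Outlier scans

**FLK** builds Reynolds distances, a neighbor-joining tree (midpoint- or
outgroup-rooted), and the kinship matrix F of shared root-to-leaf drift;
per locus `T = (p − p0·1)' V^{-1} (p − p0·1)` with
`V = p0(1−p0)(F + diag(1/k))` (the diagonal adds binomial sampling
variance) and `p0` the GLS ancestral-frequency estimate.  Because the
ascertained panel pins down F only up to scale, T is normalized so its
genome-wide *median* matches the chi-square(P−1) median — the robust analog
of the classical Lewontin–Krakauer use of realized F_ST — before p-values
are taken from chi-square(P−1).

**Fdist** matches a symmetric island model to the observed multi-locus
Weir–Cockerham F_ST (inverting Wright's `1/(1 + 4Nm(d/(d−1))^2)`, with one
feedback iteration because the inversion is approximate), simulates
neutral loci at the observed sample sizes with the same length-weighted
ascertainment, and scores each locus against simulated loci in its
expected-heterozygosity bin (20 quantile bins, widened below a 100-locus
floor).  The per-locus null is discrete at low minor-allele counts, so the
reported `p` is the mid-p and a seeded randomized `p_uniform` (exactly
uniform under the null) is provided for calibration checks.  Per-test
outliers are `q < 0.05` (Benjamini–Hochberg); the consensus is the
intersection across all supplied tests, which removes each test's private
false positives.

## Numerical and design choices

- All randomness flows from explicit integer seeds; pipeline stages derive
  seeds from one master seed via `SeedSequence`.
- Genotypes are int8 with −1 for missing; VCF I/O reads through cyvcf2 and
  writes minimal VCF v4.2 text with the stack id in CHROM.
- Recovery experiments in the test suite and acceptance script run at
  reduced scale (≈6,000–10,000 SNPs, 6,000–10,000 expected-SFS genealogies
  per likelihood evaluation, 2–3 optimizer starts, bootstrap replicate
  counts of 6–30); these sizes are the package's desk-scale defaults and
  give recovery accuracy of a few percent on split times.
- Known limitations: composite likelihood ignores within-stack linkage
  (SEs from it are optimistic; jackknife/bootstrap quantities use stacks as
  the unit instead); the admixture-graph drift model is the standard linear
  approximation, accurate for small drifts; stairway absolute scaling is
  external; Fdist's envelope resolution is bounded by the per-bin
  simulation count.
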