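"""Per-population diversity and between-population differentiation.

Nucleotide diversity is reported per variant site (GBS panels provide no
callable-sites denominator); expected and observed heterozygosity are both
emitted; multi-locus F_ST uses the Weir & Cockerham (1984) variance
components combined as a ratio of sums, with per-site values retained for
outlier diagnostics and negative components kept (not truncated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, SNPMatrix

__all__ = ["nucleotide_diversity", "heterozygosity", "expected_heterozygosity",
           "weir_cockerham_fst", "diversity_table"]


def nucleotide_diversity(m: SNPMatrix, pop: str) -> tuple[np.ndarray, float]:
    """Per-site pi and its mean over contributing sites for one population.

    Per site, pi = (k/(k-1)) * 2 p (1-p) with k observed allele copies and p
    the observed alternate-allele frequency — the average pairwise difference
    among the k copies.  Sites with k < 2 are NaN and excluded from the mean.
    """
    alt, k = m.allele_counts(pop)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k > 0, alt / np.maximum(k, 1), np.nan)
        pi = np.where(k >= 2, (k / np.maximum(k - 1, 1)) * 2 * p * (1 - p), np.nan)
    mean = float(np.nanmean(pi)) if np.isfinite(pi).any() else float("nan")
    return pi, mean


def heterozygosity(m: SNPMatrix) -> pd.Series:
    """Observed heterozygosity per accession: fraction of non-missing
    genotypes that are heterozygous.  Accessions with no genotyped sites get
    NaN with a warning."""
    obs = m.genotypes != MISSING
    n_obs = obs.sum(axis=1)
    het = (m.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_obs > 0, het / np.maximum(n_obs, 1), np.nan)
    if (n_obs == 0).any():
        bad = [a for a, n in zip(m.accession_ids, n_obs) if n == 0]
        warnings.warn(f"accessions with no genotyped sites: {bad}")
    return pd.Series(frac, index=m.accession_ids, name="observed_het")


def expected_heterozygosity(m: SNPMatrix, pop: str) -> float:
    """Mean unbiased expected heterozygosity 2p(1-p)k/(k-1) over variant
    sites with k >= 2 observed copies."""
    alt, k = m.allele_counts(pop)
    ok = k >= 2
    p = alt[ok] / k[ok]
    he = 2 * p * (1 - p) * k[ok] / (k[ok] - 1)
    return float(he.mean()) if len(he) else float("nan")


@dataclass
class FstResult:
    fst: float
    per_site: np.ndarray       # per-site a/(a+b+c), NaN where undefined
    components: np.ndarray     # (3, n_sites): a, b, c


def weir_cockerham_fst(m: SNPMatrix, pops: list[str]) -> FstResult:
    """Weir–Cockerham theta over >= 2 populations.

    Per-site variance components (a, b, c) follow the 1984 two-allele
    formulation with per-site sample sizes (missing genotypes reduce n_i);
    the multi-locus estimate is sum(a) / sum(a+b+c) over sites where every
    population has at least one genotyped diploid and total variance is
    non-zero.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    r = len(pops)
    n_i = np.empty((r, m.n_sites))
    p_i = np.empty((r, m.n_sites))
    h_i = np.empty((r, m.n_sites))
    for ix, pop in enumerate(pops):
        g = m.genotypes[m.accession_indices(pop)]
        obs = g != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = (g == 1).sum(axis=0) / np.maximum(n, 1)
        n_i[ix], p_i[ix], h_i[ix] = n, p, h
    ok = (n_i >= 1).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        cc = hbar / 2
    tot = a + b + cc
    ok &= np.isfinite(tot) & (np.abs(tot) > 0)
    per_site = np.full(m.n_sites, np.nan)
    per_site[ok] = a[ok] / tot[ok]
    fst = float(a[ok].sum() / tot[ok].sum()) if ok.any() else float("nan")
    comps = np.vstack([a, b, cc])
    comps[:, ~ok] = np.nan
    return FstResult(fst, per_site, comps)


def diversity_table(m: SNPMatrix, pops: list[str] | None = None) -> pd.DataFrame:
    """Per-population pi (mean and per-variant-site sum), expected and mean
    observed heterozygosity, plus pairwise multi-locus F_ST rows."""
    if pops is None:
        pops = m.populations()
    het = heterozygosity(m)
    rows = []
    for p in pops:
        pi, mean_pi = nucleotide_diversity(m, p)
        accs = [m.accession_ids[i] for i in m.accession_indices(p)]
        rows.append({
            "kind": "population", "population": p, "pi_mean": mean_pi,
            "pi_sum": float(np.nansum(pi)),
            "expected_het": expected_heterozygosity(m, p),
            "observed_het_mean": float(het.loc[accs].mean()),
        })
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            res = weir_cockerham_fst(m, [pops[i], pops[j]])
            rows.append({"kind": "pair",
                         "population": f"{pops[i]}~{pops[j]}",
                         "fst": res.fst})
    return pd.DataFrame(rows)
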