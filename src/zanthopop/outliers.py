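"""F_ST outlier detection: the FLK test and an Fdist-style simulation null,
combined by an all-tests consensus rule.

FLK extends the Lewontin–Krakauer test by modeling the covariance of
population allele frequencies with a kinship matrix derived from a
neighbor-joining tree of Reynolds distances: under neutrality

    T_FLK = (p - p0 1)' V^{-1} (p - p0 1),   V = p0 (1 - p0) F,

is approximately chi-square with (number of populations - 1) degrees of
freedom, with p0 the GLS estimate of the ancestral frequency.

The Fdist test matches a symmetric island model to the observed multi-locus
Weir–Cockerham F_ST, simulates neutral loci under it with the observed
sample sizes, and scores each observed locus against the simulated F_ST
distribution within its heterozygosity bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .fstats import FreqMatrix
from .genotype_io import SNPMatrix
from .popstats import weir_cockerham_fst
from .simulate import SimConfig, island_model, simulate_genotypes

__all__ = ["flk_test", "fdist_test", "consensus", "kinship_from_freqs",
           "reynolds_distance"]


def reynolds_distance(f: FreqMatrix) -> np.ndarray:
    """Pairwise Reynolds (1983) coancestry distance between populations,
    D = -ln(1 - theta) with theta estimated by ratio of sums over loci."""
    P = f.freqs.shape[0]
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            pa, pb = f.freqs[i], f.freqs[j]
            ka, kb = f.counts[i] / 2.0, f.counts[j] / 2.0  # diploid counts
            ok = (f.counts[i] >= 2) & (f.counts[j] >= 2)
            ok &= np.isfinite(pa) & np.isfinite(pb)
            a1, a2 = pa[ok], pb[ok]
            n1, n2 = ka[ok], kb[ok]
            # per-locus numerator/denominator of theta (Reynolds eq. for
            # biallelic loci, summed over the two alleles)
            sq = (a1 - a2) ** 2
            h1 = a1 * (1 - a1)
            h2 = a2 * (1 - a2)
            al = sq - (n1 + n2) * (n1 * h1 + n2 * h2) / (
                4 * n1 * n2 * (n1 + n2 - 1))
            albl = sq + (4 * n1 * n2 - n1 - n2) * (n1 * h1 + n2 * h2) / (
                4 * n1 * n2 * (n1 + n2 - 1))
            theta = al.sum() / albl.sum() if albl.sum() > 0 else 0.0
            theta = min(max(theta, 0.0), 0.999999)
            D[i, j] = D[j, i] = -np.log(1.0 - theta)
    return D


def kinship_from_freqs(f: FreqMatrix, outgroup: str | None = None) -> np.ndarray:
    """Kinship matrix F from a neighbor-joining tree of Reynolds distances.

    The tree is rooted at the outgroup when given, else at the midpoint;
    F_ij is the shared root-to-leaf path length of populations i and j,
    F_ii the total root-to-leaf length.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = reynolds_distance(f)
    dm = DistanceMatrix(D, ids=f.pops)
    tree = nj(dm)
    if outgroup is not None:
        tree = tree.root_at(tree.find(outgroup).parent)
    else:
        tree = tree.root_at_midpoint()
    P = len(f.pops)
    F = np.zeros((P, P))
    tips = {t.name: t for t in tree.tips()}
    # accumulate root-to-tip paths
    paths = {}
    for name, tip in tips.items():
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[name] = path
    for i, a in enumerate(f.pops):
        for j, b in enumerate(f.pops):
            if i == j:
                F[i, i] = sum(max(nd.length or 0.0, 0.0) for nd in paths[a])
            else:
                shared = set(id(nd) for nd in paths[a]) & set(
                    id(nd) for nd in paths[b])
                F[i, j] = sum(max(nd.length or 0.0, 0.0) for nd in paths[a]
                              if id(nd) in shared)
    return F


def flk_test(f: FreqMatrix, outgroup: str | None = None,
             q_threshold: float = 0.05,
             ridge: float = 1e-6) -> pd.DataFrame:
    """Per-locus FLK statistics, chi-square p-values and BH q-values.

    Needs at least three populations for a non-trivial kinship matrix.
    A singular covariance (e.g. duplicated populations) is ridge-
    regularized with a warning.
    """
    P = len(f.pops)
    if P < 3:
        raise ValueError("FLK needs at least three populations")
    F = kinship_from_freqs(f, outgroup)
    ones = np.ones(P)
    rows = []
    for s in range(f.freqs.shape[1]):
        p = f.freqs[:, s]
        k = f.counts[:, s]
        if not np.isfinite(p).all() or (k < 2).any():
            rows.append((np.nan, np.nan))
            continue
        # drift covariance plus binomial sampling variance of p-hat
        Fs = F + np.diag(1.0 / k)
        try:
            Finv = np.linalg.inv(Fs)
        except np.linalg.LinAlgError:
            warnings.warn("kinship matrix singular; ridge-regularizing")
            Finv = np.linalg.inv(Fs + ridge * np.eye(P))
        p0 = float(ones @ Finv @ p / (ones @ Finv @ ones))
        if p0 <= 0.0 or p0 >= 1.0:
            rows.append((0.0, 1.0))
            continue
        d = p - p0
        t = float(d @ Finv @ d / (p0 * (1 - p0)))
        rows.append((t, np.nan))
    df = pd.DataFrame(rows, columns=["flk", "p"])
    # self-calibrate against the realized genome-wide dispersion (the FLK
    # chi-square approximation holds up to the overall scale of F, which the
    # ascertained SNP panel does not pin down): normalize so the genome
    # median of T matches the chi-square median, robustly to outliers
    finite = df["flk"].notna()
    med = float(np.nanmedian(df.loc[finite, "flk"]))
    if med > 0:
        df.loc[finite, "flk"] *= chi2.median(P - 1) / med
    df.loc[finite, "p"] = chi2.sf(df.loc[finite, "flk"], P - 1)
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        _, qv, _, _ = multipletests(df.loc[ok, "p"], method="fdr_bh")
        q[ok.to_numpy()] = qv
    df["q"] = q
    df["outlier"] = df["q"] < q_threshold
    return df


def _island_nm_for_fst(fst: float, n_demes: int) -> float:
    """Invert Wright's island-model expectation
    F_ST = 1 / (1 + 4 N m (d/(d-1))^2) for the scaled migration rate Nm."""
    fst = min(max(fst, 1e-4), 0.99)
    corr = (n_demes / (n_demes - 1.0)) ** 2
    return (1.0 / fst - 1.0) / (4.0 * corr)


def fdist_test(m: SNPMatrix, pops: list[str], n_sim_loci: int = 20_000,
               seed: int = 0, q_threshold: float = 0.05, n_bins: int = 20,
               min_bin: int = 100) -> pd.DataFrame:
    """Fdist-style outlier scan against a simulated island-model null.

    The neutral F_ST is estimated from the data; neutral loci are simulated
    under a symmetric island model matched to it (observed sample sizes,
    simulator deme size 5,000 diploids); each observed locus is scored as
    the proportion of simulated loci in its expected-heterozygosity bin
    with F_ST at or above the observed value.
    """
    if len(pops) < 2:
        raise ValueError("Fdist needs at least two populations")
    obs_fst = weir_cockerham_fst(m, pops)
    nm = _island_nm_for_fst(obs_fst.fst, len(pops))
    n_island = 5000.0
    samples = {p: len(m.accession_indices(p)) for p in pops}
    # simulate the island-model null; one calibration pass corrects Wright's
    # approximate Nm inversion so the realized multi-locus F_ST matches the
    # observed one.  Length-weighted tree resampling (the default) keeps the
    # same segregating-site ascertainment as mutation-driven SNP discovery.
    sim = sim_fst = None
    for attempt in range(2):
        demo = island_model(len(pops), n_island, nm / n_island,
                            labels=list(pops))
        sim = simulate_genotypes(
            demo, SimConfig(n_loci=n_sim_loci, samples_per_deme=samples,
                            seed=(int(seed) + attempt) % (2**31 - 1)))
        sim_fst = weir_cockerham_fst(sim, pops)
        ratio = ((1.0 / max(obs_fst.fst, 1e-4) - 1.0)
                 / (1.0 / max(sim_fst.fst, 1e-4) - 1.0))
        if 0.9 < ratio < 1.1:
            break
        nm = nm * ratio
    sim_het = _mean_het(sim, pops)
    obs_het = _mean_het(m, pops)
    ok_sim = np.isfinite(sim_fst.per_site) & np.isfinite(sim_het)
    sim_f, sim_h = sim_fst.per_site[ok_sim], sim_het[ok_sim]
    edges = np.quantile(sim_h, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    rng = np.random.default_rng(int(seed) + 1)
    rows = []
    for s in range(m.n_sites):
        fobs, hobs = obs_fst.per_site[s], obs_het[s]
        if not (np.isfinite(fobs) and np.isfinite(hobs)):
            rows.append((fobs, hobs, np.nan, np.nan))
            continue
        b = int(np.searchsorted(edges, hobs, side="right") - 1)
        b = min(max(b, 0), n_bins - 1)
        sel = (sim_h >= edges[b]) & (sim_h < edges[b + 1])
        lo, hi = b, b + 1
        while sel.sum() < min_bin and (lo > 0 or hi < n_bins):
            lo, hi = max(lo - 1, 0), min(hi + 1, n_bins)
            sel = (sim_h >= edges[lo]) & (sim_h < edges[hi])
            if lo == 0 and hi == n_bins:
                break
        if sel.sum() < min_bin:
            warnings.warn("Fdist: widened heterozygosity bin below floor")
        if not sel.any():
            rows.append((fobs, hobs, np.nan, np.nan))
            continue
        # the per-locus F_ST null is discrete at low minor-allele counts, so
        # the plain exceedance proportion is super-uniform; report the mid-p
        # and a seeded randomized p (exactly uniform under the null)
        vals = sim_f[sel]
        n_gt = int((vals > fobs + 1e-12).sum())
        n_eq = int((np.abs(vals - fobs) <= 1e-12).sum())
        n_tot_bin = int(sel.sum())
        mid = (n_gt + 0.5 * n_eq) / n_tot_bin
        rnd = (n_gt + rng.random() * n_eq) / n_tot_bin
        rows.append((fobs, hobs, mid, rnd))
    df = pd.DataFrame(rows, columns=["fst", "het", "p", "p_uniform"])
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        _, qv, _, _ = multipletests(df.loc[ok, "p"], method="fdr_bh")
        q[ok.to_numpy()] = qv
    df["q"] = q
    df["outlier"] = df["q"] < q_threshold
    return df


def _mean_het(m: SNPMatrix, pops: list[str]) -> np.ndarray:
    """Per-site expected heterozygosity averaged over populations."""
    hs = []
    for p in pops:
        alt, k = m.allele_counts(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            pf = np.where(k > 0, alt / np.maximum(k, 1), np.nan)
            hs.append(np.where(k >= 2, 2 * pf * (1 - pf)
                               * k / np.maximum(k - 1, 1), np.nan))
    return np.nanmean(np.vstack(hs), axis=0)


def consensus(flags: list[np.ndarray]) -> np.ndarray:
    """Intersection of per-test outlier flags over aligned loci (a locus is
    a consensus outlier only if every supplied test flags it)."""
    if not flags:
        raise ValueError("need at least one test result")
    lengths = {len(fl) for fl in flags}
    if len(lengths) != 1:
        raise ValueError("misaligned locus sets across tests")
    out = np.ones(lengths.pop(), dtype=bool)
    for fl in flags:
        out &= np.asarray(fl, dtype=bool)
    return out
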