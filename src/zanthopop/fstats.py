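"""Allele-frequency f-statistics (f2, admixture-f3, outgroup-f3, D/f4) with
block-jackknife standard errors and FDR-adjusted scans.

Statistics are computed from a :class:`FreqMatrix` (per-population allele
frequencies with observed allele-copy counts).  Because no chromosome map
exists for this non-model genome, jackknife blocks default to contiguous
runs of ~200 SNPs in stack order, always cutting on stack boundaries.
Admixture-f3 subtracts the target's sampling-heterozygosity bias term
(needed for unbiasedness at finite sample size); outgroup-f3 is the plain
uncorrected ranking statistic.  Standard errors use the weighted (Busing)
delete-one-block jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, SNPMatrix

__all__ = ["FreqMatrix", "FStatResult", "block_jackknife", "f2", "f3",
           "outgroup_f3", "d_stat", "f4", "f3_scan"]


@dataclass
class FreqMatrix:
    """Populations x sites allele frequencies with per-site copy counts and
    jackknife block ids (contiguous in site order)."""

    freqs: np.ndarray    # (P, S) alternate-allele frequency, NaN if k < 1
    counts: np.ndarray   # (P, S) observed allele copies
    pops: list[str]
    block_ids: np.ndarray  # (S,) int

    def __post_init__(self) -> None:
        if self.freqs.shape != self.counts.shape:
            raise ValueError("freqs/counts shape mismatch")
        if len(self.pops) != self.freqs.shape[0]:
            raise ValueError("pops length mismatch")
        if self.block_ids.shape != (self.freqs.shape[1],):
            raise ValueError("block_ids length mismatch")
        d = np.diff(self.block_ids)
        if (d < 0).any():
            raise ValueError("block_ids must be non-decreasing in site order")

    @classmethod
    def from_snp_matrix(cls, m: SNPMatrix, pops: list[str] | None = None,
                        block_size: int = 200) -> "FreqMatrix":
        if pops is None:
            pops = m.populations()
        P, S = len(pops), m.n_sites
        freqs = np.full((P, S), np.nan)
        counts = np.zeros((P, S), dtype=np.int64)
        for i, p in enumerate(pops):
            alt, k = m.allele_counts(p)
            counts[i] = k
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs[i] = np.where(k > 0, alt / np.maximum(k, 1), np.nan)
        # contiguous whole-stack blocks of ~block_size SNPs
        block_ids = np.zeros(S, dtype=np.int64)
        stacks = m.stack_ids
        cur_block, in_block = 0, 0
        prev = None
        for s in range(S):
            if prev is not None and stacks[s] != prev and in_block >= block_size:
                cur_block += 1
                in_block = 0
            block_ids[s] = cur_block
            in_block += 1
            prev = stacks[s]
        return cls(freqs, counts, list(pops), block_ids)

    def index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass
class FStatResult:
    statistic: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_sites: int
    p: float | None = None
    q: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be non-negative")


def block_jackknife(num: np.ndarray, den: np.ndarray,
                    block_ids: np.ndarray) -> tuple[float, float]:
    """Delete-one-block jackknife for a ratio statistic sum(num)/sum(den).

    Uses the weighted jackknife (Busing et al. 1999) with block weights
    m_j = per-block sum of ``den``; returns (estimate, SE).  Requires at
    least two non-empty blocks.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    ids = np.unique(block_ids)
    bn = np.array([num[block_ids == b].sum() for b in ids])
    bd = np.array([den[block_ids == b].sum() for b in ids])
    nonempty = bd > 0
    bn, bd = bn[nonempty], bd[nonempty]
    G = len(bn)
    if G < 2:
        raise ValueError("block jackknife needs at least two non-empty blocks")
    tot_n, tot_d = bn.sum(), bd.sum()
    theta = tot_n / tot_d
    theta_j = (tot_n - bn) / (tot_d - bd)
    h = tot_d / bd
    ps = G * theta - np.sum((1.0 - bd / tot_d) * theta_j)
    var = np.mean((h * theta - (h - 1.0) * theta_j - ps) ** 2 / (h - 1.0))
    return float(theta), float(np.sqrt(max(var, 0.0)))


def _usable(f: FreqMatrix, idx: list[int], min_copies: int = 2) -> np.ndarray:
    ok = np.ones(f.freqs.shape[1], dtype=bool)
    for i in idx:
        ok &= f.counts[i] >= min_copies
        ok &= np.isfinite(f.freqs[i])
    return ok


def _ratio_result(stat: str, pops: tuple[str, ...], num: np.ndarray,
                  den: np.ndarray, ok: np.ndarray,
                  block_ids: np.ndarray) -> FStatResult:
    if ok.sum() == 0:
        raise ValueError(f"no informative sites for {stat}{pops}")
    est, se = block_jackknife(num[ok], den[ok], block_ids[ok])
    z = est / se if se > 0 else float("inf") * np.sign(est or 1.0)
    return FStatResult(stat, pops, est, se, float(z), int(ok.sum()))


def f2(a: str, b: str, f: FreqMatrix) -> FStatResult:
    """Unbiased f2(A,B) = (pA - pB)^2 - hA/kA - hB/kB averaged over sites."""
    ia, ib = f.index(a), f.index(b)
    ok = _usable(f, [ia, ib])
    pa, pb = f.freqs[ia], f.freqs[ib]
    ka, kb = f.counts[ia], f.counts[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        ha = pa * (1 - pa) / np.maximum(ka - 1, 1)
        hb = pb * (1 - pb) / np.maximum(kb - 1, 1)
        num = (pa - pb) ** 2 - ha - hb
    return _ratio_result("f2", (a, b), num, np.ones_like(num), ok, f.block_ids)


def f3(target: str, a: str, b: str, f: FreqMatrix,
       corrected: bool = True) -> FStatResult:
    """Admixture f3(target; a, b): mean of (c-a)(c-b), with the target's
    sampling-heterozygosity bias term c(1-c)/(k_c - 1) subtracted when
    ``corrected``.  Significantly negative values signal admixture."""
    if target in (a, b):
        raise ValueError("target must differ from both source populations")
    it, ia, ib = f.index(target), f.index(a), f.index(b)
    ok = _usable(f, [it, ia, ib])
    c, pa, pb = f.freqs[it], f.freqs[ia], f.freqs[ib]
    kc = f.counts[it]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (c - pa) * (c - pb)
        if corrected:
            num = num - c * (1 - c) / np.maximum(kc - 1, 1)
    return _ratio_result("f3", (target, a, b), num, np.ones_like(num), ok,
                         f.block_ids)


def outgroup_f3(outgroup: str, x: str, y: str, f: FreqMatrix) -> FStatResult:
    """Outgroup-f3: shared drift of x and y relative to the outgroup
    (uncorrected ranking statistic; larger = closer)."""
    res = f3(outgroup, x, y, f, corrected=False)
    return FStatResult("outgroup_f3", (outgroup, x, y), res.estimate, res.se,
                       res.z, res.n_sites)


def f4(w: str, x: str, y: str, z: str, f: FreqMatrix) -> FStatResult:
    """f4(W,X;Y,Z) = mean of (w-x)(y-z)."""
    iw, ix, iy, iz = (f.index(p) for p in (w, x, y, z))
    ok = _usable(f, [iw, ix, iy, iz])
    num = (f.freqs[iw] - f.freqs[ix]) * (f.freqs[iy] - f.freqs[iz])
    return _ratio_result("f4", (w, x, y, z), num, np.ones_like(num), ok,
                         f.block_ids)


def d_stat(w: str, x: str, y: str, z: str, f: FreqMatrix) -> FStatResult:
    """Normalized D (ABBA-BABA): sum (w-x)(y-z) / sum (w+x-2wx)(y+z-2yz)."""
    if len({w, x, y, z}) != 4:
        raise ValueError("D-statistic needs four distinct populations")
    iw, ix, iy, iz = (f.index(p) for p in (w, x, y, z))
    ok = _usable(f, [iw, ix, iy, iz])
    pw, px, py, pz = (f.freqs[i] for i in (iw, ix, iy, iz))
    num = (pw - px) * (py - pz)
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
    if not np.nansum(np.abs(den[ok])) > 0:
        raise ValueError("no informative sites: D denominator vanishes")
    return _ratio_result("D", (w, x, y, z), num, den, ok, f.block_ids)


def f3_scan(f: FreqMatrix, targets: list[str] | None = None,
            z_threshold: float = 1.96) -> pd.DataFrame:
    """All admixture-f3 tests (every target against every unordered source
    pair), with one-sided p-values for the negative (admixture) direction
    and Benjamini-Hochberg adjustment across the scan.

    A test is flagged significant when its adjusted p corresponds to a
    Z-score at or beyond -``z_threshold``.
    """
    if len(f.pops) < 3:
        raise ValueError("f3 scan needs at least three populations")
    targets = targets if targets is not None else list(f.pops)
    rows = []
    for t in targets:
        for a, b in combinations([p for p in f.pops if p != t], 2):
            r = f3(t, a, b, f)
            rows.append({"target": t, "source_a": a, "source_b": b,
                         "f3": r.estimate, "se": r.se, "z": r.z,
                         "n_sites": r.n_sites,
                         "p": float(norm.cdf(r.z))})
    df = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(df["p"], alpha=float(norm.cdf(-z_threshold)),
                                 method="fdr_bh")
    df["q"] = q
    df["adjusted_z"] = norm.ppf(np.clip(q, 1e-300, 1 - 1e-16))
    df["significant"] = rej
    return df
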