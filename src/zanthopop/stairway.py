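"""Stairway-style single-population Ne(t) inference from the folded SFS.

The expected folded SFS under piecewise-constant Ne is computed exactly:
the ancestral-lineage count process is a pure-death chain whose occupancy
times per epoch follow from matrix exponentials of the (bidiagonal)
transient rate matrix, and the expected count of sites with i derived
copies is E[xi_i] = sum_k k E[T_k] p_{n,k}(i) with the classical
combinatorial weights p_{n,k}(i) = C(n-i-1, k-2) / C(n-1, k-1).

The fit maximizes the multinomial composite likelihood of the folded SFS
over per-epoch sizes on a fixed logarithmic time grid; the number of free
epochs (contiguous groupings of grid intervals) is chosen by a
train/validation split of the site counts.  Bootstrap spectra are refit to
form median / 75% / 95% envelopes, and times/sizes are rescaled to years
via the generation time.  Because a SNP-only panel carries no callable-site
total, the absolute scale is anchored either by a Watterson estimate (when
``total_sites`` is supplied along with the mutation rate) or by an explicit
reference size ``n_ref``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize


from .sfs import FoldedSFS

__all__ = ["StairwayConfig", "NeTrajectory", "expected_folded_sfs_piecewise",
           "fit_stairway"]

GENERATION_TIME = 4.0
MUTATION_RATE_PER_YEAR = 2.6e-9


def _pnk_matrix(n: int) -> np.ndarray:
    """p[k, i] = P(a given one of k ancestral lineages subtends i of n leaves)
    for k = 2..n, i = 1..n-1 (zero elsewhere)."""
    p = np.zeros((n + 1, n))
    for k in range(2, n + 1):
        for i in range(1, n - k + 2):
            p[k, i] = np.exp(
                _log_comb(n - i - 1, k - 2) - _log_comb(n - 1, k - 1))
    return p


def _log_comb(n: int, k: int) -> float:
    from math import lgamma
    if k < 0 or k > n:
        return -np.inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _occupancy_times(n: int, breakpoints: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """E[time spent with k ancestral lineages], k = 2..n, under piecewise-
    constant diploid sizes.  ``breakpoints`` are epoch start times (first 0),
    ``sizes`` the size within each epoch (last extends to infinity)."""
    ks = np.arange(n, 1, -1)          # states n, n-1, ..., 2
    nstate = len(ks)
    rates = ks * (ks - 1) / 2.0       # per unit of 2N-scaled ... in gens: /(2N)
    T = np.zeros(nstate)
    v = np.zeros(nstate)
    v[0] = 1.0                        # all n lineages at time 0
    for e, N in enumerate(sizes):
        lam = rates / (2.0 * N)       # per-generation leaving rates
        Q = np.diag(-lam)
        for s in range(nstate - 1):
            Q[s, s + 1] = lam[s]
        if e < len(sizes) - 1:
            tau = breakpoints[e + 1] - breakpoints[e]
            P = expm(Q * tau)
            # integral of v expm(Qt) dt over [0, tau]
            occ = np.linalg.solve(Q.T, (P.T - np.eye(nstate)) @ v)
            v = P.T @ v
        else:
            occ = np.linalg.solve(-Q.T, v)
        T += occ
    out = np.zeros(n + 1)
    out[ks] = T
    return out


def expected_folded_sfs_piecewise(breakpoints: np.ndarray, sizes: np.ndarray,
                                  n: int) -> np.ndarray:
    """Expected folded SFS (probabilities over classes 1..n//2) for a sample
    of ``n`` haploid lineages under piecewise-constant diploid Ne.

    ``breakpoints`` must start at 0 and be strictly increasing; ``sizes``
    has one entry per epoch (the last lasting forever).  With a single
    epoch this reduces to the standard-coalescent 1/i + 1/(n-i) form.
    """
    breakpoints = np.asarray(breakpoints, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) != len(breakpoints):
        raise ValueError("need one size per epoch")
    if breakpoints[0] != 0 or np.any(np.diff(breakpoints) <= 0):
        raise ValueError("breakpoints must start at 0 and increase strictly")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    if n < 4:
        raise ValueError("need a haploid sample size of at least 4")
    occ = _occupancy_times(n, breakpoints, sizes)
    p = _pnk_matrix(n)
    xi = np.zeros(n)
    for i in range(1, n):
        xi[i] = float(np.sum(np.arange(n + 1) * occ * p[:, i]))
    folded = np.zeros(n // 2 + 1)
    for i in range(1, n):
        j = min(i, n - i)
        folded[j] += xi[i] if (2 * i != n) else 0.0
    if n % 2 == 0:
        folded[n // 2] += xi[n // 2]
    return folded[: n // 2 + 1] / folded.sum()


@dataclass
class StairwayConfig:
    mu: float = MUTATION_RATE_PER_YEAR          # per site per year
    gen_time: float = GENERATION_TIME           # years
    total_sites: int | None = None              # callable sites for Watterson anchor
    n_ref: float | None = None                  # explicit anchor (diploids)
    n_grid: int = 12
    t_min_coal: float = 0.02                    # grid span, units of 2 N_ref gens
    t_max_coal: float = 8.0
    candidate_epochs: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    val_fraction: float = 0.5
    seed: int = 0
    size_bounds_log10: tuple[float, float] = (-2.5, 2.5)  # around N_ref


@dataclass
class NeTrajectory:
    """Piecewise-constant Ne(t): epoch start times (generations, ascending)
    with per-epoch point estimates and bootstrap envelopes."""

    breakpoints: np.ndarray
    sizes: np.ndarray
    median: np.ndarray | None = None
    ci75: tuple[np.ndarray, np.ndarray] | None = None
    ci95: tuple[np.ndarray, np.ndarray] | None = None
    gen_time: float = GENERATION_TIME
    mu: float = MUTATION_RATE_PER_YEAR
    n_epochs_free: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.sizes <= 0):
            raise ValueError("sizes must be positive")

    @property
    def times_years(self) -> np.ndarray:
        return self.breakpoints * self.gen_time

    def size_at(self, t_gens: float, which: str = "point") -> float:
        arr = {"point": self.sizes, "median": self.median}[which]
        e = int(np.searchsorted(self.breakpoints, t_gens, side="right") - 1)
        return float(arr[max(e, 0)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {"time_years": self.times_years, "ne": self.sizes}
        if self.median is not None:
            cols["ne_median"] = self.median
        if self.ci75 is not None:
            cols["ne_lo75"], cols["ne_hi75"] = self.ci75
        if self.ci95 is not None:
            cols["ne_lo95"], cols["ne_hi95"] = self.ci95
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _group_sizes(n_grid: int, n_epochs: int) -> list[np.ndarray]:
    """Contiguous grouping of grid intervals into n_epochs blocks (as equal
    as possible)."""
    edges = np.linspace(0, n_grid, n_epochs + 1).round().astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_epochs)]


def _fit_sizes(counts: np.ndarray, n: int, breakpoints: np.ndarray,
               groups: list[np.ndarray], n_ref: float,
               bounds: tuple[float, float], x0: np.ndarray | None = None):
    """Maximize the multinomial lnL over per-group log10(N / N_ref)."""
    def expand(x):
        sizes = np.empty(len(breakpoints))
        for g, xi in zip(groups, x):
            sizes[g] = n_ref * 10.0 ** xi
        return sizes

    def nll(x):
        q = expected_folded_sfs_piecewise(breakpoints, expand(x), n)[1:]
        q = np.maximum(q, 1e-12)
        q = q / q.sum()
        return -float(np.dot(counts[1:], np.log(q)))

    if x0 is None:
        x0 = np.zeros(len(groups))
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[bounds] * len(groups))
    return expand(res.x), -res.fun, res.x


def fit_stairway(sfs: FoldedSFS, bootstraps: list[FoldedSFS] | None = None,
                 config: StairwayConfig | None = None) -> NeTrajectory:
    """Fit a piecewise-constant Ne trajectory to a 1-D folded SFS.

    The number of free epochs is chosen by splitting the site counts into
    train/validation halves (multinomial thinning) and scoring each
    candidate on the held-out half; bootstrap spectra are refit with the
    chosen epoch count to form the envelopes.
    """
    config = config or StairwayConfig()
    if sfs.ndim_pops != 1:
        raise ValueError("stairway fitting needs a 1-D folded SFS")
    n = sfs.sample_sizes[0]
    if n < 4:
        raise ValueError("need n >= 4 haploid samples")
    counts = sfs.counts.ravel()[: n // 2 + 1].copy()
    counts[0] = 0.0
    if (counts > 0).sum() < 2:
        raise ValueError("degenerate SFS: all mass in one class")
    s_total = counts.sum()
    if config.n_ref is not None:
        n_ref = float(config.n_ref)
    elif config.total_sites:
        a_n = np.sum(1.0 / np.arange(1, n))
        theta_w = s_total / (config.total_sites * a_n)
        n_ref = theta_w / (4.0 * config.mu * config.gen_time)
    else:
        raise ValueError("supply total_sites (Watterson anchor) or n_ref")

    grid = np.concatenate(
        ([0.0], np.geomspace(config.t_min_coal, config.t_max_coal,
                             config.n_grid - 1) * 2.0 * n_ref))
    rng = np.random.default_rng(config.seed)
    train = rng.binomial(counts.astype(int), config.val_fraction).astype(float)
    val = counts - train
    scores: dict[int, float] = {}
    for k in config.candidate_epochs:
        groups = _group_sizes(config.n_grid, k)
        sizes, _, _ = _fit_sizes(train, n, grid, groups, n_ref,
                                 config.size_bounds_log10)
        q = expected_folded_sfs_piecewise(grid, sizes, n)[1:]
        q = np.maximum(q, 1e-12)
        q /= q.sum()
        scores[k] = float(np.dot(val[1:], np.log(q)))
    best_score = max(scores.values())
    # parsimony: smallest epoch count within 2 lnL units of the best
    # held-out score (the SFS shape cannot anchor the absolute scale, so
    # unneeded epochs wander along the size/time ridge)
    best_k = min(k for k, s in scores.items() if s >= best_score - 2.0)
    groups = _group_sizes(config.n_grid, best_k)
    sizes, _, xhat = _fit_sizes(counts, n, grid, groups, n_ref,
                                config.size_bounds_log10)
    boot_sizes = []
    for b in bootstraps or []:
        bc = b.counts.ravel()[: n // 2 + 1].copy()
        bc[0] = 0.0
        bsizes, _, _ = _fit_sizes(bc, n, grid, groups, n_ref,
                                  config.size_bounds_log10, x0=xhat)
        boot_sizes.append(bsizes)
    med = ci75 = ci95 = None
    if boot_sizes:
        arr = np.vstack(boot_sizes)
        med = np.median(arr, axis=0)
        ci75 = (np.quantile(arr, 0.125, axis=0), np.quantile(arr, 0.875, axis=0))
        ci95 = (np.quantile(arr, 0.025, axis=0), np.quantile(arr, 0.975, axis=0))
    return NeTrajectory(grid, sizes, med, ci75, ci95, config.gen_time,
                        config.mu, n_epochs_free=best_k)
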