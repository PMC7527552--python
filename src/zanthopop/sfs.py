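"""Folded site-frequency spectra (1-D and joint) with hypergeometric
projection for missing data, plus stack-level bootstrap resampling.

Joint spectra are folded over the *pooled* (global) minor allele: the cell
``c`` (per-population derived counts) and its complement ``n - c`` are merged
onto a canonical representative.  Cells whose pooled count equals exactly
half the pooled sample size are counted once (the lexicographically smaller
member of the pair is the representative).  Projection to smaller sample
sizes distributes each site's mass by the hypergeometric distribution, which
keeps the spectrum deterministic in the presence of missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import hypergeom

from .genotype_io import MISSING, SNPMatrix

__all__ = ["FoldedSFS", "fold_joint", "folded_sfs", "bootstrap_sfs",
           "write_sfs", "read_sfs"]


def _canonical_maps(sample_sizes: tuple[int, ...]):
    """Flat index maps implementing global-minor folding.

    Returns (fold_to, canon_mask): ``fold_to[i]`` is the flat canonical cell
    receiving cell i's mass; ``canon_mask`` flags canonical cells.
    """
    dims = tuple(n + 1 for n in sample_sizes)
    n_tot = sum(sample_sizes)
    size = int(np.prod(dims))
    fold_to = np.empty(size, dtype=np.int64)
    canon = np.zeros(size, dtype=bool)
    for i, c in enumerate(product(*[range(d) for d in dims])):
        comp = tuple(n - x for n, x in zip(sample_sizes, c))
        tot = sum(c)
        if 2 * tot < n_tot or (2 * tot == n_tot and c <= comp):
            canon[i] = True
            fold_to[i] = i
        else:
            fold_to[i] = np.ravel_multi_index(comp, dims)
    return fold_to, canon


@dataclass
class FoldedSFS:
    """A folded (1-D or joint) site-frequency spectrum.

    ``counts`` has shape ``(n_1+1, ..., n_P+1)`` with all mass on canonical
    (minor-allele) cells; non-canonical cells are zero.  The monomorphic cell
    (all zeros after folding) is recorded but excluded from likelihoods.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, ...]
    pop_labels: tuple[str, ...] = ()
    n_sites_used: float = 0.0
    is_probability: bool = False
    _canon: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        if self.counts.shape != tuple(n + 1 for n in self.sample_sizes):
            raise ValueError("counts shape inconsistent with sample_sizes")
        if (self.counts < -1e-9).any():
            raise ValueError("negative SFS entries")
        if not self.pop_labels:
            self.pop_labels = tuple(f"pop{i}" for i in range(len(self.sample_sizes)))
        _, canon = _canonical_maps(self.sample_sizes)
        self._canon = canon

    @property
    def ndim_pops(self) -> int:
        return len(self.sample_sizes)

    def segregating_mask(self) -> np.ndarray:
        """Boolean flat mask of canonical, segregating (pooled count > 0) cells."""
        mask = self._canon.copy()
        mask[0] = False  # pooled-monomorphic cell folds to the origin
        return mask

    def segregating_values(self) -> np.ndarray:
        return self.counts.ravel()[self.segregating_mask()]

    def normalized(self) -> "FoldedSFS":
        """Probability version: mass over segregating cells sums to one."""
        flat = self.counts.ravel().copy()
        mask = self.segregating_mask()
        tot = flat[mask].sum()
        if tot <= 0:
            raise ValueError("SFS has no segregating mass")
        out = np.zeros_like(flat)
        out[mask] = flat[mask] / tot
        return FoldedSFS(out.reshape(self.counts.shape), self.sample_sizes,
                         self.pop_labels, self.n_sites_used, True)

    def marginalize(self, pop: int) -> "FoldedSFS":
        """1-D folded SFS of population ``pop`` obtained by summing out the
        others (then re-folding, since pooled-minor folding is not closed
        under marginalization)."""
        axes = tuple(i for i in range(self.ndim_pops) if i != pop)
        unf = _unfold(self.counts, self.sample_sizes)
        marg = unf.sum(axis=axes)
        folded = fold_joint(marg, (self.sample_sizes[pop],))
        return FoldedSFS(folded, (self.sample_sizes[pop],),
                         (self.pop_labels[pop],), self.n_sites_used,
                         self.is_probability)


def _unfold(folded: np.ndarray, sample_sizes: tuple[int, ...]) -> np.ndarray:
    """Spread folded mass evenly over each cell/complement pair (used only
    for marginalization, where the split cancels in expectation)."""
    dims = tuple(n + 1 for n in sample_sizes)
    fold_to, canon = _canonical_maps(sample_sizes)
    flat = folded.ravel()
    out = np.zeros_like(flat)
    for i in range(flat.size):
        j = fold_to[i]
        if i == j:
            comp_idx = np.ravel_multi_index(
                tuple(n - x for n, x in zip(sample_sizes,
                                            np.unravel_index(i, dims))), dims)
            if comp_idx == i:
                out[i] += flat[i]
            else:
                out[i] += flat[i] / 2
                out[comp_idx] += flat[i] / 2
    return out.reshape(dims)


def fold_joint(unfolded: np.ndarray, sample_sizes: tuple[int, ...]) -> np.ndarray:
    """Fold an unfolded joint spectrum over the pooled minor allele."""
    dims = tuple(n + 1 for n in sample_sizes)
    if unfolded.shape != dims:
        raise ValueError("array shape inconsistent with sample sizes")
    fold_to, _ = _canonical_maps(sample_sizes)
    out = np.zeros(unfolded.size)
    np.add.at(out, fold_to, unfolded.ravel())
    return out.reshape(dims)


def _site_mass(alt: int, copies: int, proj: int, cache: dict) -> np.ndarray:
    """Hypergeometric projection mass over 0..proj derived copies."""
    key = (alt, copies, proj)
    got = cache.get(key)
    if got is None:
        if copies == proj:
            got = np.zeros(proj + 1)
            got[alt] = 1.0
        else:
            j = np.arange(proj + 1)
            got = hypergeom.pmf(j, copies, alt, proj)
        cache[key] = got
    return got


def folded_sfs(m: SNPMatrix, pops: list[str],
               projections: list[int] | None = None) -> FoldedSFS:
    """Build the joint folded SFS for ``pops`` from a genotype matrix.

    ``projections`` are haploid sample sizes per population (default: the
    full 2 x diploid count).  Sites with fewer observed allele copies than
    the projection in any population are skipped; sites with more are
    down-projected hypergeometrically.
    """
    if not pops:
        raise ValueError("need at least one population")
    alt_obs = []
    cop_obs = []
    for p in pops:
        a, k = m.allele_counts(p)
        alt_obs.append(a)
        cop_obs.append(k)
    full = [2 * len(m.accession_indices(p)) for p in pops]
    if projections is None:
        projections = full
    projections = [int(x) for x in projections]
    for p, n_p, f in zip(pops, projections, full):
        if n_p <= 0:
            raise ValueError(f"projection for {p} must be positive")
        if n_p > f:
            raise ValueError(f"projection {n_p} exceeds 2 x diploids ({f}) for {p}")
    dims = tuple(n + 1 for n in projections)
    unfolded = np.zeros(dims)
    cache: dict = {}
    usable = np.ones(m.n_sites, dtype=bool)
    for k, n_p in zip(cop_obs, projections):
        usable &= k >= n_p
    n_used = 0
    for s in np.flatnonzero(usable):
        mass = _site_mass(int(alt_obs[0][s]), int(cop_obs[0][s]),
                          projections[0], cache)
        for d in range(1, len(pops)):
            mass = np.multiply.outer(
                mass, _site_mass(int(alt_obs[d][s]), int(cop_obs[d][s]),
                                 projections[d], cache))
        unfolded += mass
        n_used += 1
    return FoldedSFS(fold_joint(unfolded, tuple(projections)),
                     tuple(projections), tuple(pops), float(n_used))


def bootstrap_sfs(m: SNPMatrix, pops: list[str],
                  projections: list[int] | None, n_reps: int,
                  seed: int, _identity: bool = False) -> list[FoldedSFS]:
    """Bootstrap the folded SFS by resampling stacks with replacement.

    Stacks (GBS loci) are the exchangeable unit so within-stack linkage is
    respected.  ``_identity`` is a test hook forcing each replicate to equal
    the original stack multiset.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    stacks = m.stack_ids
    uniq = list(dict.fromkeys(stacks))
    by_stack = {s: np.flatnonzero(stacks == s) for s in uniq}
    out = []
    for _ in range(n_reps):
        if _identity:
            chosen = np.arange(len(uniq))
        else:
            chosen = rng.integers(len(uniq), size=len(uniq))
        idx = np.concatenate([by_stack[uniq[c]] for c in chosen])
        out.append(folded_sfs(m.take_sites(idx), pops, projections))
    return out


def write_sfs(sfs: FoldedSFS, path) -> None:
    """Serialize in a dadi/fastsimcoal-style flat text format."""
    with open(path, "w") as fh:
        fh.write("# zanthopop folded SFS\n")
        fh.write(" ".join(str(n + 1) for n in sfs.sample_sizes) + " folded\n")
        fh.write("# pops: " + " ".join(sfs.pop_labels) + "\n")
        fh.write(f"# n_sites_used: {sfs.n_sites_used}\n")
        fh.write(" ".join(f"{x:.10g}" for x in sfs.counts.ravel()) + "\n")
        mask = (~sfs._canon).astype(int)
        fh.write(" ".join(str(x) for x in mask) + "\n")


def read_sfs(path) -> FoldedSFS:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    body = [ln for ln in lines if not ln.startswith("#")]
    header = body[0].split()
    dims = tuple(int(x) for x in header[:-1])
    sizes = tuple(d - 1 for d in dims)
    labels: tuple[str, ...] = ()
    n_used = 0.0
    for ln in lines:
        if ln.startswith("# pops:"):
            labels = tuple(ln.split(":", 1)[1].split())
        if ln.startswith("# n_sites_used:"):
            n_used = float(ln.split(":", 1)[1])
    counts = np.array([float(x) for x in body[1].split()]).reshape(dims)
    return FoldedSFS(counts, sizes, labels, n_used)
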