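"""Coalescent synthetic-data generation under explicit multi-deme demographies.

A :class:`Demography` is a set of demes (present-day diploid size, optional
forward-time exponential growth) plus backward-in-time events: joins (deme
merges into another, looking back), size/growth changes, and migration-rate
changes.  Genealogies are simulated under the structured coalescent with
time in generations; one (or several, for multi-SNP GBS stacks) segregating
site is placed uniformly on total branch length, i.e. the infinite-sites
model conditioned on the site segregating, so the number of loci equals the
SNP count and no mutation rate is needed at simulation time.

The same machinery provides a Monte-Carlo estimate of the expected joint
folded SFS (branch-length contributions averaged over genealogies), which is
the engine behind SFS-based composite-likelihood model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coalescent
from .genotype_io import MISSING, SNPMatrix, write_popmap, write_vcf
from .sfs import FoldedSFS, fold_joint

__all__ = ["Deme", "Demography", "SimConfig", "simulate_genotypes",
           "expected_sfs_mc", "pairwise_tmrca", "island_model",
           "make_study_fixture"]


@dataclass
class Deme:
    """A present-day deme: label, diploid size, forward exponential growth
    rate per generation (negative = forward decline, so the size grows
    looking backward)."""

    label: str
    size: float
    growth: float = 0.0


@dataclass
class Demography:
    """Demes plus backward-time events.

    Events are tuples:

    - ``("join", t, derived, ancestral)`` — at age ``t`` all lineages of
      ``derived`` move into ``ancestral`` and ``derived`` disappears.
    - ``("size", t, label, size, growth)`` — from age ``t`` (going back) the
      deme has the given size at ``t`` and growth rate.
    - ``("migration", t, src, dst, rate)`` — from age ``t`` backwards,
      lineages in ``src`` move to ``dst`` at ``rate`` per generation.

    ``migration`` is the present-day backward rate matrix (rows = source).
    """

    demes: list[Deme]
    events: list[tuple] = field(default_factory=list)
    migration: np.ndarray | None = None

    def labels(self) -> list[str]:
        return [d.label for d in self.demes]

    def _index(self, label: str) -> int:
        try:
            return self.labels().index(label)
        except ValueError:
            raise KeyError(f"unknown deme {label!r}") from None

    def compile(self):
        """Flatten to the epoch arrays the simulation kernels consume."""
        D = len(self.demes)
        if D == 0:
            raise ValueError("demography needs at least one deme")
        for d in self.demes:
            if d.size <= 0:
                raise ValueError(f"deme {d.label} has non-positive size")
        times = {0.0}
        for ev in self.events:
            if ev[1] < 0:
                raise ValueError("event times must be non-negative")
            times.add(float(ev[1]))
        epoch_t = np.array(sorted(times))
        E = len(epoch_t)
        size = np.empty((E, D))
        growth = np.empty((E, D))
        mig = np.zeros((E, D, D))
        if self.migration is not None:
            mg = np.asarray(self.migration, dtype=float)
            if mg.shape != (D, D):
                raise ValueError("migration matrix must be D x D")
            if (mg < 0).any():
                raise ValueError("migration rates must be >= 0")
            mig[0] = mg
            np.fill_diagonal(mig[0], 0.0)
        cur_size = np.array([d.size for d in self.demes], dtype=float)
        cur_growth = np.array([d.growth for d in self.demes], dtype=float)
        active = np.ones(D, dtype=bool)
        mv_epoch, mv_src, mv_dst = [], [], []
        by_time: dict[float, list[tuple]] = {}
        for ev in self.events:
            by_time.setdefault(float(ev[1]), []).append(ev)
        for e in range(E):
            t = epoch_t[e]
            if e > 0:
                dt = epoch_t[e] - epoch_t[e - 1]
                cur_size = cur_size * np.exp(-cur_growth * dt)
                mig[e] = mig[e - 1]
            for ev in by_time.get(t, []):
                kind = ev[0]
                if kind == "join":
                    src = self._index(ev[2])
                    dst = self._index(ev[3])
                    if not active[src] or not active[dst]:
                        raise ValueError(f"join at t={t} references inactive deme")
                    mv_epoch.append(e)
                    mv_src.append(src)
                    mv_dst.append(dst)
                    active[src] = False
                    mig[e, src, :] = 0.0
                    mig[e, :, src] = 0.0
                    # the joined deme is inert from here back; freeze its
                    # size so exponential carry-forward cannot overflow
                    cur_size[src] = 1.0
                    cur_growth[src] = 0.0
                elif kind == "size":
                    d = self._index(ev[2])
                    if ev[3] <= 0:
                        raise ValueError("size must be positive")
                    cur_size[d] = float(ev[3])
                    cur_growth[d] = float(ev[4]) if len(ev) > 4 else 0.0
                elif kind == "migration":
                    src = self._index(ev[2])
                    dst = self._index(ev[3])
                    mig[e, src, dst] = float(ev[4])
                else:
                    raise ValueError(f"unknown event kind {kind!r}")
            size[e] = cur_size
            growth[e] = cur_growth
            np.fill_diagonal(mig[e], 0.0)
        for e in range(E):
            out = mig[e].sum(axis=1)
            if (out >= 1.0).any():
                raise ValueError("per-deme migration rates must sum to < 1 per generation")
        # final epoch must allow complete coalescence
        rem = np.flatnonzero(active)
        if len(rem) > 1:
            import networkx as nx

            g = nx.DiGraph()
            g.add_nodes_from(rem.tolist())
            last = mig[E - 1]
            for i in rem:
                for j in rem:
                    if i != j and last[i, j] > 0:
                        g.add_edge(int(i), int(j))
            if not nx.is_strongly_connected(g):
                raise ValueError(
                    "demography never coalesces to a single deme: remaining "
                    "demes are not connected by migration in the final epoch")
        return (epoch_t, size, growth, mig,
                np.array(mv_epoch, dtype=np.int64),
                np.array(mv_src, dtype=np.int64),
                np.array(mv_dst, dtype=np.int64))


@dataclass
class SimConfig:
    """Simulation settings: loci (stacks), diploid samples per deme, SNPs per
    stack distribution, missing-genotype rate, and the master seed."""

    n_loci: int
    samples_per_deme: dict[str, int]
    snps_per_stack: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    missing_rate: float = 0.0
    stack_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if any(v < 1 for v in self.samples_per_deme.values()):
            raise ValueError("samples_per_deme must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        tot = sum(self.snps_per_stack.values())
        if tot <= 0 or any(k < 1 for k in self.snps_per_stack):
            raise ValueError("snps_per_stack must map counts >= 1 to positive weights")
        self.snps_per_stack = {k: v / tot for k, v in self.snps_per_stack.items()}


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _tree_length_from_times(tim: np.ndarray, n_leaves: int) -> float:
    """Total branch length of a contemporary-sample binary genealogy from
    its (non-decreasing) internal-node times."""
    taus = tim[n_leaves:]
    counts = np.arange(n_leaves, 1, -1, dtype=float)
    prev = np.concatenate(([0.0], taus[:-1]))
    return float(np.sum(counts * (taus - prev)))


def _leaf_sets(parent: np.ndarray, n_leaves: int, node: int) -> np.ndarray:
    """Leaves below ``node`` (inclusive) given parent pointers."""
    n_nodes = parent.shape[0]
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for c, p in enumerate(parent):
        if p >= 0:
            children[p].append(c)
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n_leaves:
            out.append(v)
        else:
            stack.extend(children[v])
    return np.asarray(out, dtype=np.intp)


def simulate_genotypes(d: Demography, c: SimConfig,
                       stack_snp_counts: np.ndarray | None = None,
                       pool_factor: int = 3) -> SNPMatrix:
    """Simulate a diploid genotype matrix under the structured coalescent.

    One genealogy per stack; each stack carries a number of SNPs drawn from
    ``c.snps_per_stack`` (all SNPs of a stack share the genealogy, emulating
    within-locus linkage).  Conditioning a locus on carrying ``s``
    segregating sites under low-rate infinite-sites mutation weights its
    genealogy by (total branch length)^s, so stack genealogies are
    importance-resampled by that weight from a pool of ``pool_factor`` x
    n_stacks candidate trees; each SNP is then placed uniformly on branch
    length within its tree.  Genotypes pair consecutive lineages within a
    deme; missing calls are masked completely at random at
    ``c.missing_rate``.
    """
    labels = d.labels()
    for lab in c.samples_per_deme:
        if lab not in labels:
            raise KeyError(f"sampled deme {lab!r} not in demography")
    samp_labels = [lab for lab in labels if lab in c.samples_per_deme]
    dip = np.array([c.samples_per_deme[lab] for lab in samp_labels])
    # demes without samples keep zero lineages; kernel needs per-deme counts
    samp = np.zeros(len(labels), dtype=np.int64)
    for lab in samp_labels:
        samp[labels.index(lab)] = 2 * c.samples_per_deme[lab]
    compiled = d.compile()
    rng = np.random.default_rng(c.seed)
    if stack_snp_counts is None:
        ks = np.array(sorted(c.snps_per_stack))
        ps = np.array([c.snps_per_stack[k] for k in ks])
        stack_snp_counts = rng.choice(ks, size=c.n_loci, p=ps)
    else:
        stack_snp_counts = np.asarray(stack_snp_counts)
    n_stacks = len(stack_snp_counts)
    n_hap = int(samp.sum())
    n_dip = n_hap // 2

    # pass 1: total branch length of every candidate tree, chunked so the
    # full pool never sits in memory; pass 2 re-simulates the same chunks
    # (same seeds) and extracts the resampled trees.
    n_pool = max(pool_factor, 1) * n_stacks
    chunk = max(1, min(n_pool, 4096))
    chunk_seeds = [_kernel_seed(rng) for _ in range(0, n_pool, chunk)]
    ltot = np.empty(n_pool)
    off = 0
    for cs in chunk_seeds:
        size = min(chunk, n_pool - off)
        _, ntime = _coalescent.sim_trees(cs, size, samp, *compiled)
        # total length = sum over nodes of (n_children) weighted depths;
        # equivalently sum of (t_parent - t_node) over non-root nodes
        tot = np.empty(size)
        for r in range(size):
            tot[r] = _tree_length_from_times(ntime[r], n_hap)
        ltot[off:off + size] = tot
        off += size
    chosen = np.empty(n_stacks, dtype=np.int64)
    for s_val in np.unique(stack_snp_counts):
        w = ltot.astype(float) ** int(s_val)
        w /= w.sum()
        which = stack_snp_counts == s_val
        chosen[which] = rng.choice(n_pool, size=int(which.sum()), p=w)
    # pass 2
    trees_parent = {}
    trees_time = {}
    need = np.unique(chosen)
    off = 0
    for ci, cs in enumerate(chunk_seeds):
        size = min(chunk, n_pool - off)
        local = need[(need >= off) & (need < off + size)]
        if len(local):
            parent, ntime = _coalescent.sim_trees(cs, size, samp, *compiled)
            for ix in local:
                trees_parent[int(ix)] = parent[ix - off].copy()
                trees_time[int(ix)] = ntime[ix - off].copy()
        off += size

    n_snps = int(stack_snp_counts.sum())
    geno = np.empty((n_dip, n_snps), dtype=np.int8)
    stack_col, pos_col, ref_col, alt_col = [], [], [], []
    nucs = np.array(list("ACGT"))
    snp = 0
    width = len(str(n_stacks))
    for st in range(n_stacks):
        par = trees_parent[int(chosen[st])]
        tim = trees_time[int(chosen[st])]
        bl = np.zeros(par.shape[0])
        has_par = par >= 0
        bl[has_par] = tim[par[has_par]] - tim[np.flatnonzero(has_par)]
        w = bl / bl.sum()
        k = int(stack_snp_counts[st])
        nodes = rng.choice(par.shape[0], size=k, p=w)
        positions = 1 + np.sort(rng.choice(c.stack_length, size=k, replace=False)
                                if k <= c.stack_length else np.arange(k))
        sid = f"stack_{st:0{width}d}"
        for j, node in enumerate(nodes):
            carriers = _leaf_sets(par, n_hap, int(node))
            hap = np.zeros(n_hap, dtype=np.int8)
            hap[carriers] = 1
            geno[:, snp] = hap[0::2] + hap[1::2]
            ra = rng.choice(4, size=2, replace=False)
            stack_col.append(sid)
            pos_col.append(int(positions[j]))
            ref_col.append(nucs[ra[0]])
            alt_col.append(nucs[ra[1]])
            snp += 1
    if c.missing_rate > 0:
        mask = rng.random(geno.shape) < c.missing_rate
        geno[mask] = MISSING
    acc_ids = []
    pop_map = {}
    for lab, nd in zip(samp_labels, dip):
        for i in range(nd):
            a = f"{lab}_{i:03d}"
            acc_ids.append(a)
            pop_map[a] = lab
    meta = pd.DataFrame({"stack_id": stack_col, "pos": pos_col,
                         "ref": ref_col, "alt": alt_col})
    return SNPMatrix(geno, meta, acc_ids, pop_map)


def expected_sfs_mc(d: Demography, samples_per_deme: dict[str, int],
                    n_sims: int, seed: int,
                    haploid: bool = False) -> FoldedSFS:
    """Monte-Carlo expected joint folded SFS from branch-length contributions.

    ``samples_per_deme`` are diploid counts unless ``haploid=True``.  The
    returned spectrum is a probability distribution over segregating folded
    classes (mass per entry proportional to expected branch length).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    labels = d.labels()
    samp_labels = [lab for lab in labels if lab in samples_per_deme]
    if not samp_labels:
        raise ValueError("no sampled demes")
    samp = np.zeros(len(labels), dtype=np.int64)
    for lab in samp_labels:
        n = int(samples_per_deme[lab])
        samp[labels.index(lab)] = n if haploid else 2 * n
    compiled = d.compile()
    flat = _coalescent.sim_branch_sfs(int(seed) % (2**31 - 1) or 1, n_sims,
                                      samp, *compiled)
    sizes = tuple(int(samp[labels.index(lab)]) for lab in samp_labels)
    # drop axes for unsampled demes: kernel indexes only sampled demes if we
    # pass reduced samp?  samp covers all demes; unsampled have size 1 axis.
    dims_all = tuple(int(s) + 1 for s in samp)
    arr = flat.reshape(dims_all)
    keep = tuple(i for i, s in enumerate(samp) if s > 0)
    arr = arr.reshape([dims_all[i] for i in keep])
    folded = fold_joint(arr, sizes)
    out = FoldedSFS(folded, sizes, tuple(samp_labels), float(n_sims))
    return out.normalized()


def pairwise_tmrca(d: Demography, deme: str, n_reps: int, seed: int) -> np.ndarray:
    """TMRCA of two lineages sampled in ``deme`` across replicate genealogies
    (a direct oracle hook for E[T2] = 2N under a constant-size deme)."""
    labels = d.labels()
    samp = np.zeros(len(labels), dtype=np.int64)
    samp[labels.index(deme)] = 2
    compiled = d.compile()
    _, ntime = _coalescent.sim_trees(int(seed) % (2**31 - 1) or 1, n_reps,
                                     samp, *compiled)
    return ntime[:, -1]


def island_model(n_demes: int, size: float, m_per_gen: float,
                 labels: list[str] | None = None) -> Demography:
    """Symmetric island model: each deme sends migrants at total rate
    ``m_per_gen`` split evenly among the other demes."""
    if labels is None:
        labels = [f"deme{i}" for i in range(n_demes)]
    mig = np.full((n_demes, n_demes), m_per_gen / max(n_demes - 1, 1))
    np.fill_diagonal(mig, 0.0)
    return Demography([Deme(lab, size) for lab in labels], migration=mig)


# --- study-scale fixture -----------------------------------------------------

#: Generation time (years) and per-site per-year mutation rate used to convert
#: the published divergence times into generations for the fixture demography.
GENERATION_TIME = 4.0
MUTATION_RATE_PER_YEAR = 2.6e-9

STUDY_SAMPLES = {"CladeI": 30, "CladeII": 20, "CladeIII": 20, "CladeIV": 17,
                 "CladeV": 12, "CladeVI": 13}
STUDY_N_SNPS = 38395


def study_demography(n_bungeanum: float = 20_000.0,
                     n_armatum: float = 10_000.0,
                     cultivated_fold_decline: float = 200.0) -> Demography:
    """Composite demography emulating the study design.

    Two species split 12 Mya-equivalent (3e6 generations at g = 4 yr);
    the Z. bungeanum clades split ~221/219 kya-equivalent (55,250 / 54,750
    generations) with Clade IV attached at 75,000 generations; wild and
    cultivated Z. armatum split 5,440 yr-equivalent (1,360 generations) with
    a 200-fold exponential decline in the cultivated deme.  Absolute sizes
    are declared assumptions (config-overridable), not published values.
    """
    t_cult = 5440.0 / GENERATION_TIME
    n_cult_present = n_armatum / cultivated_fold_decline
    g_cult = -np.log(cultivated_fold_decline) / t_cult  # forward decline
    demes = [
        Deme("CladeI", n_bungeanum),
        Deme("CladeII", n_bungeanum),
        Deme("CladeIII", n_bungeanum),
        Deme("CladeIV", n_bungeanum),
        Deme("CladeV", n_armatum),
        Deme("CladeVI", n_cult_present, growth=g_cult),
    ]
    events = [
        ("join", t_cult, "CladeVI", "CladeV"),
        ("size", t_cult, "CladeV", n_armatum, 0.0),
        ("join", 219_000.0 / GENERATION_TIME, "CladeIII", "CladeII"),
        ("join", 221_000.0 / GENERATION_TIME, "CladeII", "CladeI"),
        ("join", 300_000.0 / GENERATION_TIME, "CladeIV", "CladeI"),
        ("join", 12_000_000.0 / GENERATION_TIME, "CladeI", "CladeV"),
        ("size", 12_000_000.0 / GENERATION_TIME, "CladeV", n_armatum, 0.0),
    ]
    return Demography(demes, events)


def make_study_fixture(seed: int, out_dir, n_snps: int = STUDY_N_SNPS,
                       missing_rate: float = 0.1) -> tuple[str, str]:
    """Emit a VCF + popmap emulating the 112-accession, 6-clade study design
    with ~``n_snps`` biallelic SNPs grouped into GBS stacks.

    Returns (vcf_path, popmap_path).  Byte-identical for a given seed.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo = study_demography()
    rng = np.random.default_rng(seed)
    dist = {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks])
    counts = []
    tot = 0
    while tot < n_snps:
        k = int(rng.choice(ks, p=ps))
        k = min(k, n_snps - tot)
        counts.append(k)
        tot += k
    cfg = SimConfig(n_loci=len(counts), samples_per_deme=STUDY_SAMPLES,
                    snps_per_stack=dist, missing_rate=missing_rate,
                    seed=_kernel_seed(rng))
    m = simulate_genotypes(demo, cfg, stack_snp_counts=np.array(counts))
    vcf_path = out / "study_fixture.vcf"
    pm_path = out / "study_fixture.popmap.tsv"
    write_vcf(m, vcf_path, seed=seed)
    write_popmap(m.pop_map, pm_path)
    return str(vcf_path), str(pm_path)
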