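"""Genotype matrix I/O and matrix-level site filtering for GBS SNP panels.

The central container is :class:`SNPMatrix`: diploid genotype codes
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
-1 = missing) for accessions x sites, with per-site stack (GBS locus)
metadata and a population map.  The GBS dialect adopted throughout is that
the VCF CHROM column holds the stack identifier and POS the 1-based position
of the SNP within the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SNPMatrix",
    "FilterReport",
    "VcfParseError",
    "UnsupportedPloidyError",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "filter_sites",
    "thin_one_snp_per_locus",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


class UnsupportedPloidyError(ValueError):
    """Raised when a genotype is not diploid."""


@dataclass
class SNPMatrix:
    """Diploid genotypes for accessions x sites plus site/population metadata.

    Attributes
    ----------
    genotypes
        int8 array of shape (n_accessions, n_sites), codes {0, 1, 2, -1}.
    site_meta
        DataFrame with columns ``stack_id`` (str), ``pos`` (int, 1-based
        position within the stack), ``ref``, ``alt`` (comma-joined when
        multiallelic).
    accession_ids
        Ordered accession labels (rows of ``genotypes``).
    pop_map
        Mapping accession -> population label.
    """

    genotypes: np.ndarray
    site_meta: pd.DataFrame
    accession_ids: list[str]
    pop_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (accessions x sites)")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if len(self.accession_ids) != self.genotypes.shape[0]:
            raise ValueError("accession_ids length mismatch")
        if len(self.site_meta) != self.genotypes.shape[1]:
            raise ValueError("site_meta length mismatch")
        unknown = set(self.pop_map) - set(self.accession_ids)
        if unknown:
            raise ValueError(f"pop_map accessions not in matrix: {sorted(unknown)}")

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def stack_ids(self) -> np.ndarray:
        return self.site_meta["stack_id"].to_numpy()

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accession_ids:
            p = self.pop_map.get(a)
            if p is not None and p not in seen:
                seen[p] = None
        return list(seen)

    def accession_indices(self, pop: str) -> np.ndarray:
        """Row indices of accessions assigned to ``pop``."""
        idx = [i for i, a in enumerate(self.accession_ids)
               if self.pop_map.get(a) == pop]
        if not idx:
            raise KeyError(f"population {pop!r} not present in pop_map")
        return np.asarray(idx, dtype=np.intp)

    def take_sites(self, idx: np.ndarray) -> "SNPMatrix":
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            site_meta=self.site_meta.iloc[idx].reset_index(drop=True),
        )

    def is_biallelic(self) -> np.ndarray:
        """Per-site flag: at most one alternate allele in the ALT field."""
        alts = self.site_meta["alt"].astype(str).to_numpy()
        return np.array(["," not in a for a in alts])

    def allele_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt copies, observed copies) for a population (or all)."""
        g = self.genotypes if pop is None else self.genotypes[self.accession_indices(pop)]
        obs = g != MISSING
        alt = np.where(obs, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * obs.sum(axis=0).astype(np.int64)


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_sites` (removal reasons are assigned in
    priority order: non-biallelic before excess missingness)."""

    n_in: int
    n_non_biallelic: int
    n_missingness_fail: int
    n_out: int

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_non_biallelic, self.n_missingness_fail, self.n_out) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_out != self.n_in - self.n_non_biallelic - self.n_missingness_fail:
            raise ValueError("inconsistent FilterReport counts")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def read_vcf(path, popmap: dict[str, str] | None = None) -> SNPMatrix:
    """Read diploid GT calls from a VCF into an :class:`SNPMatrix`.

    Genotypes are coded by alternate-allele count; any allele index > 0
    counts as alternate, so multiallelic records are retained (flagged
    non-biallelic via their ALT field) and removed later by
    :func:`filter_sites`.  ``./.`` becomes missing (-1).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has no sample columns")
    gts: list[np.ndarray] = []
    meta = {"stack_id": [], "pos": [], "ref": [], "alt": []}
    for lineno, var in enumerate(vcf, start=1):
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"non-diploid genotype at record {lineno} "
                    f"({var.CHROM}:{var.POS}), sample {samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        gts.append(col)
        meta["stack_id"].append(var.CHROM)
        meta["pos"].append(var.POS)
        meta["ref"].append(var.REF)
        meta["alt"].append(",".join(var.ALT) if var.ALT else ".")
    geno = (np.stack(gts, axis=1) if gts
            else np.empty((len(samples), 0), dtype=np.int8))
    return SNPMatrix(
        genotypes=geno,
        site_meta=pd.DataFrame(meta),
        accession_ids=samples,
        pop_map=popmap or {},
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(m: SNPMatrix, path, seed: int | None = None) -> None:
    """Write an :class:`SNPMatrix` as a minimal VCF v4.2 text file."""
    contigs = list(dict.fromkeys(m.site_meta["stack_id"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zanthopop\n")
        if seed is not None:
            fh.write(f"##zanthopop_seed={seed}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.accession_ids) + "\n")
        meta = m.site_meta
        for s in range(m.n_sites):
            row = meta.iloc[s]
            cells = "\t".join(_GT_STR[int(g)] for g in m.genotypes[:, s])
            fh.write(f"{row.stack_id}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{cells}\n")


def read_popmap(path) -> dict[str, str]:
    """Read a 2-column (accession, population) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["accession"], df["population"]))


def write_popmap(pop_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, pop in pop_map.items():
            fh.write(f"{acc}\t{pop}\n")


def filter_sites(m: SNPMatrix, max_missing_fraction: float = 0.4,
                 drop_monomorphic: bool = False) -> tuple[SNPMatrix, FilterReport]:
    """Retain biallelic sites with missing fraction <= ``max_missing_fraction``.

    Monomorphic-within-panel sites are retained by default (they carry SFS
    information); pass ``drop_monomorphic=True`` to count them as
    non-biallelic removals.  Removal reasons are assigned with non-biallelic
    taking priority over missingness so report counts are well defined.
    """
    if m.n_sites == 0:
        raise ValueError("empty matrix: no sites to filter")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be within [0, 1]")
    biallelic = m.is_biallelic()
    if drop_monomorphic:
        alt, total = m.allele_counts()
        poly = (alt > 0) & (alt < total)
        biallelic &= poly
    miss_frac = (m.genotypes == MISSING).mean(axis=0)
    miss_ok = miss_frac <= max_missing_fraction + 1e-12
    keep = biallelic & miss_ok
    n_nb = int((~biallelic).sum())
    n_miss = int((biallelic & ~miss_ok).sum())
    report = FilterReport(
        n_in=m.n_sites,
        n_non_biallelic=n_nb,
        n_missingness_fail=n_miss,
        n_out=int(keep.sum()),
    )
    return m.take_sites(np.flatnonzero(keep)), report


def thin_one_snp_per_locus(m: SNPMatrix, seed: int) -> SNPMatrix:
    """Keep exactly one uniformly-chosen SNP per stack (GBS locus).

    Deterministic for a given seed; relative site order is preserved.
    """
    rng = np.random.default_rng(seed)
    stacks = m.stack_ids
    keep: list[int] = []
    # group site indices by stack, preserving first-appearance order
    order: dict[str, list[int]] = {}
    for i, s in enumerate(stacks):
        order.setdefault(s, []).append(i)
    for sites in order.values():
        keep.append(sites[int(rng.integers(len(sites)))])
    keep.sort()
    return m.take_sites(np.asarray(keep, dtype=np.intp))
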