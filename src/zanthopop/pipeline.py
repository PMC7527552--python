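"""End-to-end pipeline orchestration from a single validated config.

Stages run in dependency order (io -> filter -> stats/sfs -> stairway |
fstats -> outliers), every stage's randomness derives from one master seed,
and a machine-readable JSON report collects per-stage summaries.  The
expensive inference stages (multi-population model fitting, admixture-graph
search) are exposed through the library API and the CLI rather than being
forced through the default pipeline run.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .fstats import FreqMatrix, f3_scan
from .genotype_io import (SNPMatrix, filter_sites, read_popmap, read_vcf,
                          thin_one_snp_per_locus, write_vcf, write_popmap)
from .outliers import consensus, fdist_test, flk_test
from .popstats import diversity_table
from .sfs import bootstrap_sfs, folded_sfs, write_sfs
from .simulate import make_study_fixture
from .stairway import StairwayConfig, fit_stairway

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class InputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vcf: str | None = None
    popmap: str | None = None
    synthetic: bool = False
    synthetic_n_snps: int = 2000


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_missing_fraction: float = Field(0.4, ge=0.0, le=1.0)
    thin_one_snp_per_locus: bool = False


class SfsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pops: list[str] | None = None
    projections: list[int] | None = None


class StairwayStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pop: str | None = None
    n_bootstrap: int = 50
    n_ref: float | None = None
    total_sites: int | None = None


class FstatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    block_size: int = 200
    z_threshold: float = 1.96


class OutlierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pops: list[str] | None = None
    n_sim_loci: int = 10_000
    q_threshold: float = 0.05


class RunConfig(BaseModel):
    """Top-level pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "zanthopop_out"
    seed: int = 0
    mu: float = 2.6e-9           # substitutions per site per year
    generation_time: float = 4.0  # years
    stages: list[str] = Field(
        default_factory=lambda: ["filter", "stats", "sfs"])
    input: InputConfig = Field(default_factory=InputConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    sfs: SfsConfig = Field(default_factory=SfsConfig)
    stairway: StairwayStage = Field(default_factory=StairwayStage)
    fstats: FstatsConfig = Field(default_factory=FstatsConfig)
    outliers: OutlierConfig = Field(default_factory=OutlierConfig)


_STAGE_ORDER = ["filter", "stats", "sfs", "stairway", "fstats", "outliers"]


def validate_config(cfg: dict | RunConfig) -> RunConfig:
    """Normalize a raw mapping into a RunConfig: defaults injected, unknown
    keys rejected with the offending key path."""
    if isinstance(cfg, RunConfig):
        return cfg
    try:
        out = RunConfig.model_validate(cfg or {})
    except ValidationError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
    unknown = [s for s in out.stages if s not in _STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    return out


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derivation from the master seed."""
    return int(np.random.SeedSequence(
        [master % 2**31, _STAGE_ORDER.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)) or 1


def _load(cfg: RunConfig, out: Path) -> SNPMatrix:
    inp = cfg.input
    if inp.synthetic:
        vcf, pm = make_study_fixture(cfg.seed, out / "fixture",
                                     n_snps=inp.synthetic_n_snps)
        return read_vcf(vcf, read_popmap(pm))
    if not inp.vcf:
        raise PipelineError("stage io: no VCF given and synthetic input disabled")
    popmap = read_popmap(inp.popmap) if inp.popmap else {}
    return read_vcf(inp.vcf, popmap)


def run_pipeline(cfg: dict | RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run report."""
    cfg = validate_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": json.loads(cfg.model_dump_json()),
                    "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    try:
        m = _load(cfg, out)
    except Exception as exc:
        raise PipelineError(f"stage io failed: {exc}") from exc
    report["stages"]["io"] = {"n_accessions": m.n_accessions,
                              "n_sites": m.n_sites,
                              "n_populations": len(m.populations())}
    for stage in _STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        try:
            m, summary = _run_stage(stage, m, cfg, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        report["stages"][stage] = summary
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _run_stage(stage: str, m: SNPMatrix, cfg: RunConfig, out: Path):
    seed = _stage_seed(cfg.seed, stage)
    if stage == "filter":
        m2, rep = filter_sites(m, cfg.filter.max_missing_fraction)
        if cfg.filter.thin_one_snp_per_locus:
            m2 = thin_one_snp_per_locus(m2, seed)
        (out / "filter_report.json").write_text(rep.to_json())
        write_vcf(m2, out / "filtered.vcf", seed=cfg.seed)
        write_popmap(m2.pop_map, out / "filtered.popmap.tsv")
        return m2, {"n_in": rep.n_in, "n_non_biallelic": rep.n_non_biallelic,
                    "n_missingness_fail": rep.n_missingness_fail,
                    "n_out": rep.n_out,
                    "thinned": cfg.filter.thin_one_snp_per_locus,
                    "n_sites_final": m2.n_sites}
    if stage == "stats":
        tab = diversity_table(m)
        tab.to_csv(out / "diversity.tsv", sep="\t", index=False)
        return m, {"n_rows": len(tab)}
    if stage == "sfs":
        pops = cfg.sfs.pops or m.populations()
        files = []
        for p in pops:
            proj = None
            if cfg.sfs.projections:
                proj = [cfg.sfs.projections[pops.index(p)]]
            s = folded_sfs(m, [p], proj)
            path = out / f"sfs_{p}.txt"
            write_sfs(s, path)
            files.append(str(path))
        return m, {"pops": pops, "files": files}
    if stage == "stairway":
        pop = cfg.stairway.pop or m.populations()[0]
        s = folded_sfs(m, [pop])
        boots = bootstrap_sfs(m, [pop], None, cfg.stairway.n_bootstrap, seed)
        sw = StairwayConfig(mu=cfg.mu, gen_time=cfg.generation_time,
                            n_ref=cfg.stairway.n_ref,
                            total_sites=cfg.stairway.total_sites, seed=seed)
        traj = fit_stairway(s, boots, sw)
        traj.to_tsv(out / f"stairway_{pop}.tsv")
        return m, {"pop": pop, "n_epochs_free": traj.n_epochs_free,
                   "file": str(out / f"stairway_{pop}.tsv")}
    if stage == "fstats":
        f = FreqMatrix.from_snp_matrix(m, block_size=cfg.fstats.block_size)
        if len(f.pops) < 3:
            raise PipelineError("stage fstats: needs >= 3 populations")
        scan = f3_scan(f, z_threshold=cfg.fstats.z_threshold)
        scan.to_csv(out / "f3_scan.tsv", sep="\t", index=False)
        return m, {"n_tests": len(scan),
                   "n_significant": int(scan["significant"].sum())}
    if stage == "outliers":
        pops = cfg.outliers.pops or m.populations()
        f = FreqMatrix.from_snp_matrix(m, pops)
        res = {}
        flags = []
        if len(pops) >= 3:
            flk = flk_test(f, q_threshold=cfg.outliers.q_threshold)
            flk.to_csv(out / "flk.tsv", sep="\t", index=False)
            flags.append(flk["outlier"].to_numpy())
            res["flk_outliers"] = int(flk["outlier"].sum())
        fd = fdist_test(m, pops, n_sim_loci=cfg.outliers.n_sim_loci,
                        seed=seed, q_threshold=cfg.outliers.q_threshold)
        fd.to_csv(out / "fdist.tsv", sep="\t", index=False)
        flags.append(fd["outlier"].fillna(False).to_numpy())
        res["fdist_outliers"] = int(fd["outlier"].sum())
        cons = consensus(flags)
        np.savetxt(out / "consensus_outliers.tsv",
                   np.flatnonzero(cons), fmt="%d")
        res["consensus_outliers"] = int(cons.sum())
        return m, res
    raise PipelineError(f"unknown stage {stage!r}")
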