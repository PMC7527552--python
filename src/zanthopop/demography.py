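"""SFS-based composite-likelihood demographic model fitting.

The likelihood is multinomial over the segregating entries of the joint
folded SFS (no invariant-site class: GBS panels carry no callable-site
count), with the model's expected spectrum estimated by Monte-Carlo
branch-length simulation (:func:`zanthopop.simulate.expected_sfs_mc`) under
common random numbers, so the likelihood surface is smooth in the parameters
for a fixed per-start seed.  Optimization is cyclic one-dimensional Brent
line searches over the (log-transformed) parameters, repeated from
independent random starts; models are compared by AIC and Akaike weights.

The model library covers the two-population families used for the wild vs
cultivated split (isolation with exponential shrinkage in the cultivated
deme, optionally with asymmetric migration or shrinkage in both demes), a
plain no-migration isolation model for the between-species split, and the
three-population model in which two clades split shortly after both
diverged from the first.  Additional topologies can be expressed through the
declarative :class:`DemographicModel` (any parameter-to-demography builder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .sfs import FoldedSFS
from .simulate import Deme, Demography, expected_sfs_mc

__all__ = ["Param", "DemographicModel", "FitConfig", "ModelFit", "fit_model",
           "compare_models", "parametric_bootstrap", "model_isolation",
           "model_9", "model_11", "model_12", "model_13",
           "GENERATION_TIME", "MUTATION_RATE_PER_YEAR", "generations_to_years"]

GENERATION_TIME = 4.0
MUTATION_RATE_PER_YEAR = 2.6e-9


def generations_to_years(t_gens: float, gen_time: float = GENERATION_TIME) -> float:
    """Rescale a time in generations to years (g = 4 yr by default)."""
    return t_gens * gen_time


@dataclass
class Param:
    """A free model parameter with box bounds; ``log=True`` optimizes in
    log10 space (sizes, times), else linearly (fractions, rates)."""

    name: str
    lo: float
    hi: float
    log: bool = True

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"infeasible bounds for {self.name}")
        if self.log and self.lo <= 0:
            raise ValueError(f"log-scale parameter {self.name} needs lo > 0")

    def to_internal(self, x: float) -> float:
        return math.log10(x) if self.log else x

    def from_internal(self, z: float) -> float:
        return 10.0 ** z if self.log else z

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.log:
            return math.log10(self.lo), math.log10(self.hi)
        return self.lo, self.hi


@dataclass
class DemographicModel:
    """A declarative model: free parameters plus a builder mapping a
    parameter dict to a :class:`Demography`.  ``sample_labels`` fixes the
    order of SFS axes."""

    model_id: str
    params: list[Param]
    builder: Callable[[dict], Demography]
    sample_labels: list[str]
    description: str = ""
    #: optional map from fitted parameters to reported quantities (e.g. a
    #: split time in years, a fold-decline) — attached to ModelFit.derived
    derived: Callable[[dict], dict] | None = None

    @property
    def k(self) -> int:
        return len(self.params)


@dataclass
class FitConfig:
    """Optimizer settings.

    ``n_sims`` genealogies per expected-SFS evaluation (10,000 by default, a
    desk-scale setting; raise for production fits), up to ``n_cycles`` cycles
    of coordinate-wise Brent line search (cycles stop early once a full
    cycle improves the log-likelihood by less than ``tol``), ``n_starts``
    independent random starts.  ``floor`` guards empty expected classes.
    """

    n_sims: int = 10_000
    n_cycles: int = 50
    n_starts: int = 50
    seed: int = 0
    tol: float = 0.01
    floor: float = 1e-6
    brent_maxiter: int = 12
    start_values: dict | None = None
    polish_sims: int | None = None   # default 10 x n_sims; 0 disables polish
    polish_cycles: int = 4
    polish_bracket: float = 0.2      # half-width (internal units) of the
                                     # narrowed per-coordinate polish bracket


@dataclass
class ModelFit:
    model_id: str
    params: dict[str, float]
    lnl: float
    k: int
    aic: float
    n_sites: float
    sample_sizes: tuple[int, ...]
    trace: list = field(default_factory=list)
    weight: float | None = None
    derived: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.aic - (2 * self.k - 2 * self.lnl)) > 1e-6 * max(1, abs(self.aic)):
            raise ValueError("AIC inconsistent with lnL and k")


def _expected_probs(model: DemographicModel, values: dict, sizes: tuple[int, ...],
                    mask: np.ndarray, n_sims: int, kernel_seed: int,
                    floor: float) -> np.ndarray:
    demo = model.builder(values)
    samples = {lab: n for lab, n in zip(model.sample_labels, sizes)}
    exp = expected_sfs_mc(demo, samples, n_sims, kernel_seed, haploid=True)
    q = exp.counts.ravel()[mask]
    q = np.maximum(q, floor)
    return q / q.sum()


def fit_model(obs: FoldedSFS, model: DemographicModel,
              config: FitConfig | None = None) -> ModelFit:
    """Maximize the multinomial composite likelihood of ``obs`` under
    ``model``; returns the best fit over all random starts with AIC."""
    config = config or FitConfig()
    if obs.ndim_pops != len(model.sample_labels):
        raise ValueError(
            f"observed SFS has {obs.ndim_pops} populations but model "
            f"{model.model_id} expects {len(model.sample_labels)}")
    mask = obs.segregating_mask()
    o = obs.counts.ravel()[mask]
    if (o > 0).sum() < 2:
        raise ValueError("degenerate SFS: all mass in a single class")
    sizes = obs.sample_sizes
    rng = np.random.default_rng(config.seed)
    names = [p.name for p in model.params]
    bounds = [p.internal_bounds for p in model.params]

    def run_cycles(z, kernel_seed, n_sims, n_cycles, bracket=None):
        """Cyclic coordinate-wise Brent line search under common random
        numbers (one kernel seed per optimization run)."""
        cache: dict[tuple, float] = {}

        def neg_lnl(zvec) -> float:
            key = tuple(np.round(zvec, 9))
            got = cache.get(key)
            if got is not None:
                return got
            values = {nm: p.from_internal(zv)
                      for nm, p, zv in zip(names, model.params, zvec)}
            q = _expected_probs(model, values, sizes, mask, n_sims,
                                kernel_seed, config.floor)
            val = -float(np.dot(o, np.log(q)))
            cache[key] = val
            return val

        cur = neg_lnl(z)
        for _cycle in range(n_cycles):
            prev = cur
            for i in range(len(z)):
                lo, hi = bounds[i]
                if bracket is not None:
                    lo = max(lo, z[i] - bracket)
                    hi = min(hi, z[i] + bracket)

                def f1(zi, i=i):
                    zz = z.copy()
                    zz[i] = zi
                    return neg_lnl(zz)

                res = minimize_scalar(
                    f1, bounds=(lo, hi), method="bounded",
                    options={"xatol": (hi - lo) * 1e-3,
                             "maxiter": config.brent_maxiter})
                if res.fun <= cur:
                    z[i] = res.x
                    cur = res.fun
            if prev - cur < config.tol:
                break
        return z, cur

    best_lnl = -np.inf
    best_z = None
    trace = []
    for start in range(config.n_starts):
        kernel_seed = int(rng.integers(1, 2**31 - 1))
        if start == 0 and config.start_values:
            z = np.array([p.to_internal(config.start_values[p.name])
                          for p in model.params])
        else:
            z = np.array([lo + rng.random() * (hi - lo) for lo, hi in bounds])
        z, cur = run_cycles(z, kernel_seed, config.n_sims, config.n_cycles)
        vals = {nm: p.from_internal(zv)
                for nm, p, zv in zip(names, model.params, z)}
        trace.append({"start": start, "lnl": -cur, "params": vals})
        if -cur > best_lnl:
            best_lnl = -cur
            best_z = z.copy()
    # polish the winning start with a larger simulation budget to damp
    # Monte-Carlo bias along weakly identified directions
    polish_sims = (10 * config.n_sims if config.polish_sims is None
                   else config.polish_sims)
    if polish_sims and config.polish_cycles:
        kernel_seed = int(rng.integers(1, 2**31 - 1))
        best_z, cur = run_cycles(best_z, kernel_seed, polish_sims,
                                 config.polish_cycles,
                                 bracket=config.polish_bracket)
        best_lnl = -cur
    best_vals = {nm: p.from_internal(zv)
                 for nm, p, zv in zip(names, model.params, best_z)}
    k = model.k
    derived = model.derived(best_vals) if model.derived else {}
    return ModelFit(model.model_id, best_vals, best_lnl, k,
                    2 * k - 2 * best_lnl, float(o.sum()), sizes, trace,
                    derived=derived)


def compare_models(fits: list[ModelFit]) -> list[ModelFit]:
    """Sort fits (to the same observed SFS) by AIC and attach Akaike weights
    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    sig = {(f.n_sites, f.sample_sizes) for f in fits}
    if len(sig) > 1:
        raise ValueError("fits were made to different observed data")
    ranked = sorted(fits, key=lambda f: f.aic)
    delta = np.array([f.aic - ranked[0].aic for f in ranked])
    w = np.exp(-delta / 2)
    w /= w.sum()
    for f, wi in zip(ranked, w):
        f.weight = float(wi)
    return ranked


def parametric_bootstrap(obs: FoldedSFS, model: DemographicModel,
                         fit: ModelFit, n_reps: int, seed: int,
                         config: FitConfig | None = None) -> dict[str, np.ndarray]:
    """Refit datasets drawn from the fitted model (multinomial resampling of
    the expected SFS at the MLE); returns per-parameter arrays of bootstrap
    estimates.  Replicate fits warm-start from the MLE with a single start.
    """
    base = config or FitConfig()
    mask = obs.segregating_mask()
    rng = np.random.default_rng(seed)
    q = _expected_probs(model, fit.params, obs.sample_sizes, mask,
                        max(base.n_sims, 20_000),
                        int(rng.integers(1, 2**31 - 1)), base.floor)
    n_sites = int(round(fit.n_sites))
    out = {p.name: [] for p in model.params}
    for _ in range(n_reps):
        counts = rng.multinomial(n_sites, q)
        flat = np.zeros(obs.counts.size)
        flat[mask] = counts
        rep = FoldedSFS(flat.reshape(obs.counts.shape), obs.sample_sizes,
                        obs.pop_labels, float(n_sites))
        cfg = FitConfig(n_sims=base.n_sims, n_cycles=max(base.n_cycles // 3, 5),
                        n_starts=1, seed=int(rng.integers(1, 2**31 - 1)),
                        tol=base.tol, floor=base.floor,
                        brent_maxiter=base.brent_maxiter,
                        start_values=fit.params,
                        polish_sims=2 * base.n_sims, polish_cycles=2)
        rfit = fit_model(rep, model, cfg)
        for nm, v in rfit.params.items():
            out[nm].append(v)
    return {nm: np.asarray(v) for nm, v in out.items()}


# --- model library -----------------------------------------------------------

def model_isolation(n1: float, n2: float, n_anc: float,
                    t_bounds: tuple[float, float],
                    migration: bool = False,
                    labels: tuple[str, str] = ("pop1", "pop2")) -> DemographicModel:
    """Two-population isolation: constant sizes, split at free time T, no
    post-split size change; optional free asymmetric migration."""
    params = [Param("T_split", *t_bounds)]
    if migration:
        params += [Param("m12", 1e-8, 1e-2), Param("m21", 1e-8, 1e-2)]

    def build(v: dict) -> Demography:
        mig = None
        if migration:
            mig = np.array([[0.0, v["m12"]], [v["m21"], 0.0]])
        return Demography(
            [Deme(labels[0], n1), Deme(labels[1], n2)],
            [("join", v["T_split"], labels[1], labels[0]),
             ("size", v["T_split"], labels[0], n_anc, 0.0)],
            migration=mig)

    return DemographicModel(
        "isolation_migration" if migration else "isolation",
        params, build, list(labels),
        "two-deme isolation" + (" with asymmetric migration" if migration else ""))


def _two_pop_shrink(v: dict, n_wild: float, n_anc: float,
                    labels: tuple[str, str], both: bool,
                    migration: bool) -> Demography:
    t = v["T_split"]
    n_cult0 = t / v["cult_drift"]
    g_cult = -math.log(n_anc / n_cult0) / t
    if both:
        n_wild0 = t / v["wild_drift"]
        g_wild = -math.log(n_anc / n_wild0) / t
        wild = Deme(labels[0], n_wild0, growth=g_wild)
    else:
        wild = Deme(labels[0], n_wild)
    mig = None
    if migration:
        mig = np.array([[0.0, v["m12"]], [v["m21"], 0.0]])
    return Demography(
        [wild, Deme(labels[1], n_cult0, growth=g_cult)],
        [("join", t, labels[1], labels[0]),
         ("size", t, labels[0], n_anc, 0.0)],
        migration=mig)


def _shrink_derived(v: dict, n_anc: float) -> dict:
    out = {"N_cult_present": v["T_split"] / v["cult_drift"]}
    out["fold_decline"] = n_anc / out["N_cult_present"]
    out["T_split_years"] = generations_to_years(v["T_split"])
    if "wild_drift" in v:
        out["N_wild_present"] = v["T_split"] / v["wild_drift"]
    return out


# The exponential-shrinkage models are parameterized by the split time T
# (generations) and the cultivated "drift" T / N_cult_present: the amount of
# genetic drift the cultivated deme accumulates is governed almost entirely
# by that ratio, so these coordinates keep the likelihood surface close to
# axis-aligned for the cyclic line search.  Reported quantities
# (N_cult_present, fold-decline) are attached as derived parameters.

def model_9(n_wild: float = 10_000.0, n_anc: float = 10_000.0,
            t_bounds: tuple[float, float] = (100.0, 20_000.0),
            drift_bounds: tuple[float, float] = (1.0, 1_000.0),
            labels: tuple[str, str] = ("wild", "cultivated")) -> DemographicModel:
    """Isolation with exponential shrinkage in the cultivated deme: the
    cultivated population starts at the ancestral size at the split and
    declines exponentially to the present.  Free parameters: split time
    (generations) and cultivated drift T / N_present; the fold-decline
    n_anc / N_cult_present is reported as a derived quantity."""
    return DemographicModel(
        "model_9",
        [Param("T_split", *t_bounds), Param("cult_drift", *drift_bounds)],
        lambda v: _two_pop_shrink(v, n_wild, n_anc, labels, False, False),
        list(labels),
        "isolation + exponential cultivated shrinkage",
        derived=lambda v: _shrink_derived(v, n_anc))


def model_11(n_wild: float = 10_000.0, n_anc: float = 10_000.0,
             t_bounds: tuple[float, float] = (100.0, 20_000.0),
             drift_bounds: tuple[float, float] = (1.0, 1_000.0),
             labels: tuple[str, str] = ("wild", "cultivated")) -> DemographicModel:
    """Model 9 plus free asymmetric post-split migration."""
    return DemographicModel(
        "model_11",
        [Param("T_split", *t_bounds), Param("cult_drift", *drift_bounds),
         Param("m12", 1e-8, 1e-2), Param("m21", 1e-8, 1e-2)],
        lambda v: _two_pop_shrink(v, n_wild, n_anc, labels, False, True),
        list(labels),
        "isolation-with-migration + exponential cultivated shrinkage",
        derived=lambda v: _shrink_derived(v, n_anc))


def model_12(n_anc: float = 10_000.0,
             t_bounds: tuple[float, float] = (100.0, 20_000.0),
             drift_bounds: tuple[float, float] = (1.0, 1_000.0),
             wild_drift_bounds: tuple[float, float] = (0.005, 100.0),
             labels: tuple[str, str] = ("wild", "cultivated")) -> DemographicModel:
    """Exponential decay in both wild and cultivated demes, no migration."""
    return DemographicModel(
        "model_12",
        [Param("T_split", *t_bounds), Param("cult_drift", *drift_bounds),
         Param("wild_drift", *wild_drift_bounds)],
        lambda v: _two_pop_shrink(v, float("nan"), n_anc, labels, True, False),
        list(labels),
        "isolation + exponential shrinkage in both demes",
        derived=lambda v: _shrink_derived(v, n_anc))


def model_13(n_each: float = 50_000.0,
             t_old_bounds: tuple[float, float] = (5_000.0, 500_000.0),
             labels: tuple[str, str, str] = ("CladeI", "CladeII", "CladeIII"),
             migration_rate: float = 0.0) -> DemographicModel:
    """Three-population model: Clades II and III split at T_young = frac *
    T_old shortly after both diverged from Clade I at T_old; constant per-
    deme sizes, optional symmetric migration between all demes."""
    params = [Param("T_old", *t_old_bounds), Param("frac_young", 0.2, 0.999, log=False)]

    def build(v: dict) -> Demography:
        t_old = v["T_old"]
        t_young = v["frac_young"] * t_old
        mig = None
        if migration_rate > 0:
            mig = np.full((3, 3), migration_rate)
            np.fill_diagonal(mig, 0.0)
        return Demography(
            [Deme(lab, n_each) for lab in labels],
            [("join", t_young, labels[2], labels[1]),
             ("join", t_old, labels[1], labels[0])],
            migration=mig)

    return DemographicModel("model_13", params, build, list(labels),
                            "three-clade near-simultaneous divergence")
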