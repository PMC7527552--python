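"""Admixture graphs: prediction of f-statistics from drift edges and mixture
proportions, least-squares fitting to observed f-statistics, max-|Z| scoring
over the full f2/f3/f4 basis, and an incremental graph-growing search.

The model is the standard linearized drift approximation: each population's
allele frequency is the root frequency plus independent increments along the
edges it traverses, with admixture nodes mixing parental frequencies
linearly by their proportions.  Hence

    f2(A, B) = sum_e d_e (w_A(e) - w_B(e))^2

where w_X(e) is the expected usage of edge e by X's lineage (products of
admixture proportions summed over paths) and d_e the edge's drift length;
f3 and f4 follow by the usual linear identities.  Drift lengths are stored
in plain f2 units and reported in 1000 x F_ST units.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .fstats import FreqMatrix, block_jackknife
from .genotype_io import SNPMatrix

logger = logging.getLogger(__name__)

__all__ = ["AdmixtureGraph", "GraphFit", "ObservedF2", "enumerate_f_stats",
           "predict_f_stats", "fit_graph", "incremental_search",
           "merge_groups"]

DRIFT_UNIT = 1000.0  # reported drift = 1000 x f2-scale length


class AdmixtureGraph:
    """Rooted DAG with drift edges; nodes with two parents are admixture
    nodes whose incoming edges carry mixture proportions summing to 1."""

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    def copy(self) -> "AdmixtureGraph":
        out = AdmixtureGraph()
        out.g = self.g.copy()
        return out

    def add_edge(self, parent: str, child: str, length: float = 0.0,
                 prop: float | None = None) -> None:
        if length < 0:
            raise ValueError("drift lengths must be >= 0")
        self.g.add_edge(parent, child, length=float(length), prop=prop)
        self.validate(light=True)

    def validate(self, light: bool = False) -> None:
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError("admixture graph must be acyclic")
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if not light:
            if len(roots) != 1:
                raise ValueError(f"graph must have exactly one root, got {roots}")
            for n in self.g:
                ind = self.g.in_degree(n)
                if ind > 2:
                    raise ValueError(f"node {n} has {ind} parents (max 2)")
                if ind == 2:
                    props = [self.g.edges[p, n].get("prop")
                             for p in self.g.predecessors(n)]
                    if any(pr is None for pr in props):
                        raise ValueError(f"admixture node {n} missing proportions")
                    if abs(sum(props) - 1.0) > 1e-8:
                        raise ValueError(f"proportions at {n} must sum to 1")
                    if any(not 0.0 < pr < 1.0 for pr in props):
                        raise ValueError(f"proportions at {n} must lie in (0,1)")

    @property
    def root(self) -> str:
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError("graph must have exactly one root")
        return roots[0]

    def leaves(self) -> list[str]:
        return sorted(n for n in self.g if self.g.out_degree(n) == 0)

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.g.edges())

    def edge_usage(self, leaf: str) -> dict[tuple[str, str], float]:
        """Expected usage w_leaf(e) of every edge by the leaf's lineage."""
        if leaf not in self.g:
            raise KeyError(f"leaf {leaf!r} not in graph")
        flow = {leaf: 1.0}
        usage: dict[tuple[str, str], float] = {}
        for node in reversed(list(nx.topological_sort(self.g))):
            fl = flow.get(node, 0.0)
            if fl == 0.0:
                continue
            parents = list(self.g.predecessors(node))
            for p in parents:
                prop = self.g.edges[p, node].get("prop")
                w = fl * (prop if prop is not None else 1.0)
                usage[(p, node)] = usage.get((p, node), 0.0) + w
                flow[p] = flow.get(p, 0.0) + w
        return usage

    def f2_matrix(self, leaves: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Predicted f2 between all leaf pairs."""
        self.validate()
        leaves = leaves or self.leaves()
        edges = self.edge_list()
        lens = np.array([self.g.edges[e]["length"] for e in edges])
        W = np.zeros((len(leaves), len(edges)))
        for i, leaf in enumerate(leaves):
            us = self.edge_usage(leaf)
            for j, e in enumerate(edges):
                W[i, j] = us.get(e, 0.0)
        diff = W[:, None, :] - W[None, :, :]
        return np.einsum("ijk,k->ij", diff**2, lens), leaves

    def to_dot(self) -> str:
        lines = ["digraph admixture_graph {"]
        for u, v, data in self.g.edges(data=True):
            if data.get("prop") is not None:
                lines.append(
                    f'  "{u}" -> "{v}" [style=dotted, '
                    f'label="{100*data["prop"]:.0f}%"];')
            else:
                lines.append(
                    f'  "{u}" -> "{v}" [label="{DRIFT_UNIT*data["length"]:.0f}"];')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "edges": [{"parent": u, "child": v,
                       "length_1000fst": DRIFT_UNIT * d["length"],
                       "prop": d.get("prop")}
                      for u, v, d in self.g.edges(data=True)]})


def enumerate_f_stats(n: int, labels: list[str] | None = None):
    """All distinct f2 / f3 / f4 statistics over ``n`` populations.

    Counts: C(n,2) f2 (unordered pairs), n * C(n-1,2) f3 (ordered target,
    unordered source pair) and 3 * C(n,4) f4 (unordered quadruples, three
    pairings).  Returns (list of ("kind", pops), total count).
    """
    if n < 2:
        raise ValueError("need at least two populations")
    labels = labels or [f"P{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    stats: list[tuple[str, tuple[str, ...]]] = []
    for a, b in itertools.combinations(labels, 2):
        stats.append(("f2", (a, b)))
    for t in labels:
        for a, b in itertools.combinations([x for x in labels if x != t], 2):
            stats.append(("f3", (t, a, b)))
    for quad in itertools.combinations(labels, 4):
        a, b, c, d = quad
        stats.append(("f4", (a, b, c, d)))
        stats.append(("f4", (a, c, b, d)))
        stats.append(("f4", (a, d, b, c)))
    return stats, len(stats)


def _f_from_f2(kind: str, pops: tuple[str, ...], f2m: np.ndarray,
               index: dict[str, int]) -> float:
    """f3/f4 from pairwise f2 by the standard linear identities."""
    def g(a, b):
        return f2m[index[a], index[b]]

    if kind == "f2":
        return g(*pops)
    if kind == "f3":
        t, a, b = pops
        return 0.5 * (g(t, a) + g(t, b) - g(a, b))
    if kind == "f4":
        a, b, c, d = pops
        return 0.5 * (g(a, d) + g(b, c) - g(a, c) - g(b, d))
    raise ValueError(f"unknown statistic kind {kind!r}")


def predict_f_stats(graph: AdmixtureGraph, stats) -> np.ndarray:
    """Predicted values for a list of ("kind", pops) statistics."""
    f2m, leaves = graph.f2_matrix()
    index = {lab: i for i, lab in enumerate(leaves)}
    for kind, pops in stats:
        for p in pops:
            if p not in index:
                raise KeyError(f"population {p!r} missing from graph leaves")
    return np.array([_f_from_f2(k, p, f2m, index) for k, p in stats])


class ObservedF2:
    """Observed pairwise f2 with per-block sums, so any linear combination
    of f2 values (hence any f3/f4) gets a delete-one-block jackknife SE."""

    def __init__(self, f: FreqMatrix):
        self.pops = list(f.pops)
        P = len(self.pops)
        ids = np.unique(f.block_ids)
        self.block_num = {}
        self.block_den = {}
        self.f2 = np.zeros((P, P))
        self.se = np.zeros((P, P))
        for i, j in itertools.combinations(range(P), 2):
            pa, pb = f.freqs[i], f.freqs[j]
            ka, kb = f.counts[i], f.counts[j]
            ok = (ka >= 2) & (kb >= 2) & np.isfinite(pa) & np.isfinite(pb)
            with np.errstate(invalid="ignore", divide="ignore"):
                num = ((pa - pb) ** 2
                       - pa * (1 - pa) / np.maximum(ka - 1, 1)
                       - pb * (1 - pb) / np.maximum(kb - 1, 1))
            bn = np.array([num[ok & (f.block_ids == b)].sum() for b in ids])
            bd = np.array([float((ok & (f.block_ids == b)).sum()) for b in ids])
            self.block_num[(i, j)] = bn
            self.block_den[(i, j)] = bd
            est, se = block_jackknife(num[ok], np.ones(int(ok.sum())),
                                      f.block_ids[ok])
            self.f2[i, j] = self.f2[j, i] = est
            self.se[i, j] = self.se[j, i] = max(se, 1e-12)
        self.index = {p: i for i, p in enumerate(self.pops)}
        self._ids = ids

    def stat_estimate(self, kind: str, pops: tuple[str, ...]) -> tuple[float, float]:
        """Estimate and jackknife SE of one f-statistic, combining per-block
        f2 sums linearly across the involved pairs."""
        coefs: dict[tuple[int, int], float] = {}

        def add(a, b, c):
            i, j = sorted((self.index[a], self.index[b]))
            coefs[(i, j)] = coefs.get((i, j), 0.0) + c

        if kind == "f2":
            add(pops[0], pops[1], 1.0)
        elif kind == "f3":
            t, a, b = pops
            add(t, a, 0.5)
            add(t, b, 0.5)
            add(a, b, -0.5)
        elif kind == "f4":
            a, b, c, d = pops
            add(a, d, 0.5)
            add(b, c, 0.5)
            add(a, c, -0.5)
            add(b, d, -0.5)
        else:
            raise ValueError(kind)
        G = len(self._ids)
        tot = 0.0
        del_est = np.zeros(G)
        # per-pair ratios: statistic = sum_pairs coef * (sum num / sum den)
        bd_any = None
        for (i, j), c in coefs.items():
            bn = self.block_num[(i, j)]
            bd = self.block_den[(i, j)]
            pair_tot = bn.sum() / bd.sum()
            tot += c * pair_tot
            with np.errstate(invalid="ignore", divide="ignore"):
                del_est += c * (bn.sum() - bn) / np.maximum(bd.sum() - bd, 1e-300)
            bd_any = bd if bd_any is None else bd_any + bd
        m = bd_any
        n_tot = m.sum()
        h = n_tot / np.maximum(m, 1e-300)
        ps = G * tot - np.sum((1.0 - m / n_tot) * del_est)
        var = np.mean((h * tot - (h - 1.0) * del_est - ps) ** 2 / (h - 1.0))
        return float(tot), float(np.sqrt(max(var, 0.0)))


@dataclass
class GraphFit:
    graph: AdmixtureGraph
    residual_z: np.ndarray
    stats: list
    max_abs_z: float
    worst: tuple
    sse: float

    def __post_init__(self) -> None:
        if len(self.residual_z) and not np.isclose(
                self.max_abs_z, np.nanmax(np.abs(self.residual_z))):
            raise ValueError("max|Z| inconsistent with residuals")


def _free_parameters(topology: AdmixtureGraph):
    """Free edge lengths (non-admixture incoming edges) and admixture
    proportions (one free alpha per 2-parent node)."""
    edges = []
    admix_nodes = []
    for n in topology.g:
        if topology.g.in_degree(n) == 2:
            admix_nodes.append(n)
    for u, v in topology.edge_list():
        edges.append((u, v))
    return edges, sorted(admix_nodes)


def fit_graph(topology: AdmixtureGraph, observed: ObservedF2,
              seed: int = 0, n_starts: int = 5,
              full_stats: bool = True) -> GraphFit:
    """Fit drift lengths and admixture proportions by weighted least squares
    on the pairwise-f2 basis; score with residual Z over the full enumerated
    f2/f3/f4 set (or just f2 when ``full_stats`` is false).

    Identifiability is checked via the rank of the prediction Jacobian at a
    random interior point; a deficient rank logs a warning and the
    best-effort fit is returned.
    """
    topology = topology.copy()
    leaves = topology.leaves()
    for leaf in leaves:
        if leaf not in observed.index:
            raise KeyError(f"graph leaf {leaf!r} absent from observed data")
    edges, admix_nodes = _free_parameters(topology)
    n_e, n_a = len(edges), len(admix_nodes)
    pairs = list(itertools.combinations(leaves, 2))
    obs = np.array([observed.f2[observed.index[a], observed.index[b]]
                    for a, b in pairs])
    w = np.array([1.0 / observed.se[observed.index[a], observed.index[b]]
                  for a, b in pairs])

    def apply(x):
        lens = x[:n_e]
        alphas = x[n_e:]
        for (u, v), ln in zip(edges, lens):
            topology.g.edges[u, v]["length"] = float(ln)
        for node, al in zip(admix_nodes, alphas):
            ps = sorted(topology.g.predecessors(node))
            topology.g.edges[ps[0], node]["prop"] = float(al)
            topology.g.edges[ps[1], node]["prop"] = float(1.0 - al)

    def resid(x):
        apply(x)
        f2m, ls = topology.f2_matrix(leaves)
        pred = np.array([f2m[ls.index(a), ls.index(b)] for a, b in pairs])
        return (pred - obs) * w

    rng = np.random.default_rng(seed)
    scale = max(np.abs(obs).max(), 1e-4)
    lo = np.concatenate([np.zeros(n_e), np.full(n_a, 1e-3)])
    hi = np.concatenate([np.full(n_e, 10 * scale), np.full(n_a, 1 - 1e-3)])
    # identifiability probe
    x_probe = lo + (hi - lo) * rng.random(n_e + n_a)
    eps = 1e-6
    J = np.empty((len(pairs), len(x_probe)))
    r0 = resid(x_probe)
    for k in range(len(x_probe)):
        xp = x_probe.copy()
        xp[k] += eps * max(abs(xp[k]), 1.0)
        J[:, k] = (resid(xp) - r0) / (xp[k] - x_probe[k])
    rank = np.linalg.matrix_rank(J, tol=1e-8)
    if rank < len(x_probe):
        logger.warning("graph parameterization rank-deficient (%d < %d); "
                       "best-effort fit", rank, len(x_probe))
    best = None
    for s in range(n_starts):
        x0 = lo + (hi - lo) * rng.random(n_e + n_a)
        if s == 0:
            x0[:n_e] = scale * 0.5
            x0[n_e:] = 0.5
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    apply(best.x)
    stats = ([("f2", p) for p in pairs] if not full_stats
             else enumerate_f_stats(len(leaves), leaves)[0])
    pred = predict_f_stats(topology, stats)
    zs = np.empty(len(stats))
    for i, (kind, pops) in enumerate(stats):
        est, se = observed.stat_estimate(kind, pops)
        zs[i] = (est - pred[i]) / max(se, 1e-12)
    worst_i = int(np.nanargmax(np.abs(zs)))
    return GraphFit(topology, zs, stats, float(np.abs(zs[worst_i])),
                    stats[worst_i], float(2 * best.cost))


def _attachment_candidates(graph: AdmixtureGraph):
    """Edges a new leaf can be grafted onto (plus 'above root')."""
    return graph.edge_list()


def _graft_leaf(graph: AdmixtureGraph, edge: tuple[str, str], leaf: str,
                tag: str) -> AdmixtureGraph:
    g = graph.copy()
    u, v = edge
    mid = f"n_{tag}"
    data = g.g.edges[u, v]
    g.g.remove_edge(u, v)
    g.g.add_edge(u, mid, length=data["length"] / 2, prop=data.get("prop"))
    g.g.add_edge(mid, v, length=data["length"] / 2, prop=None)
    g.g.add_edge(mid, leaf, length=0.01, prop=None)
    return g


def _graft_admixed_leaf(graph: AdmixtureGraph, e1, e2, leaf, tag) -> AdmixtureGraph:
    g = graph.copy()
    mids = []
    for k, (u, v) in enumerate((e1, e2)):
        mid = f"n_{tag}_{k}"
        data = g.g.edges[u, v]
        g.g.remove_edge(u, v)
        g.g.add_edge(u, mid, length=data["length"] / 2, prop=data.get("prop"))
        g.g.add_edge(mid, v, length=data["length"] / 2, prop=None)
        mids.append(mid)
    ad = f"adm_{tag}"
    g.g.add_edge(mids[0], ad, length=0.0, prop=0.5)
    g.g.add_edge(mids[1], ad, length=0.0, prop=0.5)
    g.g.add_edge(ad, leaf, length=0.01, prop=None)
    if not nx.is_directed_acyclic_graph(g.g):
        return None
    return g


def _n_admixture(graph: AdmixtureGraph) -> int:
    return sum(1 for n in graph.g if graph.g.in_degree(n) == 2)


def incremental_search(skeleton_pops: list[str], remaining: list[str],
                       observed: ObservedF2, seed: int = 0,
                       allow_admixture: bool = True,
                       n_starts: int = 3) -> GraphFit:
    """Grow an admixture graph by incremental insertion.

    Builds the best-fitting rooted tree on the four skeleton populations
    (the first is used as the outgroup side of the root), then adds each
    remaining population in turn to every existing edge — and, when
    ``allow_admixture``, as a two-parent admixture of every edge pair —
    keeping the solution with minimal max|Z| (ties: fewer admixture events,
    then lexicographic attachment identity).  Deterministic per seed.
    """
    if len(skeleton_pops) != 4:
        raise ValueError("skeleton needs exactly four populations")
    rng = np.random.default_rng(seed)
    og, rest = skeleton_pops[0], skeleton_pops[1:]
    best_fit = None
    for pair in itertools.combinations(rest, 2):
        inner = [p for p in rest if p not in pair]
        g = AdmixtureGraph()
        g.g.add_edge("root", og, length=0.01)
        g.g.add_edge("root", "x1", length=0.01)
        g.g.add_edge("x1", "x2", length=0.01)
        g.g.add_edge("x2", pair[0], length=0.01)
        g.g.add_edge("x2", pair[1], length=0.01)
        g.g.add_edge("x1", inner[0], length=0.01)
        fit = fit_graph(g, observed, seed=int(rng.integers(2**31 - 1)),
                        n_starts=n_starts, full_stats=True)
        if best_fit is None or fit.max_abs_z < best_fit.max_abs_z:
            best_fit = fit
    for step, pop in enumerate(remaining):
        cands: list[tuple[float, int, str, GraphFit]] = []
        base = best_fit.graph
        edges = _attachment_candidates(base)
        for edge in edges:
            g = _graft_leaf(base, edge, pop, f"{step}_{edge[0]}_{edge[1]}")
            fit = fit_graph(g, observed, seed=int(rng.integers(2**31 - 1)),
                            n_starts=n_starts, full_stats=True)
            cands.append((fit.max_abs_z, _n_admixture(fit.graph),
                          f"t:{edge}", fit))
        if allow_admixture:
            for e1, e2 in itertools.combinations(edges, 2):
                g = _graft_admixed_leaf(base, e1, e2, pop, f"{step}a")
                if g is None:
                    continue
                try:
                    fit = fit_graph(g, observed,
                                    seed=int(rng.integers(2**31 - 1)),
                                    n_starts=n_starts, full_stats=True)
                except (ValueError, KeyError):
                    continue
                cands.append((fit.max_abs_z, _n_admixture(fit.graph),
                              f"a:{e1}|{e2}", fit))
        cands.sort(key=lambda c: (round(c[0], 6), c[1], c[2]))
        best_fit = cands[0][3]
        logger.info("added %s via %s, max|Z|=%.3f", pop, cands[0][2],
                    best_fit.max_abs_z)
    return best_fit


def merge_groups(m: SNPMatrix, group_map: dict[str, list[str]]) -> SNPMatrix:
    """Merge populations into named genetic groups (e.g. geographically
    close cultivars pooled into one group); accessions are relabeled and
    frequencies recomputed downstream from the pooled genotypes."""
    seen: dict[str, str] = {}
    for grp, members in group_map.items():
        for mem in members:
            if mem in seen:
                raise ValueError(f"population {mem!r} appears in two groups")
            seen[mem] = grp
    new_map = {acc: seen.get(pop, pop) for acc, pop in m.pop_map.items()}
    from dataclasses import replace
    return replace(m, pop_map=new_map)
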