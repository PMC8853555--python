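"""Admixture graphs: expected f-statistics, parameter fitting, model scoring.

An admixture graph is a rooted DAG in which drift edges carry lengths in
f2 units (variance of normalized allele-frequency change) and admixture
nodes mix two parent lineages with a pulse weight w.  For a leaf X, let
a_e(X) be the probability that a lineage sampled from X traverses drift
edge e (the product of admixture weights along each path, summed over
paths).  Allele-frequency covariances around the root are then

    C(X, Y) = sum_e length_e * a_e(X) * a_e(Y)

and every expected f-statistic is a linear combination of C entries:
f2(X,Y) = C(X,X) + C(Y,Y) - 2 C(X,Y), f3 and f4 by their algebraic
identities.  Fitting minimizes the generalized least-squares quadratic
form of observed minus expected f2/f3 basis statistics under the block
jackknife covariance: lengths enter linearly and are solved by
non-negative least squares at fixed weights; weights are optimized by
bounded quasi-Newton from random restarts.  The fit score is
-1/2 d' Q^-1 d (a Gaussian log-likelihood up to a constant), and model
comparison uses log-likelihood and worst-residual cut-offs.
"""

from __future__ import annotations

import copy as _copy
import warnings
import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .fstats import block_jackknife_cov
from .genio import BlockPartition, FreqTable

__all__ = [
    "DriftEdge", "AdmixNode", "AdmixtureGraph", "GraphFit", "ComparisonVerdict",
    "FitConfig", "ExpectedStats", "expected_stats", "GraphData",
    "fit_graph", "fit_graph_to_basis", "compare_fits", "has_trifurcation",
    "parse_graph", "format_graph", "read_graph", "write_graph",
]


class GraphError(ValueError):
    pass


@dataclass
class DriftEdge:
    name: str
    parent: str
    child: str
    length: float | None = None


@dataclass
class AdmixNode:
    child: str
    parentA: str
    parentB: str
    weight: float | None = None  # weight of parentA; parentB gets 1 - w
    fixed: bool = False


@dataclass
class AdmixtureGraph:
    """Rooted DAG with drift edges (lengths) and pulse admixture nodes."""

    root: str
    drift_edges: list[DriftEdge] = field(default_factory=list)
    admix_nodes: list[AdmixNode] = field(default_factory=list)
    leaf_map: dict[str, str] = field(default_factory=dict)  # leaf node -> population

    # -- structure ---------------------------------------------------------
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {self.root: None}
        for e in self.drift_edges:
            seen.setdefault(e.parent, None)
            seen.setdefault(e.child, None)
        for a in self.admix_nodes:
            seen.setdefault(a.child, None)
            seen.setdefault(a.parentA, None)
            seen.setdefault(a.parentB, None)
        return list(seen)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        for e in self.drift_edges:
            g.add_edge(e.parent, e.child, kind="drift", name=e.name)
        for a in self.admix_nodes:
            g.add_edge(a.parentA, a.child, kind="admix")
            g.add_edge(a.parentB, a.child, kind="admix")
        return g

    def leaves(self) -> list[str]:
        g = self.to_networkx()
        return [n for n in g.nodes if g.out_degree(n) == 0]

    def populations(self) -> list[str]:
        return [self.leaf_map[v] for v in self.leaves()]

    def edge(self, name: str) -> DriftEdge:
        for e in self.drift_edges:
            if e.name == name:
                return e
        raise KeyError(name)

    def validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a cycle")
        admix_children = {a.child for a in self.admix_nodes}
        if len(admix_children) != len(self.admix_nodes):
            raise GraphError("a node has more than one admixture definition")
        drift_parents: dict[str, int] = {}
        for e in self.drift_edges:
            drift_parents[e.child] = drift_parents.get(e.child, 0) + 1
        for v in g.nodes:
            if v == self.root:
                if v in drift_parents or v in admix_children:
                    raise GraphError("root must have no parents")
                continue
            nd = drift_parents.get(v, 0)
            if v in admix_children:
                if nd != 0:
                    raise GraphError(f"admixed node {v} also has a drift parent")
            elif nd != 1:
                raise GraphError(f"node {v} has {nd} drift parents (expected 1)")
        for v in g.nodes:
            if v != self.root and not nx.has_path(g, self.root, v):
                raise GraphError(f"node {v} not reachable from the root")
        leaves = set(self.leaves())
        for v in self.leaf_map:
            if v not in leaves:
                raise GraphError(f"labelled node {v} is not a leaf")
        for v in leaves:
            if v not in self.leaf_map:
                raise GraphError(f"leaf {v} has no population label")
        names = [e.name for e in self.drift_edges]
        if len(set(names)) != len(names):
            raise GraphError("duplicate drift edge names")

    def copy(self) -> "AdmixtureGraph":
        return _copy.deepcopy(self)

    # -- parameters --------------------------------------------------------
    def free_weights(self) -> list[AdmixNode]:
        return [a for a in self.admix_nodes if not a.fixed]

    def require_parameters(self) -> None:
        for e in self.drift_edges:
            if e.length is None:
                raise GraphError(f"drift edge {e.name!r} has no length set")
        for a in self.admix_nodes:
            if a.weight is None:
                raise GraphError(f"admixture into {a.child!r} has no weight set")


# ---------------------------------------------------------------------------
# graph text dialect

def parse_graph(text: str) -> AdmixtureGraph:
    """Parse the line-oriented graph dialect.

    ``root R`` / ``edge name parent child [length]`` /
    ``admix child parentA parentB [weight] [fixed]`` /
    ``label leaf population``.
    """
    root = None
    edges: list[DriftEdge] = []
    admix: list[AdmixNode] = []
    labels: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kw = tok[0]
        if kw == "root":
            root = tok[1]
        elif kw == "edge":
            length = float(tok[4]) if len(tok) > 4 else None
            edges.append(DriftEdge(tok[1], tok[2], tok[3], length))
        elif kw == "admix":
            weight = float(tok[4]) if len(tok) > 4 else None
            fixed = len(tok) > 5 and tok[5] == "fixed"
            admix.append(AdmixNode(tok[1], tok[2], tok[3], weight, fixed))
        elif kw == "label":
            labels[tok[1]] = tok[2]
        else:
            raise GraphError(f"unknown directive {kw!r}")
    if root is None:
        raise GraphError("no root directive")
    g = AdmixtureGraph(root, edges, admix, labels)
    g.validate()
    return g


def format_graph(G: AdmixtureGraph) -> str:
    out = [f"root {G.root}"]
    for e in G.drift_edges:
        s = f"edge {e.name} {e.parent} {e.child}"
        if e.length is not None:
            s += f" {e.length:.6g}"
        out.append(s)
    for a in G.admix_nodes:
        s = f"admix {a.child} {a.parentA} {a.parentB}"
        if a.weight is not None:
            s += f" {a.weight:.6g}"
            if a.fixed:
                s += " fixed"
        out.append(s)
    for leaf, pop in G.leaf_map.items():
        out.append(f"label {leaf} {pop}")
    return "\n".join(out) + "\n"


def read_graph(path) -> AdmixtureGraph:
    with open(path) as fh:
        return parse_graph(fh.read())


def write_graph(G: AdmixtureGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_graph(G))


# ---------------------------------------------------------------------------
# expected statistics

def path_probabilities(G: AdmixtureGraph) -> tuple[list[str], dict[str, np.ndarray]]:
    """Per-leaf probabilities of traversing each drift edge.

    Returns the drift-edge name order and, for each leaf node, the vector
    a_e(leaf) over that order.
    """
    for a in G.admix_nodes:
        if a.weight is None:
            raise GraphError(f"admixture into {a.child!r} has no weight set")
    edge_ix = {e.name: i for i, e in enumerate(G.drift_edges)}
    drift_parent = {e.child: e for e in G.drift_edges}
    admix_of = {a.child: a for a in G.admix_nodes}
    order = list(nx.topological_sort(G.to_networkx()))[::-1]  # leaves first
    out: dict[str, np.ndarray] = {}
    for leaf in G.leaves():
        mass = {leaf: 1.0}
        a_vec = np.zeros(len(G.drift_edges))
        for v in order:
            q = mass.get(v, 0.0)
            if q == 0.0 or v == G.root:
                continue
            if v in admix_of:
                an = admix_of[v]
                mass[an.parentA] = mass.get(an.parentA, 0.0) + an.weight * q
                mass[an.parentB] = mass.get(an.parentB, 0.0) + (1.0 - an.weight) * q
            else:
                e = drift_parent[v]
                a_vec[edge_ix[e.name]] += q
                mass[e.parent] = mass.get(e.parent, 0.0) + q
        out[leaf] = a_vec
    return [e.name for e in G.drift_edges], out


class ExpectedStats:
    """Closed-form expected f-statistics of a fully parameterized graph."""

    def __init__(self, G: AdmixtureGraph):
        G.require_parameters()
        self.graph = G
        edge_names, paths = path_probabilities(G)
        self.populations = [G.leaf_map[v] for v in G.leaves()]
        self._ix = {p: i for i, p in enumerate(self.populations)}
        lengths = np.array([e.length for e in G.drift_edges])
        A = np.stack([paths[v] for v in G.leaves()])  # leaves x edges
        self.path_matrix = A
        self.edge_names = edge_names
        self.C = (A * lengths[None, :]) @ A.T

    def f2(self, X: str, Y: str) -> float:
        i, j = self._ix[X], self._ix[Y]
        return float(self.C[i, i] + self.C[j, j] - 2.0 * self.C[i, j])

    def f3(self, X: str, A: str, B: str) -> float:
        x, a, b = self._ix[X], self._ix[A], self._ix[B]
        return float(self.C[x, x] - self.C[x, a] - self.C[x, b] + self.C[a, b])

    def f4(self, A: str, B: str, C: str, D: str) -> float:
        a, b, c, d = (self._ix[p] for p in (A, B, C, D))
        return float(self.C[a, c] - self.C[a, d] - self.C[b, c] + self.C[b, d])

    def basis(self, base: str) -> tuple[list[tuple], np.ndarray]:
        """The fitting basis: f2(base, X) and f3(base; X, Y) over non-base leaves."""
        labels = basis_labels(self.populations, base)
        vals = [self.f2(*lab[1]) if lab[0] == "f2" else self.f3(*lab[1]) for lab in labels]
        return labels, np.array(vals)


def expected_stats(G: AdmixtureGraph, base: str | None = None) -> ExpectedStats:
    """Expected f2/f3/f4 statistics of ``G`` (``base`` kept for basis calls)."""
    es = ExpectedStats(G)
    if base is not None and base not in es.populations:
        raise KeyError(f"base {base!r} is not a leaf population")
    return es


def basis_labels(populations: list[str], base: str) -> list[tuple]:
    others = [p for p in populations if p != base]
    labels: list[tuple] = [("f2", (base, x)) for x in others]
    labels += [("f3", (base, others[i], others[j]))
               for i in range(len(others)) for j in range(i + 1, len(others))]
    return labels


# ---------------------------------------------------------------------------
# observed statistics for fitting

@dataclass
class FitConfig:
    """Settings for graph fitting and model search.

    block_span: jackknife block width (Morgans).  cov_diag: fraction of the
    mean covariance diagonal added for regularization.  n_restarts: random
    restarts of the admixture-weight optimization.  tol: weight-optimizer
    precision.  lsq_mode: drop covariance off-diagonals.  zthresh: report
    only residuals with |Z| above it (0 = all).
    """

    block_span: float = 0.05
    cov_diag: float = 1e-4
    n_restarts: int = 100
    tol: float = 1e-4
    lsq_mode: bool = False
    trifurcation_tol: float = 1e-7
    zthresh: float = 0.0
    residual_scope: str = "hires"  # all leaf f2/f3/f4
    seed: int = 0
    base: str | None = None


def _jackknife_many(block_sums: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted jackknife mean and SE for many statistics sharing one SNP set.

    block_sums: g x d per-block sums of per-SNP terms; counts: g SNPs/block.
    """
    m = counts.astype(float)
    n = m.sum()
    g = m.size
    theta = block_sums.sum(axis=0) / n
    loo = (n * theta[None, :] - block_sums) / (n - m)[:, None]
    h = n / m
    tau = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    theta_bc = g * theta - ((1.0 - m / n)[:, None] * loo).sum(axis=0)
    var = (np.square(tau - theta_bc[None, :]) / (h - 1.0)[:, None]).sum(axis=0) / g
    return theta, np.sqrt(np.maximum(var, 0.0))


class GraphData:
    """Observed f-statistic summaries for one population set and SNP set.

    Precomputes, on the complete-case SNPs across all populations, the
    per-block frequency cross-products and bias-correction sums from which
    every f2/f3/f4 block sum is a four-term linear combination.  Shared
    across all candidate models in a topology search.
    """

    def __init__(self, F: FreqTable, populations: list[str], blocks: BlockPartition):
        self.populations = list(populations)
        idx = F.index_of(self.populations)
        mask = (F.total[idx] > 0).all(axis=0)
        if mask.sum() == 0:
            raise ValueError("no SNPs with defined frequencies in every population")
        p = F.freq[idx][:, mask]                      # P x S
        c = F.total[idx][:, mask].astype(float)
        hc = p * (1.0 - p) / np.maximum(c - 1.0, 1.0)  # h/c per pop per SNP
        bid = blocks.block_of[mask]
        # remap to dense consecutive block ids
        uniq, dense = np.unique(bid, return_inverse=True)
        g = uniq.size
        if g < 2:
            raise ValueError("need >= 2 non-empty jackknife blocks")
        P = len(self.populations)
        S = p.shape[1]
        self.counts = np.bincount(dense, minlength=g).astype(float)
        # per-block cross products: g x P x P
        PB = np.zeros((g, P, P))
        HB = np.zeros((g, P))
        for b in range(g):
            sel = dense == b
            pb = p[:, sel]
            PB[b] = pb @ pb.T
            HB[b] = hc[:, sel].sum(axis=1)
        self.PB, self.HB = PB, HB
        self.n_blocks = g
        self.n_snps = int(S)
        self._basis_cache: dict[tuple, tuple] = {}
        self._resid_cache: dict[str, tuple] = {}

    def _pi(self, pops) -> np.ndarray:
        look = {p: i for i, p in enumerate(self.populations)}
        return np.array([look[p] for p in pops], dtype=int)

    def _stat_block_sums(self, labels: list[tuple]) -> np.ndarray:
        """g x n_stats per-block sums of per-SNP terms (bias-corrected)."""
        PB, HB = self.PB, self.HB
        cols = []
        for kind, pops in labels:
            i = self._pi(pops)
            if kind == "f2":
                a, b = i
                s = PB[:, a, a] - 2 * PB[:, a, b] + PB[:, b, b] - HB[:, a] - HB[:, b]
            elif kind == "f3":
                x, a, b = i
                s = PB[:, x, x] - PB[:, x, a] - PB[:, x, b] + PB[:, a, b] - HB[:, x]
            else:  # f4
                a, b, c, d = i
                s = PB[:, a, c] - PB[:, a, d] - PB[:, b, c] + PB[:, b, d]
            cols.append(s)
        return np.stack(cols, axis=1)

    def basis(self, base: str, cov_diag: float, lsq_mode: bool) -> tuple[list[tuple], np.ndarray, np.ndarray]:
        """Observed basis vector and regularized jackknife covariance."""
        key = (base, cov_diag, lsq_mode)
        if key not in self._basis_cache:
            labels = basis_labels(self.populations, base)
            sums = self._stat_block_sums(labels)
            est = sums / self.counts[:, None]
            y, Q = block_jackknife_cov(est, self.counts)
            if lsq_mode:
                Q = np.diag(np.diag(Q))
            Q = Q + cov_diag * float(np.mean(np.diag(Q))) * np.eye(len(y))
            self._basis_cache[key] = (labels, y, Q)
        return self._basis_cache[key]

    def residual_stats(self) -> tuple[list[tuple], np.ndarray, np.ndarray]:
        """Observed value and jackknife SE for every leaf f2, f3 and f4."""
        if "hires" not in self._resid_cache:
            pops = self.populations
            P = len(pops)
            labels: list[tuple] = []
            for i in range(P):
                for j in range(i + 1, P):
                    labels.append(("f2", (pops[i], pops[j])))
            for x in range(P):
                rest = [k for k in range(P) if k != x]
                for i in range(len(rest)):
                    for j in range(i + 1, len(rest)):
                        labels.append(("f3", (pops[x], pops[rest[i]], pops[rest[j]])))
            from itertools import combinations
            for a, b, c, d in combinations(range(P), 4):
                labels.append(("f4", (pops[a], pops[b], pops[c], pops[d])))
                labels.append(("f4", (pops[a], pops[c], pops[b], pops[d])))
                labels.append(("f4", (pops[a], pops[d], pops[b], pops[c])))
            sums = self._stat_block_sums(labels)
            obs, se = _jackknife_many(sums, self.counts)
            self._resid_cache["hires"] = (labels, obs, se)
        return self._resid_cache["hires"]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GraphFit:
    """A fitted admixture graph with its score and residual diagnostics."""

    graph: AdmixtureGraph
    score: float
    worst_residual: float
    residuals: pd.DataFrame | None
    n_snps: int
    model_id: str = ""
    seed: int = 0
    unidentifiable_edges: list[str] = field(default_factory=list)
    backbone_edges: frozenset[str] | None = None

    @property
    def n_admix(self) -> int:
        return len(self.graph.admix_nodes)


def _design_matrix(G: AdmixtureGraph, labels: list[tuple]) -> tuple[np.ndarray, np.ndarray]:
    """Length-coefficient matrix of the basis at the graph's current weights."""
    _, paths = path_probabilities(G)
    leaves = G.leaves()
    pop_of = G.leaf_map
    A = {pop_of[v]: paths[v] for v in leaves}
    rows = []
    for kind, pops in labels:
        if kind == "f2":
            b, x = pops
            rows.append(np.square(A[x] - A[b]))
        else:
            b, x, y = pops
            rows.append((A[x] - A[b]) * (A[y] - A[b]))
    return np.array(rows), np.stack([A[p] for p in sorted(A)])


def _nnls_lengths(W: np.ndarray, y: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, float]:
    WD = W @ D
    Wy = W @ y
    lengths, _ = scipy.optimize.nnls(WD, Wy)
    resid = Wy - WD @ lengths
    return lengths, float(resid @ resid)


def fit_graph_to_basis(topology: AdmixtureGraph, labels: list[tuple], y: np.ndarray,
                       Q: np.ndarray, config: FitConfig | None = None,
                       model_id: str = "") -> tuple[AdmixtureGraph, float, list[str]]:
    """Fit lengths and free weights of ``topology`` to an observed basis.

    Returns the parameterized graph, the score -1/2 d'Q^-1 d, and the
    names of length-unidentifiable edges (zero path support everywhere).
    """
    config = config or FitConfig()
    try:
        L = scipy.linalg.cholesky(Q, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular regularized covariance; increase cov_diag") from exc
    W = scipy.linalg.solve_triangular(L, np.eye(len(y)), lower=True)
    g = topology.copy()
    free = g.free_weights()
    for a in g.admix_nodes:
        if a.fixed and a.weight is None:
            raise GraphError(f"fixed admixture into {a.child!r} has no weight")

    def solve_at(wvec: np.ndarray) -> tuple[float, np.ndarray]:
        for a, w in zip(free, wvec):
            a.weight = float(np.clip(w, 0.0, 1.0))
        D, _ = _design_matrix(g, labels)
        lengths, qform = _nnls_lengths(W, y, D)
        return qform, lengths

    if not free:
        for a in g.admix_nodes:
            if a.weight is None:
                a.weight = 0.5
        qform, lengths = solve_at(np.empty(0))
        best_w = np.empty(0)
    else:
        rng = np.random.default_rng([config.seed, zlib.crc32(model_id.encode()) & 0x7FFFFFFF])
        inits = [np.full(len(free), 0.5)]
        have = [a.weight for a in free]
        if all(w is not None for w in have):
            inits.append(np.array(have, dtype=float))
        while len(inits) < max(config.n_restarts, 1):
            inits.append(rng.uniform(0.02, 0.98, size=len(free)))
        best = (np.inf, None, None)
        for x0 in inits:
            res = scipy.optimize.minimize(
                lambda w: solve_at(w)[0], x0, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * len(free),
                options={"maxiter": 200, "ftol": config.tol * 1e-3, "eps": 1e-5})
            if res.fun < best[0]:
                best = (res.fun, res.x.copy(), None)
        qform, lengths = solve_at(best[1])
        best_w = best[1]
    for a, w in zip(free, best_w):
        a.weight = float(np.clip(w, 0.0, 1.0))
    D, _ = _design_matrix(g, labels)
    support = np.abs(D).max(axis=0)
    unident = [e.name for e, s in zip(g.drift_edges, support) if s < 1e-12]
    if unident:
        warnings.warn(f"unidentifiable edge lengths (no path support): {unident}")
    for e, ln in zip(g.drift_edges, lengths):
        e.length = float(ln)
    return g, -0.5 * qform, unident


def _residual_table(es: ExpectedStats, data: GraphData, zthresh: float) -> tuple[pd.DataFrame, float]:
    labels, obs, se = data.residual_stats()
    exp = np.empty(len(labels))
    for k, (kind, pops) in enumerate(labels):
        exp[k] = getattr(es, kind)(*pops)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (obs - exp) / se, 0.0)
    worst = float(np.abs(z).max()) if len(z) else 0.0
    df = pd.DataFrame({
        "kind": [lab[0] for lab in labels],
        "populations": [",".join(lab[1]) for lab in labels],
        "observed": obs, "expected": exp, "se": se, "z": z,
    })
    if zthresh > 0:
        df = df[np.abs(df["z"]) >= zthresh].reset_index(drop=True)
    return df, worst


def fit_graph(topology: AdmixtureGraph, F: FreqTable, blocks: BlockPartition,
              config: FitConfig | None = None, data: GraphData | None = None,
              model_id: str = "", with_residuals: bool = True) -> GraphFit:
    """Fit all free parameters of ``topology`` to observed allele frequencies."""
    config = config or FitConfig()
    topology.validate()
    pops = topology.populations()
    if data is None:
        data = GraphData(F, pops, blocks)
    base = config.base or data.populations[0]
    labels, y, Q = data.basis(base, config.cov_diag, config.lsq_mode)
    fitted, score, unident = fit_graph_to_basis(topology, labels, y, Q, config, model_id)
    residuals, worst = (None, 0.0)
    if with_residuals:
        residuals, worst = _residual_table(ExpectedStats(fitted), data, config.zthresh)
    return GraphFit(fitted, score, worst, residuals, data.n_snps,
                    model_id=model_id, seed=config.seed, unidentifiable_edges=unident)


# ---------------------------------------------------------------------------
# model comparison

@dataclass
class ComparisonVerdict:
    preferred: str | None      # model id, or None on a tie / double discard
    rule_applied: str          # delta_ll_10 | worst_resid_0.5 | delta_ll_3 | trifurcation_filter
    margin: float
    tied: bool = False


def has_trifurcation(fit: GraphFit, tol: float = 1e-7) -> bool:
    """A zero-length backbone (internal, non-attachment) drift edge.

    Backbone edges are taken from ``fit.backbone_edges`` when a topology
    search recorded them; otherwise every internal drift edge (child not a
    leaf) counts as backbone.
    """
    g = fit.graph
    if fit.backbone_edges is not None:
        names = fit.backbone_edges
    else:
        leaves = set(g.leaves())
        # root-child edges carry an arbitrary split of one identifiable sum;
        # a zero there is root-placement freedom, not a trifurcation
        names = {e.name for e in g.drift_edges
                 if e.child not in leaves and e.parent != g.root}
    for e in g.drift_edges:
        if e.name in names and e.length is not None and e.length <= tol:
            return True
    return False


def compare_fits(A: GraphFit, B: GraphFit, trifurcation_tol: float = 1e-7) -> ComparisonVerdict:
    """Apply the model-selection cut-offs to two fits on the same data.

    Different admixture counts: the more complex model is preferred only if
    it gains > 10 log-units or reduces the worst residual by > 0.5 SE.
    Equal counts: fits within 3 log-units are tied, otherwise the higher
    score wins.  A fit with a trifurcation is discarded first.
    """
    if A.n_snps != B.n_snps:
        raise ValueError("fits are on different SNP sets and cannot be compared")
    ta, tb = has_trifurcation(A, trifurcation_tol), has_trifurcation(B, trifurcation_tol)
    if ta or tb:
        if ta and tb:
            return ComparisonVerdict(None, "trifurcation_filter", 0.0)
        keep = B if ta else A
        return ComparisonVerdict(keep.model_id, "trifurcation_filter", 0.0)
    if A.n_admix == B.n_admix:
        hi, lo = (A, B) if A.score >= B.score else (B, A)
        delta = hi.score - lo.score
        if delta <= 3.0:
            return ComparisonVerdict(None, "delta_ll_3", delta, tied=True)
        return ComparisonVerdict(hi.model_id, "delta_ll_3", delta)
    simple, cplx = (A, B) if A.n_admix < B.n_admix else (B, A)
    gain = cplx.score - simple.score
    if gain > 10.0:
        return ComparisonVerdict(cplx.model_id, "delta_ll_10", gain)
    wr_red = simple.worst_residual - cplx.worst_residual
    if wr_red > 0.5:
        return ComparisonVerdict(cplx.model_id, "worst_resid_0.5", wr_red)
    return ComparisonVerdict(simple.model_id, "delta_ll_10", gain)
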