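"""Synthetic genotypes drifted along a known admixture graph.

The generator realizes the statistical model that underlies all
f-statistic machinery: a root allele frequency p0 is drawn per SNP
(uniform by default), each drift edge of length l replaces the frequency
by a Balding-Nichols Beta draw with conditional mean p and variance
l * p(1-p) (an absorbing boundary at fixation), and an admixture node
mixes its parents' frequencies linearly with weight w.  The Beta law
keeps the first two conditional moments exact at every depth, so raw
expected f-statistics follow the path-probability closed form of
:mod:`akit.graphfit` with per-edge heterozygosity-rescaled lengths and
every estimator can be validated against known truth (a clamped-normal
increment is available as ``drift_law="normal"``; it biases deep
statistics through boundary clamping).  Diploid genotypes are
binomial(2, p) per sample with independent per-call missingness.

The model deliberately omits linkage, selection, sequencing error and
array ascertainment; genetic positions are synthetic and uniform, so
jackknife blocks carry near-equal SNP counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graphfit
from .genio import MISSING, FreqTable, GenotypeMatrix
from .graphfit import AdmixtureGraph, ExpectedStats

__all__ = ["SimSpec", "SimTruth", "simulate_graph_freqs", "sample_genotypes",
           "simulate_dataset", "freqs_as_table", "truth_stats",
           "effective_truth_graph", "root_heterozygosity",
           "preset_skeleton", "preset_graph", "preset_spec"]


@dataclass
class SimSpec:
    """Conditions of one synthetic dataset.

    Drift lengths are in f2 units; the normal-increment approximation is
    accurate for lengths <= 0.1 (warned above, rejected above 0.25).
    """

    graph: AdmixtureGraph
    n_snps: int = 100_000
    root_freq_range: tuple[float, float] = (0.05, 0.95)
    samples_per_pop: dict[str, int] | int = 10
    missing_rate: float = 0.0
    n_chromosomes: int = 5
    map_length: float = 1.0  # Morgans per chromosome
    seed: int = 0
    drift_law: str = "beta"  # "beta" (exact moments) or "normal" (clamped)

    def __post_init__(self) -> None:
        self.graph.require_parameters()
        for e in self.graph.drift_edges:
            if e.length > 0.25:
                raise ValueError(f"edge {e.name}: length {e.length} outside the "
                                 "validity domain of the drift approximation (<= 0.25)")
            if e.length > 0.1:
                warnings.warn(f"edge {e.name}: length {e.length} > 0.1; "
                              "clamping bias may be noticeable")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    def samples_for(self, pop: str) -> int:
        if isinstance(self.samples_per_pop, int):
            return self.samples_per_pop
        return self.samples_per_pop[pop]


@dataclass
class SimTruth:
    """Closed-form expected statistics of the generating graph."""

    expected: ExpectedStats
    spec: SimSpec

    def f2(self, X, Y):
        return self.expected.f2(X, Y)

    def f3(self, X, A, B):
        return self.expected.f3(X, A, B)

    def f4(self, A, B, C, D):
        return self.expected.f4(A, B, C, D)


def simulate_graph_freqs(spec: SimSpec, rng: np.random.Generator | None = None) -> tuple[list[str], np.ndarray]:
    """Per-population allele-frequency matrix (populations x SNPs)."""
    rng = rng or np.random.default_rng(spec.seed)
    G = spec.graph
    p0 = rng.uniform(*spec.root_freq_range, size=spec.n_snps)
    freqs = {G.root: p0}
    admix_of = {a.child: a for a in G.admix_nodes}
    drift_parent = {e.child: e for e in G.drift_edges}
    import networkx as nx
    for v in nx.topological_sort(G.to_networkx()):
        if v == G.root:
            continue
        if v in admix_of:
            a = admix_of[v]
            freqs[v] = a.weight * freqs[a.parentA] + (1.0 - a.weight) * freqs[a.parentB]
        else:
            e = drift_parent[v]
            p = freqs[e.parent]
            freqs[v] = _drift(p, e.length, spec.drift_law, rng)
    leaves = G.leaves()
    pops = [G.leaf_map[v] for v in leaves]
    return pops, np.stack([freqs[v] for v in leaves])


def _drift(p: np.ndarray, length: float, law: str, rng: np.random.Generator) -> np.ndarray:
    if length == 0.0:
        return p.copy()
    if law == "normal":
        sd = np.sqrt(length * p * (1.0 - p))
        return np.clip(p + rng.normal(0.0, 1.0, size=p.shape) * sd, 0.0, 1.0)
    if law != "beta":
        raise ValueError(f"unknown drift law {law!r}")
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)  # fixed sites stay fixed
    k = (1.0 - length) / length
    out[seg] = rng.beta(p[seg] * k, (1.0 - p[seg]) * k)
    return out


def _snp_table(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    per = -(-spec.n_snps // spec.n_chromosomes)  # ceil
    chroms, gpos, ppos = [], [], []
    for c in range(spec.n_chromosomes):
        k = min(per, spec.n_snps - c * per)
        if k <= 0:
            break
        chroms += [str(c + 1)] * k
        gpos += list(np.linspace(0.0, spec.map_length, k, endpoint=False))
        ppos += list((np.arange(k) + 1) * 1000)
    alleles = rng.choice(list("ACGT"), size=(len(chroms), 2))
    flip = alleles[:, 0] == alleles[:, 1]
    alleles[flip, 1] = np.where(alleles[flip, 0] == "A", "G", "A")
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(chroms))],
        "chromosome": chroms,
        "genetic_pos": gpos,
        "physical_pos": np.array(ppos, dtype=np.int64),
        "allele1": alleles[:, 0],
        "allele2": alleles[:, 1],
    })


def sample_genotypes(pops: list[str], freqs: np.ndarray, spec: SimSpec,
                     rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Binomial diploid calls from population frequencies, with missingness."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    snps = _snp_table(spec, rng)
    sample_rows, call_rows = [], []
    for i, pop in enumerate(pops):
        n = spec.samples_for(pop)
        calls = rng.binomial(2, freqs[i][None, :], size=(n, spec.n_snps)).astype(np.int8)
        if spec.missing_rate > 0:
            calls[rng.random((n, spec.n_snps)) < spec.missing_rate] = MISSING
        call_rows.append(calls)
        sample_rows += [(f"{pop}_{k}", pop) for k in range(n)]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    return GenotypeMatrix(samples, snps, np.vstack(call_rows))


def simulate_dataset(spec: SimSpec) -> GenotypeMatrix:
    """Frequencies and genotypes in one deterministic pass from the seed."""
    rng = np.random.default_rng(spec.seed)
    pops, freqs = simulate_graph_freqs(spec, rng)
    return sample_genotypes(pops, freqs, spec, rng)


def freqs_as_table(pops: list[str], freqs: np.ndarray, spec: SimSpec,
                   scale: int = 10**6) -> FreqTable:
    """Wrap exact population frequencies as a FreqTable with huge totals.

    Useful for noise-free checks: sampling corrections become negligible
    at the given pseudo-count scale.
    """
    rng = np.random.default_rng(spec.seed)
    snps = _snp_table(spec, rng)
    count1 = np.rint(freqs * scale).astype(np.int64)
    total = np.full_like(count1, scale)
    return FreqTable(list(pops), snps, count1, total)


def root_heterozygosity(root_freq_range: tuple[float, float]) -> float:
    """E[p0 (1 - p0)] under the uniform root-frequency law."""
    lo, hi = root_freq_range
    mean = (lo + hi) / 2.0
    second = (hi - lo) ** 2 / 12.0 + mean ** 2
    return mean - second


def effective_truth_graph(spec: SimSpec) -> AdmixtureGraph:
    """The generating graph with lengths rescaled to raw f2 units.

    Drift lengths l are defined on the normalized scale (increment
    variance l * p(1-p)), while the f-statistic estimators work on raw
    frequencies.  Under the normal-increment model the raw-scale expected
    statistics are the same closed forms with effective lengths
    l_e * E[h_parent(e)], where the expected heterozygosity of each node
    follows exactly from the root law and the deviation covariances
    E[(p_u - p0)(p_v - p0)] accumulated down the graph.
    """
    import networkx as nx
    G = spec.graph
    h_root = root_heterozygosity(spec.root_freq_range)
    admix_of = {a.child: a for a in G.admix_nodes}
    drift_parent = {e.child: e for e in G.drift_edges}
    order = list(nx.topological_sort(G.to_networkx()))
    cov: dict[tuple[str, str], float] = {}

    def C(u, v):
        return cov.get((u, v), cov.get((v, u), 0.0))

    eff: dict[str, float] = {}
    done: list[str] = []
    for v in order:
        if v == G.root:
            done.append(v)
            continue
        if v in admix_of:
            a = admix_of[v]
            w = a.weight
            for u in done:
                cov[(v, u)] = w * C(a.parentA, u) + (1.0 - w) * C(a.parentB, u)
            cov[(v, v)] = (w * w * C(a.parentA, a.parentA)
                           + (1 - w) * (1 - w) * C(a.parentB, a.parentB)
                           + 2 * w * (1 - w) * C(a.parentA, a.parentB))
        else:
            e = drift_parent[v]
            p = e.parent
            h_parent = max(h_root - C(p, p), 0.0)
            eff[e.name] = e.length * h_parent
            for u in done:
                cov[(v, u)] = C(p, u)
            cov[(v, v)] = C(p, p) + eff[e.name]
        done.append(v)
    out = G.copy()
    for e in out.drift_edges:
        e.length = eff[e.name]
    return out


def truth_stats(spec: SimSpec) -> SimTruth:
    """Closed-form expected f-statistics of the generating process, on the
    raw-frequency scale the estimators measure (delegates to
    :func:`akit.graphfit.expected_stats` on the effective-length graph)."""
    return SimTruth(graphfit.expected_stats(effective_truth_graph(spec)), spec)


# ---------------------------------------------------------------------------
# bundled preset: an 11-leaf skeleton-like graph plus admixed targets

PRESET_SKELETON = """
root R
edge e0    R    anc     0.01
edge eO1   R    Out1    0.10
edge eO2   anc  Out2    0.10
edge e1    anc  mod     0.02
edge eAfr  mod  African 0.06
edge e2    mod  eur     0.03
edge eWE0  eur  we      0.02
edge eWE   we   WestEurasian 0.02
edge e3    eur  eas     0.02
edge eHG0  eas  hgc     0.03
edge eHGa  hgc  hg      0.03
edge eHG   hg   HunterGatherer 0.04
edge ePap  hgc  Papuan  0.08
edge e4    eas  ea      0.03
edge e5    ea   ea1     0.015
edge eEA1  ea1  EastAsian1 0.02
edge eEA2  ea1  EastAsian2 0.025
edge e6    ea   ea2     0.01
edge eEA3  ea2  EastAsian3 0.02
edge eEA4  ea2  EastAsian4 0.03
edge eSAS  sas  SouthAsian 0.02
admix sas we hg 0.55
label Out1 Outgroup1
label Out2 Outgroup2
label African African
label WestEurasian WestEurasian
label HunterGatherer HunterGatherer
label Papuan Papuan
label EastAsian1 EastAsian1
label EastAsian2 EastAsian2
label EastAsian3 EastAsian3
label EastAsian4 EastAsian4
label SouthAsian SouthAsian
"""


def preset_skeleton() -> AdmixtureGraph:
    """The bundled 11-leaf skeleton-like graph.

    Two deep outgroup-like leaves, an African-like leaf, a West
    Eurasian-related leaf, a deeply diverged hunter-gatherer leaf plus a
    Papuan-like relative, a four-leaf East/Southeast Asian clade and a
    South Asian-like leaf admixed (55/45) between the West Eurasian and
    hunter-gatherer lineages.
    """
    return graphfit.parse_graph(PRESET_SKELETON)


def _split_edge(g: AdmixtureGraph, edge_name: str, node: str) -> None:
    e = g.edge(edge_name)
    g.drift_edges.remove(e)
    half = (e.length or 0.0) / 2.0
    g.drift_edges.append(graphfit.DriftEdge(e.name + "_u", e.parent, node, half))
    g.drift_edges.append(graphfit.DriftEdge(e.name + "_d", node, e.child, half))


def preset_graph(attach: tuple[str, ...] = ("eEA3",),
                 fractions: tuple[float, ...] = (1.0,),
                 target: str = "Target",
                 leg_length: float = 0.004) -> AdmixtureGraph:
    """Truth graph: the preset skeleton plus one admixed target leaf.

    ``attach`` names 1-3 skeleton drift edges the target draws ancestry
    from (each split at its midpoint); ``fractions`` are the overall
    ancestry proportions (must sum to 1).  One component: an unadmixed
    attachment.  Multiple components: each split node grows a short
    private leg and the legs feed cascaded two-parent mixture nodes.
    """
    if len(attach) != len(fractions) or not 1 <= len(attach) <= 3:
        raise ValueError("attach and fractions must both have 1-3 entries")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    g = preset_skeleton()
    nodes = []
    for i, en in enumerate(attach):
        node = f"tsplit{i}"
        _split_edge(g, en, node)
        nodes.append(node)
    if len(nodes) == 1:
        hang = nodes[0]
    else:
        legs = []
        for i, node in enumerate(nodes):
            leg = f"tcomp{i}"
            g.drift_edges.append(graphfit.DriftEdge(f"tlegc{i}", node, leg, leg_length))
            legs.append(leg)
        if len(legs) == 2:
            g.admix_nodes.append(graphfit.AdmixNode("tmix", legs[0], legs[1], fractions[0]))
            hang = "tmix"
        else:
            w2 = fractions[0] + fractions[1]
            g.admix_nodes.append(graphfit.AdmixNode("tmix1", legs[0], legs[1],
                                                    fractions[0] / w2))
            g.admix_nodes.append(graphfit.AdmixNode("tmix2", "tmix1", legs[2], w2))
            hang = "tmix2"
    g.drift_edges.append(graphfit.DriftEdge("tleg", hang, "Tleaf", 0.005))
    g.leaf_map["Tleaf"] = target
    g.validate()
    return g


def preset_spec(sas_fraction: float = 0.0, n_snps: int = 20_000, seed: int = 0,
                samples_per_pop: int = 10, missing_rate: float = 0.0,
                target_edge: str = "eEA3") -> SimSpec:
    """A ready-to-run SimSpec: target on ``target_edge`` with an optional
    South Asian-like ancestry fraction."""
    if sas_fraction > 0.0:
        graph = preset_graph((target_edge, "eSAS"), (1.0 - sas_fraction, sas_fraction))
    else:
        graph = preset_graph((target_edge,), (1.0,))
    return SimSpec(
        graph=graph,
        n_snps=n_snps,
        samples_per_pop=samples_per_pop,
        missing_rate=missing_rate,
        n_chromosomes=10,
        map_length=1.0,
        seed=seed,
    )
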