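"""Exhaustive target mapping on a skeleton graph, and skeleton construction.

A target population is attached to a fixed, well-fitting skeleton graph
in every possible way: an unordered set of 1-3 candidate drift edges is
chosen; each chosen edge is split by a new node; with one edge the
target hangs from the split node as an unadmixed branch, with two or
three the split nodes feed cascaded two-parent mixture nodes from which
the target hangs.  For E candidate edges this yields E + C(E,2) + C(E,3)
models (E = 33 gives 33 + 528 + 5,456 = 6,017).  Every model is fitted;
models with a trifurcation (a zero-length backbone edge) are discarded;
models with more admixture waves are preferred only when they gain more
than 10 log-units of score or reduce the worst residual by more than
0.5 SE, and models with equally many waves tie when within 3 log-units.

Skeleton construction applies the same mapping to one population at a
time, adopting the single best model before the next addition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .genio import BlockPartition, FreqTable
from .graphfit import (AdmixNode, AdmixtureGraph, DriftEdge, FitConfig, GraphData,
                       GraphFit, fit_graph, has_trifurcation)

__all__ = ["AttachmentModel", "MappingReport", "enumerate_attachments",
           "map_target", "build_skeleton", "SkeletonTieError"]

log = logging.getLogger(__name__)


class SkeletonTieError(RuntimeError):
    """Raised when skeleton construction cannot adopt a unique best model."""

    def __init__(self, target: str, tied_ids: list[str]):
        super().__init__(f"tie while adding {target!r}: {tied_ids} "
                         "(adjudicate manually and restrict the candidate edges)")
        self.tied_ids = tied_ids


@dataclass
class AttachmentModel:
    """One candidate placement of a target on a skeleton graph."""

    target: str
    edges: tuple[str, ...]           # 1-3 distinct skeleton drift edges
    skeleton: AdmixtureGraph = field(repr=False)
    fit: GraphFit | None = None

    @property
    def n_admix(self) -> int:
        return len(self.edges) - 1

    @property
    def model_id(self) -> str:
        return f"{self.target}@" + "+".join(self.edges)

    def derive(self) -> AdmixtureGraph:
        """Build the attachment topology (free parameters unset)."""
        g = self.skeleton.copy()
        for e in g.drift_edges:
            e.length = None
        splits = []
        for i, name in enumerate(self.edges):
            e = g.edge(name)
            g.drift_edges.remove(e)
            node = f"_att{i}_{self.target}"
            g.drift_edges.append(DriftEdge(f"{name}_u", e.parent, node))
            g.drift_edges.append(DriftEdge(f"{name}_d", node, e.child))
            splits.append(node)
        if len(splits) == 1:
            hang = splits[0]
        else:
            prev = splits[0]
            for i, node in enumerate(splits[1:], start=1):
                mix = f"_mix{i}_{self.target}"
                g.admix_nodes.append(AdmixNode(mix, prev, node))
                prev = mix
            hang = prev
        leaf = f"_leaf_{self.target}"
        g.drift_edges.append(DriftEdge(f"_attach_{self.target}", hang, leaf))
        g.leaf_map[leaf] = self.target
        g.validate()
        return g

    def backbone_edges(self) -> frozenset[str]:
        """Internal drift edges of the derived graph, excluding the target's
        own attachment leg and the root-child edges (split halves of
        internal skeleton edges count)."""
        g = self.derive()
        leaves = set(g.leaves())
        # root-child edges are excluded: only their sum is identifiable (the
        # root slides along them), so a zero there is not a trifurcation
        return frozenset(e.name for e in g.drift_edges
                         if e.child not in leaves and e.parent != g.root
                         and e.name != f"_attach_{self.target}")


@dataclass
class MappingReport:
    target: str
    models_tested: int
    best_models: list[AttachmentModel]
    discarded_trifurcations: int
    n_failed: int
    table: pd.DataFrame  # one row per model: edges, n_admix, score, worst residual


def candidate_edges(skeleton: AdmixtureGraph, excluded: set[str] | None = None) -> list[str]:
    """Drift edges a target may attach to: all but the excluded set.

    By default the first root-child edge (the unidentifiable "edge0" at
    the top of the graph) is excluded; admixture connections cannot be
    split and never appear.
    """
    if excluded is None:
        excluded = {next(e.name for e in skeleton.drift_edges if e.parent == skeleton.root)}
    names = [e.name for e in skeleton.drift_edges]
    unknown = set(excluded) - set(names)
    if unknown:
        raise ValueError(f"excluded edges not in the skeleton: {sorted(unknown)}")
    return [n for n in names if n not in excluded]


def enumerate_attachments(skeleton: AdmixtureGraph, target: str, max_waves: int = 3,
                          excluded: set[str] | None = None) -> list[AttachmentModel]:
    """All unordered attachments of ``target`` with 1..max_waves ancestry streams."""
    if max_waves > 3:
        raise ValueError("at most 3 ancestry waves are supported")
    if max_waves < 1:
        raise ValueError("need at least 1 ancestry wave")
    if target in skeleton.populations():
        raise ValueError(f"target {target!r} is already a skeleton population")
    cand = candidate_edges(skeleton, excluded)
    models = []
    for k in range(1, max_waves + 1):
        for combo in combinations(cand, k):
            models.append(AttachmentModel(target, combo, skeleton))
    expected = sum(comb(len(cand), k) for k in range(1, max_waves + 1))
    assert len(models) == expected
    return models


def map_target(skeleton: AdmixtureGraph, target: str, F: FreqTable,
               blocks: BlockPartition, config: FitConfig | None = None,
               max_waves: int = 3, excluded: set[str] | None = None) -> MappingReport:
    """Fit every attachment of ``target`` and select the best model(s).

    Selection: the best model of each admixture count is compared in
    order of increasing complexity; the more complex challenger wins only
    by the 10-log-unit or 0.5-SE rule.  Within the winning count, every
    model within 3 log-units of the best is retained as a tie.
    """
    config = config or FitConfig()
    models = enumerate_attachments(skeleton, target, max_waves, excluded)
    pops = skeleton.populations() + [target]
    data = GraphData(F, pops, blocks)
    n_failed = 0
    rows = []
    for mdl in models:
        try:
            topo = mdl.derive()
            fit = fit_graph(topo, F, blocks, config, data=data, model_id=mdl.model_id)
            fit.backbone_edges = mdl.backbone_edges()
            mdl.fit = fit
        except Exception as exc:  # individual fit failures are logged, not fatal
            n_failed += 1
            log.warning("fit failed for %s: %s", mdl.model_id, exc)
            continue
        rows.append({"model_id": mdl.model_id, "edges": "+".join(mdl.edges),
                     "n_admix": mdl.n_admix, "score": fit.score,
                     "worst_residual": fit.worst_residual,
                     "trifurcation": has_trifurcation(fit, config.trifurcation_tol)})
    table = pd.DataFrame(rows)
    fitted = [m for m in models if m.fit is not None]
    clean = [m for m in fitted
             if not has_trifurcation(m.fit, config.trifurcation_tol)]
    n_trif = len(fitted) - len(clean)
    best_models: list[AttachmentModel] = []
    if clean:
        by_count: dict[int, list[AttachmentModel]] = {}
        for m in clean:
            by_count.setdefault(m.n_admix, []).append(m)
        counts = sorted(by_count)
        champion = max(by_count[counts[0]], key=lambda m: m.fit.score)
        for c in counts[1:]:
            challenger = max(by_count[c], key=lambda m: m.fit.score)
            gain = challenger.fit.score - champion.fit.score
            wr_red = champion.fit.worst_residual - challenger.fit.worst_residual
            if gain > 10.0 or wr_red > 0.5:
                champion = challenger
        best_models = [m for m in by_count[champion.n_admix]
                       if champion.fit.score - m.fit.score <= 3.0]
        best_models.sort(key=lambda m: -m.fit.score)
    return MappingReport(target, len(models), best_models, n_trif, n_failed, table)


def select_from_scores(table: pd.DataFrame) -> list[str]:
    """Replay the selection rules on a logged score table.

    Expects columns n_admix, score, worst_residual, trifurcation,
    model_id; returns the retained model ids (ties included), matching
    :func:`map_target` decision-for-decision.
    """
    clean = table[~table["trifurcation"]]
    if not len(clean):
        return []
    champ = None
    for c in sorted(clean["n_admix"].unique()):
        grp = clean[clean["n_admix"] == c]
        challenger = grp.loc[grp["score"].idxmax()]
        if champ is None:
            champ = challenger
            continue
        if (challenger["score"] - champ["score"] > 10.0
                or champ["worst_residual"] - challenger["worst_residual"] > 0.5):
            champ = challenger
    grp = clean[clean["n_admix"] == champ["n_admix"]]
    keep = grp[champ["score"] - grp["score"] <= 3.0]
    return list(keep.sort_values("score", ascending=False)["model_id"])


def build_skeleton(F: FreqTable, initial: AdmixtureGraph, additions: list[str],
                   blocks: BlockPartition, config: FitConfig | None = None,
                   max_waves: int = 3,
                   excluded: set[str] | None = None) -> AdmixtureGraph:
    """Grow a skeleton by mapping populations one at a time.

    Each addition must resolve to a unique best model (a tie raises
    :class:`SkeletonTieError` listing the tied models); fixed admixture
    constraints on the initial graph are preserved throughout.
    """
    config = config or FitConfig()
    current = initial.copy()
    for pop in additions:
        report = map_target(current, pop, F, blocks, config, max_waves, excluded)
        if not report.best_models:
            raise RuntimeError(f"no valid attachment model found for {pop!r}")
        if len(report.best_models) > 1:
            raise SkeletonTieError(pop, [m.model_id for m in report.best_models])
        best = report.best_models[0]
        current = best.fit.graph.copy()
        log.info("adopted %s for %s (score %.2f)", best.model_id, pop, best.fit.score)
    return current
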