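import numpy as np
import pytest

from akit import fstats, genio, graphfit, simgraph
from akit.graphfit import (AdmixNode, ComparisonVerdict, DriftEdge, FitConfig,
                           GraphError, GraphFit, compare_fits, expected_stats,
                           format_graph, parse_graph)

TWO_LEAF = """
root R
edge a R A 0.02
edge b R B 0.03
label A PopA
label B PopB
"""

ADMIXED = """
root R
edge a R X 0.01
edge b R Y 0.01
edge ax X A 0.0
edge by Y B 0.0
edge am M L 0.0
admix M X Y 0.5
label A PopA
label B PopB
label L PopM
"""


# ---------------------------------------------------------------------------
# expected statistics

def test_tree_additivity_two_leaves():
    es = expected_stats(parse_graph(TWO_LEAF))
    assert np.isclose(es.f2("PopA", "PopB"), 0.05, rtol=1e-12)


def test_admixed_leaf_path_probability_oracle():
    """50/50 mixture of two 0.01 branches: C(M,M) = C(M,A) = 0.005."""
    es = expected_stats(parse_graph(ADMIXED))
    assert np.isclose(es.f2("PopM", "PopA"), 0.005, rtol=1e-12)
    assert np.isclose(es.f2("PopM", "PopB"), 0.005, rtol=1e-12)
    assert np.isclose(es.f2("PopA", "PopB"), 0.02, rtol=1e-12)


def test_expected_f4_with_repeated_population_is_zero():
    es = expected_stats(parse_graph(ADMIXED))
    assert es.f4("PopA", "PopB", "PopM", "PopM") == 0.0


def test_expected_stats_obeys_linear_identities():
    es = expected_stats(simgraph.preset_skeleton())
    pops = es.populations
    X, A, B, D = pops[0], pops[3], pops[5], pops[8]
    assert np.isclose(es.f3(X, A, B),
                      (es.f2(X, A) + es.f2(X, B) - es.f2(A, B)) / 2, rtol=1e-12)
    assert np.isclose(es.f4(X, A, B, D),
                      (es.f2(X, D) + es.f2(A, B) - es.f2(X, B) - es.f2(A, D)) / 2,
                      rtol=1e-12)
    assert np.isclose(es.f4(X, A, B, D), -es.f4(A, X, B, D), rtol=1e-12)
    assert np.isclose(es.f4(X, A, B, D), es.f4(B, D, X, A), rtol=1e-12)


def test_zero_length_edge_leaves_expectations_unchanged():
    g = parse_graph(TWO_LEAF)
    g2 = g.copy()
    g2.drift_edges.remove(g2.edge("a"))
    g2.drift_edges += [DriftEdge("a1", "R", "mid", 0.02), DriftEdge("a2", "mid", "A", 0.0)]
    assert np.isclose(expected_stats(g2).f2("PopA", "PopB"),
                      expected_stats(g).f2("PopA", "PopB"), rtol=1e-12)


def test_unset_parameter_names_edge():
    g = parse_graph(TWO_LEAF)
    g.edge("b").length = None
    with pytest.raises(GraphError, match="'b'"):
        expected_stats(g)


# ---------------------------------------------------------------------------
# graph dialect and validation

def test_graph_text_round_trip():
    g = simgraph.preset_graph(("eEA3", "eSAS"), (0.7, 0.3))
    h = parse_graph(format_graph(g))
    assert format_graph(h) == format_graph(g)
    es_g, es_h = expected_stats(g), expected_stats(h)
    for a in es_g.populations[1:]:
        assert np.isclose(es_g.f2(es_g.populations[0], a),
                          es_h.f2(es_h.populations[0], a), rtol=1e-9)


@pytest.mark.parametrize("text,msg", [
    ("root R\nedge a R A\nedge b A R\nlabel A P\n", "cycle|parents"),
    ("root R\nedge a R A\nedge b R A\nlabel A P\n", "drift parents"),
    ("root R\nedge a R A\nlabel B P\nlabel A Q\n", "not a leaf"),
    ("root R\nedge a R A\nedge a R B\nlabel A P\nlabel B Q\n", "duplicate"),
])
def test_invalid_graphs_rejected(text, msg):
    with pytest.raises(GraphError, match=msg):
        parse_graph(text)


# ---------------------------------------------------------------------------
# fitting

def fit_noise_free(truth, seed=0, n_restarts=6):
    es = expected_stats(truth)
    labels, y = es.basis(es.populations[0])
    topo = truth.copy()
    for e in topo.drift_edges:
        e.length = None
    for a in topo.admix_nodes:
        if not a.fixed:
            a.weight = None
    cfg = FitConfig(n_restarts=n_restarts, seed=seed)
    return graphfit.fit_graph_to_basis(topo, labels, y, np.eye(len(y)), cfg)


def test_noise_free_self_fit_recovers_parameters():
    truth = simgraph.preset_skeleton()
    fitted, score, _ = fit_noise_free(truth)
    assert abs(score) < 1e-8
    tl = {e.name: e.length for e in truth.drift_edges}
    fl = {e.name: e.length for e in fitted.drift_edges}
    # the two root-child edges share one identifiable sum
    assert np.isclose(fl["e0"] + fl["eO1"], tl["e0"] + tl["eO1"], atol=1e-6)
    for k in tl:
        if k not in ("e0", "eO1"):
            assert abs(fl[k] - tl[k]) < 1e-4, k
    assert abs(fitted.admix_nodes[0].weight - 0.55) < 1e-4


def test_fixed_weight_respected_in_fit():
    truth = simgraph.preset_skeleton()
    truth.admix_nodes[0].fixed = True
    truth.admix_nodes[0].weight = 0.3  # not the generating value
    es = expected_stats(simgraph.preset_skeleton())
    labels, y = es.basis(es.populations[0])
    topo = truth.copy()
    for e in topo.drift_edges:
        e.length = None
    fitted, score, _ = graphfit.fit_graph_to_basis(topo, labels, y, np.eye(len(y)),
                                                   FitConfig(n_restarts=2))
    assert fitted.admix_nodes[0].weight == 0.3
    assert score < -1e-6  # misfit: the true weight was 0.55


def test_score_invariant_to_base_choice():
    """The f2/f3 basis spans the same space for any base; with the exact
    jackknife covariance the GLS quadratic form is base-invariant."""
    spec = simgraph.SimSpec(simgraph.preset_graph(("eEA3",), (1.0,)),
                            n_snps=4000, seed=11, n_chromosomes=6, map_length=0.25)
    G = simgraph.simulate_dataset(spec)
    F = genio.pop_freqs(G)
    blocks = genio.assign_blocks(G.snps, 0.05)
    pops = ["Outgroup1", "African", "EastAsian1", "EastAsian3", "Target"]
    data = graphfit.GraphData(F, pops, blocks)
    qforms = []
    for base in ("Outgroup1", "EastAsian3"):
        labels, y, Q = data.basis(base, cov_diag=0.0, lsq_mode=False)
        d = y  # distance from the zero model: any fixed linear functional works
        qforms.append(float(d @ np.linalg.solve(Q, d)))
    assert np.isclose(qforms[0], qforms[1], rtol=1e-6)


def test_fit_on_simulated_data_recovers_weight():
    spec = simgraph.preset_spec(0.3, n_snps=20000, seed=5)
    G = simgraph.simulate_dataset(spec)
    F = genio.pop_freqs(G)
    blocks = genio.assign_blocks(G.snps, 0.05)
    topo = spec.graph.copy()
    for e in topo.drift_edges:
        e.length = None
    for a in topo.admix_nodes:
        a.weight = None
    fit = graphfit.fit_graph(topo, F, blocks, FitConfig(n_restarts=4, seed=1))
    w = {a.child: a.weight for a in fit.graph.admix_nodes}
    assert abs(w["tmix"] - 0.7) < 0.05
    assert abs(w["sas"] - 0.55) < 0.08
    assert fit.worst_residual < 4.5
    assert fit.residuals is not None and len(fit.residuals) > 1000


# ---------------------------------------------------------------------------
# model comparison

def _mk_fit(score, wr, n_admix, model_id, n_snps=1000):
    g = parse_graph(TWO_LEAF)
    for k in range(n_admix):
        # decorative admixture nodes to set the count
        g.drift_edges += [DriftEdge(f"x{k}", "R", f"n{k}a", 0.01),
                          DriftEdge(f"y{k}", "R", f"n{k}b", 0.01),
                          DriftEdge(f"z{k}", f"m{k}", f"l{k}", 0.01)]
        g.admix_nodes.append(AdmixNode(f"m{k}", f"n{k}a", f"n{k}b", 0.5))
        g.leaf_map[f"l{k}"] = f"L{k}"
    return GraphFit(g, score, wr, None, n_snps, model_id=model_id)


def test_complex_model_wins_by_loglik_cutoff():
    v = compare_fits(_mk_fit(-25, 3.0, 0, "simple"), _mk_fit(-12, 2.8, 1, "complex"))
    assert v.preferred == "complex" and v.rule_applied == "delta_ll_10"
    assert np.isclose(v.margin, 13)


def test_simple_model_wins_when_neither_cutoff_met():
    v = compare_fits(_mk_fit(-25, 2.6, 0, "simple"), _mk_fit(-20, 2.3, 1, "complex"))
    assert v.preferred == "simple"


def test_worst_residual_cutoff_rescues_complex_model():
    v = compare_fits(_mk_fit(-25, 3.0, 0, "simple"), _mk_fit(-20, 2.4, 1, "complex"))
    assert v.preferred == "complex" and v.rule_applied == "worst_resid_0.5"


def test_equal_counts_within_three_logunits_tie():
    v = compare_fits(_mk_fit(-20, 2.0, 1, "a"), _mk_fit(-22, 2.1, 1, "b"))
    assert v.tied and v.preferred is None and v.rule_applied == "delta_ll_3"
    v2 = compare_fits(_mk_fit(-20, 2.0, 1, "a"), _mk_fit(-24, 2.1, 1, "b"))
    assert v2.preferred == "a" and not v2.tied


def test_trifurcation_discarded_before_comparison():
    bad = _mk_fit(-5, 1.0, 0, "bad")
    bad.graph.drift_edges.append(DriftEdge("b0", "R", "mid1", 0.01))
    bad.graph.drift_edges.append(DriftEdge("bb", "mid1", "mid2", 0.0))  # zero backbone
    bad.graph.drift_edges.append(DriftEdge("bl", "mid2", "C", 0.01))
    bad.graph.leaf_map["C"] = "PopC"
    assert graphfit.has_trifurcation(bad)
    v = compare_fits(bad, _mk_fit(-30, 3.0, 0, "good"))
    assert v.preferred == "good" and v.rule_applied == "trifurcation_filter"


def test_fits_on_different_snp_sets_cannot_compare():
    with pytest.raises(ValueError):
        compare_fits(_mk_fit(-5, 1, 0, "a", 100), _mk_fit(-5, 1, 0, "b", 200))
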