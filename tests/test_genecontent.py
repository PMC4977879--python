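import numpy as np
import pandas as pd
import pytest

from pvc_hgtscape import from_newick
from pvc_hgtscape.genecontent import (GeneContentError, PhyleticMatrix,
                                      ROOT_STEM, cluster_families,
                                      infer_events, markov_cluster,
                                      replay_events, summarize_hgt)
from pvc_hgtscape.simulate import SimConfig, simulate_gene_content
from _oracles import (exhaustive_gain_loss, mcl_fixed_point, random_tree)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def clique_graph(*cliques, bridges=()):
    genes = sorted({g for c in cliques for g in c})
    rows = []
    for c in cliques:
        for i, a in enumerate(c):
            for b in c[i + 1:]:
                rows.append((a, b, 1.0))
    rows += [(a, b, w) for a, b, w in bridges]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]), genes


def test_two_disjoint_cliques_two_families():
    graph, _ = clique_graph(["s1|a", "s2|b", "s3|c"],
                            ["s1|d", "s2|e", "s3|f"])
    m = cluster_families(graph, species=["s1", "s2", "s3"])
    assert len(m.families) == 2
    assert (m.presence.sum(axis=1) == 3).all()


def test_single_gene_singleton_family():
    graph = pd.DataFrame([("s1|a", "s1|a", 1.0)],
                         columns=["gene_a", "gene_b", "weight"])
    m = cluster_families(graph, species=["s1"])
    assert len(m.families) == 1
    assert m.gene_counts.iloc[0, 0] == 1


def test_barbell_splits_into_two_families_like_fixed_point_oracle():
    graph, genes = clique_graph(
        ["s1|a", "s2|b", "s3|c"], ["s1|d", "s2|e", "s3|f"],
        bridges=[("s3|c", "s1|d", 0.1)])
    m = cluster_families(graph, species=["s1", "s2", "s3"], inflation=2.0)
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((6, 6))
    for a, b, w in graph.itertuples(index=False):
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = w
    oracle = mcl_fixed_point(adj, inflation=2.0)
    assert len(m.families) == len(oracle) == 2


def test_extra_isolated_clique_adds_exactly_one_family():
    g1, _ = clique_graph(["s1|a", "s2|b"], ["s2|c", "s3|d"])
    g2, _ = clique_graph(["s1|a", "s2|b"], ["s2|c", "s3|d"],
                         ["s1|x", "s3|y"])
    m1 = cluster_families(g1, species=["s1", "s2", "s3"])
    m2 = cluster_families(g2, species=["s1", "s2", "s3"])
    assert len(m2.families) == len(m1.families) + 1


def test_negative_weight_rejected():
    graph = pd.DataFrame([("a", "b", -1.0)],
                         columns=["gene_a", "gene_b", "weight"])
    with pytest.raises(GeneContentError):
        cluster_families(graph, species=["a", "b"],
                         species_of={"a": "a", "b": "b"})


# ---------------------------------------------------------------------------
# event inference
# ---------------------------------------------------------------------------

def test_ubiquitous_family_single_root_gain(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1], "B": [1], "C": [1], "D": [1]}, index=["f1"]))
    ev = infer_events(quartet, m)
    assert [g.branch_child for g in ev.gains] == [ROOT_STEM]
    assert not ev.gains[0].specific
    assert ev.losses == []


def test_single_tip_family_specific_terminal_gain(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1], "B": [0], "C": [0], "D": [0]}, index=["f1"]))
    ev = infer_events(quartet, m)
    assert len(ev.gains) == 1 and ev.gains[0].branch_child == "A"
    assert ev.gains[0].specific
    assert ev.losses == []


def test_pair_family_gain_on_stem(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1], "B": [1], "C": [0], "D": [0]}, index=["f1"]))
    ev = infer_events(quartet, m)
    ab_stem = quartet.labels[quartet.parent[quartet.index["A"]]]
    assert [g.branch_child for g in ev.gains] == [ab_stem]
    assert not ev.gains[0].specific
    assert ev.losses == []


def test_family_absent_everywhere_rejected(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1, 0], "B": [1, 0], "C": [1, 0], "D": [1, 0]},
        index=["f1", "f2"]))
    # constructor accepts; inference must reject the empty family
    with pytest.raises(GeneContentError):
        infer_events(quartet, m)


def test_sankoff_cost_matches_exhaustive_minimum(rng):
    for _ in range(40):
        tree = random_tree(rng, int(rng.integers(3, 9)))
        pattern = {t: int(rng.integers(0, 2)) for t in tree.tip_labels}
        if not any(pattern.values()):
            pattern[tree.tip_labels[0]] = 1
        m = PhyleticMatrix(pd.DataFrame(pattern, index=["f"]))
        ev = infer_events(tree, m, gain_cost=2.0, loss_cost=1.0)
        cost = 2.0 * len(ev.gains) + 1.0 * len(ev.losses)
        oracle = exhaustive_gain_loss(tree, pattern, 2.0, 1.0)
        assert cost == oracle


def test_replay_reproduces_matrix_on_simulations(demo_tree):
    for seed in (1, 2):
        cfg = SimConfig(seed=seed, n_root_families=100,
                        rate_origination=5, rate_transfer=8)
        matrix, _ = simulate_gene_content(demo_tree, cfg)
        ev = infer_events(demo_tree, matrix)
        replay = replay_events(ev, families=matrix.families)
        assert (replay[matrix.species].to_numpy() ==
                matrix.presence.to_numpy()).all()


def test_no_loss_rate_infers_no_losses(demo_tree):
    cfg = SimConfig(seed=5, rate_loss=0.0, n_root_families=50,
                    rate_origination=5, rate_transfer=5)
    matrix, _ = simulate_gene_content(demo_tree, cfg)
    ev = infer_events(demo_tree, matrix)
    assert ev.losses == []


def test_dollo_mode_single_gain_per_family(demo_tree):
    cfg = SimConfig(seed=6, n_root_families=60, rate_origination=4,
                    rate_transfer=6)
    matrix, _ = simulate_gene_content(demo_tree, cfg)
    ev = infer_events(demo_tree, matrix, dollo=True)
    per_family = pd.Series([g.family for g in ev.gains]).value_counts()
    assert (per_family == 1).all()
    replay = replay_events(ev, families=matrix.families)
    assert (replay[matrix.species].to_numpy() ==
            matrix.presence.to_numpy()).all()


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def test_no_hgt_classified_gains_zero_proportions(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1], "B": [1], "C": [1], "D": [1]}, index=["f1"]))
    ev = infer_events(quartet, m)
    ev = ev.with_classifications({(g.family, g.branch_child): "not_HGT"
                                  for g in ev.gains})
    s = summarize_hgt(ev, m)
    assert (s.per_species["total_proportion"] == 0).all()


def test_single_specific_hgt_gene_proportion(quartet):
    pres = pd.DataFrame({"A": [1], "B": [0], "C": [0], "D": [0]},
                        index=["f1"])
    m = PhyleticMatrix(pres, proteome_sizes=pd.Series(
        {"A": 100, "B": 100, "C": 100, "D": 100}))
    ev = infer_events(quartet, m)
    ev = ev.with_classifications({(g.family, g.branch_child): "HGT"
                                  for g in ev.gains})
    s = summarize_hgt(ev, m)
    assert s.per_species.loc["A", "specific_proportion"] == 0.01
    assert s.per_species.loc["A", "nonspecific_proportion"] == 0.0
    assert s.per_species.loc["B", "total_hgt"] == 0


def test_specific_plus_nonspecific_equals_total(demo_tree):
    cfg = SimConfig(seed=9, n_root_families=80, rate_origination=6,
                    rate_transfer=10)
    matrix, _ = simulate_gene_content(demo_tree, cfg)
    ev = infer_events(demo_tree, matrix)
    labels = {}
    rng = np.random.default_rng(0)
    for g in ev.gains:
        labels[(g.family, g.branch_child)] = str(
            rng.choice(["HGT", "not_HGT", "ORFan"]))
    s = summarize_hgt(ev.with_classifications(labels), matrix)
    tbl = s.per_species
    assert (tbl["specific_hgt"] + tbl["nonspecific_hgt"] ==
            tbl["total_hgt"]).all()


def test_gain_then_loss_contributes_nothing_below_loss(quartet):
    # family gained at root stem but lost on the CD stem, regained in C
    from pvc_hgtscape.genecontent import EventMap, GainEvent
    cd = quartet.labels[quartet.parent[quartet.index["C"]]]
    ev = EventMap(
        gains=[GainEvent("f1", ROOT_STEM, specific=False,
                         classification="HGT"),
               GainEvent("f1", "C", specific=True,
                         classification="not_HGT")],
        losses=[("f1", cd)], tree=quartet)
    pres = replay_events(ev, families=["f1"])
    assert pres.loc["f1"].to_dict() == {"A": 1, "B": 1, "C": 1, "D": 0}
    m = PhyleticMatrix(pres)
    s = summarize_hgt(ev, m)
    # A and B trace to the HGT root gain; C traces to its own non-HGT gain
    assert s.per_species.loc["A", "total_hgt"] == 1
    assert s.per_species.loc["B", "total_hgt"] == 1
    assert s.per_species.loc["C", "total_hgt"] == 0


def test_unclassified_gain_blocks_summary(quartet):
    m = PhyleticMatrix(pd.DataFrame(
        {"A": [1], "B": [1], "C": [1], "D": [1]}, index=["f1"]))
    ev = infer_events(quartet, m)
    with pytest.raises(GeneContentError):
        summarize_hgt(ev.with_classifications(
            {(g.family, g.branch_child): "pending" for g in ev.gains}), m)
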