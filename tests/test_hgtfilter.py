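import numpy as np
import pandas as pd
import pytest

from pvc_hgtscape.hgtfilter import (FilterPolicy, HitTableError,
                                    assign_partner, classify_gain,
                                    lineage_context, orfan_test, rank_hits)
from _oracles import brute_force_classify, brute_force_orfan


def table(rows):
    return pd.DataFrame(rows, columns=["query", "subject_species",
                                       "subject_phylum", "evalue",
                                       "query_coverage", "identity"])


def hit(species, phylum, evalue=1e-30, coverage=90.0, identity=60.0):
    return ("g1", species, phylum, evalue, coverage, identity)


POLICY = FilterPolicy(self_phyla=frozenset({"Verrucomicrobiae"}),
                      sister_phyla=frozenset({"Planctomycetes",
                                              "Chlamydiae"}))


# ---------------------------------------------------------------------------
# ORFan rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rows,expected", [
    ([], True),                                          # no hits at all
    ([hit("x", "F", evalue=1e-3, coverage=80)], True),   # e-value fails
    ([hit("x", "F", evalue=1e-6, coverage=50.0)], True), # coverage not > 50
    ([hit("x", "F", evalue=1e-4, coverage=80)], True),   # e-value not < 1e-4
    ([hit("x", "F", evalue=9.9e-5, coverage=50.1)], False),
    ([hit("x", "F", evalue=1e-3, coverage=80),
      hit("y", "F", evalue=1e-6, coverage=90)], False),  # one qualifying hit
])
def test_orfan_rule_boundaries(rows, expected):
    assert orfan_test(table(rows), POLICY) is expected
    assert brute_force_orfan([dict(subject_species=r[1], subject_phylum=r[2],
                                   evalue=r[3], query_coverage=r[4],
                                   identity=r[5]) for r in rows]) is expected


# ---------------------------------------------------------------------------
# HGT rule
# ---------------------------------------------------------------------------

def test_all_firmicutes_hits_called_hgt():
    rows = [hit(f"Firmicutes_sp{i}", "Firmicutes") for i in range(10)]
    assert classify_gain(table(rows), POLICY) == "HGT"


def test_single_sister_hit_in_window_vetoes():
    rows = [hit(f"Firmicutes_sp{i}", "Firmicutes", evalue=10.0 ** (-50 + i))
            for i in range(9)]
    rows.append(hit("Planctomyces_maris", "Planctomycetes", evalue=1e-40))
    assert classify_gain(table(rows), POLICY) == "not_HGT"


def test_sister_hit_beyond_rank_ten_ignored():
    rows = [hit(f"Firmicutes_sp{i:02d}", "Firmicutes",
                evalue=10.0 ** (-60 + i)) for i in range(10)]
    rows += [hit("Planctomyces_maris", "Planctomycetes", evalue=1e-45),
             hit("Simkania_negevensis", "Chlamydiae", evalue=1e-44)]
    assert classify_gain(table(rows), POLICY) == "HGT"


def test_self_phylum_hits_removed_before_window():
    rows = [hit(f"Akkermansia_sp{i}", "Verrucomicrobiae",
                evalue=10.0 ** (-80 + i)) for i in range(10)]
    rows += [hit(f"Firmicutes_sp{i}", "Firmicutes",
                 evalue=10.0 ** (-40 + i)) for i in range(3)]
    assert classify_gain(table(rows), POLICY) == "HGT"


def test_quality_boundaries_kept():
    # boundary values survive the removal rule (removal is strict >/<)
    rows = [hit("Firmicutes_sp1", "Firmicutes",
                evalue=1e-5, coverage=60.0, identity=30.0)]
    assert classify_gain(table(rows), POLICY) == "HGT"
    rows = [hit("Firmicutes_sp1", "Firmicutes",
                evalue=1.01e-5, coverage=60.0, identity=30.0)]
    assert classify_gain(table(rows), POLICY) == "unclassified"


def test_zero_surviving_hits_unclassified():
    rows = [hit("Akkermansia_sp1", "Verrucomicrobiae")]
    assert classify_gain(table(rows), POLICY) == "unclassified"


def test_unknown_subject_phylum_hard_error():
    rows = [("g1", "sp1", "", 1e-30, 90.0, 60.0)]
    with pytest.raises(HitTableError, match="phylum"):
        classify_gain(table(rows), POLICY)


def test_row_permutation_never_changes_outcome(rng):
    rows = [hit(f"Firmicutes_sp{i}", "Firmicutes", evalue=1e-30)
            for i in range(6)]
    rows.append(hit("Planctomyces_maris", "Planctomycetes", evalue=1e-30))
    base = classify_gain(table(rows), POLICY)
    for _ in range(10):
        perm = [rows[i] for i in rng.permutation(len(rows))]
        assert classify_gain(table(perm), POLICY) == base


def test_classification_agrees_with_literal_rule_on_random_tables(rng):
    phyla = ["Verrucomicrobiae", "Planctomycetes", "Chlamydiae",
             "Lentisphaerae", "Firmicutes", "Proteobacteria"]
    n_disagree = 0
    for _ in range(2000):
        n = int(rng.integers(1, 16))
        rows = []
        for k in range(n):
            ph = str(rng.choice(phyla))
            # mix smooth values with exact boundary values
            ev = float(rng.choice([1e-5, 1.1e-5,
                                   10.0 ** rng.uniform(-60, -3)]))
            cov = float(rng.choice([60.0, 59.9, rng.uniform(30, 100)]))
            ident = float(rng.choice([30.0, 29.9, rng.uniform(20, 95)]))
            rows.append(("g", f"{ph}_sp{int(rng.integers(0, 6))}", ph,
                         ev, cov, ident))
        got = classify_gain(table(rows), POLICY)
        want = brute_force_classify(
            [dict(subject_species=r[1], subject_phylum=r[2], evalue=r[3],
                  query_coverage=r[4], identity=r[5]) for r in rows],
            set(POLICY.self_phyla), set(POLICY.sister_phyla))
        n_disagree += got != want
    assert n_disagree == 0


# ---------------------------------------------------------------------------
# partner assignment
# ---------------------------------------------------------------------------

def test_partner_majority():
    rows = [hit(f"Firmicutes_sp{i}", "Firmicutes") for i in range(7)]
    rows += [hit(f"Proteobacteria_sp{i}", "Proteobacteria")
             for i in range(3)]
    assert assign_partner(table(rows), POLICY) == "Firmicutes"


def test_partner_tie_goes_to_best_ranked():
    rows = [hit(f"Proteobacteria_sp{i}", "Proteobacteria",
                evalue=10.0 ** (-60 + i)) for i in range(5)]
    rows += [hit(f"Firmicutes_sp{i}", "Firmicutes",
                 evalue=10.0 ** (-50 + i)) for i in range(5)]
    assert assign_partner(table(rows), POLICY) == "Proteobacteria"


# ---------------------------------------------------------------------------
# ranking + lineage context
# ---------------------------------------------------------------------------

def test_ranking_evalue_then_identity():
    rows = [("g", "a", "F", 1e-10, 90.0, 40.0),
            ("g", "b", "F", 1e-20, 90.0, 40.0),
            ("g", "c", "F", 1e-10, 90.0, 70.0)]
    ranked = rank_hits(table(rows))
    assert list(ranked["subject_species"]) == ["b", "c", "a"]
    assert list(ranked["rank"]) == [1, 2, 3]


def test_lineage_context_on_demo_tree(demo_tree):
    self_p, sister_p = lineage_context(demo_tree, "Chlamydiaceae")
    assert self_p == {"Chlamydiae"}
    # nearest foreign phyla: the walk passes the within-phylum siblings
    assert sister_p == {"Planctomycetes", "Verrucomicrobiae",
                        "Lentisphaerae"}
    self_p, sister_p = lineage_context(demo_tree, "Chlamydiae_anc")
    assert self_p == {"Chlamydiae"}
    assert sister_p == {"Planctomycetes", "Verrucomicrobiae",
                        "Lentisphaerae"}
    self_p, sister_p = lineage_context(demo_tree, "Verrucomicrobiae_anc")
    assert self_p == {"Verrucomicrobiae"}
    assert sister_p == {"Lentisphaerae"}
    self_p, sister_p = lineage_context(demo_tree, "Akkermansia_muciniphila")
    assert self_p == {"Verrucomicrobiae"}
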