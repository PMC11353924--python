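"""Presence/Venn analysis, taxonomy aggregation and stacked composition."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

import fermflavor as ff
from fermflavor.otu import UNCLASSIFIED


def _table(counts: dict, design_rows: dict) -> ff.OtuTable:
    design = pd.DataFrame(
        {"stage": design_rows, "replicate": {s: 1 for s in design_rows}}
    )
    design.index.name = "sample"
    return ff.OtuTable(counts=pd.DataFrame(counts), design=design)


def test_presence_boundary_is_strict():
    """Mean tag count must be strictly > 1: (3,0,0) has mean exactly 1."""
    otus = _table(
        {"a": [3, 2], "b": [0, 2], "c": [0, 2]},
        {"a": "G1", "b": "G1", "c": "G1"},
    )
    presence = ff.group_presence(otus, pd.Series("G1", index=["a", "b", "c"]))
    assert presence == {"G1": {otus.otu_ids[1]}}


def test_presence_matches_bruteforce_per_group_means(community):
    otus, _ = community
    presence = ff.group_presence(otus)
    stages = otus.sample_stage()
    for stage in otus.stages:
        cols = [s for s in otus.sample_ids if stages[s] == stage]
        expected = {
            o for o in otus.otu_ids if otus.counts.loc[o, cols].mean() > 1
        }
        assert presence[stage] == expected


def test_presence_monotone_under_added_counts(community):
    otus, _ = community
    before = ff.group_presence(otus)
    boosted = ff.OtuTable(counts=otus.counts + 2, design=otus.design)
    after = ff.group_presence(boosted)
    for g in before:
        assert before[g] <= after[g]


def test_venn_identical_and_disjoint_sets():
    same = {"A": {1, 2, 3}, "B": {1, 2, 3}}
    v = ff.venn_counts(same)
    assert v["core"] == 3 and v["unique"] == {"A": 0, "B": 0}
    disjoint = {"A": {1, 2}, "B": {3}}
    v = ff.venn_counts(disjoint)
    assert v["core"] == 0 and v["unique"] == {"A": 2, "B": 1}
    with pytest.raises(ValueError):
        ff.venn_counts({"A": {1}})


def test_venn_regions_match_powerset_enumeration():
    rng = np.random.default_rng(4)
    universe = list(range(40))
    sets = {g: set(rng.choice(universe, size=15)) for g in "ABC"}
    v = ff.venn_counts(sets)
    groups = list(sets)
    # oracle: enumerate every region of the 3-set lattice
    for r in range(1, 4):
        for member in combinations(groups, r):
            inside = set.intersection(*(sets[g] for g in member))
            outside = set().union(*(sets[g] for g in groups if g not in member))
            expected = len(inside - outside)
            assert v["regions"].get(tuple(member), 0) == expected
    assert sum(v["regions"].values()) == v["union"]


def test_aggregate_taxonomy_single_and_two_phyla(small_design):
    otus, _ = ff.generate_otu_experiment(
        small_design, ff.CommunitySimParams(n_otus=5, library_size_mean=500), seed=1
    )
    tax = ff.TaxonomyMap(
        pd.DataFrame(
            {
                "kingdom": "Bacteria",
                "phylum": ["P1"] * 5,
                "class": UNCLASSIFIED,
                "order": UNCLASSIFIED,
                "family": UNCLASSIFIED,
                "genus": UNCLASSIFIED,
            },
            index=otus.otu_ids,
        )
    )
    comp = ff.aggregate_taxonomy(otus, tax, rank="phylum")
    assert (comp.loc["P1"] == 1.0).all()
    counts = pd.DataFrame({"s": [60, 40]}, index=["o1", "o2"])
    design = pd.DataFrame({"stage": ["S1"], "replicate": [1]}, index=["s"])
    two = ff.OtuTable(counts=counts, design=design)
    tax2 = ff.TaxonomyMap(
        pd.DataFrame(
            {
                "kingdom": "Bacteria",
                "phylum": ["P1", "P2"],
                "class": UNCLASSIFIED,
                "order": UNCLASSIFIED,
                "family": UNCLASSIFIED,
                "genus": UNCLASSIFIED,
            },
            index=["o1", "o2"],
        )
    )
    comp2 = ff.aggregate_taxonomy(two, tax2, rank="phylum")
    assert comp2.loc["P1", "s"] == pytest.approx(0.6)
    assert comp2.loc["P2", "s"] == pytest.approx(0.4)


def test_aggregate_taxonomy_matches_bruteforce_groupby(community):
    otus, tax = community
    comp = ff.aggregate_taxonomy(otus, tax, rank="genus")
    np.testing.assert_allclose(comp.sum(axis=0), 1.0, rtol=1e-9)
    labels = tax.rank("genus")
    sample = otus.sample_ids[0]
    for taxon in comp.index:
        members = [o for o in otus.otu_ids if labels[o] == taxon]
        expected = otus.counts.loc[members, sample].sum() / otus.counts[sample].sum()
        assert comp.loc[taxon, sample] == pytest.approx(expected)


def test_top_taxa_stack_structure_and_arithmetic(community):
    otus, tax = community
    comp = ff.aggregate_taxonomy(otus, tax, rank="genus")
    stack = ff.top_taxa_stack(comp, k=10)
    known = comp.drop(index=[UNCLASSIFIED], errors="ignore")
    top10 = known.mean(axis=1).nlargest(10).index
    assert list(stack.index[:10]) == list(top10)
    assert "Others" in stack.index and UNCLASSIFIED in stack.index
    np.testing.assert_allclose(stack.sum(axis=0), comp.sum(axis=0), rtol=1e-9)
    # Others = 1 - top-k - unclassified, per column
    for col in stack.columns:
        expected = 1 - stack.loc[top10, col].sum() - stack.loc[UNCLASSIFIED, col]
        assert stack.loc["Others", col] == pytest.approx(expected)


def test_top_taxa_stack_small_table_unchanged():
    comp = pd.DataFrame({"S1": [0.7, 0.3]}, index=["g1", "g2"])
    stack = ff.top_taxa_stack(comp, k=10)
    assert set(stack.index) == {"g1", "g2"}
    np.testing.assert_allclose(stack.sum(axis=0), 1.0)


def test_dominant_taxon_planted_ground_truth(design):
    params = ff.CommunitySimParams(
        n_otus=40,
        library_size_mean=5000,
        unclassified_fraction=0.0,
        planted_dominants=[("HT9", 3, 0.95)],
    )
    otus, tax = ff.generate_otu_experiment(design, params, seed=17)
    comp = ff.aggregate_taxonomy(otus, tax, rank="genus")
    stage_comp = ff.collapse_to_stages(comp, otus)
    taxon, abundance = ff.dominant_taxon(stage_comp, "HT9")
    planted_genus = tax.rank("genus")[otus.otu_ids[3]]
    assert taxon == planted_genus
    assert abundance == pytest.approx(0.95, abs=0.05)


def test_dominant_taxon_tie_and_single_column():
    comp = pd.DataFrame({"S1": [0.5, 0.5]}, index=["b_tax", "a_tax"])
    with pytest.warns(UserWarning, match="tie"):
        taxon, ab = ff.dominant_taxon(comp, "S1")
    assert taxon == "a_tax" and ab == 0.5
    single = pd.DataFrame({"S1": [1.0]}, index=["only"])
    assert ff.dominant_taxon(single, "S1") == ("only", 1.0)
    with pytest.raises(KeyError):
        ff.dominant_taxon(single, "S9")
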