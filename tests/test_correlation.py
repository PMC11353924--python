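"""Pearson taxa x compound grids: values, stars, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

import fermflavor as ff


def test_pearson_hand_example():
    r, p = ff.pearson_r_p([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)
    # t = 0.8 sqrt(2) / 0.6 on 2 df, two-sided
    assert p == pytest.approx(0.2, abs=0.001)


def test_pearson_perfect_linearity():
    x = np.array([0.5, 1.0, 2.5, 4.0])
    r, p = ff.pearson_r_p(x, 2 * x + 1)
    assert (r, p) == (1.0, 0.0)
    r, _ = ff.pearson_r_p(x, -3 * x + 2)
    assert r == -1.0


def test_pearson_constant_vector_flagged_not_zero():
    r, p = ff.pearson_r_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert math.isnan(r) and math.isnan(p)
    with pytest.raises(ValueError):
        ff.pearson_r_p([1, 2], [3, 4])


def test_pearson_affine_invariance_and_sign_flip():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=9), rng.normal(size=9)
    r0, p0 = ff.pearson_r_p(x, y)
    r1, p1 = ff.pearson_r_p(x, 5 * y + 3)
    assert r1 == pytest.approx(r0, abs=1e-12) and p1 == pytest.approx(p0, abs=1e-12)
    r2, _ = ff.pearson_r_p(x, -2 * y)
    assert r2 == pytest.approx(-r0, abs=1e-12)


def _grid_inputs(n_taxa=4, n_compounds=5, stages=6, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"S{i}" for i in range(stages)]
    taxa = pd.DataFrame(
        rng.random((n_taxa, stages)), index=[f"t{i}" for i in range(n_taxa)], columns=cols
    )
    compounds = pd.DataFrame(
        rng.random((n_compounds, stages)),
        index=[f"c{i}" for i in range(n_compounds)],
        columns=cols,
    )
    return taxa, compounds


def test_grid_cellwise_matches_pearson_and_star_rules():
    taxa, compounds = _grid_inputs()
    res = ff.correlation_grid(taxa, compounds)
    for t in taxa.index:
        for c in compounds.index:
            r, p = ff.pearson_r_p(taxa.loc[t], compounds.loc[c])
            assert res.r.loc[t, c] == pytest.approx(r)
            assert res.p.loc[t, c] == pytest.approx(p)
            expected = "**" if p < 0.01 else "*" if p < 0.05 else ""
            assert res.stars.loc[t, c] == expected
    strong = (res.stars == "**").to_numpy()
    loose = (res.p < 0.05).to_numpy()
    assert (~strong | loose).all()  # "**" cells are a subset of p < 0.05


def test_grid_alignment_error_names_offending_columns():
    taxa, compounds = _grid_inputs()
    with pytest.raises(ValueError, match="S5"):
        ff.correlation_grid(taxa, compounds.drop(columns="S5"))


def test_grid_transpose_symmetry():
    taxa, compounds = _grid_inputs()
    a = ff.correlation_grid(taxa, compounds)
    b = ff.correlation_grid(compounds, taxa)
    pd.testing.assert_frame_equal(a.r, b.r.T)
    pd.testing.assert_frame_equal(a.p, b.p.T)


def test_grid_invariant_under_threshold_scaling():
    """Correlating contents or OAVs gives the same r grid (scale invariance)."""
    taxa, compounds = _grid_inputs()
    thresholds = pd.Series([7.5, 0.1, 3.5, 2.0, 200.0], index=compounds.index)
    res_content = ff.correlation_grid(taxa, compounds)
    res_oav = ff.correlation_grid(taxa, compounds.div(thresholds, axis=0))
    pd.testing.assert_frame_equal(res_content.r, res_oav.r, atol=1e-12)


def test_bh_adjustment_never_creates_new_stars():
    taxa, compounds = _grid_inputs(seed=5)
    raw = ff.correlation_grid(taxa, compounds)
    adj = ff.correlation_grid(taxa, compounds, bh_adjust=True)
    raw_star = raw.stars.to_numpy() != ""
    adj_star = adj.stars.to_numpy() != ""
    assert (~adj_star | raw_star).all()


def test_constant_compound_renders_blank_cells():
    taxa, compounds = _grid_inputs()
    compounds.loc["c0"] = 1.0
    res = ff.correlation_grid(taxa, compounds)
    assert res.r["c0"].isna().all()
    assert (res.stars["c0"] == "").all()


def test_build_feature_sets_layout(design, community, flavor):
    otus, tax = community
    peaks, thresholds, _ = flavor
    content = ff.compute_absolute_content(
        peaks, ff.QuantParams(c1=1.0, v=1.0, m=3.0), design
    )
    phylum = ff.collapse_to_stages(ff.aggregate_taxonomy(otus, tax, "phylum"), otus)
    genus = ff.collapse_to_stages(ff.aggregate_taxonomy(otus, tax, "genus"), otus)
    taxa, compounds = ff.build_feature_sets(
        phylum, genus, content, keys=None, n_phyla=3, n_genera=10
    )
    assert taxa.shape[0] == 13  # 3 phyla rows above 10 genus rows
    assert "unclassified" not in taxa.index
    # taxa rows are the brute-force top-k by mean abundance
    known = genus.drop(index=["unclassified"], errors="ignore")
    assert set(taxa.index[3:]) == set(known.mean(axis=1).nlargest(10).index)
    phyla_only, _ = ff.build_feature_sets(phylum, genus, content, n_phyla=3, n_genera=0)
    assert phyla_only.shape[0] == 3
    with pytest.warns(UserWarning, match="phyla"):
        ff.build_feature_sets(phylum, genus, content, n_phyla=50, n_genera=0)


def test_planted_link_attains_row_max(design):
    """Over 20 simulated experiments the planted cell wins its row majority."""
    cparams = ff.CommunitySimParams(n_otus=20, library_size_mean=1500)
    fparams = ff.FlavorSimParams(
        n_compounds=6, noise_sd=2.0, linked_pairs=[(4, 2, 0.95)]
    )
    wins = 0
    for seed in range(20):
        otus, _ = ff.generate_otu_experiment(design, cparams, seed=100 + seed)
        _, _, truth = ff.generate_flavor_experiment(design, otus, fparams, seed=seed)
        rel = otus.relative_abundance()
        stage_means = rel.T.groupby(otus.sample_stage().values, sort=False).mean().T
        taxa = stage_means.iloc[[4]]
        taxa.index = ["planted_taxon"]
        res = ff.correlation_grid(taxa, truth.values)
        row = res.r.loc["planted_taxon"].abs()
        if row.idxmax() == truth.values.index[2]:
            wins += 1
    assert wins > 10
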