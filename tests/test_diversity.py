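"""Alpha-diversity estimators against frozen values and independent oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity import alpha as skb

import fermflavor as ff

count_vectors = st.lists(st.integers(0, 25), min_size=1, max_size=40).filter(
    lambda v: sum(v) > 0
)


@pytest.mark.parametrize(
    "counts,expected",
    [([0, 0, 0], 0), ([5, 3, 2, 0], 3), ([1], 1)],
)
def test_observed_otus_examples(counts, expected):
    assert ff.observed_otus(counts) == expected


@pytest.mark.parametrize(
    "counts,base,expected",
    [
        ([1, 1, 1, 1], 2, 2.0),
        ([7], 2, 0.0),
        ([5, 3, 2], 2, 1.48548),
        ([1, 1, 1], math.e, math.log(3)),
    ],
)
def test_shannon_examples(counts, base, expected):
    assert ff.shannon(counts, base=base) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize(
    "counts,variant,expected",
    [
        ([10, 10], "plugin", 0.5),
        ([7], "plugin", 0.0),
        ([10, 10], "unbiased", 1 - 180 / 380),
    ],
)
def test_simpson_examples(counts, variant, expected):
    assert ff.simpson(counts, variant=variant) == pytest.approx(expected)


def test_chao1_examples():
    # no singletons: estimator collapses to sobs
    assert ff.chao1([5, 5, 3]) == 3
    # sobs 10, F1 4, F2 2: bias-corrected 10 + 4*3/(2*3), classic 10 + 16/4
    counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
    assert ff.chao1(counts, "bias_corrected") == pytest.approx(12.0)
    assert ff.chao1(counts, "classic") == pytest.approx(14.0)


def test_chao1_classic_falls_back_when_no_doubletons():
    counts = [1, 1, 5]
    assert ff.chao1(counts, "classic") == ff.chao1(counts, "bias_corrected")


def test_ace_collapses_without_rare_otus():
    assert ff.ace([50, 60, 70]) == 3.0


def test_ace_falls_back_to_chao1_when_all_rare_are_singletons():
    counts = [1, 1, 1, 50]
    with pytest.warns(UserWarning, match="Chao1"):
        assert ff.ace(counts) == ff.chao1(counts)


@pytest.mark.parametrize(
    "counts,expected", [([5, 3, 2], 1.0), ([5, 3, 1, 1], 0.8), ([1], 0.0)]
)
def test_goods_coverage_examples(counts, expected):
    assert ff.goods_coverage(counts) == pytest.approx(expected)


def test_all_zero_sample_rejected():
    for fn in (ff.shannon, ff.simpson, ff.chao1, ff.ace, ff.goods_coverage):
        with pytest.raises(ValueError):
            fn([0, 0, 0])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(count_vectors)
def test_estimators_match_independent_implementation(counts):
    """Dual-route check against scikit-bio on random count vectors."""
    c = np.array(counts)
    assert ff.observed_otus(c) == skb.sobs(c)
    assert ff.shannon(c, base=2) == pytest.approx(skb.shannon(c, base=2))
    assert ff.simpson(c) == pytest.approx(skb.simpson(c))
    assert ff.chao1(c) == pytest.approx(skb.chao1(c, bias_corrected=True))
    assert ff.goods_coverage(c) == pytest.approx(skb.goods_coverage(c))
    rare = c[(c > 0) & (c <= 10)]
    if len(rare) and rare.sum() != (rare == 1).sum():
        assert ff.ace(c) == pytest.approx(skb.ace(c, rare_threshold=10))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(count_vectors)
def test_richness_estimators_bound_observed_richness(counts):
    sobs = ff.observed_otus(counts)
    assert ff.chao1(counts) >= sobs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert ff.ace(counts) >= sobs - 1e-9


@settings(max_examples=100, deadline=None, derandomize=True)
@given(count_vectors, st.randoms(use_true_random=False))
def test_indices_invariant_under_otu_permutation(counts, rnd):
    shuffled = list(counts)
    rnd.shuffle(shuffled)
    assert ff.observed_otus(shuffled) == ff.observed_otus(counts)
    assert ff.shannon(shuffled) == pytest.approx(ff.shannon(counts))
    assert ff.simpson(shuffled) == pytest.approx(ff.simpson(counts))
    assert ff.chao1(shuffled) == pytest.approx(ff.chao1(counts))


def test_shannon_maximal_at_uniform_composition():
    assert ff.shannon([4, 4, 4, 4]) >= ff.shannon([13, 1, 1, 1])
    assert ff.simpson([4, 4, 4, 4]) == pytest.approx(1 - 1 / 4)


def test_rarefaction_trivial_depths():
    counts = [2, 1]
    curve = ff.rarefaction_curve(counts, [1, 3])
    assert curve.sobs.iloc[0] == pytest.approx(1.0)  # (1-1/3)+(1-2/3)
    assert curve.sobs.iloc[1] == pytest.approx(2.0)  # full depth = sobs


def test_rarefaction_rejects_excessive_depth():
    with pytest.raises(ValueError):
        ff.rarefaction_curve([2, 1], [4])


def test_rarefaction_curve_monotone_and_concave():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 60, size=100)
    depths = list(range(1, int(counts.sum()), 50))
    curve = ff.rarefaction_curve(counts, depths)
    diffs = np.diff(curve.sobs.to_numpy())
    assert (diffs >= -1e-9).all()
    assert (np.diff(diffs) <= 1e-9).all()


def test_analytic_rarefaction_matches_subsampling():
    """Hypergeometric expectation vs Monte-Carlo subsampling (3 MC SEs)."""
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 30, size=60)
    total = int(counts.sum())
    depths = [total // 10, total // 4, total // 2, 3 * total // 4, total]
    n_rep = 2000
    analytic = ff.rarefaction_curve(counts, depths, method="analytic")
    # subsampling oracle with per-depth SE
    pool = np.repeat(np.arange(len(counts)), counts)
    for d, expected in zip(depths, analytic.sobs):
        vals = [
            len(np.unique(rng.choice(pool, size=d, replace=False)))
            for _ in range(n_rep)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(vals) - expected) <= max(3 * se, 1e-9)


def test_alpha_table_and_stage_summary(community, design):
    otus, _ = community
    table = ff.alpha_diversity_table(otus.counts)
    assert list(table.columns) == [
        "observed_otus", "shannon", "simpson", "chao1", "ace", "goods_coverage",
    ]
    assert (table["goods_coverage"].between(0, 1)).all()
    assert (table["chao1"] >= table["observed_otus"]).all()
    summary = ff.stage_summary(table, design)
    assert list(summary.index) == list(design.stages)
    ht1 = design.samples_of("HT1")
    assert summary.loc["HT1", "shannon_mean"] == pytest.approx(
        table.loc[ht1, "shannon"].mean()
    )
    assert summary.loc["HT1", "shannon_sd"] == pytest.approx(
        table.loc[ht1, "shannon"].std(ddof=1)
    )
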