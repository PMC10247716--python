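"""Community analysis: rarefaction, diversity, CSS, ordination, LDA screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from gutmediate.containers import FeatureTable
from gutmediate.microbiome import (
    alpha_diversity,
    bray_curtis,
    css_normalize,
    lda_effect_screen,
    pcoa,
    rarefy,
)


def _single_sample_table(counts):
    groups = pd.Series(["control"], index=["s1"], name="group")
    vals = pd.DataFrame({"s1": counts}, index=[f"f{i}" for i in range(len(counts))])
    return FeatureTable(vals, groups, "counts")


class TestRarefy:
    def test_columns_sum_to_depth(self, count_table):
        rare = rarefy(count_table, depth=100, seed=1)
        assert (rare.values.sum(axis=0) == 100).all()

    def test_full_depth_is_identity(self):
        t = _single_sample_table([5, 3, 2])
        rare = rarefy(t, depth=10, seed=0)
        assert (rare.values["s1"] == [5, 3, 2]).all()

    def test_absent_features_stay_absent(self, count_table):
        t = count_table.copy()
        t.values.iloc[3] = 0
        rare = rarefy(t, depth=50, seed=2)
        assert (rare.values.iloc[3] == 0).all()

    def test_shallow_sample_raises_with_name(self, count_table):
        depth = int(count_table.values.sum(axis=0).max()) + 1
        with pytest.raises(ValueError, match=count_table.sample_ids[0]):
            rarefy(count_table, depth=depth)

    def test_reproducible_for_fixed_seed(self, count_table):
        a = rarefy(count_table, depth=80, seed=9)
        b = rarefy(count_table, depth=80, seed=9)
        assert a.values.equals(b.values)

    def test_hypergeometric_expectation(self):
        # [9000, 1000] rarefied to 1000: E[feature 1] = 900,
        # per-draw var = 1000*0.9*0.1*(9000/9999) ~ 81 -> SE(mean of 500) ~ 0.4
        t = _single_sample_table([9000, 1000])
        means = np.mean(
            [rarefy(t, depth=1000, seed=s).values.iloc[0, 0] for s in range(500)]
        )
        assert abs(means - 900.0) < 3 * (81.0**0.5) / (500**0.5)


class TestAlphaDiversity:
    def test_uniform_counts_closed_form(self):
        div = alpha_diversity(_single_sample_table([4, 4, 4, 4]))
        row = div.iloc[0]
        assert row["shannon"] == pytest.approx(2.0)
        assert row["simpson"] == pytest.approx(0.75)
        assert row["observed"] == 4
        assert row["chao1"] == pytest.approx(4.0)

    def test_single_taxon(self):
        row = alpha_diversity(_single_sample_table([8])).iloc[0]
        assert row["shannon"] == 0.0 and row["simpson"] == 0.0

    def test_chao1_with_doubletons(self):
        row = alpha_diversity(_single_sample_table([1, 1, 2, 5])).iloc[0]
        assert row["chao1"] == pytest.approx(6.0)  # 4 + 2^2/(2*1)

    def test_chao1_bias_corrected_without_doubletons(self):
        row = alpha_diversity(_single_sample_table([1, 1, 5])).iloc[0]
        assert row["chao1"] == pytest.approx(3 + 2 * 1 / 2)  # S + F1(F1-1)/(2(F2+1))

    def test_observed_never_exceeds_chao1(self, count_table):
        div = alpha_diversity(rarefy(count_table, depth=60, seed=0))
        assert (div["observed"] <= div["chao1"] + 1e-12).all()

    def test_matches_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=12)
        counts[0] = 5  # ensure non-empty
        row = alpha_diversity(_single_sample_table(counts)).iloc[0]
        assert row["shannon"] == pytest.approx(float(skbio_alpha.shannon(counts, base=2)))
        assert row["simpson"] == pytest.approx(float(skbio_alpha.simpson(counts)))
        assert row["observed"] == int(skbio_alpha.sobs(counts))

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError):
            alpha_diversity(_single_sample_table([0, 0]))


class TestCssNormalize:
    def test_identical_samples_identical_columns(self, groups12):
        col = np.array([1, 5, 10, 0, 2])
        vals = pd.DataFrame(
            {s: col for s in groups12.index}, index=[f"f{i}" for i in range(5)]
        )
        out = css_normalize(FeatureTable(vals, groups12, "counts"))
        assert np.allclose(out.values.to_numpy(), out.values.iloc[:, [0]].to_numpy())

    def test_scaling_invariance(self):
        groups = pd.Series(["control", "hypoxia"], index=["a", "b"], name="group")
        vals = pd.DataFrame({"a": [1, 5, 10], "b": [7, 35, 70]}, index=list("xyz"))
        out = css_normalize(FeatureTable(vals, groups, "counts"))
        assert np.allclose(out.values["a"], out.values["b"])

    def test_hand_computed_scaling_factor(self):
        # counts [1,5,10]: median nonzero = 5, s = 1+5 = 6
        t = _single_sample_table([1, 5, 10])
        out = css_normalize(t, quantile=0.5, scale=1000.0)
        assert np.allclose(out.values["s1"], np.array([1, 5, 10]) / 6.0 * 1000.0)

    def test_bad_quantile_raises(self, count_table):
        with pytest.raises(ValueError):
            css_normalize(count_table, quantile=1.5)


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        groups = pd.Series(["control"] * 3, index=["a", "b", "c"], name="group")
        vals = pd.DataFrame(
            {"a": [2, 1, 0], "b": [2, 1, 0], "c": [0, 0, 5]}, index=list("xyz")
        )
        d = bray_curtis(FeatureTable(vals, groups, "counts"))
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_direct_formula(self):
        groups = pd.Series(["control", "hypoxia"], index=["a", "b"], name="group")
        vals = pd.DataFrame({"a": [2, 1], "b": [1, 3]}, index=["x", "y"])
        d = bray_curtis(FeatureTable(vals, groups, "counts"))
        assert d.loc["a", "b"] == pytest.approx(3 / 7)

    def test_bounded_symmetric_zero_diagonal(self, count_table):
        d = bray_curtis(count_table).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_all_zero_pair_warns_and_reports_zero(self, groups12):
        vals = pd.DataFrame(
            np.zeros((3, 12)), index=list("xyz"), columns=groups12.index
        )
        vals.iloc[0, 0] = 5
        with pytest.warns(RuntimeWarning):
            d = bray_curtis(FeatureTable(vals, groups12, "counts"))
        assert d.iloc[1, 2] == 0.0


class TestPcoa:
    def test_two_samples(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        res = pcoa(d)
        assert res.coordinates.shape == (2, 1)
        assert np.allclose(np.abs(res.coordinates.to_numpy().ravel()), 0.3)

    def test_three_equidistant_samples(self):
        d = np.full((3, 3), 1.0) - np.eye(3)
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_proportions_sum_to_at_most_one(self, count_table):
        res = pcoa(bray_curtis(count_table))
        assert res.proportion_explained.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_asymmetric_input_raises(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_matches_scikit_bio_on_euclidean_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        n = ours.coordinates.shape[1]
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1],
            np.sort(np.asarray(theirs.eigvals))[::-1][:n],
            atol=1e-8,
        )


def _screen_table(groups12, seed=0, n_features=30, planted=None):
    rng = np.random.default_rng(seed)
    base = 10.0 ** rng.normal(3.0, 0.5, size=n_features)
    vals = base[:, None] * np.exp(rng.normal(0, 0.05, size=(n_features, 12)))
    if planted is not None:
        lo, hi = planted
        row = np.where(groups12.to_numpy() == "hypoxia", hi, lo)
        vals[0] = row * np.exp(rng.normal(0, 0.05, size=12))
    counts = np.round(vals).astype(int)
    ids = [f"Genus_{i + 1:03d}" for i in range(n_features)]
    return FeatureTable(
        pd.DataFrame(counts, index=ids, columns=groups12.index), groups12, "counts"
    )


class TestLdaEffectScreen:
    def test_identical_feature_not_passed(self, groups12):
        t = _screen_table(groups12, seed=1)
        t.values.iloc[5] = 1000  # constant across all samples
        res = lda_effect_screen(t, seed=0)
        row = res[res["feature_id"] == "Genus_006"].iloc[0]
        assert not row["passed"] and row["lda_score"] == pytest.approx(0.0, abs=0.5)

    def test_planted_strong_feature_passes(self, groups12):
        # per-million means ~2e5 vs ~2e3 with 5% CV: score ~ log10(mean diff) ~ 5
        t = _screen_table(groups12, seed=2, planted=(2e3, 2e5))
        # make the planted feature dominate per-million space as designed
        res = lda_effect_screen(t, seed=3)
        row = res.iloc[0]
        assert row["passed"] and row["lda_score"] > 3.0
        assert row["enriched_group"] == "hypoxia"

    def test_sample_order_invariance(self, groups12):
        t = _screen_table(groups12, seed=4, planted=(1e3, 5e4))
        perm = np.random.default_rng(0).permutation(12)
        shuffled = FeatureTable(
            t.values.iloc[:, perm], groups12.iloc[perm], "counts"
        )
        a = lda_effect_screen(t, seed=7)
        b = lda_effect_screen(shuffled, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_false_positive_rate_bounded(self, groups12):
        # 200 null features, same log-normal in both groups
        rng = np.random.default_rng(10)
        vals = np.round(10.0 ** rng.normal(3.0, 0.4, size=(200, 12))).astype(int)
        t = FeatureTable(
            pd.DataFrame(
                vals, index=[f"g{i}" for i in range(200)], columns=groups12.index
            ),
            groups12,
            "counts",
        )
        res = lda_effect_screen(t, seed=11)
        assert res["passed"].mean() <= 0.05 + 0.03

    def test_requires_two_groups(self, groups12):
        t = _screen_table(groups12)
        mono = FeatureTable(
            t.values, pd.Series("control", index=groups12.index), "counts"
        )
        with pytest.raises(ValueError):
            lda_effect_screen(mono)
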