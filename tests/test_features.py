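import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from fluorostress.features import (
    correlation_matrix,
    feature_scores,
    make_table,
    select_features,
    tree_importances,
)
from fluorostress.indices import INDEX_NAMES


def table_from_matrix(x, labels):
    """Wrap an (n, 8) array + labels into a feature table."""
    rows = [dict(zip(INDEX_NAMES, row)) for row in np.asarray(x)]
    return make_table(rows, labels)


@pytest.fixture
def random_table(rng):
    x = rng.normal(size=(30, 8))
    labels = ["controlled"] * 10 + ["stressed"] * 10 + ["recovered"] * 10
    # give two features some class signal so trees have something to split
    x[10:20, 0] += 2.0
    x[20:30, 3] += 2.0
    return table_from_matrix(x, labels)


class TestCorrelationMatrix:
    def test_diagonal_symmetry_and_bounds(self, default_table):
        r, sig = correlation_matrix(default_table, "controlled")
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert ((r.to_numpy() >= -1) & (r.to_numpy() <= 1)).all()
        assert bool(sig.iloc[0, 0])  # a column against itself

    def test_affine_column_correlates_exactly(self, rng):
        x = np.tile(rng.normal(size=(10, 1)), (1, 8))
        x[:, 1] = 2 * x[:, 0] + 1
        table = table_from_matrix(x, ["controlled"] * 10)
        r, sig = correlation_matrix(table, "controlled")
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert bool(sig.iloc[0, 1])

    def test_matches_scipy_pearsonr_oracle(self, rng):
        """r and the p < 0.05 flag agree pairwise with scipy.stats.pearsonr
        on a 10-sample table."""
        x = rng.normal(size=(10, 8))
        table = table_from_matrix(x, ["stressed"] * 10)
        r, sig = correlation_matrix(table, "stressed")
        for a in range(8):
            for b in range(a + 1, 8):
                ref = stats.pearsonr(x[:, a], x[:, b])
                assert r.iloc[a, b] == pytest.approx(ref.statistic, abs=1e-12)
                assert bool(sig.iloc[a, b]) == (ref.pvalue < 0.05)

    def test_constant_column_yields_nan_with_warning(self, rng, caplog):
        x = rng.normal(size=(10, 8))
        x[:, 2] = 0.7
        table = table_from_matrix(x, ["recovered"] * 10)
        with caplog.at_level("WARNING"):
            r, _ = correlation_matrix(table, "recovered")
        assert np.isnan(r.iloc[2, 0]) and np.isnan(r.iloc[2, 2])
        assert any("constant" in rec.message for rec in caplog.records)

    def test_too_few_samples_raises(self, rng):
        table = table_from_matrix(rng.normal(size=(2, 8)), ["controlled"] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(table, "controlled")


class TestTreeImportances:
    def test_hand_computed_depth1_importance(self):
        """Six samples, one perfectly splitting feature: root Gini is
        0.5, both children pure, all 6 samples reach the root, so the
        weighted impurity decrease is (6/6) * (0.5 - 0) = 0.5 on that
        feature and 0 elsewhere."""
        x = np.zeros((6, 8))
        x[:, 4] = [0, 0, 0, 1, 1, 1]
        y = ["controlled"] * 3 + ["stressed"] * 3
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        imp = tree_importances(tree, 8)
        expected = np.zeros(8)
        expected[4] = 0.5
        np.testing.assert_allclose(imp, expected, atol=1e-12)

    def test_matches_sklearn_importances(self, random_table):
        """The explicit traversal reproduces sklearn's own normalised
        impurity importances on a deeper tree (independent cross-check)."""
        x = random_table[list(INDEX_NAMES)].to_numpy()
        y = random_table["label"].to_numpy()
        tree = DecisionTreeClassifier(random_state=0).fit(x, y)
        mine = tree_importances(tree, 8)
        np.testing.assert_allclose(
            mine / mine.sum(), tree.feature_importances_, atol=1e-12
        )


class TestFeatureScores:
    def test_single_tree_mode_is_hand_checkable(self):
        x = np.zeros((6, 8))
        x[:, 4] = [0, 0, 0, 1, 1, 1]
        table = table_from_matrix(x, ["controlled"] * 3 + ["stressed"] * 3)
        scores = feature_scores(table, n_trees=1, bootstrap=False, max_depth=1)
        assert scores["ci_rededge"] == pytest.approx(1.0)  # index 4
        assert scores.drop("ci_rededge").sum() == pytest.approx(0.0)

    def test_scores_sum_to_one(self, random_table):
        assert feature_scores(random_table, seed=0).sum() == pytest.approx(1.0, abs=1e-9)

    def test_separating_feature_dominates_noise(self, rng):
        x = rng.normal(size=(60, 8))
        labels = np.repeat(["controlled", "stressed", "recovered"], 20)
        x[:, 6] = np.repeat([0.0, 5.0, 10.0], 20) + rng.normal(0, 0.1, 60)
        scores = feature_scores(table_from_matrix(x, list(labels)), seed=0)
        assert all(scores["sr"] > scores[f] for f in INDEX_NAMES if f != "sr")

    def test_permutation_equivariance_single_tree(self, random_table):
        """Swapping two feature columns swaps their scores exactly in
        the deterministic single-tree mode (no bootstrap ties)."""
        a, b = INDEX_NAMES[0], INDEX_NAMES[3]
        swapped = random_table.copy()
        swapped[[a, b]] = swapped[[b, a]].to_numpy()
        scores = feature_scores(random_table, n_trees=1, bootstrap=False)
        scores_swapped = feature_scores(swapped, n_trees=1, bootstrap=False)
        assert scores_swapped[b] == pytest.approx(scores[a], abs=1e-9)
        assert scores_swapped[a] == pytest.approx(scores[b], abs=1e-9)

    def test_permutation_equivariance_ensemble(self, random_table):
        """The bootstrap ensemble is equivariant up to the split-search
        tie-breaking noise of individual trees."""
        a, b = INDEX_NAMES[0], INDEX_NAMES[3]
        swapped = random_table.copy()
        swapped[[a, b]] = swapped[[b, a]].to_numpy()
        scores = feature_scores(random_table, seed=7)
        scores_swapped = feature_scores(swapped, seed=7)
        assert scores_swapped[b] == pytest.approx(scores[a], abs=0.02)
        assert scores_swapped[a] == pytest.approx(scores[b], abs=0.02)

    def test_single_class_raises(self, rng):
        table = table_from_matrix(rng.normal(size=(10, 8)), ["stressed"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            feature_scores(table)

    def test_signal_features_outscore_noise_on_synthetic_data(self, default_table):
        """On the default generator every index is driven by the same
        class-dependent spectral parameters except none is pure noise;
        appending four pure-noise columns, the real indices must carry
        nearly all the importance."""
        rng = np.random.default_rng(0)
        noisy = default_table.copy()
        signal = feature_scores(noisy, seed=0)
        # scramble half the columns into noise and re-score
        for f in ("psnd_a", "pssr_a", "ndre", "sr"):
            noisy[f] = rng.normal(size=len(noisy))
        scores = feature_scores(noisy, seed=0)
        intact = [f for f in INDEX_NAMES if f not in ("psnd_a", "pssr_a", "ndre", "sr")]
        assert scores[intact].sum() > scores.drop(intact).sum()
        assert signal.sum() == pytest.approx(1.0, abs=1e-9)


class TestSelectFeatures:
    def test_k8_returns_all(self, random_table):
        scores = feature_scores(random_table, seed=0)
        assert set(select_features(scores, 8)) == set(INDEX_NAMES)

    def test_k1_returns_dominant_feature(self, rng):
        x = rng.normal(size=(60, 8))
        labels = np.repeat(["controlled", "stressed", "recovered"], 20)
        x[:, 7] = np.repeat([0.0, 5.0, 10.0], 20)
        scores = feature_scores(table_from_matrix(x, list(labels)), seed=0)
        assert select_features(scores, 1) == ["rvsi"]

    def test_four_signal_indices_selected(self, rng):
        """When exactly four indices carry class signal, those four are
        selected in score order."""
        x = rng.normal(size=(90, 8))
        labels = np.repeat(["controlled", "stressed", "recovered"], 30)
        shift = np.repeat([0.0, 3.0, 6.0], 30)
        for col in (1, 3, 4, 7):  # psnd_b, pssr_b, ci_rededge, rvsi
            x[:, col] += shift + rng.normal(0, 0.2, 90)
        scores = feature_scores(table_from_matrix(x, list(labels)), seed=0)
        assert set(select_features(scores, 4)) == {"psnd_b", "pssr_b", "ci_rededge", "rvsi"}

    def test_ties_break_by_canonical_order(self):
        scores = pd.Series(1 / 8, index=list(INDEX_NAMES))
        assert select_features(scores, 3) == list(INDEX_NAMES[:3])

    def test_bad_k_raises(self):
        scores = pd.Series(1 / 8, index=list(INDEX_NAMES))
        with pytest.raises(ValueError):
            select_features(scores, 0)
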