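"""Session splitting, SMOTE balancing, Lasso selection and the classifier."""

import numpy as np
import pandas as pd
import pytest

import asap
from asap.classifier import DEFAULT_LAMBDA_GRID


def make_informative(n=1200, n_noise=8, seed=0, prevalence=0.3):
    """Log-odds linear in the first three features, the rest pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 3 + n_noise))
    eta = 1.8 * X[:, 0] - 1.5 * X[:, 1] + 1.2 * X[:, 2]
    eta += np.log(prevalence / (1 - prevalence))
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    names = [f"inf{i}" for i in range(3)] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=names), y


class TestSplitSessions:
    @staticmethod
    def _sessions():
        ages = [6.0] * 15 + [9.0] * 15 + [12.0] * 15 + [24.0] * 16 + [36.0] * 14
        return [f"s{i}" for i in range(75)], ages

    def test_75_sessions_gives_67_8(self):
        sessions, ages = self._sessions()
        train, test = asap.split_sessions(sessions, ages=ages, seed=0)
        assert (len(train), len(test)) == (67, 8)
        assert set(train).isdisjoint(test)

    def test_stratified_across_age_groups(self):
        sessions, ages = self._sessions()
        _, test = asap.split_sessions(sessions, ages=ages, seed=1)
        by_age = {a: 0 for a in (6.0, 9.0, 12.0, 24.0, 36.0)}
        lookup = dict(zip(sessions, ages))
        for s in test:
            by_age[lookup[s]] += 1
        assert all(1 <= c <= 2 for c in by_age.values())

    def test_ten_sessions_nine_one(self):
        train, test = asap.split_sessions(list("abcdefghij"), ages=[12.0] * 10, seed=2)
        assert (len(train), len(test)) == (9, 1)

    def test_deterministic_under_seed(self):
        sessions, ages = self._sessions()
        a = asap.split_sessions(sessions, ages=ages, seed=7)
        b = asap.split_sessions(sessions, ages=ages, seed=7)
        assert a == b

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            asap.split_sessions([])


class TestBalanceSmote:
    def test_imbalanced_becomes_balanced(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (200, 4))
        y = (rng.random(200) < 0.29).astype(int)
        Xb, yb = asap.balance_smote(X, y, seed=1)
        _, counts = np.unique(yb, return_counts=True)
        assert counts[0] == counts[1]

    def test_originals_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 3))
        y = np.array([1] * 12 + [0] * 48)
        Xb, yb = asap.balance_smote(X, y, seed=2)
        assert np.allclose(Xb[:60], X)
        assert np.array_equal(yb[:60], y)

    def test_already_balanced_untouched(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 3))
        y = np.array([0, 1] * 20)
        Xb, yb = asap.balance_smote(X, y)
        assert Xb.shape == X.shape

    def test_synthetic_rows_lie_on_minority_segments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (40, 2))
        y = np.array([1] * 8 + [0] * 32)
        Xb, yb = asap.balance_smote(X, y, seed=4)
        minority = X[y == 1]
        for row in Xb[40:]:
            on_segment = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = (
                        np.linalg.norm(row - minority[i])
                        + np.linalg.norm(row - minority[j])
                        - np.linalg.norm(minority[i] - minority[j])
                    )
                    on_segment |= abs(d) < 1e-9
            assert on_segment

    def test_tiny_minority_raises(self):
        X = np.zeros((10, 2))
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(ValueError):
            asap.balance_smote(X, y, k_neighbors=5)


class TestSelectFeatures:
    def test_informative_features_found(self):
        X, y = make_informative(seed=5)
        selected, importance, _ = asap.select_features(X, y, lam=1e-4, seed=0)
        assert {"inf0", "inf1", "inf2"} <= set(selected)

    def test_threshold_above_everything_empty(self):
        X, y = make_informative(seed=6)
        selected, _, _ = asap.select_features(X, y, lam=1e-4, threshold=1e6, seed=0)
        assert selected == []

    def test_huge_lambda_kills_all_coefficients(self):
        X, y = make_informative(seed=7)
        selected, importance, _ = asap.select_features(X, y, lam=10.0, seed=0)
        assert selected == []
        assert np.allclose(importance.to_numpy(), 0.0)

    def test_selection_monotone_in_threshold(self):
        X, y = make_informative(seed=8)
        low, imp, _ = asap.select_features(X, y, lam=1e-4, threshold=0.01, seed=0)
        high = [n for n in imp.index if imp[n] > 0.5]
        assert set(high) <= set(low)

    def test_single_class_raises(self):
        X, _ = make_informative(seed=9)
        with pytest.raises(ValueError):
            asap.select_features(X, np.zeros(len(X), dtype=int))


class TestSustainedAttentionClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(0, 1, (300, 4)), columns=list("abcd"))
        y = (X["a"] > 0).astype(int).to_numpy()
        clf = asap.SustainedAttentionClassifier(lam=1e-4, smote=False, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_probabilities_bounded(self):
        X, y = make_informative(seed=11)
        clf = asap.SustainedAttentionClassifier(lam=1e-4, random_state=0).fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        assert np.all((p >= 0) & (p <= 1))

    def test_feature_name_mismatch_raises(self):
        X, y = make_informative(seed=12)
        clf = asap.SustainedAttentionClassifier(lam=1e-4, random_state=0).fit(X, y)
        bad = X.rename(columns={"inf0": "wrong"})
        with pytest.raises(ValueError, match="feature names"):
            clf.predict(bad)

    def test_refit_deterministic_under_seed(self):
        X, y = make_informative(seed=13)
        a = asap.SustainedAttentionClassifier(lam=1e-4, random_state=3).fit(X, y)
        b = asap.SustainedAttentionClassifier(lam=1e-4, random_state=3).fit(X, y)
        assert np.allclose(a.coef_, b.coef_)
        assert a.selected_features_ == b.selected_features_

    def test_json_roundtrip_identical_predictions(self, tmp_path):
        X, y = make_informative(seed=14)
        clf = asap.SustainedAttentionClassifier(lam=1e-4, random_state=0).fit(X, y)
        path = tmp_path / "model.json"
        clf.to_json(path)
        back = asap.SustainedAttentionClassifier.from_json(path)
        assert np.allclose(back.predict_proba(X), clf.predict_proba(X))

    def test_sklearn_params_roundtrip(self):
        clf = asap.SustainedAttentionClassifier(threshold=0.05, lam=1e-3)
        params = clf.get_params()
        assert params["threshold"] == 0.05
        clone = asap.SustainedAttentionClassifier(**params)
        assert clone.get_params() == params


def test_lambda_grid_matches_contract():
    assert DEFAULT_LAMBDA_GRID.size == 50
    assert DEFAULT_LAMBDA_GRID.min() == pytest.approx(1e-6)
    assert DEFAULT_LAMBDA_GRID.max() == pytest.approx(1e-1)
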