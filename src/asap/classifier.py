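"""Step-2 point-wise attention classification.

Session-stratified splitting, L1-penalised logistic feature selection with
a 0.03 mean-importance threshold, SMOTE class balancing, and an unpenalised
logistic refit on the selected features.  The model is exposed as a
scikit-learn estimator (:class:`SustainedAttentionClassifier`) so it
composes with pipelines and model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "split_sessions",
    "balance_smote",
    "select_features",
    "SustainedAttentionClassifier",
]

AGE_GROUP_MONTHS = (6.0, 9.0, 12.0, 24.0, 36.0)
DEFAULT_THRESHOLD = 0.03
DEFAULT_LAMBDA_GRID = np.logspace(-6, -1, 50)


def age_group(age_months: float) -> float:
    """Nearest study age bin (6, 9, 12, 24 or 36 months)."""
    groups = np.asarray(AGE_GROUP_MONTHS)
    return float(groups[np.argmin(np.abs(groups - age_months))])


def split_sessions(
    sessions: list,
    ages: list[float] | None = None,
    test_fraction: float = 1.0 / 9.0,
    seed: int = 0,
) -> tuple[list, list]:
    """Age-stratified train/test split of whole sessions (~9:1).

    ``sessions`` may be any objects; ages are read from an ``age_months``
    attribute unless passed explicitly.  Deterministic under ``seed``; no
    session appears in both sets.
    """
    if not sessions:
        raise ValueError("empty session list")
    if ages is None:
        ages = [float(s.age_months) for s in sessions]
    if len(ages) != len(sessions):
        raise ValueError("ages must align with sessions")

    rng = np.random.default_rng(seed)
    n_test = int(round(len(sessions) * test_fraction))
    n_test = max(1, min(n_test, len(sessions) - 1))

    strata: dict[float, list[int]] = {}
    for i, a in enumerate(ages):
        strata.setdefault(age_group(a), []).append(i)

    # proportional quota with largest-remainder rounding
    keys = sorted(strata)
    exact = np.array([len(strata[k]) for k in keys]) * n_test / len(sessions)
    quota = np.floor(exact).astype(int)
    rema = exact - quota
    for k in np.argsort(-rema)[: n_test - quota.sum()]:
        quota[k] += 1

    test_idx: list[int] = []
    for k, q in zip(keys, quota):
        members = np.array(strata[k])
        take = rng.permutation(members.size)[: min(q, members.size)]
        test_idx.extend(members[take])
    test_set = set(test_idx)
    train = [s for i, s in enumerate(sessions) if i not in test_set]
    test = [s for i, s in enumerate(sessions) if i in test_set]
    return train, test


def balance_smote(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling to exactly balanced classes.

    Each synthetic row lies on the segment between a minority row and one
    of its ``k_neighbors`` nearest minority neighbours; original rows are
    preserved, in order, ahead of the synthetic block.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min < k_neighbors + 1:
        raise ValueError("minority class too small for SMOTE")

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)  # skip self at 0
    gap = rng.random((n_new, 1))
    neigh = X_min[idx[base, pick]]
    synth = X_min[base] + gap * (neigh - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _lambda_to_C(lam: float, n: int) -> float:
    # sklearn minimises ||w||_1 + C * sum(loss); glmnet-style lambda is the
    # per-observation penalty weight, hence C = 1 / (lambda * n)
    return 1.0 / (max(lam, 1e-300) * n)


def select_features(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
    lam: float | str = "auto",
    seed: int = 0,
    smote: bool = True,
    k_neighbors: int = 5,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> tuple[list[str], pd.Series, float]:
    """Lasso-importance feature selection.

    Features are standardised on the training rows; an L1-penalised
    logistic regression is fitted per CV fold (SMOTE-balanced inside each
    fold) and the importance of a feature is the mean absolute standardised
    coefficient across folds.  ``lam='auto'`` picks the penalty minimising
    mean cross-validated deviance over a 50-point logarithmic grid.
    Returns (selected names, importance series, lambda used).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")

    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (Xv - mu) / sd

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_data = []
    for f, (tr, va) in enumerate(skf.split(Z, y)):
        Ztr, ytr = Z[tr], y[tr]
        if smote:
            Ztr, ytr = balance_smote(Ztr, ytr, seed=seed + 17 * f, k_neighbors=k_neighbors)
        fold_data.append((Ztr, ytr, Z[va], y[va]))

    grid = np.sort(np.atleast_1d(lambda_grid))[::-1] if lam == "auto" else np.array([float(lam)])
    dev = np.zeros((grid.size, folds))
    coefs = np.zeros((grid.size, folds, Z.shape[1]))
    for gi, lam_g in enumerate(grid):
        for f, (Ztr, ytr, Zva, yva) in enumerate(fold_data):
            clf = LogisticRegression(
                l1_ratio=1.0, C=_lambda_to_C(lam_g, Ztr.shape[0]),
                solver="liblinear", max_iter=200, tol=1e-4,
            )
            clf.fit(Ztr, ytr)
            coefs[gi, f] = clf.coef_[0]
            p = clf.predict_proba(Zva)[:, 1]
            dev[gi, f] = log_loss(yva, p, labels=[0, 1])
    if lam == "auto":
        # one-standard-error rule: the sparsest lambda whose CV deviance is
        # within one SE of the minimum
        mean_dev = dev.mean(axis=1)
        se = dev.std(axis=1, ddof=1) / np.sqrt(folds)
        i_min = int(np.argmin(mean_dev))
        cutoff = mean_dev[i_min] + se[i_min]
        best = int(np.flatnonzero(mean_dev <= cutoff)[0])  # grid is descending
    else:
        best = 0
    lam_used = float(grid[best])

    importance = pd.Series(np.abs(coefs[best]).mean(axis=0), index=names, name="importance")
    selected = [n for n in names if importance[n] > threshold]
    return selected, importance, lam_used


class SustainedAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Point-wise SA classifier: Lasso selection + SMOTE + logistic refit.

    Parameters
    ----------
    threshold : float
        Mean-importance cut for feature selection (importance is the mean
        absolute standardised Lasso coefficient across CV folds).
    lam : float or "auto"
        L1 penalty weight; "auto" selects by cross-validated deviance.
    n_folds : int
        Cross-validation folds for selection.
    smote : bool
        Balance classes by SMOTE before fitting (inside each fold and for
        the final refit).
    k_neighbors : int
        SMOTE neighbourhood size.
    decision_threshold : float
        Probability cut for the binary label.
    random_state : int
        Seed for folds, SMOTE interpolation and solver.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        lam: float | str = "auto",
        n_folds: int = 5,
        smote: bool = True,
        k_neighbors: int = 5,
        decision_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.lam = lam
        self.n_folds = n_folds
        self.smote = smote
        self.k_neighbors = k_neighbors
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate(self, X, reset: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        if reset:
            self.feature_names_in_ = np.asarray(names, dtype=object)
            self.n_features_in_ = Xv.shape[1]
        else:
            if list(names) != list(self.feature_names_in_):
                raise ValueError("feature names at predict do not match fit")
        return Xv

    def fit(self, X, y):
        Xv = self._validate(X, reset=True)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need both classes to fit")

        names = list(self.feature_names_in_)
        Xdf = pd.DataFrame(Xv, columns=names)
        selected, importance, lam_used = select_features(
            Xdf, y,
            folds=self.n_folds, threshold=self.threshold, lam=self.lam,
            seed=self.random_state, smote=self.smote, k_neighbors=self.k_neighbors,
        )
        if not selected:
            raise ValueError("feature selection kept no features")
        self.importances_ = importance
        self.selected_features_ = selected
        self.lambda_ = lam_used

        self.mean_ = Xv.mean(axis=0)
        self.scale_ = np.where(Xv.std(axis=0) == 0, 1.0, Xv.std(axis=0))
        sel_idx = [names.index(n) for n in selected]
        Z = (Xv - self.mean_) / self.scale_
        Zs, ys = Z[:, sel_idx], y
        if self.smote:
            Zs, ys = balance_smote(Zs, ys, seed=self.random_state, k_neighbors=self.k_neighbors)
        final = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        final.fit(Zs, ys)
        self.coef_ = final.coef_[0]
        self.intercept_ = float(final.intercept_[0])
        self._sel_idx = sel_idx
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xv = self._validate(X, reset=False)
        Z = (Xv - self.mean_) / self.scale_
        eta = Z[:, self._sel_idx] @ self.coef_ + self.intercept_
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.decision_threshold).astype(int)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> dict:
        """Serialise the fitted model as a structured text document."""
        check_is_fitted(self, "coef_")
        doc = {
            "selected_features": list(self.selected_features_),
            "feature_names": list(self.feature_names_in_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "coefficients": self.coef_.tolist(),
            "intercept": self.intercept_,
            "lambda": self.lambda_,
            "seed": self.random_state,
            "importance": self.importances_.tolist(),
            "decision_threshold": self.decision_threshold,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "SustainedAttentionClassifier":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        est = cls(decision_threshold=doc["decision_threshold"], random_state=doc["seed"])
        names = doc["feature_names"]
        est.feature_names_in_ = np.asarray(names, dtype=object)
        est.n_features_in_ = len(names)
        est.classes_ = np.array([0, 1])
        est.selected_features_ = list(doc["selected_features"])
        est.mean_ = np.asarray(doc["mean"], dtype=float)
        est.scale_ = np.asarray(doc["scale"], dtype=float)
        est.coef_ = np.asarray(doc["coefficients"], dtype=float)
        est.intercept_ = float(doc["intercept"])
        est.lambda_ = float(doc["lambda"])
        est.importances_ = pd.Series(doc["importance"], index=names)
        est._sel_idx = [names.index(n) for n in est.selected_features_]
        return est
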