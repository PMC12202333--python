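"""Base learners and the stacking ensemble.

Three fast classifiers are fused: L2 logistic regression (LR), an extreme
learning machine (ELM) written here — a single-hidden-layer network whose
input weights are random and whose output weights are solved analytically
by ridge least squares — and LightGBM gradient-boosted trees (LGBM).

The stacking scheme is the classical out-of-fold construction: each base
learner's probabilities on held-out inner folds form a 3-column
meta-feature matrix; a logistic meta-combiner is fitted on those
out-of-fold columns only (so the meta-learner never sees a base prediction
made on a row the base was trained on), and the bases are then refitted on
the full training split for deployment.  ``fusion="mean"`` replaces the
learned combiner by a plain average of the three probabilities.

LR and the ELM expect z-scored inputs; standardization is the caller's
responsibility (the evaluation module fits a scaler per training fold).
"""

from __future__ import annotations

import warnings

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

BASE_LEARNER_NAMES = ("lr", "elm", "lgbm")

# lightgbm's sklearn wrapper invents "Column_i" feature names for array
# input and then warns on every array predict; pure noise in this pipeline
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names",
    category=UserWarning)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine for binary classification.

    Hidden layer H = sigmoid(X W + b) with W, b ~ uniform(-1, 1) drawn once
    from ``seed``; output weights solve the ridge-regularized least-squares
    problem mapping H to the 0/1 targets.  Scores are the (clipped) linear
    read-out, interpreted as probabilities of the positive class.
    """

    def __init__(self, n_hidden: int = 200, ridge: float = 1e-3,
                 seed: int = 0):
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.seed = seed

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y).astype(int)
        self.input_weights_ = rng.uniform(-1, 1, size=(X.shape[1],
                                                       self.n_hidden))
        self.hidden_bias_ = rng.uniform(-1, 1, size=self.n_hidden)
        h = _sigmoid(X @ self.input_weights_ + self.hidden_bias_)
        gram = h.T @ h + self.ridge * np.eye(self.n_hidden)
        self.output_weights_ = np.linalg.solve(gram, h.T @ y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with training data")
        h = _sigmoid(X @ self.input_weights_ + self.hidden_bias_)
        return h @ self.output_weights_

    def predict_proba(self, X) -> np.ndarray:
        score = np.clip(self.decision_function(X), 0.0, 1.0)
        return np.column_stack([1.0 - score, score])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _substream_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(int(seed) & 0x7FFFFFFF).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def make_base_learners(seed: int = 0, elm_hidden: int = 200,
                       elm_ridge: float = 1e-3, lgbm_estimators: int = 200,
                       lgbm_depth: int = 6, lgbm_lr: float = 0.1) -> dict:
    """The three base learners with seeds derived from one pipeline seed."""
    elm_seed, lgbm_seed, _ = _substream_seeds(seed, 3)
    return {
        "lr": LogisticRegression(C=1.0, max_iter=2000),  # L2 penalty (default)
        "elm": ELMClassifier(n_hidden=elm_hidden, ridge=elm_ridge,
                             seed=elm_seed),
        "lgbm": LGBMClassifier(n_estimators=lgbm_estimators,
                               max_depth=lgbm_depth, learning_rate=lgbm_lr,
                               random_state=lgbm_seed, n_jobs=1, verbose=-1),
    }


class StackingEnsemble(BaseEstimator, ClassifierMixin):
    """LR + ELM + LGBM fused by a logistic meta-combiner (or a mean).

    ``fit`` builds the out-of-fold meta-feature matrix with ``n_inner_folds``
    stratified inner folds, fits the combiner on it, then refits the bases
    on all rows.  ``feature_names`` (optional) is recorded at fit time and
    enforced at predict time.
    """

    def __init__(self, n_inner_folds: int = 5, fusion: str = "stack",
                 seed: int = 0, elm_hidden: int = 200, elm_ridge: float = 1e-3,
                 lgbm_estimators: int = 200, lgbm_depth: int = 6,
                 lgbm_lr: float = 0.1):
        if fusion not in ("stack", "mean"):
            raise ValueError("fusion must be 'stack' or 'mean'")
        self.n_inner_folds = n_inner_folds
        self.fusion = fusion
        self.seed = seed
        self.elm_hidden = elm_hidden
        self.elm_ridge = elm_ridge
        self.lgbm_estimators = lgbm_estimators
        self.lgbm_depth = lgbm_depth
        self.lgbm_lr = lgbm_lr

    def _bases(self) -> dict:
        return make_base_learners(self.seed, self.elm_hidden, self.elm_ridge,
                                  self.lgbm_estimators, self.lgbm_depth,
                                  self.lgbm_lr)

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need both classes to train the stacking model")
        self.classes_ = classes
        self.feature_names_ = list(feature_names) if feature_names else None
        self.n_features_in_ = X.shape[1]

        k = min(self.n_inner_folds, int(counts.min()))
        if k < self.n_inner_folds:
            warnings.warn(f"reducing inner folds from {self.n_inner_folds} "
                          f"to {k}: smallest class has {counts.min()} rows",
                          stacklevel=2)
        if k < 2:
            raise ValueError("smallest class too small for inner stacking folds")
        _, _, fold_seed = _substream_seeds(self.seed, 3)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)

        oof = np.zeros((len(y), len(BASE_LEARNER_NAMES)))
        for tr, te in skf.split(X, y):
            bases = self._bases()
            for col, name in enumerate(BASE_LEARNER_NAMES):
                model = clone(bases[name]).fit(X[tr], y[tr])
                oof[te, col] = model.predict_proba(X[te])[:, 1]
        self.oof_meta_features_ = oof

        if self.fusion == "stack":
            self.meta_model_ = LogisticRegression(max_iter=2000).fit(oof, y)
        else:
            self.meta_model_ = None
        self.base_models_ = {name: clone(model).fit(X, y)
                             for name, model in self._bases().items()}
        return self

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with training data")
        return X

    def base_probabilities(self, X) -> np.ndarray:
        """Positive-class probabilities of the refitted bases, shape (n, 3)."""
        X = self._check(X)
        return np.column_stack([
            self.base_models_[name].predict_proba(X)[:, 1]
            for name in BASE_LEARNER_NAMES])

    def predict_proba(self, X) -> np.ndarray:
        meta = self.base_probabilities(X)
        if self.fusion == "mean":
            score = meta.mean(axis=1)
        else:
            score = self.meta_model_.predict_proba(meta)[:, 1]
        score = np.clip(score, 0.0, 1.0)
        return np.column_stack([1.0 - score, score])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# functional wrappers -------------------------------------------------------

def train_elm(X, y, n_hidden: int = 200, ridge: float = 1e-3,
              seed: int = 0) -> ELMClassifier:
    return ELMClassifier(n_hidden=n_hidden, ridge=ridge, seed=seed).fit(X, y)


def train_stack(X, y, n_inner_folds: int = 5, fusion: str = "stack",
                seed: int = 0, **kwargs) -> StackingEnsemble:
    return StackingEnsemble(n_inner_folds=n_inner_folds, fusion=fusion,
                            seed=seed, **kwargs).fit(X, y)


def predict_stack(model: StackingEnsemble, X) -> np.ndarray:
    """Positive-class scores of a fitted stacking model, in [0, 1]."""
    return model.predict_proba(X)[:, 1]


def make_classifier(kind: str, seed: int = 0, **kwargs):
    """One of 'lr', 'elm', 'lgbm', 'stack', 'mean' with derived seeds."""
    if kind in ("stack", "mean"):
        return StackingEnsemble(fusion=kind, seed=seed, **kwargs)
    bases = make_base_learners(seed)
    if kind not in bases:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return bases[kind]
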