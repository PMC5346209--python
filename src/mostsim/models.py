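"""Probabilistic classifiers on the two-feature neighbor representation.

A query compound is represented by just two numbers derived from the
most-similar annotated ligand of a target: the Tanimoto similarity
``tc_most`` and an activity feature.  In *explicit* mode the activity
feature is the neighbor's real-valued pKi taken as-is; in *implicit* mode
it is collapsed to the 0/1 indicator ``pKi_most >= threshold``.  A single
global model is trained on pooled (feature, label) rows across all
targets, and emits complementary class probabilities ``p_a`` (active) and
``p_i`` (inactive); ``p_i`` doubles as the per-target p-value in
multiple-target scanning.

Three backends are provided, all via scikit-learn: Gaussian Naive Bayes,
(unpenalized) Logistic Regression, and a 100-tree Random Forest.  The
logistic model is

    p(active | tc_most, act) = 1 / (1 + exp(-(a0 + a1*tc_most + a2*act)))

and its fitted coefficients (a0, a1, a2) are exposed directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .fingerprints import NearestNeighbor

__all__ = [
    "FeatureVector",
    "ModelSpec",
    "LogisticCoefficients",
    "PredictionResult",
    "TrainedModel",
    "TrainingError",
    "encode_features",
    "train",
    "predict",
    "predict_proba_active",
    "save_model",
    "load_model",
]

METHODS = ("naive_bayes", "logistic_regression", "random_forest")
ACTIVITY_MODES = ("explicit", "implicit")
MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a model cannot be fitted (e.g. single-class data)."""


@dataclass(frozen=True)
class FeatureVector:
    tc_most: float
    activity_feature: float


@dataclass(frozen=True)
class ModelSpec:
    method: str = "logistic_regression"
    activity_mode: str = "explicit"
    threshold: float = 6.0
    scheme: str = "morgan"
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.activity_mode not in ACTIVITY_MODES:
            raise ValueError(
                f"unknown activity mode {self.activity_mode!r}; choose from {ACTIVITY_MODES}"
            )


@dataclass(frozen=True)
class LogisticCoefficients:
    a0: float
    a1: float
    a2: float


@dataclass(frozen=True)
class PredictionResult:
    p_a: float
    p_i: float
    label: int

    @property
    def p_value(self) -> float:
        """The probability of inactivity, used as the per-target p-value."""
        return self.p_i


def encode_features(nn: NearestNeighbor, mode: str, threshold: float) -> FeatureVector:
    """(Tc_most, pKi_most) as-is, or with pKi binarized at the threshold."""
    if mode == "explicit":
        return FeatureVector(nn.tc_most, nn.pki_most)
    if mode == "implicit":
        return FeatureVector(nn.tc_most, float(nn.pki_most >= threshold))
    raise ValueError(f"unknown activity mode: {mode!r}")


class TrainedModel:
    """A fitted backend plus the spec it was trained under."""

    def __init__(self, spec: ModelSpec, estimator):
        self.spec = spec
        self.estimator = estimator

    @property
    def coefficients(self) -> LogisticCoefficients:
        if self.spec.method != "logistic_regression":
            raise AttributeError("coefficients are only defined for the logistic backend")
        est = self.estimator
        return LogisticCoefficients(
            a0=float(est.intercept_[0]),
            a1=float(est.coef_[0][0]),
            a2=float(est.coef_[0][1]),
        )

    def _check_features(self, X: np.ndarray) -> None:
        if self.spec.activity_mode == "implicit":
            act = X[:, 1]
            if not np.all((act == 0.0) | (act == 1.0)):
                raise ValueError(
                    "implicit-mode model was given a non-indicator activity feature; "
                    "encode features with encode_features(..., mode='implicit', ...)"
                )

    def predict_proba_active(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        self._check_features(X)
        proba = self.estimator.predict_proba(X)
        active_col = int(np.where(self.estimator.classes_ == 1)[0][0])
        return proba[:, active_col]


def _feature_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([(fv.tc_most, fv.activity_feature) for fv, _ in data], dtype=float)
    y = np.array([label for _, label in data], dtype=int)
    return X, y


def train(spec: ModelSpec, data) -> TrainedModel:
    """Fit the backend named by the spec on (FeatureVector, 0/1 label) rows.

    Deterministic given ``spec.seed``.  Raises :class:`TrainingError` if
    the data contains fewer than two classes.
    """
    X, y = _feature_matrix(data)
    return train_arrays(spec, X, y)


def train_arrays(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError(
            "training data must contain both active and inactive examples"
        )
    if spec.activity_mode == "implicit" and not np.all((X[:, 1] == 0) | (X[:, 1] == 1)):
        raise ValueError("implicit-mode training features must have a 0/1 activity feature")
    if spec.method == "naive_bayes":
        est = GaussianNB()
    elif spec.method == "logistic_regression":
        # unpenalized maximum likelihood: coefficients stay comparable to
        # a data-generating (a0, a1, a2)
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
    else:
        est = RandomForestClassifier(
            n_estimators=100, random_state=spec.seed, n_jobs=1
        )
    est.fit(X, y)
    return TrainedModel(spec, est)


def predict(model: TrainedModel, fv: FeatureVector) -> PredictionResult:
    """Class probabilities and label for one feature vector.

    ``p_a + p_i == 1`` exactly (``p_i`` is computed as the complement);
    a tie ``p_a == p_i`` is conservatively called inactive.
    """
    p_a = float(
        model.predict_proba_active(np.array([[fv.tc_most, fv.activity_feature]]))[0]
    )
    p_i = 1.0 - p_a
    return PredictionResult(p_a=p_a, p_i=p_i, label=int(p_a > p_i))


def predict_proba_active(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized ``p_a`` over an (n, 2) feature matrix."""
    return model.predict_proba_active(X)


# ---------------------------------------------------------------------------
# text persistence
#
# Models are stored as JSON with a format-version field.  Naive Bayes and
# logistic models store their parameters directly; random forests store
# each tree's node arrays, which are re-evaluated by a small pure-Python
# traversal on load (verified against the scikit-learn predictions).


def _serialize_estimator(model: TrainedModel) -> dict:
    est = model.estimator
    if model.spec.method == "naive_bayes":
        return {
            "classes": est.classes_.tolist(),
            "priors": est.class_prior_.tolist(),
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
        }
    if model.spec.method == "logistic_regression":
        return {
            "classes": est.classes_.tolist(),
            "intercept": est.intercept_.tolist(),
            "coef": est.coef_.tolist(),
        }
    trees = []
    for t in est.estimators_:
        tr = t.tree_
        trees.append(
            {
                "children_left": tr.children_left.tolist(),
                "children_right": tr.children_right.tolist(),
                "feature": tr.feature.tolist(),
                "threshold": tr.threshold.tolist(),
                "value": tr.value[:, 0, :].tolist(),
            }
        )
    return {"classes": est.classes_.tolist(), "trees": trees}


class _FrozenForest:
    """Pure-Python evaluator for a persisted random forest."""

    def __init__(self, payload: dict):
        self.classes_ = np.array(payload["classes"])
        self._trees = payload["trees"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros((len(X), len(self.classes_)))
        for tree in self._trees:
            left = tree["children_left"]
            right = tree["children_right"]
            feat = tree["feature"]
            thr = tree["threshold"]
            val = tree["value"]
            for i, x in enumerate(X):
                node = 0
                while left[node] != -1:
                    node = left[node] if x[feat[node]] <= thr[node] else right[node]
                leaf = np.asarray(val[node], dtype=float)
                acc[i] += leaf / leaf.sum()
        return acc / len(self._trees)


class _FrozenNB:
    def __init__(self, payload: dict):
        self.classes_ = np.array(payload["classes"])
        self._priors = np.array(payload["priors"])
        self._theta = np.array(payload["theta"])
        self._var = np.array(payload["var"])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        log_lik = -0.5 * np.sum(
            np.log(2.0 * np.pi * self._var)
            + (X[:, None, :] - self._theta) ** 2 / self._var,
            axis=2,
        )
        joint = log_lik + np.log(self._priors)
        joint -= joint.max(axis=1, keepdims=True)
        p = np.exp(joint)
        return p / p.sum(axis=1, keepdims=True)


class _FrozenLogistic:
    def __init__(self, payload: dict):
        self.classes_ = np.array(payload["classes"])
        self._intercept = np.array(payload["intercept"])
        self._coef = np.array(payload["coef"])
        # mimic sklearn's coef_/intercept_ attribute surface
        self.intercept_ = self._intercept
        self.coef_ = self._coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = X @ self._coef[0] + self._intercept[0]
        p1 = expit(z)
        return np.column_stack([1.0 - p1, p1])


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": asdict(model.spec),
        "estimator": _serialize_estimator(model),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version in {path}")
    spec = ModelSpec(**payload["spec"])
    est_payload = payload["estimator"]
    if spec.method == "naive_bayes":
        est = _FrozenNB(est_payload)
    elif spec.method == "logistic_regression":
        est = _FrozenLogistic(est_payload)
    else:
        est = _FrozenForest(est_payload)
    return TrainedModel(spec, est)
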