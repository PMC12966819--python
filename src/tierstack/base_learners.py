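"""Binary threshold base learners.

For each outcome (bed days or ED visits) and each of its three thresholds, a
binary classifier predicts the probability that next-year usage reaches the
threshold.  Four model families are supported — logistic regression, gradient
boosted trees, multilayer perceptron, and an adaptive-spline logistic model
standing in for MARS — all with library-default hyperparameters, mirroring a
deliberately untuned modelling protocol.  The fitted probabilities become
meta-features for the stacking ensemble.

The three threshold models per outcome are trained independently (no shared
ordinal structure), so a patient's probability triple is not guaranteed to be
monotone in the threshold; :func:`monotone_violation_rate` quantifies how
often that happens without correcting it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from xgboost import XGBClassifier

from .errors import DegenerateTargetError, MissingDataError, SchemaMismatchError
from ._seeds import derive_seed

__all__ = [
    "BASE_FAMILIES",
    "BaseLearnerSpec",
    "BinaryThresholdScorer",
    "fit_binary",
    "predict_proba",
    "monotone_violation_rate",
]

#: The four supported base-learner families.
BASE_FAMILIES = ("logistic", "boosted_tree", "mlp", "mars")


@dataclass
class BaseLearnerSpec:
    """Identifies one binary exceedance task and its model family.

    ``hyperparameters`` holds explicit overrides only; everything else stays
    at the library default.
    """

    family: str
    threshold_index: int
    outcome: str = "LOS"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in BASE_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {BASE_FAMILIES}")
        if self.threshold_index not in (1, 2, 3):
            raise ValueError(f"threshold_index must be in {{1,2,3}}, got {self.threshold_index}")

    @property
    def model_seed(self) -> int:
        """Seed fixed per (family, outcome, threshold) from the spec seed."""
        return derive_seed(self.seed, "base", self.family, self.outcome, self.threshold_index)


def _make_model(family: str, seed: int, overrides: dict):
    """Construct an unfitted probability model for one family.

    Logistic models are fitted unpenalized (maximum likelihood), matching the
    plain GLM behaviour of the method families being emulated; continuous
    inputs are standardized inside a pipeline for optimizer stability.
    """
    if family == "logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(penalty=None, max_iter=2000, **overrides)),
            ]
        )
    if family == "boosted_tree":
        return XGBClassifier(random_state=seed, n_jobs=1, **overrides)
    if family == "mlp":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", MLPClassifier(random_state=seed, **overrides)),
            ]
        )
    if family == "mars":
        # Adaptive-spline logistic stand-in for MARS: piecewise-polynomial
        # basis expansion followed by an (L2-regularized) logistic fit; the
        # regularization keeps the expanded basis identifiable.
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("spline", SplineTransformer(degree=2, n_knots=4, include_bias=False)),
                ("clf", LogisticRegression(max_iter=2000, **overrides)),
            ]
        )
    raise ValueError(f"unknown family {family!r}")


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))


class BinaryThresholdScorer(BaseEstimator, ClassifierMixin):
    """Scikit-learn style binary classifier for one usage-threshold task.

    Parameters
    ----------
    family : str
        One of :data:`BASE_FAMILIES`.
    threshold_index : int
        1-based threshold position in the outcome's scheme (kept as metadata
        for reporting; labels are supplied already binarized).
    outcome : str
        ``"LOS"`` or ``"ED"``; metadata.
    hyperparameters : dict
        Explicit library-hyperparameter overrides.
    seed : int
        Master seed; the model seed is derived per (family, outcome,
        threshold).
    """

    def __init__(self, family="logistic", threshold_index=1, outcome="LOS", hyperparameters=None, seed=0):
        self.family = family
        self.threshold_index = threshold_index
        self.outcome = outcome
        self.hyperparameters = hyperparameters
        self.seed = seed

    def fit(self, X, y):
        spec = BaseLearnerSpec(
            family=self.family,
            threshold_index=self.threshold_index,
            outcome=self.outcome,
            hyperparameters=self.hyperparameters or {},
            seed=self.seed,
        )
        X = _as_frame(X)
        y = np.asarray(y)
        if X.isna().any().any() or (np.issubdtype(y.dtype, np.floating) and np.isnan(y).any()):
            raise MissingDataError("missing values present; complete-case inputs are required")
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTargetError(f"labels contain a single class ({classes.tolist()}); cannot fit")
        if not set(classes.tolist()) <= {0, 1}:
            raise DegenerateTargetError(f"binary labels in {{0,1}} required, got {classes.tolist()}")
        self.feature_names_ = list(X.columns)
        self.model_ = _make_model(self.family, spec.model_seed, spec.hyperparameters)
        with warnings.catch_warnings():
            # default-hyperparameter MLPs routinely stop at max_iter
            warnings.simplefilter("ignore")
            self.model_.fit(X.to_numpy(dtype=float), y.astype(int))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_schema(self, X) -> np.ndarray:
        X = _as_frame(X)
        if list(X.columns) != self.feature_names_:
            raise SchemaMismatchError(
                f"feature schema mismatch: trained on {self.feature_names_}, got {list(X.columns)}"
            )
        if X.isna().any().any():
            raise MissingDataError("missing values present; complete-case inputs are required")
        return X.to_numpy(dtype=float)

    def predict_proba(self, X):
        arr = self._check_schema(X)
        return self.model_.predict_proba(arr)

    def probability(self, X) -> np.ndarray:
        """Per-record probability of exceeding the task threshold, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.probability(X) >= 0.5).astype(int)


def fit_binary(spec: BaseLearnerSpec, features, labels) -> BinaryThresholdScorer:
    """Fit one binary exceedance model described by ``spec``."""
    scorer = BinaryThresholdScorer(
        family=spec.family,
        threshold_index=spec.threshold_index,
        outcome=spec.outcome,
        hyperparameters=spec.hyperparameters,
        seed=spec.seed,
    )
    return scorer.fit(features, labels)


def predict_proba(scorer: BinaryThresholdScorer, features) -> np.ndarray:
    """Probability of exceeding the scorer's threshold, one value per record."""
    return scorer.probability(features)


def monotone_violation_rate(prob_matrix) -> float:
    """Fraction of records whose threshold-probability triple is non-monotone.

    ``prob_matrix`` has one column per threshold in increasing order; a row
    violates monotonicity when any later (rarer, higher-bar) threshold gets a
    strictly larger probability than an earlier one.  Violations are reported,
    not corrected.
    """
    p = np.asarray(prob_matrix, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise SchemaMismatchError("prob_matrix must be 2-D with one column per threshold")
    viol = np.any(np.diff(p, axis=1) > 0.0, axis=1)
    return float(np.mean(viol)) if p.shape[0] else 0.0
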