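"""Stacking ensemble for four-tier usage prediction.

The ensemble takes, per patient-year, the three base-learner exceedance
probabilities of the matching outcome plus the current-year usage count as
meta-features, balances the training tiers by random upsampling (sampling
minority tiers with replacement until every tier matches the majority count),
and fits a multiclass meta-learner — random forest, boosted trees, or linear
SVM — to predict the four mutually exclusive usage tiers.

:class:`TierStackingClassifier` is the estimator-level interface (scikit-learn
fit/predict/predict_proba, composable with sklearn model selection); the
module-level functions (:func:`upsample_balance`, :func:`split_train_test`,
:func:`fit_meta`, :func:`predict_tier`) expose the individual steps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .base_learners import BASE_FAMILIES, BinaryThresholdScorer
from .errors import (
    EmptyInputError,
    InvalidSpecError,
    MissingTierError,
    SchemaMismatchError,
    UnbalancedInputError,
)
from .tiers import UsageClassScheme, assign_class, scheme_by_name
from ._seeds import derive_seed

__all__ = [
    "META_FAMILIES",
    "META_FEATURE_COLUMNS",
    "TierStackingClassifier",
    "upsample_balance",
    "split_train_test",
    "fit_meta",
    "predict_tier",
    "build_meta_features",
]

#: The three supported meta-learner families.
META_FAMILIES = ("random_forest", "boosted_tree", "linear_svm")

#: Column order of the meta-feature matrix.
META_FEATURE_COLUMNS = ("p_ge_t1", "p_ge_t2", "p_ge_t3", "current_usage")

_TIERS = np.array([0, 1, 2, 3])


def upsample_balance(rows, tier_labels, seed: int = 0):
    """Random upsampling to equal tier counts in the training data.

    Every tier must be present.  Original rows are all retained; each
    minority tier is extended by sampling its own rows with replacement until
    it matches the majority tier count, so the output size is
    ``4 * max tier count``.
    """
    rows = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(np.asarray(rows))
    labels = np.asarray(tier_labels)
    if len(rows) != labels.shape[0]:
        raise SchemaMismatchError(f"rows ({len(rows)}) and labels ({labels.shape[0]}) disagree in length")
    counts = {t: int(np.sum(labels == t)) for t in _TIERS}
    missing = [t for t, c in counts.items() if c == 0]
    if missing:
        raise MissingTierError(f"tiers {missing} absent from training data; cannot balance")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    parts_r, parts_l = [], []
    for t in _TIERS:
        idx = np.flatnonzero(labels == t)
        extra = rng.choice(idx, size=target - idx.size, replace=True) if idx.size < target else np.empty(0, int)
        take = np.concatenate([idx, extra])
        parts_r.append(rows.iloc[take])
        parts_l.append(labels[take])
    out_rows = pd.concat(parts_r, ignore_index=True)
    out_labels = np.concatenate(parts_l)
    return out_rows, out_labels


def split_train_test(rows, labels, fraction: float = 0.75, seed: int = 0, stratify: bool = True):
    """Random train/test partition of patient-year rows (default 75:25).

    Stratified by tier by default; upsampling belongs on the train side only,
    after this split, so duplicated minority rows never leak into the test
    set.  Returns ``(rows_train, rows_test, labels_train, labels_test)``.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidSpecError(f"train fraction must lie in (0,1), got {fraction}")
    labels = np.asarray(labels)
    if labels.shape[0] == 0:
        raise EmptyInputError("cannot split an empty dataset")
    strat = labels if stratify else None
    return train_test_split(rows, labels, train_size=fraction, random_state=seed, stratify=strat)


def _make_meta_model(family: str, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "boosted_tree":
        return XGBClassifier(random_state=seed, n_jobs=1)
    if family == "linear_svm":
        return Pipeline([("scale", StandardScaler()), ("clf", LinearSVC(random_state=seed))])
    raise InvalidSpecError(f"unknown meta family {family!r}; choose from {META_FAMILIES}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _MetaLearner:
    """Fitted multiclass meta-learner over meta-feature rows."""

    def __init__(self, family: str, model, classes: np.ndarray):
        self.family = family
        self.model = model
        self.classes_ = classes

    def predict(self, meta_rows) -> np.ndarray:
        arr = _meta_array(meta_rows)
        return np.asarray(self.model.predict(arr)).astype(int)

    def predict_scores(self, meta_rows) -> np.ndarray:
        """Per-tier scores usable for one-vs-rest AUROC.

        Probabilities where the library provides them; for the linear SVM,
        decision values passed through a softmax normalization.
        """
        arr = _meta_array(meta_rows)
        if hasattr(self.model, "predict_proba"):
            return np.asarray(self.model.predict_proba(arr))
        dec = np.asarray(self.model.decision_function(arr))
        if dec.ndim == 1:
            dec = np.column_stack([-dec, dec])
        return _softmax(dec)


def _meta_array(meta_rows) -> np.ndarray:
    if isinstance(meta_rows, pd.DataFrame):
        cols = list(meta_rows.columns)
        if cols != list(META_FEATURE_COLUMNS):
            raise SchemaMismatchError(f"meta-feature columns must be {list(META_FEATURE_COLUMNS)}, got {cols}")
        arr = meta_rows.to_numpy(dtype=float)
    else:
        arr = np.asarray(meta_rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise SchemaMismatchError(f"meta-feature matrix must have 4 columns, got shape {arr.shape}")
    probs = arr[:, :3]
    if np.any(probs < 0) or np.any(probs > 1):
        raise SchemaMismatchError("base-learner probabilities must lie in [0, 1]")
    if np.any(arr[:, 3] < 0):
        raise SchemaMismatchError("current usage counts must be non-negative")
    return arr


def fit_meta(meta_family: str, meta_rows, tier_labels, seed: int = 0, require_balanced: bool = True) -> _MetaLearner:
    """Fit a multiclass meta-learner on meta-feature rows.

    When ``require_balanced`` (the training protocol's default), tier counts
    must already be equal — balancing is an explicit prior step, never
    implicit.
    """
    labels = np.asarray(tier_labels).astype(int)
    arr = _meta_array(meta_rows)
    if arr.shape[0] != labels.shape[0]:
        raise SchemaMismatchError("meta rows and labels disagree in length")
    counts = np.bincount(labels, minlength=4)
    if np.any(counts == 0):
        raise MissingTierError(f"tier counts {counts.tolist()} include an absent tier")
    if require_balanced and len(set(counts.tolist())) != 1:
        raise UnbalancedInputError(f"tier counts {counts.tolist()} are not balanced; upsample first")
    model = _make_meta_model(meta_family, derive_seed(seed, "meta", meta_family))
    model.fit(arr, labels)
    return _MetaLearner(meta_family, model, _TIERS.copy())


def predict_tier(predictor: _MetaLearner, meta_rows) -> np.ndarray:
    """Predicted tier in {0,1,2,3}, one per meta-feature row."""
    return predictor.predict(meta_rows)


def build_meta_features(base_scorers, features, current_usage) -> pd.DataFrame:
    """Assemble the meta-feature frame from fitted base scorers.

    ``base_scorers`` are the three threshold models in increasing threshold
    order; ``current_usage`` is the current-year count of the same outcome.
    """
    if len(base_scorers) != 3:
        raise InvalidSpecError("exactly 3 base scorers (one per threshold) required")
    usage = np.asarray(current_usage, dtype=float)
    cols = {f"p_ge_t{j + 1}": s.probability(features) for j, s in enumerate(base_scorers)}
    cols["current_usage"] = usage
    return pd.DataFrame(cols, columns=list(META_FEATURE_COLUMNS))


class TierStackingClassifier(BaseEstimator, ClassifierMixin):
    """Stacked four-tier usage classifier (scikit-learn interface).

    Fits three binary base learners at the outcome's usage thresholds, feeds
    their probabilities plus current-year usage to a multiclass meta-learner,
    and predicts the four-tier outcome.

    Parameters
    ----------
    base_family : str
        Base-learner family, one of ``("logistic", "boosted_tree", "mlp",
        "mars")``.
    meta_family : str
        Meta-learner family, one of ``("random_forest", "boosted_tree",
        "linear_svm")``.
    scheme : str or UsageClassScheme
        Usage tier scheme (``"LOS"`` or ``"ED"`` for the packaged schemes).
    usage_col : str or None
        Column of ``X`` holding current-year usage of the same outcome; by
        default ``current_los_days`` / ``current_ed_visits`` by scheme name.
    feature_cols : list of str or None
        Covariate columns for the base learners; default: every column of
        ``X`` except the usage column is a covariate, and the usage column is
        also appended as a base-learner predictor.
    upsample : bool
        Balance training tiers by random upsampling before the meta fit.
    seed : int
        Master seed; base and meta seeds are derived from it.

    Attributes
    ----------
    base_scorers_ : list of BinaryThresholdScorer
        The three fitted threshold models, in increasing threshold order.
    meta_ : fitted meta-learner
    classes_ : ndarray of the four tier labels
    monotone_violation_rate_ : float
        Fraction of training records whose base-probability triple is
        non-monotone (reported, not corrected).
    """

    def __init__(
        self,
        base_family: str = "logistic",
        meta_family: str = "boosted_tree",
        scheme="LOS",
        usage_col: str | None = None,
        feature_cols: list | None = None,
        upsample: bool = True,
        base_hyperparameters: dict | None = None,
        seed: int = 0,
    ):
        self.base_family = base_family
        self.meta_family = meta_family
        self.scheme = scheme
        self.usage_col = usage_col
        self.feature_cols = feature_cols
        self.upsample = upsample
        self.base_hyperparameters = base_hyperparameters
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _scheme(self) -> UsageClassScheme:
        return self.scheme if isinstance(self.scheme, UsageClassScheme) else scheme_by_name(self.scheme)

    def _usage_col(self) -> str:
        if self.usage_col is not None:
            return self.usage_col
        return "current_los_days" if self._scheme().name.upper() == "LOS" else "current_ed_visits"

    def _design(self, X: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        if not isinstance(X, pd.DataFrame):
            raise SchemaMismatchError("X must be a DataFrame with named columns")
        ucol = self._usage_col()
        if ucol not in X.columns:
            raise SchemaMismatchError(f"usage column {ucol!r} not in X")
        cols = self.feature_cols if self.feature_cols is not None else [c for c in X.columns if c != ucol]
        base_X = X[list(cols) + [ucol]]
        return base_X, X[ucol].to_numpy(dtype=float)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        """Fit base learners and meta-learner.

        ``y`` may be raw next-year counts or tier labels; counts are detected
        (any value > 3) and mapped through the scheme.
        """
        y = np.asarray(y)
        scheme = self._scheme()
        tiers = assign_class(y, scheme) if np.any(y > 3) else y.astype(int)
        base_X, usage = self._design(X)

        if BASE_FAMILIES and self.base_family not in BASE_FAMILIES:
            raise InvalidSpecError(f"unknown base family {self.base_family!r}")
        self.base_scorers_ = []
        for j in (1, 2, 3):
            scorer = BinaryThresholdScorer(
                family=self.base_family,
                threshold_index=j,
                outcome=scheme.name,
                hyperparameters=self.base_hyperparameters,
                seed=self.seed,
            )
            scorer.fit(base_X, (tiers >= j).astype(int))
            self.base_scorers_.append(scorer)

        meta = build_meta_features(self.base_scorers_, base_X, usage)
        from .base_learners import monotone_violation_rate

        self.monotone_violation_rate_ = monotone_violation_rate(meta.iloc[:, :3].to_numpy())

        labels = tiers
        if self.upsample:
            meta, labels = upsample_balance(meta, tiers, seed=derive_seed(self.seed, "upsample"))
        self.meta_ = fit_meta(
            self.meta_family, meta, labels, seed=self.seed, require_balanced=self.upsample
        )
        self.classes_ = _TIERS.copy()
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _meta_for(self, X) -> pd.DataFrame:
        base_X, usage = self._design(X)
        return build_meta_features(self.base_scorers_, base_X, usage)

    def predict(self, X) -> np.ndarray:
        return self.meta_.predict(self._meta_for(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.meta_.predict_scores(self._meta_for(X))
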