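"""Regressors for clearance-index prediction and leave-one-out cross-validation.

Three model kinds are supported:

``linear``
    Ordinary least squares with intercept on the selected (normalized)
    descriptors.  Stable on small n but cannot express curvature.
``forest``
    A bagged ensemble of unpruned regression trees in which every split
    considers all features — i.e. a random forest whose only randomness is
    the bootstrap.  :class:`BaggedTrees` reproduces
    ``sklearn.ensemble.RandomForestRegressor(max_features=None)``
    prediction-for-prediction (same bootstrap and seeding scheme) while
    fitting several-fold faster, which matters because wrapper feature
    selection below refits the forest tens of thousands of times.
``ensemble``
    A voting regressor averaging the two, the rationale being that
    descriptors worth keeping should inform both a linear and a non-linear
    learner; with equal weights the prediction is the plain mean of the
    component predictions.

Model performance throughout the package is the Pearson correlation between
predicted and observed CI; LOOCV refits the model n times, leaving each
chemical out in turn.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import config_context
from sklearn.tree import DecisionTreeRegressor

from .preprocess import NormalizationParams, apply_normalizer
from .tables import DescriptorTable

__all__ = [
    "ModelSpec",
    "FittedModel",
    "BaggedTrees",
    "fit",
    "predict",
    "loocv",
    "rank_features",
    "save_model",
    "load_model",
]

_MAX_INT = np.iinfo(np.int32).max


@dataclass(frozen=True)
class ModelSpec:
    kind: Literal["linear", "forest", "ensemble"]
    n_trees: int = 100
    seed: int | None = None
    ensemble_weights: tuple[float, float] = (0.5, 0.5)
    bootstrap: bool = True
    max_fit_features: int | None = None  # default cap p <= n - 2, warning only

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "forest", "ensemble"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.kind != "linear" and self.seed is None:
            raise ValueError("forest/ensemble models require an explicit seed")
        if abs(sum(self.ensemble_weights) - 1.0) > 1e-12:
            raise ValueError("ensemble_weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "ensemble_weights": list(self.ensemble_weights),
            "bootstrap": self.bootstrap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            kind=d["kind"],
            n_trees=d.get("n_trees", 100),
            seed=d.get("seed"),
            ensemble_weights=tuple(d.get("ensemble_weights", (0.5, 0.5))),
            bootstrap=d.get("bootstrap", True),
        )


@lru_cache(maxsize=32)
def _bootstrap_plan(seed: int, n_trees: int, n_samples: int):
    """Tree seeds and bootstrap sample weights, identical to sklearn's scheme.

    sklearn draws one int seed per tree from RandomState(seed), then each
    tree's bootstrap indices from a fresh RandomState(tree_seed).  The plan
    depends only on (seed, n_trees, n_samples), so LOOCV folds — all of size
    n − 1 — share one cached plan.
    """
    rs = np.random.RandomState(seed)
    tree_seeds = rs.randint(_MAX_INT, size=n_trees)
    weights = np.empty((n_trees, n_samples), dtype=np.float64)
    for t, s in enumerate(tree_seeds):
        idx = np.random.RandomState(s).randint(
            0, n_samples, n_samples, dtype=np.int32
        )
        weights[t] = np.bincount(idx, minlength=n_samples)
    return tree_seeds, weights


class BaggedTrees:
    """Bootstrap-aggregated unpruned regression trees, all features per split.

    Prediction-identical to ``RandomForestRegressor(n_estimators=n_trees,
    max_features=None, random_state=seed)`` (asserted in the test suite).
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, bootstrap: bool = True):
        self.n_trees = n_trees
        self.seed = seed
        self.bootstrap = bootstrap
        self.trees_: list[DecisionTreeRegressor] = []
        self.n_features_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTrees":
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        n = X32.shape[0]
        self.n_features_ = X32.shape[1]
        if self.bootstrap:
            tree_seeds, weights = _bootstrap_plan(self.seed, self.n_trees, n)
        else:
            tree_seeds = np.random.RandomState(self.seed).randint(
                _MAX_INT, size=self.n_trees
            )
            weights = None
        self.trees_ = []
        with config_context(skip_parameter_validation=True):
            for t in range(self.n_trees):
                tree = DecisionTreeRegressor(random_state=int(tree_seeds[t]))
                w = weights[t] if weights is not None else None
                tree.fit(X32, y, sample_weight=w, check_input=False)
                self.trees_.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        out = np.zeros(X32.shape[0], dtype=np.float64)
        for tree in self.trees_:
            out += tree.predict(X32, check_input=False)
        return out / self.n_trees

    @property
    def feature_importances_(self) -> np.ndarray:
        """Impurity-based importances, averaged over trees and renormalized."""
        imps = [
            t.feature_importances_ for t in self.trees_ if t.tree_.node_count > 1
        ]
        if not imps:
            return np.zeros(self.n_features_)
        mean = np.mean(imps, axis=0)
        total = mean.sum()
        return mean / total if total > 0 else mean


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    linear_intercept: float | None = None
    linear_coef: np.ndarray | None = None  # aligned with feature_names
    forest: BaggedTrees | None = None
    normalization: NormalizationParams | None = None
    training_ids: list[str] = field(default_factory=list)
    training_hash: str | None = None


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """OLS with intercept via lstsq; raises on singular design."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        raise ValueError("singular design matrix: features are collinear")
    return float(coef[0]), coef[1:]


def _training_hash(X: np.ndarray, y: np.ndarray, features: Sequence[str]) -> str:
    h = hashlib.sha256()
    h.update(",".join(features).encode())
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.float64).tobytes())
    return h.hexdigest()


def fit(
    table: DescriptorTable,
    features: Sequence[str],
    spec: ModelSpec,
    normalization: NormalizationParams | None = None,
) -> FittedModel:
    """Fit a model of ``spec.kind`` on the given (normalized) table.

    The table must carry the CI target.  An ensemble fit stores exactly the
    linear and forest components a standalone fit of each kind would produce.
    """
    if table.ci is None:
        raise ValueError("fitting requires the CI target column")
    n = table.n_chemicals
    if n < 3:
        raise ValueError("fitting requires at least 3 chemicals")
    features = list(features)
    idx = table.feature_index(features)
    p = len(features)
    cap = spec.max_fit_features if spec.max_fit_features is not None else n - 2
    if p > cap:
        warnings.warn(
            f"fitting {p} features on {n} chemicals (cap {cap}): "
            "expect an ill-conditioned or overfit model",
            stacklevel=2,
        )
    X = table.values[:, idx]
    y = table.ci
    model = FittedModel(
        spec=spec,
        feature_names=features,
        normalization=normalization,
        training_ids=list(table.chemical_ids),
        training_hash=_training_hash(X, y, features),
    )
    if spec.kind in ("linear", "ensemble"):
        model.linear_intercept, model.linear_coef = _ols(X, y)
    if spec.kind in ("forest", "ensemble"):
        model.forest = BaggedTrees(
            n_trees=spec.n_trees, seed=int(spec.seed or 0), bootstrap=spec.bootstrap
        ).fit(X, y)
    return model


def predict(
    model: FittedModel, table: DescriptorTable, auto_normalize: bool = False
) -> np.ndarray:
    """Predict CI for every chemical of ``table``.

    ``table`` must already be normalized with the model's training
    parameters; with ``auto_normalize=True`` a raw table is normalized here
    using the stored parameters.
    """
    if auto_normalize:
        if model.normalization is None:
            raise ValueError("model stores no normalization parameters")
        if not table.normalized:
            # restrict to the model's features first: a raw table may carry
            # columns the training filters pruned, which have no parameters
            table = apply_normalizer(
                table.select_features(model.feature_names), model.normalization
            )
    idx = table.feature_index(model.feature_names)
    X = table.values[:, idx]
    parts = []
    if model.linear_coef is not None:
        parts.append(model.linear_intercept + X @ model.linear_coef)
    if model.forest is not None:
        parts.append(model.forest.predict(X))
    if model.spec.kind == "ensemble":
        w = model.spec.ensemble_weights
        return w[0] * parts[0] + w[1] * parts[1]
    return parts[0]


def loocv(
    table: DescriptorTable,
    features: Sequence[str],
    spec: ModelSpec,
    refit_normalization: bool = False,
) -> np.ndarray:
    """Leave-one-out cross-validated predictions, aligned to chemical order.

    Each chemical is predicted by a model fitted (with the same spec seed)
    on the other n − 1.  By default the table is used as given — mirroring a
    pipeline that normalizes once on the full training set before selection
    and cross-validation.  ``refit_normalization=True`` is the strict
    variant: the table is taken as raw and z-scoring is re-estimated inside
    every fold.
    """
    from .preprocess import fit_normalizer  # local import to avoid cycle

    if table.ci is None:
        raise ValueError("LOOCV requires the CI target column")
    n = table.n_chemicals
    if n < 3:
        raise ValueError("LOOCV requires at least 3 chemicals")
    features = list(features)
    sub = table.select_features(features)
    preds = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = DescriptorTable(
            chemical_ids=[sub.chemical_ids[k] for k in np.flatnonzero(mask)],
            feature_names=features,
            values=sub.values[mask],
            ci=sub.ci[mask],
            normalized=sub.normalized,
        )
        test = DescriptorTable(
            chemical_ids=[sub.chemical_ids[i]],
            feature_names=features,
            values=sub.values[i : i + 1],
            normalized=sub.normalized,
        )
        try:
            if refit_normalization:
                params = fit_normalizer(train)
                train = apply_normalizer(train, params)
                test = apply_normalizer(test, params)
            m = fit(train, features, spec)
            preds[i] = predict(m, test)[0]
        except Exception as e:  # noqa: BLE001 - annotate fold then re-raise
            raise RuntimeError(
                f"LOOCV failed with chemical {sub.chemical_ids[i]!r} left out: {e}"
            ) from e
    return preds


def rank_features(model: FittedModel) -> pd.DataFrame:
    """Rank an ensemble model's features by both component views.

    Features are ranked by absolute linear coefficient (descending) and by
    forest impurity importance (descending); the overall ranking is the rank
    of the sum of the two ranks, tied features sharing the smaller rank.
    """
    if model.spec.kind != "ensemble":
        raise ValueError("feature ranking is defined for ensemble models only")
    coef = np.asarray(model.linear_coef, dtype=float)
    imp = model.forest.feature_importances_
    rank_lin = rankdata(-np.abs(coef), method="min").astype(int)
    rank_for = rankdata(-imp, method="min").astype(int)
    overall = rankdata(rank_lin + rank_for, method="min").astype(int)
    return pd.DataFrame(
        {
            "feature": model.feature_names,
            "linear_coefficient": coef,
            "rank_linear": rank_lin,
            "forest_importance": imp,
            "rank_forest": rank_for,
            "overall_rank": overall,
        }
    )


_MODEL_FORMAT = 1


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a model as portable JSON.

    Forests are not serialized opaquely: the file stores the spec, seed and
    a hash of the training matrix, and :func:`load_model` refits the forest
    deterministically from the referenced training table.
    """
    doc: dict = {
        "format": _MODEL_FORMAT,
        "spec": model.spec.to_dict(),
        "features": model.feature_names,
        "training_ids": model.training_ids,
        "training_hash": model.training_hash,
    }
    if model.linear_coef is not None:
        doc["linear"] = {
            "intercept": model.linear_intercept,
            "coefficients": {
                f: float(c) for f, c in zip(model.feature_names, model.linear_coef)
            },
        }
    if model.normalization is not None:
        doc["normalization"] = model.normalization.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_model(
    path: str | Path, training_table: DescriptorTable | None = None
) -> FittedModel:
    """Load a model saved by :func:`save_model`.

    Linear models load standalone.  Forest/ensemble models additionally
    need the original training table (raw or normalized); the forest is
    refit from it and the stored training hash is verified.
    """
    doc = json.loads(Path(path).read_text())
    spec = ModelSpec.from_dict(doc["spec"])
    features = list(doc["features"])
    norm = (
        NormalizationParams.from_dict(doc["normalization"])
        if "normalization" in doc
        else None
    )
    model = FittedModel(
        spec=spec,
        feature_names=features,
        normalization=norm,
        training_ids=list(doc["training_ids"]),
        training_hash=doc["training_hash"],
    )
    if "linear" in doc:
        model.linear_intercept = float(doc["linear"]["intercept"])
        model.linear_coef = np.array(
            [doc["linear"]["coefficients"][f] for f in features]
        )
    if spec.kind in ("forest", "ensemble"):
        if training_table is None:
            raise ValueError(
                "forest/ensemble models need the training table to refit the forest"
            )
        table = training_table
        if not table.normalized and norm is not None:
            table = apply_normalizer(table, norm)
        refit = fit(table, features, spec, normalization=norm)
        if refit.training_hash != model.training_hash:
            raise ValueError(
                "training table does not match the stored training-data hash"
            )
        model.forest = refit.forest
        if model.linear_coef is None and refit.linear_coef is not None:
            model.linear_intercept = refit.linear_intercept
            model.linear_coef = refit.linear_coef
    return model
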