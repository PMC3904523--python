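"""Supervised learning on signatures: noise reduction, model training,
cross-validation protocols and evaluation metrics.

The regression default is Gaussian-process regression with a stationary
(RBF + white-noise) kernel on standardized features, matching the model
family used for the ΔΔG regression tasks.  Metrics are pooled over all
held-out predictions — the statistics one would read off a single scatter
plot of every prediction — rather than averaged per fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .errors import (
    DegenerateMatrixError,
    ProtocolError,
    UndefinedMetricError,
)

# ---------------------------------------------------------------------------
# Noise reduction


@dataclass
class NoiseReducer:
    """Drops uninformative signature columns, remembering the kept mask.

    Zero-variance columns are always dropped; optionally one member of
    each near-duplicate column pair (absolute Pearson correlation above
    ``corr_threshold``) is dropped too.  The fitted mask is reapplied to
    any later matrix so train and test data stay aligned.
    """

    corr_threshold: float = 0.999
    drop_correlated: bool = True
    mask_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "NoiseReducer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("noise reduction needs a 2-D matrix with >= 2 rows")
        mask = X.std(axis=0) > 0
        if self.drop_correlated and mask.sum() > 1:
            kept_idx = np.flatnonzero(mask)
            corr = np.corrcoef(X[:, kept_idx], rowvar=False)
            drop: set = set()
            for a in range(len(kept_idx)):
                if a in drop:
                    continue
                for b in range(a + 1, len(kept_idx)):
                    if b in drop:
                        continue
                    if abs(corr[a, b]) > self.corr_threshold:
                        drop.add(b)
            for b in drop:
                mask[kept_idx[b]] = False
        if not mask.any():
            raise DegenerateMatrixError("noise reduction dropped every column")
        self.mask_ = mask
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mask_ is None:
            raise ValueError("NoiseReducer is not fitted")
        return np.asarray(X, dtype=float)[:, self.mask_]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def noise_reduction(
    X: np.ndarray, corr_threshold: float = 0.999, drop_correlated: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Functional form: returns (reduced matrix, kept-column boolean mask)."""
    reducer = NoiseReducer(corr_threshold, drop_correlated)
    reduced = reducer.fit_transform(X)
    return reduced, reducer.mask_


# ---------------------------------------------------------------------------
# Models


@dataclass(frozen=True)
class ModelSpec:
    """Model family and hyperparameters.

    Families: ``gpr`` (Gaussian-process regression, default), ``ridge``,
    ``rf`` (random forests) for regression; ``rf`` (default), ``logistic``
    for classification.
    """

    family: str = "gpr"
    hyperparams: Tuple[Tuple[str, object], ...] = ()

    def params(self) -> Dict[str, object]:
        return dict(self.hyperparams)


@dataclass
class SignatureModel:
    """A fitted model bundling the noise-reduction mask, the feature
    scaling and the estimator, keyed to a feature-name layout."""

    estimator: object
    reducer: NoiseReducer
    scaler: StandardScaler
    feature_names: Optional[List[str]]
    task: str
    spec: ModelSpec
    seed: int

    def _prepare(self, X: np.ndarray, feature_names: Optional[Sequence[str]]) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if feature_names is not None and self.feature_names is not None:
            if list(feature_names) != self.feature_names:
                missing = set(self.feature_names) - set(feature_names)
                if missing:
                    raise ValueError(
                        f"signature layout incompatible; missing features: {sorted(missing)[:5]}"
                    )
                order = [list(feature_names).index(n) for n in self.feature_names]
                X = X[:, order]
        return self.scaler.transform(self.reducer.transform(X))

    def predict(
        self, X: np.ndarray, feature_names: Optional[Sequence[str]] = None
    ) -> np.ndarray:
        return self.estimator.predict(self._prepare(X, feature_names))

    def predict_score(
        self, X: np.ndarray, feature_names: Optional[Sequence[str]] = None
    ) -> np.ndarray:
        """Continuous score: regression prediction, or P(class 1)."""
        Xp = self._prepare(X, feature_names)
        if self.task == "classification":
            return self.estimator.predict_proba(Xp)[:, 1]
        return self.estimator.predict(Xp)


def _make_regressor(spec: ModelSpec, seed: int):
    params = spec.params()
    if spec.family == "gpr":
        kernel = ConstantKernel(1.0, (1e-3, 1e6)) * RBF(
            length_scale=params.get("length_scale", 10.0),
            length_scale_bounds=(1e-2, 1e4),
        ) + WhiteKernel(
            noise_level=params.get("noise_level", 0.5), noise_level_bounds=(1e-6, 1e2)
        )
        return GaussianProcessRegressor(
            kernel=kernel,
            alpha=params.get("alpha", 1e-10),
            normalize_y=True,
            n_restarts_optimizer=int(params.get("n_restarts_optimizer", 0)),
            random_state=seed,
        )
    if spec.family == "ridge":
        return Ridge(alpha=params.get("alpha", 1.0), random_state=seed)
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=int(params.get("n_estimators", 300)), random_state=seed
        )
    raise ValueError(f"unknown regressor family {spec.family!r}")


def _make_classifier(spec: ModelSpec, seed: int):
    params = spec.params()
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 300)), random_state=seed
        )
    if spec.family == "logistic":
        return LogisticRegression(
            C=params.get("C", 1.0), max_iter=int(params.get("max_iter", 2000)),
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family {spec.family!r}")


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    seed: int,
    task: str,
    feature_names: Optional[Sequence[str]],
) -> SignatureModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task == "regression" and not np.all(np.isfinite(y.astype(float))):
        raise ValueError("targets must be finite")
    reducer = NoiseReducer()
    Xr = reducer.fit_transform(X)
    scaler = StandardScaler().fit(Xr)
    Xs = scaler.transform(Xr)
    est = _make_regressor(spec, seed) if task == "regression" else _make_classifier(spec, seed)
    est.fit(Xs, y)
    return SignatureModel(
        est, reducer, scaler,
        list(feature_names) if feature_names is not None else None,
        task, spec, seed,
    )


def train_regressor(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> SignatureModel:
    """Fit the regression model (default: GP with RBF + white kernel)."""
    return _fit(X, y, spec or ModelSpec("gpr"), seed, "regression", feature_names)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> SignatureModel:
    """Fit the direction-of-change classifier (default: random forest)."""
    return _fit(X, y, spec or ModelSpec("rf"), seed, "classification", feature_names)


# ---------------------------------------------------------------------------
# Cross-validation protocols


@dataclass(frozen=True)
class CVProtocol:
    """k-fold protocol with optional low-redundancy grouping.

    ``grouping``: ``per-mutation`` (plain shuffled k-fold),
    ``per-protein`` or ``per-position`` — under the latter two, all
    mutations sharing a protein (or a sequence position) land in a single
    fold, so no group straddles the train/test boundary.
    """

    k: int = 10
    grouping: str = "per-mutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.grouping not in ("per-mutation", "per-protein", "per-position"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


def make_folds(
    protocol: CVProtocol, n: int, groups: Optional[Sequence[object]] = None
) -> np.ndarray:
    """Assign each of ``n`` records to one test fold; returns fold ids.

    Grouped modes shuffle the distinct groups with the protocol seed and
    assign each, largest first, to the currently smallest fold — groups
    never split across folds.
    """
    if protocol.k > n:
        raise ProtocolError(f"k={protocol.k} exceeds number of records n={n}")
    if protocol.grouping == "per-mutation":
        fold_of = np.empty(n, dtype=int)
        kf = KFold(n_splits=protocol.k, shuffle=True, random_state=protocol.seed)
        for fold, (_, test_idx) in enumerate(kf.split(np.zeros((n, 1)))):
            fold_of[test_idx] = fold
        return fold_of
    if groups is None:
        raise ProtocolError(f"grouping {protocol.grouping!r} requires group labels")
    groups = list(groups)
    if len(groups) != n:
        raise ProtocolError("group labels must align with records")
    unique: List[object] = []
    sizes: Dict[object, int] = {}
    for g in groups:
        if g not in sizes:
            unique.append(g)
            sizes[g] = 0
        sizes[g] += 1
    if len(unique) < protocol.k:
        raise ProtocolError(
            f"only {len(unique)} groups for k={protocol.k} grouped folds"
        )
    rng = np.random.default_rng(protocol.seed)
    order = list(rng.permutation(len(unique)))
    shuffled = [unique[i] for i in order]
    shuffled.sort(key=lambda g: -sizes[g])  # stable: ties keep shuffled order
    fold_sizes = np.zeros(protocol.k, dtype=int)
    fold_of_group: Dict[object, int] = {}
    for g in shuffled:
        fold = int(np.argmin(fold_sizes))
        fold_of_group[g] = fold
        fold_sizes[fold] += sizes[g]
    return np.array([fold_of_group[g] for g in groups], dtype=int)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class EvaluationReport:
    """Pooled held-out metrics plus the audit trail to recompute them."""

    task: str
    pearson_rho: Optional[float] = None
    sigma: Optional[float] = None  # RMSE of held-out predictions, kcal/mol
    accuracy: Optional[float] = None
    mcc: Optional[float] = None
    auc: Optional[float] = None
    n_used: int = 0
    outlier_fraction_applied: float = 0.0
    per_fold: List[Dict[str, float]] = field(default_factory=list)
    fold_of: List[int] = field(default_factory=list)
    record_ids: List[str] = field(default_factory=list)
    truth: List[float] = field(default_factory=list)
    predictions: List[float] = field(default_factory=list)
    scores: List[float] = field(default_factory=list)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "task": self.task,
            "pearson_rho": self.pearson_rho,
            "sigma_rmse_kcal_per_mol": self.sigma,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
            "n_used": self.n_used,
            "outlier_fraction_applied": self.outlier_fraction_applied,
            "per_fold": self.per_fold,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"task: {self.task}", f"n: {self.n_used}"]
        if self.pearson_rho is not None:
            lines.append(f"Pearson rho: {self.pearson_rho:.3f}")
        if self.sigma is not None:
            lines.append(f"sigma (RMSE, kcal/mol): {self.sigma:.3f}")
        if self.accuracy is not None:
            lines.append(f"accuracy: {self.accuracy:.3f}")
        if self.mcc is not None:
            lines.append(f"MCC: {self.mcc:.3f}")
        if self.auc is not None:
            lines.append(f"AUC: {self.auc:.3f}")
        return "\n".join(lines)

    def save_audit(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "record_id": self.record_ids,
                "fold": self.fold_of,
                "truth": self.truth,
                "prediction": self.predictions,
            }
        )
        if self.scores:
            frame["score"] = self.scores
        frame.to_csv(path, sep="\t", index=False)


def metrics(
    predictions: Sequence[float],
    truth: Sequence[float],
    task: str = "regression",
    scores: Optional[Sequence[float]] = None,
) -> Dict[str, float]:
    """Pooled metrics for one prediction set.

    Regression: Pearson ρ and σ (root-mean-square error, kcal/mol).
    Classification: accuracy, MCC and rank-based AUC (``scores`` holds the
    continuous score of the positive class; defaults to predictions).
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truth, dtype=float)
    if len(pred) != len(true) or len(pred) < 2:
        raise ValueError("predictions and truth must share length >= 2")
    out: Dict[str, float] = {}
    if task == "regression":
        if np.std(pred) == 0 or np.std(true) == 0:
            raise UndefinedMetricError("Pearson rho undefined for zero-variance data")
        out["pearson_rho"] = float(stats.pearsonr(pred, true)[0])
        out["sigma"] = float(np.sqrt(np.mean((pred - true) ** 2)))
    elif task == "classification":
        out["accuracy"] = float(np.mean(pred == true))
        out["mcc"] = float(matthews_corrcoef(true, pred))
        s = np.asarray(scores if scores is not None else predictions, dtype=float)
        if len(np.unique(true)) < 2:
            raise UndefinedMetricError("AUC undefined with a single class")
        out["auc"] = float(roc_auc_score(true, s))
    else:
        raise ValueError(f"unknown task {task!r}")
    return out


def outlier_removal(
    predictions: Sequence[float], truth: Sequence[float], fraction: float = 0.10
) -> np.ndarray:
    """Indices kept after dropping the ⌈fraction·n⌉ largest |residuals|."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truth, dtype=float)
    n = len(pred)
    n_drop = math.ceil(fraction * n)
    if n_drop == 0:
        return np.arange(n)
    order = np.argsort(-np.abs(pred - true), kind="stable")
    dropped = set(order[:n_drop].tolist())
    return np.array([i for i in range(n) if i not in dropped])


# ---------------------------------------------------------------------------
# Cross-validation driver


def cross_validate(
    X: np.ndarray,
    y: Sequence[float],
    protocol: CVProtocol,
    spec: Optional[ModelSpec] = None,
    task: str = "regression",
    groups: Optional[Sequence[object]] = None,
    record_ids: Optional[Sequence[str]] = None,
    outlier_fraction: float = 0.0,
) -> EvaluationReport:
    """Run the k-fold protocol and pool held-out predictions into a report.

    Metrics are computed over the pooled held-out predictions; a per-fold
    breakdown and the full fold map are kept for audit.  With
    ``outlier_fraction`` > 0 the headline regression metrics are
    recomputed after removing that fraction of largest residuals (no
    refitting).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X rows and targets must align")
    fold_of = make_folds(protocol, n, groups)
    pred = np.empty(n, dtype=float)
    score = np.empty(n, dtype=float)
    per_fold: List[Dict[str, float]] = []
    for fold in range(protocol.k):
        test = fold_of == fold
        train = ~test
        model = _fit(X[train], y[train], spec or ModelSpec(
            "gpr" if task == "regression" else "rf"
        ), protocol.seed, task, None)
        pred[test] = model.predict(X[test])
        score[test] = model.predict_score(X[test])
        try:
            fold_metrics = metrics(
                pred[test], y[test].astype(float), task, scores=score[test]
            )
        except (UndefinedMetricError, ValueError):
            fold_metrics = {}
        per_fold.append({"fold": fold, "n_test": int(test.sum()), **fold_metrics})

    pooled = metrics(pred, y.astype(float), task, scores=score)
    report = EvaluationReport(
        task=task,
        n_used=n,
        outlier_fraction_applied=outlier_fraction,
        per_fold=per_fold,
        fold_of=fold_of.tolist(),
        record_ids=list(record_ids) if record_ids is not None else [str(i) for i in range(n)],
        truth=np.asarray(y, dtype=float).tolist(),
        predictions=pred.tolist(),
        scores=score.tolist(),
    )
    if task == "regression" and outlier_fraction > 0:
        keep = outlier_removal(pred, y.astype(float), outlier_fraction)
        pooled = metrics(pred[keep], y.astype(float)[keep], task)
    report.pearson_rho = pooled.get("pearson_rho")
    report.sigma = pooled.get("sigma")
    report.accuracy = pooled.get("accuracy")
    report.mcc = pooled.get("mcc")
    report.auc = pooled.get("auc")
    return report
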