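"""MechanoAge: stacked tree-ensemble age classification of single cells.

Three base learners — bagged decision trees (50 bootstrap resamples), a
random forest tuned over the number of variables sampled per split, and
extremely randomised trees at their default operating point — are trained
under repeated stratified k-fold cross-validation optimising ROC AUC, with
the majority class down-sampled *inside* each training fold.  A gradient
boosted meta-learner is then stacked on the base learners' out-of-fold
class probabilities (5-fold CV, tuning length 10).  Evaluation is by ROC
analysis with DeLong confidence intervals, and two learning-curve designs
(cell-level subsampling and donor-level leave-one-sample-out over random
inclusion orders) probe how performance scales with data.

All randomness flows from a single config seed through named substreams.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .feature_engineering import (
    CONTINUOUS_FEATURES,
    FEATURE_COLUMNS,
    RECOVERY_DUMMIES,
    FeatureMatrix,
    apply_yeo_johnson,
    fit_yeo_johnson,
)

__all__ = [
    "TrainingConfig",
    "ModelBundle",
    "downsample_fold",
    "train",
    "predict",
    "evaluate_roc",
    "delong_ci",
    "delong_test",
    "variable_importance",
    "learning_curve_cells",
    "learning_curve_samples",
    "save_bundle",
    "load_bundle",
]

POSITIVE_CLASS = "older"
NEGATIVE_CLASS = "younger"

BASE_LEARNERS = ("bagged_trees", "random_forest", "extra_trees")


def _derive_seed(seed: int, name: str) -> int:
    """Stable 31-bit child seed for a named substream."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()[:4]
    return int.from_bytes(digest, "little") % (2**31 - 1)


@dataclass
class TrainingConfig:
    """Training protocol constants.

    Defaults follow the published protocol: 50 bagged bootstrap resamples,
    random-forest tuning length 30 (capped at the number of features),
    repeated 10-fold / 5-repeat CV for the base learners, a GBM meta-learner
    with tuning length 10 under 5-fold CV, ROC AUC as the metric, and
    in-fold down-sampling of the majority class.  ``fast()`` gives a reduced
    protocol for simulation studies and tests.
    """

    bagged_trees_resamples: int = 50
    rf_tune_length: int = 30
    n_trees: int = 200
    cv_folds: int = 10
    cv_repeats: int = 5
    meta_folds: int = 5
    meta_tune_length: int = 10
    metric: str = "roc_auc"
    downsample: bool = True
    class_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2 or self.meta_folds < 2:
            raise ValueError("CV needs at least 2 folds")
        if not 0.0 < self.class_threshold < 1.0:
            raise ValueError("class threshold must lie in (0, 1)")

    @classmethod
    def fast(cls, seed: int = 0) -> "TrainingConfig":
        """Reduced protocol: 5-fold x 1 repeat, small forests, short grids."""
        return cls(bagged_trees_resamples=25, rf_tune_length=4, n_trees=60,
                   cv_folds=5, cv_repeats=1, meta_folds=3, meta_tune_length=3,
                   seed=seed)


@dataclass
class ModelBundle:
    """Fitted preprocessing state, base learners, meta-learner and metadata."""

    transform_state: dict[str, float | None]
    base_models: dict[str, object]
    meta_model: GradientBoostingClassifier
    config: TrainingConfig
    feature_columns: tuple[str, ...]
    best_params: dict[str, dict]
    oof_fold_assignment: np.ndarray  # fold id per training row
    version: str = "1"


def downsample_fold(labels: Sequence[str] | np.ndarray, seed: int) -> np.ndarray:
    """Indices after randomly reducing the majority class to minority size.

    Applied to *training* folds only; validation and test rows are never
    down-sampled.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate fold: only one class present")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


# ------------------------------------------------------------ base learners


def _make_learner(name: str, params: Mapping, cfg: TrainingConfig, seed: int):
    if name == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=cfg.bagged_trees_resamples,
            random_state=seed,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=seed, **params)
    if name == "extra_trees":
        # default operating point, no grid: the algorithm's own
        # randomisation does the variance reduction
        return ExtraTreesClassifier(n_estimators=cfg.n_trees, random_state=seed)
    raise KeyError(name)


def _cv_auc(model, X: np.ndarray, y: np.ndarray, cfg: TrainingConfig,
            seed: int) -> float:
    """Mean AUC under repeated stratified CV with in-fold down-sampling."""
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=seed)
    aucs = []
    for k, (tr, va) in enumerate(splitter.split(X, y)):
        tr_use = tr
        if cfg.downsample:
            tr_use = tr[downsample_fold(y[tr], _derive_seed(seed, f"ds{k}"))]
        m = clone(model)
        m.fit(X[tr_use], y[tr_use])
        p = m.predict_proba(X[va])[:, 1]
        aucs.append(roc_auc_score(y[va], p))
    return float(np.mean(aucs))


def _tune_rf(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig) -> dict:
    n_feat = X.shape[1]
    grid = np.unique(np.linspace(1, n_feat, min(cfg.rf_tune_length, n_feat))
                     .round().astype(int))
    seed = _derive_seed(cfg.seed, "rf-tune")
    best, best_auc = None, -np.inf
    for mf in grid:
        model = _make_learner("random_forest", {"max_features": int(mf)},
                              cfg, seed)
        auc = _cv_auc(model, X, y, cfg, seed)
        if auc > best_auc:
            best, best_auc = {"max_features": int(mf)}, auc
    return best


def _gbm_grid(tune_length: int) -> list[dict]:
    grid = []
    k = 1
    while len(grid) < tune_length:
        for depth in (1, 2, 3):
            grid.append({"n_estimators": 50 * k, "max_depth": depth})
        k += 1
    return grid[:tune_length]


def _tune_meta(Z: np.ndarray, y: np.ndarray, cfg: TrainingConfig) -> dict:
    seed = _derive_seed(cfg.seed, "meta-tune")
    splitter = StratifiedKFold(n_splits=cfg.meta_folds, shuffle=True,
                               random_state=seed)
    best, best_auc = None, -np.inf
    for params in _gbm_grid(cfg.meta_tune_length):
        aucs = []
        for k, (tr, va) in enumerate(splitter.split(Z, y)):
            tr_use = tr
            if cfg.downsample:
                tr_use = tr[downsample_fold(y[tr],
                                            _derive_seed(seed, f"mds{k}"))]
            m = GradientBoostingClassifier(random_state=seed, **params)
            m.fit(Z[tr_use], y[tr_use])
            aucs.append(roc_auc_score(y[va], m.predict_proba(Z[va])[:, 1]))
        auc = float(np.mean(aucs))
        if auc > best_auc:
            best, best_auc = params, auc
    return best


# ----------------------------------------------------------------- training


def train(features: FeatureMatrix, config: TrainingConfig | None = None) -> ModelBundle:
    """Fit the stacked ensemble on a feature matrix.

    The Yeo-Johnson state is fitted here, on training data only.  Base
    learners are tuned by repeated stratified CV optimising AUC with in-fold
    down-sampling; the meta-learner is trained on out-of-fold base-learner
    probabilities (standard stacking) under ``meta_folds``-fold CV.
    """
    cfg = config or TrainingConfig()
    if tuple(features.X.columns) != FEATURE_COLUMNS:
        raise ValueError("feature matrix does not match the ten-feature schema")
    y = (features.label == POSITIVE_CLASS).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(y) < cfg.cv_folds:
        raise ValueError("fewer rows than CV folds")

    lambdas = fit_yeo_johnson(features.X[list(CONTINUOUS_FEATURES)])
    X = features.transformed(lambdas).to_numpy(dtype=float)

    best_params: dict[str, dict] = {
        "bagged_trees": {},
        "random_forest": _tune_rf(X, y, cfg),
        "extra_trees": {},
    }

    # out-of-fold base probabilities for the meta-learner
    oof_seed = _derive_seed(cfg.seed, "oof")
    splitter = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                               random_state=oof_seed)
    Z = np.zeros((len(y), len(BASE_LEARNERS)))
    fold_of = np.full(len(y), -1, dtype=int)
    for k, (tr, va) in enumerate(splitter.split(X, y)):
        fold_of[va] = k
        tr_use = tr
        if cfg.downsample:
            tr_use = tr[downsample_fold(y[tr], _derive_seed(oof_seed, f"ds{k}"))]
        for j, name in enumerate(BASE_LEARNERS):
            m = _make_learner(name, best_params[name], cfg,
                              _derive_seed(cfg.seed, f"{name}-oof{k}"))
            m.fit(X[tr_use], y[tr_use])
            Z[va, j] = m.predict_proba(X[va])[:, 1]

    meta_params = _tune_meta(Z, y, cfg)
    meta = GradientBoostingClassifier(
        random_state=_derive_seed(cfg.seed, "meta-final"), **meta_params)
    meta_idx = np.arange(len(y))
    if cfg.downsample:
        meta_idx = downsample_fold(y, _derive_seed(cfg.seed, "meta-ds"))
    meta.fit(Z[meta_idx], y[meta_idx])

    # final base learners on the full (down-sampled) training set
    base_models: dict[str, object] = {}
    full_idx = np.arange(len(y))
    if cfg.downsample:
        full_idx = downsample_fold(y, _derive_seed(cfg.seed, "final-ds"))
    for name in BASE_LEARNERS:
        m = _make_learner(name, best_params[name], cfg,
                          _derive_seed(cfg.seed, f"{name}-final"))
        m.fit(X[full_idx], y[full_idx])
        base_models[name] = m

    return ModelBundle(
        transform_state=lambdas,
        base_models=base_models,
        meta_model=meta,
        config=cfg,
        feature_columns=FEATURE_COLUMNS,
        best_params={**best_params, "meta": meta_params},
        oof_fold_assignment=fold_of,
    )


def predict(bundle: ModelBundle, X: pd.DataFrame | FeatureMatrix,
            cell_ids: Sequence | None = None) -> pd.DataFrame:
    """Per-cell probability of the 'older' class and thresholded label.

    No preprocessing is refitted: the training-time Yeo-Johnson state is
    applied to the new rows.
    """
    if isinstance(X, FeatureMatrix):
        if cell_ids is None and "cell_id" in X.X.index.names:
            cell_ids = X.X.index
        X = X.X
    if tuple(X.columns) != bundle.feature_columns:
        raise ValueError("feature schema mismatch with the trained bundle")
    Xt = X.copy()
    Xt[list(CONTINUOUS_FEATURES)] = apply_yeo_johnson(
        X[list(CONTINUOUS_FEATURES)], bundle.transform_state)
    Xa = Xt.to_numpy(dtype=float)
    Z = np.column_stack([
        bundle.base_models[name].predict_proba(Xa)[:, 1]
        for name in BASE_LEARNERS
    ])
    p = bundle.meta_model.predict_proba(Z)[:, 1]
    cls = np.where(p >= bundle.config.class_threshold,
                   POSITIVE_CLASS, NEGATIVE_CLASS)
    out = pd.DataFrame({"prob_older": p, "class": cls})
    out.insert(0, "cell_id",
               list(cell_ids) if cell_ids is not None else np.arange(len(p)))
    return out


# --------------------------------------------------------------- evaluation


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, scores: np.ndarray):
    """AUC and its DeLong structural components (V10 per positive, V01 per
    negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for ROC analysis")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n           # per positive
    v01 = 1.0 - (tz[m:] - ty) / m     # per negative
    return auc, v10, v01


def delong_ci(y_true: np.ndarray, scores: np.ndarray,
              alpha: float = 0.95) -> tuple[float, float, float]:
    """AUC with its DeLong 95% (by default) confidence interval."""
    auc, v10, v01 = _delong_components(np.asarray(y_true), np.asarray(scores))
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(
    y_a: np.ndarray, scores_a: np.ndarray,
    y_b: np.ndarray | None = None, scores_b: np.ndarray | None = None,
    *,
    paired: bool | None = None,
) -> tuple[float, float]:
    """DeLong z-test comparing two AUCs; returns (z, two-sided p).

    Paired form when both score vectors are on the same labelled cells
    (``y_b`` omitted or identical); unpaired z-test on independent AUC
    variances otherwise.
    """
    y_a = np.asarray(y_a)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if paired is None:
        paired = y_b is None or (len(y_a) == len(y_b)
                                 and np.array_equal(np.asarray(y_b), y_a))
    a1, v10_1, v01_1 = _delong_components(y_a, scores_a)
    if paired:
        a2, v10_2, v01_2 = _delong_components(y_a, scores_b)
        m, n = len(v10_1), len(v01_1)
        s10 = np.cov(v10_1, v10_2, ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(v01_1, v01_2, ddof=1) if n > 1 else np.zeros((2, 2))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        a2, v10_2, v01_2 = _delong_components(np.asarray(y_b), scores_b)
        var = np.var(v10_1, ddof=1) / len(v10_1) + np.var(v01_1, ddof=1) / len(v01_1) \
            + np.var(v10_2, ddof=1) / len(v10_2) + np.var(v01_2, ddof=1) / len(v01_2)
    diff = a1 - a2
    if var <= 1e-16:
        return 0.0, 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def evaluate_roc(scores: np.ndarray, labels: Sequence) -> dict:
    """ROC curve, trapezoidal AUC and DeLong 95% CI.

    ``labels`` may be 'older'/'younger' strings or 0/1 integers.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == POSITIVE_CLASS).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for ROC analysis")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc, lo, hi = delong_ci(y, np.asarray(scores, dtype=float))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
            "auc": auc, "ci95": (lo, hi)}


# ----------------------------------------------------------- interpretation


def _learner_importances(model) -> np.ndarray:
    if isinstance(model, BaggingClassifier):
        return np.mean([t.feature_importances_ for t in model.estimators_],
                       axis=0)
    return model.feature_importances_


def variable_importance(bundle: ModelBundle) -> pd.DataFrame:
    """Consensus variable importance across the three base learners.

    Each learner's raw importances are rescaled so its maximum is 100, then
    averaged.  The five recovery-bin dummies are additionally reported as a
    cumulative group in ``df.attrs['recovery_cumulative_consensus']``.
    """
    cols = {}
    for name in BASE_LEARNERS:
        imp = _learner_importances(bundle.base_models[name])
        mx = imp.max()
        cols[name] = 100.0 * imp / mx if mx > 0 else imp
    df = pd.DataFrame(cols, index=list(bundle.feature_columns))
    df["consensus"] = df[list(BASE_LEARNERS)].mean(axis=1)
    df.attrs["recovery_cumulative_consensus"] = float(
        df.loc[list(RECOVERY_DUMMIES), "consensus"].sum())
    return df


# ------------------------------------------------------------ learning curves


def _subset(features: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        X=features.X.iloc[idx].reset_index(drop=True),
        label=features.label.iloc[idx].reset_index(drop=True),
        donor_id=features.donor_id.iloc[idx].reset_index(drop=True),
    )


def learning_curve_cells(
    features: FeatureMatrix,
    sizes: Sequence[int],
    reps: int = 5,
    seed: int = 0,
    config: TrainingConfig | None = None,
    test_fraction: float = 0.25,
) -> pd.DataFrame:
    """AUC versus training-set size on a fixed held-out set.

    For each size, ``reps`` random subsamples of the training pool are drawn,
    a model trained on each, and mean AUC and standard error reported.
    """
    cfg = config or TrainingConfig.fast(seed)
    rng = np.random.default_rng(_derive_seed(seed, "lc-cells"))
    n = features.n_cells
    y = (features.label == POSITIVE_CLASS).to_numpy(int)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx, pool = perm[:n_test], perm[n_test:]
    if max(sizes) > len(pool):
        raise ValueError("requested size exceeds available training rows")
    test_fm = _subset(features, test_idx)

    rows = []
    for size in sizes:
        aucs = []
        for r in range(reps):
            sub = rng.choice(pool, size=size, replace=False)
            # guarantee both classes in the subsample
            if len(np.unique(y[sub])) < 2:
                continue
            bundle = train(_subset(features, sub),
                           replace(cfg, seed=_derive_seed(seed, f"{size}-{r}")))
            pred = predict(bundle, test_fm.X)
            aucs.append(roc_auc_score(y[test_idx], pred["prob_older"]))
        rows.append({
            "n_cells": size,
            "auc_mean": float(np.mean(aucs)),
            "auc_se": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
            if len(aucs) > 1 else 0.0,
            "n_reps": len(aucs),
        })
    return pd.DataFrame(rows)


def learning_curve_samples(
    features: FeatureMatrix,
    orders: int = 50,
    seed: int = 0,
    config: TrainingConfig | None = None,
    min_donors: int = 2,
) -> pd.DataFrame:
    """Donor-level learning curve via leave-one-sample-out validation.

    For each of ``orders`` random donor inclusion orders and each prefix of
    donors, every prefix donor is held out in turn, the model trained on the
    rest, and the pooled held-out predictions scored by AUC.  Prefixes whose
    training donors span a single class are logged and skipped.
    """
    import logging
    logger = logging.getLogger(__name__)

    cfg = config or TrainingConfig.fast(seed)
    donors = features.donor_id.unique()
    if len(donors) < 3:
        raise ValueError("need at least 3 donors")
    rng = np.random.default_rng(_derive_seed(seed, "lc-samples"))
    y_all = (features.label == POSITIVE_CLASS).to_numpy(int)

    records: list[dict] = []
    for o in range(orders):
        order = rng.permutation(donors)
        for k in range(min_donors, len(donors) + 1):
            prefix = order[:k]
            scores = np.full(features.n_cells, np.nan)
            for held in prefix:
                train_mask = features.donor_id.isin(prefix).to_numpy() \
                    & (features.donor_id != held).to_numpy()
                if features.label[train_mask].nunique() < 2:
                    logger.info("order %d prefix %d: training donors span a "
                                "single class with %s held out; skipped",
                                o, k, held)
                    continue
                idx = np.nonzero(train_mask)[0]
                bundle = train(_subset(features, idx),
                               replace(cfg, seed=_derive_seed(seed, f"{o}-{k}-{held}")))
                hmask = (features.donor_id == held).to_numpy()
                scores[hmask] = predict(
                    bundle, features.X.loc[hmask].reset_index(drop=True)
                )["prob_older"].to_numpy()
            have = ~np.isnan(scores)
            if have.sum() == 0 or len(np.unique(y_all[have])) < 2:
                continue
            records.append({
                "order": o, "n_donors": k,
                "auc": roc_auc_score(y_all[have], scores[have]),
            })
    df = pd.DataFrame(records)
    summary = df.groupby("n_donors")["auc"].agg(
        auc_mean="mean", auc_sd="std", n_orders="count").reset_index()
    summary.attrs["per_order"] = df
    return summary


# ---------------------------------------------------------------- persistence


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    joblib.dump({"version": bundle.version, "bundle": bundle}, path)


def load_bundle(path: str | Path) -> ModelBundle:
    payload = joblib.load(path)
    if payload.get("version") != "1":
        raise ValueError(f"unsupported bundle version {payload.get('version')!r}")
    return payload["bundle"]
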