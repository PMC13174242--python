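"""CyTOF marker analysis: differential expression and transfer signatures.

Per-protein differential expression uses a Wilcoxon rank-sum test with
Bonferroni correction across the panel; a marker is significant when the
adjusted p-value is below 0.05 *and* the absolute log fold change exceeds
0.5.  Group signatures are gradient-boosted binary classifiers trained once
on unperturbed control cells (stratified 70/30 split, 5-fold CV maximising
AUC) and then applied, frozen, to perturbation conditions; AUC differences
against control are assessed with DeLong's test.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from hashlib import sha256
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .mechanoage import delong_test

__all__ = [
    "DepResult",
    "dep_analysis",
    "FrozenSignature",
    "train_signature",
    "transfer_evaluate",
    "delong_compare",
    "log_transform",
]

DEP_P_THRESHOLD = 0.05
DEP_LFC_THRESHOLD = 0.5

#: Comparisons supported by :func:`train_signature`.
COMPARISONS = {
    "younger-vs-older": ("younger", "older"),
    "younger-vs-HR": ("younger", "high_risk"),
}


def log_transform(x: np.ndarray, method: str = "log1p",
                  cofactor: float = 5.0) -> np.ndarray:
    """Intensity transform for fold changes: natural log1p (default) or
    arcsinh with a mass-cytometry cofactor."""
    x = np.asarray(x, dtype=float)
    if method == "log1p":
        return np.log1p(x)
    if method == "arcsinh":
        return np.arcsinh(x / cofactor)
    raise ValueError(f"unknown transform {method!r}")


@dataclass
class DepResult:
    marker: str
    lfc: float
    p_raw: float
    p_adjusted: float
    significant: bool


def _marker_columns(matrix: pd.DataFrame) -> list[str]:
    meta = {"cell_id", "lineage", "group", "condition"}
    return [c for c in matrix.columns if c not in meta]


def dep_analysis(
    matrix: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    transform: str = "log1p",
) -> pd.DataFrame:
    """Per-marker differential expression between two groups.

    LFC is the difference of group means of log-transformed intensities
    (``group_b`` minus ``group_a``); p-values from the Wilcoxon rank-sum
    test, Bonferroni-adjusted over the panel.  Markers constant in both
    groups get p = 1 and are kept, not dropped.
    """
    markers = _marker_columns(matrix)
    a = matrix[matrix["group"] == group_a]
    b = matrix[matrix["group"] == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 cells")
    rows = []
    for m in markers:
        xa = log_transform(a[m].to_numpy(), transform)
        xb = log_transform(b[m].to_numpy(), transform)
        lfc = float(xb.mean() - xa.mean())
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"marker": m, "lfc": lfc, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method="bonferroni")[1]
    df["significant"] = (df["p_adjusted"] < DEP_P_THRESHOLD) & \
                        (df["lfc"].abs() > DEP_LFC_THRESHOLD)
    return df


@dataclass
class FrozenSignature:
    """A trained, frozen gradient-boosted group signature."""

    model: GradientBoostingClassifier
    markers: tuple[str, ...]
    classes: tuple[str, str]  # (negative, positive)
    comparison: str
    transform: str
    test_auc: float
    test_index: np.ndarray = field(repr=False, default=None)

    def checksum(self) -> str:
        return sha256(pickle.dumps(self.model)).hexdigest()


def train_signature(
    matrix_controls: pd.DataFrame,
    comparison: str = "younger-vs-older",
    *,
    lineage: str = "luminal",
    seed: int = 0,
    transform: str = "log1p",
) -> FrozenSignature:
    """Train the control-condition GBM signature for one binary comparison.

    Uses the luminal-cell subset by default; stratified 70/30 train-test
    split, hyperparameters selected by 5-fold CV maximising AUC; the model is
    frozen after training (transfer evaluation never updates it).
    """
    neg, pos = COMPARISONS[comparison]
    df = matrix_controls
    if "lineage" in df.columns and lineage is not None:
        df = df[df["lineage"] == lineage]
    df = df[df["group"].isin([neg, pos])]
    y = (df["group"] == pos).to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"class absent for comparison {comparison!r}")
    markers = tuple(_marker_columns(df))
    X = log_transform(df[list(markers)].to_numpy(), transform)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.30, stratify=y, random_state=seed)
    grid = {"n_estimators": [50, 100, 200], "max_depth": [1, 2, 3]}
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(
        GradientBoostingClassifier(random_state=seed), grid,
        scoring="roc_auc", cv=cv, refit=True)
    search.fit(X_tr, y_tr)
    model = search.best_estimator_
    test_auc = float(roc_auc_score(y_te, model.predict_proba(X_te)[:, 1]))
    return FrozenSignature(model=model, markers=markers, classes=(neg, pos),
                           comparison=comparison, transform=transform,
                           test_auc=test_auc)


def transfer_evaluate(
    signature: FrozenSignature,
    matrix_condition: pd.DataFrame,
    *,
    lineage: str = "luminal",
) -> dict:
    """Apply a frozen signature to a perturbation condition, no retraining.

    Scores every cell and computes ROC/AUC against the condition's
    chronological-class labels.  The model checksum is asserted unchanged.
    """
    if len(matrix_condition) == 0:
        raise ValueError("empty condition matrix")
    missing = set(signature.markers) - set(matrix_condition.columns)
    if missing:
        raise ValueError(f"condition matrix lacks markers: {sorted(missing)}")
    before = signature.checksum()
    df = matrix_condition
    if "lineage" in df.columns and lineage is not None:
        df = df[df["lineage"] == lineage]
    neg, pos = signature.classes
    df = df[df["group"].isin([neg, pos])]
    y = (df["group"] == pos).to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("condition matrix must contain both classes")
    X = log_transform(df[list(signature.markers)].to_numpy(),
                      signature.transform)
    scores = signature.model.predict_proba(X)[:, 1]
    assert signature.checksum() == before, "frozen-model contract violated"
    from .mechanoage import evaluate_roc
    roc = evaluate_roc(scores, y)
    roc["scores"] = scores
    roc["y"] = y
    return roc


def delong_compare(roc_a: dict, roc_b: dict) -> tuple[float, float]:
    """DeLong z and two-sided p comparing two transfer ROCs.

    Paired when the two evaluations share the same labelled cells, unpaired
    otherwise.
    """
    return delong_test(roc_a["y"], roc_a["scores"],
                       roc_b["y"], roc_b["scores"])
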