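"""Per-cell design matrix for the MechanoAge classifier.

Ten features per cell: five continuous mechanophenotypes (free diameter,
wCDI, contraction transit time, deformation length, transverse deformation)
plus five binary indicators for the recovery-time bins (0 ms; 50-60 ms;
60-70 ms; 70-120 ms; infinite).  Continuous columns are Yeo-Johnson
transformed with lambdas fitted by maximum likelihood on training data only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .device_physics import RECOVERY_CLASSES

__all__ = [
    "CONTINUOUS_FEATURES",
    "RECOVERY_DUMMIES",
    "FEATURE_COLUMNS",
    "bin_recovery",
    "recovery_class_of",
    "fit_yeo_johnson",
    "apply_yeo_johnson",
    "build_feature_table",
    "FeatureMatrix",
]

logger = logging.getLogger(__name__)

CONTINUOUS_FEATURES = ("D_cell_um", "wCDI", "dT_cont_ms", "L_deform_um",
                       "delta_deform")
RECOVERY_DUMMIES = tuple(f"recovery_{c}" for c in RECOVERY_CLASSES)
FEATURE_COLUMNS = CONTINUOUS_FEATURES + RECOVERY_DUMMIES

#: Age cut-offs defining the two chronological classes (years).
OLDER_MIN_AGE = 50.0
YOUNGER_MAX_AGE = 35.0


def recovery_class_of(dT_r_ms: float) -> str:
    """Bin a recovery time (ms, possibly ``inf``) into its printed class.

    Bins: exactly-0 recoveries (and the sub-50 ms values the discrete
    recovery segments make rare) -> ``0ms``; then [50, 60), [60, 70),
    [70, 120); unrecovered past the observation window -> ``Inf``.
    """
    if isinstance(dT_r_ms, str):
        if dT_r_ms.lower() in {"inf", "infinite"}:
            return "Inf"
        dT_r_ms = float(dT_r_ms)
    if np.isnan(dT_r_ms):
        raise ValueError("dT_r is NaN; flagged cells must be excluded upstream")
    if dT_r_ms < 0:
        raise ValueError("recovery time cannot be negative")
    if np.isinf(dT_r_ms):
        return "Inf"
    if dT_r_ms < 50.0:
        if dT_r_ms > 0:
            logger.debug("recovery time %.2f ms in (0, 50); assigned to 0ms bin",
                         dT_r_ms)
        return "0ms"
    if dT_r_ms < 60.0:
        return "50-60ms"
    if dT_r_ms < 70.0:
        return "60-70ms"
    if dT_r_ms < 120.0:
        return "70-120ms"
    logger.warning("finite recovery time %.2f ms at/past the 120 ms window; "
                   "treated as infinite", dT_r_ms)
    return "Inf"


def bin_recovery(dT_r_ms: float) -> np.ndarray:
    """One-hot vector over the five recovery-time bins."""
    cls = recovery_class_of(dT_r_ms)
    out = np.zeros(len(RECOVERY_CLASSES), dtype=int)
    out[RECOVERY_CLASSES.index(cls)] = 1
    return out


def fit_yeo_johnson(train_columns: pd.DataFrame) -> dict[str, float | None]:
    """Maximum-likelihood Yeo-Johnson lambda per continuous column.

    Constant columns get ``None`` (pass-through) with a warning.
    """
    lambdas: dict[str, float | None] = {}
    for col in train_columns.columns:
        x = np.asarray(train_columns[col], dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"column {col!r} is constant; Yeo-Johnson lambda "
                          "undefined, passing through", stacklevel=2)
            lambdas[col] = None
            continue
        _, lmbda = stats.yeojohnson(x)
        lambdas[col] = float(lmbda)
    return lambdas


def apply_yeo_johnson(
    columns: pd.DataFrame,
    lambdas: dict[str, float | None],
) -> pd.DataFrame:
    """Apply previously fitted Yeo-Johnson transforms (monotone, invertible)."""
    out = columns.copy()
    for col, lmbda in lambdas.items():
        if lmbda is None:
            continue
        out[col] = stats.yeojohnson(np.asarray(columns[col], dtype=float), lmbda)
    return out


@dataclass
class FeatureMatrix:
    """Design matrix plus labels, donor ids, and fitted transform state."""

    X: pd.DataFrame
    label: pd.Series  # 'younger' / 'older'
    donor_id: pd.Series
    transform_state: dict[str, float | None] = field(default_factory=dict)
    n_excluded_midrange_age: int = 0

    def __post_init__(self) -> None:
        assert tuple(self.X.columns) == FEATURE_COLUMNS, "bad feature schema"

    @property
    def n_cells(self) -> int:
        return len(self.X)

    def transformed(self, lambdas: dict[str, float | None] | None = None) -> pd.DataFrame:
        """Yeo-Johnson-transformed design matrix (continuous columns only).

        If no ``lambdas`` are given, the stored ``transform_state`` is used;
        an empty state means the matrix is returned untransformed.
        """
        lambdas = self.transform_state if lambdas is None else lambdas
        if not lambdas:
            return self.X.copy()
        Xt = self.X.copy()
        cont = Xt[list(CONTINUOUS_FEATURES)]
        Xt[list(CONTINUOUS_FEATURES)] = apply_yeo_johnson(cont, lambdas)
        return Xt

    def save_transform(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"yeo_johnson_lambda": self.transform_state}, fh)

    @staticmethod
    def load_transform(path: str | Path) -> dict[str, float | None]:
        with open(path) as fh:
            return yaml.safe_load(fh)["yeo_johnson_lambda"]


def build_feature_table(
    phenotypes: pd.DataFrame,
    donor_meta: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble the ten-column design matrix from a phenotype table.

    ``phenotypes`` needs the five continuous columns, ``recovery_class`` (or
    ``dT_r_ms``), ``cell_id`` and either a ``donor_id``+``age`` pair inline or
    a ``donor_meta`` table (``donor_id, age``) to join on.  Cells from donors
    aged in (35, 50] belong to neither chronological class and are excluded
    (the count is recorded); labels are 'older' (>50 y) or 'younger' (<35 y).
    """
    df = phenotypes.copy()
    if donor_meta is not None:
        df = df.merge(donor_meta, on="donor_id", how="left", validate="m:1")
    if "donor_id" not in df:
        df["donor_id"] = "donor0"
    if "age" not in df:
        raise ValueError("donor age required to assign class labels")

    if "recovery_class" not in df:
        df["recovery_class"] = df["dT_r_ms"].map(recovery_class_of)

    in_class = (df["age"] > OLDER_MIN_AGE) | (df["age"] < YOUNGER_MAX_AGE)
    n_excluded = int((~in_class).sum())
    if n_excluded:
        logger.info("excluded %d cells from donors aged within (35, 50]",
                    n_excluded)
    df = df.loc[in_class].reset_index(drop=True)

    X = df.reindex(columns=list(CONTINUOUS_FEATURES)).astype(float)
    for cls, dummy in zip(RECOVERY_CLASSES, RECOVERY_DUMMIES):
        X[dummy] = (df["recovery_class"] == cls).astype(int)
    label = pd.Series(
        np.where(df["age"] > OLDER_MIN_AGE, "older", "younger"),
        index=X.index, name="label", dtype="object",
    )
    if len(X):
        assert X[list(RECOVERY_DUMMIES)].sum(axis=1).eq(1).all()
    return FeatureMatrix(
        X=X,
        label=label,
        donor_id=df["donor_id"].reset_index(drop=True)
        if len(df) else pd.Series([], dtype="object", name="donor_id"),
        n_excluded_midrange_age=n_excluded,
    )
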