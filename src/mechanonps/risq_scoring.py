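"""Mechano-RISQ: deviation of a sample's "older"-classification rate.

The score is the ratio of the fraction of a sample's cells classified as
older to a baseline error rate measured on average-risk reference cells of
the same chronological class: 1.0 means no deviation, values above (below)
1.0 mean an elevated (reduced) misclassification rate.  Inference wraps the
score in a Crawford-Howell single-case t-test against the normative
average-risk distribution (with simulation-based power), Benjamini-Hochberg
correction across samples, Wilcoxon rank-sum group comparisons, and Fisher's
exact test for perturbation experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RisqResult",
    "baseline_error_rate",
    "mechano_risq",
    "crawford_howell",
    "ch_power_simulation",
    "bh_adjust",
    "group_compare",
    "perturbation_fisher",
    "risq_table",
]


@dataclass
class RisqResult:
    sample_id: str
    n_cells: int
    p_older: float
    baseline: float
    risq: float
    ch_t: float | None = None
    ch_df: int | None = None
    p_value: float | None = None
    p_adjusted: float | None = None


def baseline_error_rate(
    reference_predictions: Sequence[str],
    reference_labels: Sequence[str],
) -> float:
    """Fraction of reference *younger* cells misclassified as 'older'.

    The reference set must be average-risk validation cells that were not
    used in training.  A zero rate leaves the RISQ ratio undefined and is an
    error (enlarge the reference set).
    """
    pred = np.asarray(reference_predictions)
    lab = np.asarray(reference_labels)
    young = lab == "younger"
    if young.sum() == 0:
        raise ValueError("reference set contains no younger cells")
    b = float((pred[young] == "older").mean())
    if b == 0.0:
        raise ValueError("baseline error rate is zero; RISQ undefined — "
                         "use a larger reference set")
    return b


def mechano_risq(sample_predictions: Sequence[str], b: float) -> float:
    """RISQ ratio p_older / b for one sample's predicted classes."""
    pred = np.asarray(sample_predictions)
    if pred.size == 0:
        raise ValueError("empty sample")
    if b <= 0:
        raise ValueError("baseline error rate must be positive")
    return float((pred == "older").mean() / b)


def crawford_howell(
    case_value: float,
    normative_values: Sequence[float],
    *,
    alternative: str = "two-sided",
) -> tuple[float, int, float]:
    """Crawford-Howell single-case t-test.

    ``t = (x* - mean) / (s * sqrt((n + 1) / n))`` with ``df = n - 1``; the
    default p-value is two-sided.  Valid for comparing one case against a
    small normative group.
    """
    norm = np.asarray(normative_values, dtype=float)
    n = len(norm)
    if n < 2:
        raise ValueError("normative sample needs at least 2 values")
    s = norm.std(ddof=1)
    if s == 0:
        raise ValueError("normative sample is constant; t undefined")
    t = (case_value - norm.mean()) / (s * np.sqrt((n + 1) / n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), int(df), float(min(p, 1.0))


def ch_power_simulation(
    n_norm: int,
    cohens_d: float = 3.0,
    alpha: float = 0.05,
    iterations: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Crawford-Howell test.

    Each iteration draws a normative sample of size ``n_norm`` from N(0, 1)
    and a case at ``cohens_d`` population SDs from the normative mean; power
    is the fraction of two-sided rejections at ``alpha``.
    """
    if n_norm < 2:
        raise ValueError("normative sample needs at least 2 values")
    if iterations < 100:
        warnings.warn("fewer than 100 iterations gives an unstable power "
                      "estimate", stacklevel=2)
    rng = np.random.default_rng(seed)
    norm = rng.normal(0.0, 1.0, size=(iterations, n_norm))
    case = rng.normal(cohens_d, 1.0, size=iterations)
    mean = norm.mean(axis=1)
    s = norm.std(axis=1, ddof=1)
    t = (case - mean) / (s * np.sqrt((n_norm + 1) / n_norm))
    p = 2.0 * stats.t.sf(np.abs(t), n_norm - 1)
    return float((p < alpha).mean())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def group_compare(
    risq_a: Sequence[float],
    risq_b: Sequence[float],
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing RISQ between groups.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic method selection).
    """
    a = np.asarray(risq_a, dtype=float)
    b = np.asarray(risq_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def perturbation_fisher(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 older/younger x condition table."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(tab, alternative="two-sided").pvalue)


def risq_table(
    predictions: pd.DataFrame,
    donor_meta: pd.DataFrame,
    baseline: float,
    normative_risq: Sequence[float],
) -> pd.DataFrame:
    """Per-sample RISQ with Crawford-Howell inference and BH correction.

    ``predictions`` must carry ``donor_id`` and ``class`` columns;
    ``normative_risq`` is the distribution of RISQ scores among the
    average-risk normative samples.  BH is applied across all samples in the
    table (one analysis panel).
    """
    rows = []
    for donor_id, grp in predictions.groupby("donor_id", sort=True):
        risq = mechano_risq(grp["class"], baseline)
        t, df, p = crawford_howell(risq, normative_risq)
        rows.append({
            "sample_id": donor_id,
            "n_cells": len(grp),
            "p_older": float((grp["class"] == "older").mean()),
            "baseline": baseline,
            "risq": risq,
            "t": t,
            "df": df,
            "p": p,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.merge(donor_meta[["donor_id", "age", "risk_group"]]
                     .rename(columns={"donor_id": "sample_id"}),
                     on="sample_id", how="left")
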