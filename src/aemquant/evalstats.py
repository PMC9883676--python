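"""Accuracy metrics for simulation studies.

The central metric is the absolute proportion error
``APE = |E - T| / (T + 1)`` between an estimate ``E`` and the truth ``T``;
the +1 in the denominator keeps the error finite for unexpressed isoforms.
Per-isoform accuracy over a multi-sample simulation is summarized as the
median APE across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .matrix import DesignMatrix

__all__ = [
    "ape",
    "median_ape",
    "categorize_columns",
    "aggregate_truth",
    "recovery_report",
]


def ape(E, T):
    """Absolute proportion error ``|E - T| / (T + 1)``; truth must be >= 0."""
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("true expression must be non-negative")
    result = np.abs(E - T) / (T + 1.0)
    return result if result.ndim else float(result)


def median_ape(estimates, truths) -> np.ndarray:
    """Per-isoform median over samples of the APE.

    ``estimates`` and ``truths`` are (isoform x sample) arrays of identical
    shape; for merged paralog groups the caller supplies the summed member
    truth (see :func:`aggregate_truth`).
    """
    E = np.atleast_2d(np.asarray(estimates, dtype=float))
    T = np.atleast_2d(np.asarray(truths, dtype=float))
    if E.shape != T.shape:
        raise ValueError(f"shape mismatch: {E.shape} vs {T.shape}")
    if E.shape[1] == 0:
        raise ValueError("no samples to take the median over")
    return np.median(ape(E, T), axis=1)


def categorize_columns(X: DesignMatrix) -> dict[str, str]:
    """Assign each design-matrix column to singleton / multi / paralog.

    Paralog-merged columns are those recorded in ``X.merged_groups``; a
    singleton is a column whose every occupied pattern contains it alone
    (its reads never mix with another transcript's); everything else is a
    multi-isoform non-paralog column.
    """
    merged_ids = {g.merged_id for g in X.merged_groups}
    mask = X.mask
    categories: dict[str, str] = {}
    for col, tid in enumerate(X.transcripts):
        if tid in merged_ids:
            categories[tid] = "paralog"
        elif all(row.sum() == 1 for row in mask if row[col]):
            categories[tid] = "singleton"
        else:
            categories[tid] = "multi"
    return categories


def aggregate_truth(
    truth: np.ndarray,
    truth_ids: list[str],
    X: DesignMatrix,
) -> np.ndarray:
    """Align a per-transcript truth matrix to X's columns.

    Members of a merged paralog group are summed: the merged column estimates
    the group's total abundance, so that is the comparable truth.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    idx = {t: i for i, t in enumerate(truth_ids)}
    rows = []
    for tid in X.transcripts:
        members = tid.split("+")
        missing = [m for m in members if m not in idx]
        if missing:
            raise KeyError(f"truth is missing transcripts {missing}")
        rows.append(truth[[idx[m] for m in members]].sum(axis=0))
    return np.array(rows)


def recovery_report(
    beta_hat: np.ndarray,
    beta_true: np.ndarray,
    X_hat: DesignMatrix,
    X_true: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Per-category parameter-recovery summary.

    ``beta_hat`` is (columns-of-X_hat x samples); ``beta_true`` must already
    be aligned to X_hat's columns (:func:`aggregate_truth`). Reports, per
    isoform category, the median APE, Pearson and Spearman correlation over
    all (isoform, sample) cells, and — when ``X_true`` is given and shapes
    match — the Frobenius error of the category's design-matrix columns.
    Categories with no members are omitted.
    """
    beta_hat = np.atleast_2d(np.asarray(beta_hat, dtype=float))
    beta_true = np.atleast_2d(np.asarray(beta_true, dtype=float))
    if beta_hat.shape != beta_true.shape:
        raise ValueError("estimate/truth shape mismatch")
    categories = categorize_columns(X_hat)
    med = median_ape(beta_hat, beta_true)
    rows = []
    for cat in ("singleton", "multi", "paralog"):
        cols = [i for i, t in enumerate(X_hat.transcripts) if categories[t] == cat]
        if not cols:
            continue
        E = beta_hat[cols].ravel()
        T = beta_true[cols].ravel()
        if np.std(E) > 0 and np.std(T) > 0:
            pear = float(pearsonr(E, T).statistic)
            spear = float(spearmanr(E, T).statistic)
        else:
            pear = spear = float("nan")
        frob = float("nan")
        if X_true is not None and X_true.x.shape == X_hat.x.shape:
            frob = float(np.linalg.norm(X_hat.x[:, cols] - X_true.x[:, cols]))
        rows.append(
            {
                "category": cat,
                "n_isoforms": len(cols),
                "median_ape": float(np.median(med[cols])),
                "pearson": pear,
                "spearman": spear,
                "x_frobenius_error": frob,
            }
        )
    return pd.DataFrame(rows)
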