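"""Two-group differential expression and rediscovery-rate validation.

The downstream check of quantification quality: normalize counts
(counts-per-million, log2, per-sample median centering), test each isoform
between two groups with a Welch t-test, carry the top-M significant isoforms
from a training set into an independent validation set, and report the
rediscovery rate (RDR) — the fraction that are significant there too. Under
a pure-noise null the RDR is calibrated at the significance level (~0.05);
accurate quantification of true signal pushes it toward 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "RDRResult",
    "cpm_log_mediannorm",
    "ttest_pvalues",
    "rdr",
]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-isoform two-group test results on normalized expression."""

    normalized: pd.DataFrame  # isoform x sample log-CPM
    pvalues: pd.Series  # per isoform, in [0, 1]
    direction: pd.Series  # sign of mean(group1) - mean(group2)

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.pvalues.index[self.pvalues < alpha]


@dataclass(frozen=True)
class RDRResult:
    """Rediscovery of training-set top hits in a validation set."""

    M: int
    rediscovered: int
    rdr: float

    def __post_init__(self) -> None:
        if not (0 <= self.rdr <= 1):
            raise ValueError("rdr must lie in [0, 1]")


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    return pd.DataFrame(
        counts,
        index=[f"iso{i + 1}" for i in range(counts.shape[0])],
        columns=[f"s{j + 1}" for j in range(counts.shape[1])],
    )


def cpm_log_mediannorm(counts, median_center: bool = True) -> pd.DataFrame:
    """Counts-per-million, log2(CPM + 1), per-sample median centering.

    CPM divides by the sample's library size (column sum) and rescales to a
    million, making samples with different sequencing depths comparable; the
    log tames the dynamic range; centering subtracts each sample's median
    log-CPM over its *expressed* (nonzero-count) isoforms, removing residual
    per-sample level shifts. Samples with an empty library are dropped with
    a warning.
    """
    df = _as_frame(counts)
    libsize = df.sum(axis=0)
    empty = libsize <= 0
    if empty.any():
        logger.warning("dropping zero-library samples: %s", list(df.columns[empty]))
        df = df.loc[:, ~empty]
        libsize = libsize[~empty]
    cpm = df / libsize * 1e6
    logcpm = np.log2(cpm + 1.0)
    if median_center:
        centered = {}
        for col in logcpm.columns:
            values = logcpm[col]
            nonzero = values[df[col] > 0]
            center = float(nonzero.median()) if len(nonzero) else 0.0
            centered[col] = values - center
        logcpm = pd.DataFrame(centered)[logcpm.columns]
    return logcpm


def ttest_pvalues(normalized: pd.DataFrame, group_labels) -> DEResult:
    """Per-isoform two-sided Welch t-test between the two groups.

    Groups are the two distinct labels in ``group_labels`` (order of first
    appearance); each needs at least two samples. Isoforms with zero
    variance in both groups get p = 1. Direction is the sign of
    mean(group1) - mean(group2).
    """
    normalized = _as_frame(normalized)
    labels = pd.Series(list(group_labels), index=normalized.columns)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two group labels, got {groups}")
    a = normalized.loc[:, labels == groups[0]].to_numpy()
    b = normalized.loc[:, labels == groups[1]].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals = np.where(flat, 1.0, pvals)
    direction = np.sign(a.mean(axis=1) - b.mean(axis=1))
    return DEResult(
        normalized,
        pd.Series(pvals, index=normalized.index, name="pvalue"),
        pd.Series(direction, index=normalized.index, name="direction"),
    )


def rdr(
    train: DEResult,
    valid: DEResult,
    M: int,
    alpha: float = 0.05,
    require_direction: bool = False,
) -> RDRResult:
    """Rediscovery rate of the training set's top-M hits in the validation set.

    The top M training isoforms are the significant ones (p < ``alpha``)
    ordered by ascending p (ties broken by id); M is truncated to the number
    available (logged). An isoform is rediscovered when its validation p is
    below ``alpha`` (and, with ``require_direction``, the effect signs
    agree).
    """
    shared = train.pvalues.index.intersection(valid.pvalues.index)
    if len(shared) == 0:
        raise ValueError("training and validation isoform sets are disjoint")
    train_p = train.pvalues.loc[shared]
    significant = train_p[train_p < alpha]
    order = sorted(significant.index, key=lambda i: (significant[i], i))
    if M > len(order):
        logger.info("M=%d truncated to %d significant training isoforms", M, len(order))
        M = len(order)
    top = order[:M]
    if M == 0:
        return RDRResult(0, 0, 0.0)
    hit = valid.pvalues.loc[top] < alpha
    if require_direction:
        hit &= valid.direction.loc[top] == train.direction.loc[top]
    rediscovered = int(hit.sum())
    return RDRResult(M, rediscovered, rediscovered / M)
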