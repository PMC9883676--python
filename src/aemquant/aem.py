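"""Alternating EM estimation of abundances and the design matrix.

Model: observed equivalence-class counts of sample ``n`` are independent
Poisson, ``y_jn ~ Poisson(mu_jn)`` with ``mu_n = X beta_n``. The design
matrix X (patterns x transcripts, columns summing to one) is shared across
samples; abundances ``beta_tn`` are per sample. Both are estimated by
alternating two steps until joint convergence:

A. *beta step* (X fixed): a variational-Bayes EM update. Reads of class
   ``j`` are allocated to its member transcripts with weights
   ``x_jt * exp(psi(beta0 + beta_t))`` where ``psi`` is the digamma
   function and ``beta0`` a prior pseudo-count (the mean read count per
   transcript); the new ``beta_t`` is ``beta0`` plus its allocated reads.

B. *X step* (beta fixed): reads of each class are re-allocated by the
   current ``x_jt beta_tn``, pooled across samples, and every transcript
   column is renormalized to proportions. Pooling across samples is what
   lets the shared X absorb sample-independent distortions (unknown biases)
   that a per-sample fit could not identify.

Running with the X step disabled reproduces a conventional fixed-design
estimator, which is the natural no-bias-correction baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .matrix import DesignMatrix
from .simgen import EqclassCounts

__all__ = [
    "CountMatrix",
    "AbundanceMatrix",
    "ConvergenceCriterion",
    "AEMDiagnostics",
    "build_count_matrix",
    "init_beta",
    "beta_update",
    "x_update",
    "converged",
    "aem_fit",
    "poisson_deviance",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Observed eqclass counts ``y_jn``, rows matched to a design matrix's patterns."""

    patterns: list[tuple[int, ...]]
    y: np.ndarray  # (J, N)
    sample_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] != len(self.patterns):
            raise ValueError("row count does not match number of patterns")
        if np.any(self.y < 0):
            raise ValueError("negative counts")
        if self.sample_names is None:
            self.sample_names = [f"s{i + 1}" for i in range(self.y.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.y.shape[1]


@dataclass
class AbundanceMatrix:
    """Per-transcript, per-sample abundance estimates plus the prior offset.

    ``beta`` is the raw iterate of the allocation update and includes the
    additive pseudo-count ``beta0``; :attr:`counts` is the number of reads
    allocated to each transcript (``beta - beta0``, kept in exact form for
    exclusive patterns).
    """

    beta: np.ndarray  # (T, N)
    beta0: float
    transcripts: list[str]
    sample_names: list[str] | None = None
    alloc: np.ndarray | None = None  # allocated reads, beta - beta0 pre-rounding

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[0] != len(self.transcripts):
            raise ValueError("beta rows do not match transcripts")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")

    @property
    def counts(self) -> np.ndarray:
        """Estimated read counts attributable to each transcript."""
        if self.alloc is not None:
            return self.alloc
        return np.clip(self.beta - self.beta0, 0.0, None)


@dataclass(frozen=True)
class ConvergenceCriterion:
    """Elementwise 1% rule with an absolute floor for small entries.

    An element with previous magnitude >= ``abs_floor_value`` must change by
    less than ``rel_tol`` relatively; smaller elements must change by less
    than ``abs_floor_tol`` (1% of the floor) absolutely.
    """

    rel_tol: float = 0.01
    abs_floor_value: float = 0.01
    abs_floor_tol: float = 1e-4
    max_iter: int = 100


@dataclass
class AEMDiagnostics:
    iterations: int = 0
    converged: bool = False
    beta0: float = 0.0
    max_delta_beta: list[float] = field(default_factory=list)
    max_delta_x: list[float] = field(default_factory=list)
    deviance: list[float] = field(default_factory=list)
    unmatched_classes: int = 0

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "beta0": self.beta0,
            "max_delta_beta": self.max_delta_beta,
            "max_delta_x": self.max_delta_x,
            "deviance": self.deviance,
            "unmatched_classes": self.unmatched_classes,
        }


def build_count_matrix(
    X: DesignMatrix,
    samples: list[EqclassCounts],
    sample_names: list[str] | None = None,
) -> CountMatrix:
    """Match per-sample eqclass counts to X's patterns by transcript-set identity.

    Transcripts merged in X are mapped to their merged column before
    matching. Observed classes with no corresponding pattern are dropped
    (logged): they carry reads the design matrix cannot explain.
    """
    member_map = X.member_to_column()
    pattern_index = {
        frozenset(np.flatnonzero(p)): j
        for j, p in enumerate(np.array(X.patterns))
    }
    y = np.zeros((X.n_patterns, len(samples)))
    unmatched = 0
    for n, sample in enumerate(samples):
        for eqclass, count in sample.counts.items():
            cols = frozenset(
                member_map[t] for t in eqclass if t in member_map
            )
            j = pattern_index.get(cols) if cols else None
            if j is None:
                unmatched += 1
                logger.debug("unmatched eqclass %s (%d reads)", sorted(eqclass), count)
            else:
                y[j, n] += count
    if unmatched:
        logger.info("dropped %d observed classes with no matching pattern", unmatched)
    cm = CountMatrix(list(X.patterns), y, sample_names)
    cm.unmatched_classes = unmatched  # type: ignore[attr-defined]
    return cm


def init_beta(Y: CountMatrix, X: DesignMatrix) -> AbundanceMatrix:
    """Flat start: ``beta0`` = mean read count per transcript across all samples."""
    total = float(Y.y.sum())
    T, N = X.n_transcripts, Y.n_samples
    if total == 0:
        logger.warning("all-zero count matrix; beta0 set to 1")
        beta0 = 1.0
    else:
        beta0 = total / (T * N)
    beta = np.full((T, N), beta0)
    return AbundanceMatrix(
        beta, beta0, list(X.transcripts), Y.sample_names, alloc=np.zeros((T, N))
    )


def beta_update(
    Y: CountMatrix,
    X: DesignMatrix,
    beta_prev: AbundanceMatrix,
    literal_eq7: bool = False,
) -> AbundanceMatrix:
    """One variational-Bayes allocation step for every sample.

    Class ``j``'s reads are split among its member transcripts with weight
    ``x_jt * exp(l_jt)`` where ``l_jt = psi(beta0 + beta_t) -
    psi(sum_{t' in j} (beta0 + beta_t'))``; the second term is constant
    within a class and cancels in the ratio. With ``literal_eq7`` the
    ``x_jt`` factor is omitted and members are weighted by ``exp(l_jt)``
    alone (the allocation then ignores the design proportions; kept as an
    auditable variant).
    """
    beta0 = beta_prev.beta0
    theta = beta0 + beta_prev.beta  # (T, N)
    log_w = digamma(theta)
    log_w -= log_w.max(axis=0, keepdims=True)  # per-sample shift, cancels in ratios
    ew = np.exp(log_w)
    T, N = theta.shape
    alloc = np.zeros((T, N))
    unallocated = 0
    for j, bits in enumerate(X.patterns):
        members = np.flatnonzero(bits)
        w = ew[members] if literal_eq7 else X.x[j, members, None] * ew[members]
        denom = w.sum(axis=0)  # (N,)
        ok = denom > 0
        unallocated += int((~ok & (Y.y[j] > 0)).sum())
        # normalized within the class, so an exclusive pattern allocates exactly
        norm = np.where(ok, w / np.where(ok, denom, 1.0), 0.0)
        alloc[members] += Y.y[j] * norm
    if unallocated:
        logger.warning(
            "%d pattern/sample cells have zero allocation weight; their reads "
            "are left unallocated",
            unallocated,
        )
    beta = beta0 + alloc
    return AbundanceMatrix(
        beta,
        beta0,
        list(beta_prev.transcripts),
        beta_prev.sample_names,
        alloc=alloc,
    )


def x_update(
    Y: CountMatrix,
    X_prev: DesignMatrix,
    beta: AbundanceMatrix,
) -> DesignMatrix:
    """Re-estimate the design proportions from the pooled read allocations.

    Reads of class ``j`` in sample ``n`` are allocated proportionally to
    ``x_jt beta_tn``; allocations are pooled over samples and each column is
    standardized to sum to one. Structural zeros persist (the allocation is
    multiplicative in ``x_jt``). A column receiving no reads anywhere keeps
    its previous values (logged) rather than becoming undefined.
    """
    if beta.beta.shape != (X_prev.n_transcripts, Y.n_samples):
        raise ValueError("dimension mismatch between X, Y and beta")
    b = beta.beta
    denom = X_prev.x @ b  # (J, N)
    ok = denom > 0
    ratio = np.where(ok, Y.y / np.where(ok, denom, 1.0), 0.0)
    A = X_prev.x * (ratio @ b.T)  # (J, T) pooled allocations
    colsums = A.sum(axis=0)
    dead = colsums <= 0
    if dead.any():
        logger.warning(
            "columns with no allocated reads keep previous values: %s",
            [t for t, d in zip(X_prev.transcripts, dead) if d],
        )
    x = np.where(dead[None, :], X_prev.x, A / np.where(dead, 1.0, colsums)[None, :])
    return DesignMatrix(
        list(X_prev.transcripts),
        list(X_prev.patterns),
        x,
        list(X_prev.merged_groups),
    )


def _element_converged(prev: np.ndarray, new: np.ndarray, crit: ConvergenceCriterion) -> bool:
    prev = np.asarray(prev, dtype=float)
    new = np.asarray(new, dtype=float)
    delta = np.abs(new - prev)
    big = np.abs(prev) >= crit.abs_floor_value
    rel_ok = delta < crit.rel_tol * np.abs(np.where(big, prev, 1.0))
    abs_ok = delta < crit.abs_floor_tol
    return bool(np.all(np.where(big, rel_ok, abs_ok)))


def converged(
    state_prev: tuple[DesignMatrix, AbundanceMatrix],
    state_next: tuple[DesignMatrix, AbundanceMatrix],
    crit: ConvergenceCriterion = ConvergenceCriterion(),
) -> bool:
    """True when every element of X and beta satisfies the 1%/floor rule."""
    X_prev, b_prev = state_prev
    X_next, b_next = state_next
    return _element_converged(X_prev.x, X_next.x, crit) and _element_converged(
        b_prev.beta, b_next.beta, crit
    )


def poisson_deviance(Y: CountMatrix, X: DesignMatrix, counts: np.ndarray) -> float:
    """Poisson deviance between observed counts and fitted means ``X @ counts``.

    ``counts`` is the abundance on the model scale (prior offset removed),
    so fitted totals match observed totals per sample.
    """
    mu = X.x @ counts
    y = Y.y
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(mu > 0, y / np.where(mu > 0, mu, 1.0), np.inf)), 0.0)
    term = np.where((y > 0) & (mu == 0), np.inf, term)
    return float(2.0 * np.sum(term - (y - mu)))


def aem_fit(
    Y: CountMatrix,
    X0: DesignMatrix,
    crit: ConvergenceCriterion | None = None,
    update_X: bool = True,
    literal_eq7: bool = False,
) -> tuple[DesignMatrix, AbundanceMatrix, AEMDiagnostics]:
    """Alternate the beta and X steps until joint convergence.

    With ``update_X=False`` the design matrix stays at ``X0`` and only the
    abundances are iterated (the fixed-design baseline). Returns the final
    design matrix, the abundances (raw ``beta`` and offset; read-count
    estimates via ``.counts``) and per-iteration diagnostics. Non-convergence
    within ``crit.max_iter`` iterations returns the last state with the
    ``converged`` flag unset.
    """
    if crit is None:
        crit = ConvergenceCriterion()
    X = X0
    beta = init_beta(Y, X0)
    diag = AEMDiagnostics(beta0=beta.beta0)
    for iteration in range(1, crit.max_iter + 1):
        beta_next = beta_update(Y, X, beta, literal_eq7=literal_eq7)
        X_next = x_update(Y, X, beta_next) if update_X else X
        diag.iterations = iteration
        diag.max_delta_beta.append(float(np.max(np.abs(beta_next.beta - beta.beta))))
        diag.max_delta_x.append(float(np.max(np.abs(X_next.x - X.x))))
        diag.deviance.append(poisson_deviance(Y, X_next, beta_next.counts))
        is_done = converged((X, beta), (X_next, beta_next), crit)
        X, beta = X_next, beta_next
        if is_done:
            diag.converged = True
            break
    if not diag.converged:
        logger.warning("AEM did not converge in %d iterations", crit.max_iter)
    return X, beta, diag
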