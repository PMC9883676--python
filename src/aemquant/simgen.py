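"""Toy transcriptomes, read simulation and equivalence-class counting.

This module emulates, at desk scale, the simulation machinery needed both to
construct an empirical design matrix (single-transcript read simulation plus
mapping) and to generate multi-sample synthetic experiments (Poisson
equivalence-class counts under a known design matrix, beta-Poisson expression
across samples, and a generic non-uniform-bias distortion of the design
matrix).

Reads are exact substrings of their source transcript, optionally corrupted
by per-base substitution errors; mapping is exact-substring lookup against
the transcriptome. This is a deliberately transparent, brute-force-verifiable
stand-in for quasi-mapping: the equivalence-class abstraction downstream only
needs the *set* of transcripts a read is compatible with.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .matrix import DesignMatrix

__all__ = [
    "ToyTranscript",
    "SimulationConfig",
    "BetaPoissonParams",
    "EqclassCounts",
    "SubstringIndex",
    "make_toy_transcriptome",
    "simulate_reads",
    "quasi_map",
    "sample_beta_poisson",
    "simulate_multisample_counts",
    "apply_bias",
    "simulate_null_experiment",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ToyTranscript:
    """A synthetic transcript: an id, its nucleotide sequence and a gene id."""

    id: str
    sequence: str
    gene_id: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.id}: sequence has non-ACGT characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulationConfig:
    """Read-simulation settings.

    The number of reads per transcript follows the rule
    ``L = max(2 * transcript_length, min_reads)`` so that every transcript,
    however short, yields enough reads for a stable response profile.
    Defaults: 100 bp reads, per-base substitution error 0.005, fragment
    length 250 +/- 25 bp (fragments only matter when ``paired`` is set;
    mapping always uses the reads as single-end exact substrings).
    """

    base_error_rate: float = 0.005
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    paired: bool = False
    min_reads: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_error_rate < 1):
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")

    def n_reads(self, transcript_length: int) -> int:
        return max(2 * transcript_length, self.min_reads)


@dataclass(frozen=True)
class BetaPoissonParams:
    """Four-parameter beta-Poisson expression model.

    Per sample: draw ``p ~ Beta(alpha, beta)``, then the expression value is
    ``lambda2 * Poisson(lambda1 * p)``. ``lambda1`` scales the Poisson rate,
    ``lambda2`` the amplitude. Mean expression is
    ``lambda2 * lambda1 * alpha / (alpha + beta)``.
    """

    alpha: float
    beta: float
    lambda1: float
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.lambda2) <= 0 or self.lambda1 < 0:
            raise ValueError("beta-Poisson parameters must be positive")


@dataclass
class EqclassCounts:
    """Read counts keyed by equivalence class (a frozenset of transcript ids)."""

    counts: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for class {sorted(key)}")

    @property
    def total_mapped(self) -> int:
        return int(sum(self.counts.values()))

    def __len__(self) -> int:
        return len(self.counts)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_toy_transcriptome(
    n_genes: int,
    isoforms_per_gene: int,
    shared_block_len: int = 200,
    unique_block_len: int = 150,
    seed: int = 0,
    read_length: int = 100,
) -> list[ToyTranscript]:
    """Build a transcriptome of genes whose isoforms share one sequence block.

    Each gene gets a random shared block; isoform ``i`` is the shared block
    followed by its own random unique block, so isoforms of one gene share
    equivalence classes while distinct genes share none. Set
    ``unique_block_len = 0`` to make all isoforms of a gene identical
    (exact paralogs).

    Blocks must be at least ``read_length`` long (a shorter block could not
    hold a read and the sharing structure would be vacuous); ``unique_block_len``
    may also be exactly 0.
    """
    if shared_block_len < read_length:
        raise ValueError("shared_block_len must be >= read_length")
    if unique_block_len != 0 and unique_block_len < read_length:
        raise ValueError("unique_block_len must be 0 or >= read_length")
    rng = np.random.default_rng(seed)
    for _ in range(20):  # retry until no k-mer is shared across genes
        transcripts: list[ToyTranscript] = []
        for g in range(1, n_genes + 1):
            shared = _random_seq(rng, shared_block_len)
            for i in range(1, isoforms_per_gene + 1):
                unique = _random_seq(rng, unique_block_len)
                transcripts.append(
                    ToyTranscript(f"g{g}tx{i}", shared + unique, f"g{g}")
                )
        gene_kmers: dict[str, set[str]] = {}
        for t in transcripts:
            gene_kmers.setdefault(t.gene_id, set()).update(
                _kmers(t.sequence, read_length)
            )
        genes = list(gene_kmers)
        collision = any(
            gene_kmers[a] & gene_kmers[b]
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        )
        if not collision:
            return transcripts
    raise RuntimeError("could not generate collision-free transcriptome")


def simulate_reads(
    transcript: ToyTranscript,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> list[str]:
    """Simulate uniformly positioned reads with per-base substitution errors.

    The read count defaults to ``config.n_reads(len(transcript))``; pass
    ``n_reads`` to simulate a sample with a known expression level instead.
    Transcripts shorter than the read length yield no reads (logged).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = len(transcript)
    k = config.read_length
    if L < k:
        logger.warning("transcript %s shorter than read length; skipped", transcript.id)
        return []
    n = config.n_reads(L) if n_reads is None else int(n_reads)
    if n == 0:
        return []
    if config.paired:
        # Fragment-based start positions: the read is the 5' end of a
        # fragment whose length is N(fragment_mean, fragment_sd), clipped to
        # fit; only fragment sampling differs from the single-end path.
        frag = rng.normal(config.fragment_mean, config.fragment_sd, size=n)
        frag = np.clip(np.rint(frag), k, L).astype(int)
        starts = (rng.random(n) * (L - frag + 1)).astype(int)
    else:
        starts = rng.integers(0, L - k + 1, size=n)
    seq = np.frombuffer(transcript.sequence.encode("ascii"), dtype=np.uint8)
    reads = seq[starts[:, None] + np.arange(k)[None, :]].copy()
    if config.base_error_rate > 0:
        err = rng.random(reads.shape) < config.base_error_rate
        if err.any():
            # substitute with a uniformly chosen *different* base
            idx = np.searchsorted(_BASES, reads[err])
            shift = rng.integers(1, 4, size=idx.shape)
            reads[err] = _BASES[(idx + shift) % 4]
    return [r.tobytes().decode("ascii") for r in reads]


class SubstringIndex:
    """Exact-substring index over a transcriptome.

    For a fixed read length ``k``, hashes every k-mer of every transcript to
    the set of transcripts containing it. Lookup of a read returns the
    equivalence class (the frozenset of compatible transcripts), or an empty
    set when the read occurs nowhere (e.g. it carries a sequencing error).
    """

    def __init__(self, transcriptome: list[ToyTranscript], k: int):
        ids = [t.id for t in transcriptome]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids in transcriptome")
        self.k = k
        self.transcripts = list(transcriptome)
        table: dict[str, set[str]] = {}
        for t in transcriptome:
            for kmer in _kmers(t.sequence, k):
                table.setdefault(kmer, set()).add(t.id)
        self._table: dict[str, frozenset[str]] = {
            kmer: frozenset(s) for kmer, s in table.items()
        }

    def lookup(self, read: str) -> frozenset[str]:
        if len(read) != self.k:
            raise ValueError(f"read length {len(read)} != index k {self.k}")
        return self._table.get(read, frozenset())


def quasi_map(
    reads: list[str],
    transcriptome: list[ToyTranscript] | SubstringIndex,
) -> EqclassCounts:
    """Assign each read to the set of transcripts containing it exactly.

    Reads matching no transcript are unmapped and excluded from the totals.
    Pass a prebuilt :class:`SubstringIndex` when mapping many read sets
    against the same transcriptome.
    """
    if not reads:
        return EqclassCounts({})
    if isinstance(transcriptome, SubstringIndex):
        index = transcriptome
    else:
        index = SubstringIndex(transcriptome, k=len(reads[0]))
    counter: Counter[frozenset[str]] = Counter()
    for read in reads:
        eqclass = index.lookup(read)
        if eqclass:
            counter[eqclass] += 1
    return EqclassCounts(dict(counter))


def sample_beta_poisson(
    params: BetaPoissonParams,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw per-sample expression values from the beta-Poisson model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.beta(params.alpha, params.beta, size=n_samples)
    return params.lambda2 * rng.poisson(params.lambda1 * p)


def simulate_multisample_counts(
    X: DesignMatrix,
    beta_true: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``y_jn ~ Poisson(sum_t x_jt beta_tn)`` for every pattern and sample.

    ``beta_true`` is ``(T, N)`` (or ``(T,)`` for one sample); the result is
    ``(J, N)`` with rows ordered like ``X.patterns``. Because columns of X
    sum to one, the expected total count of a sample equals its total
    abundance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta_true = np.atleast_2d(np.asarray(beta_true, dtype=float).T).T
    if beta_true.shape[0] != X.n_transcripts:
        raise ValueError(
            f"beta has {beta_true.shape[0]} transcripts, X has {X.n_transcripts}"
        )
    if np.any(beta_true < 0):
        raise ValueError("beta_true must be non-negative")
    mu = X.x @ beta_true
    return rng.poisson(mu).astype(float)


def apply_bias(
    X: DesignMatrix,
    bias_strength: float,
    seed: int | np.random.Generator = 0,
) -> DesignMatrix:
    """Distort X columnwise to emulate non-uniform read distribution.

    Every entry is multiplied by an independent log-normal perturbation with
    log-sd ``bias_strength`` and the columns are renormalized to sum to one.
    ``bias_strength = 0`` returns X unchanged. The zero pattern is preserved,
    so the distortion changes proportions, never which classes a transcript
    can emit reads into.
    """
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    if bias_strength == 0:
        return X.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factors = rng.lognormal(mean=0.0, sigma=bias_strength, size=X.x.shape)
    x = X.x * factors
    x /= x.sum(axis=0, keepdims=True)
    return DesignMatrix(list(X.transcripts), list(X.patterns), x, list(X.merged_groups))


def simulate_null_experiment(
    n_isoforms: int = 2000,
    samples_per_group: int = 40,
    n_batches: int = 2,
    seed: int | np.random.Generator = 0,
):
    """Pure-noise multi-batch count matrices for null differential expression.

    Per-isoform mean expression ``lambda`` is drawn once, log-uniform on
    [20, 2000], and shared by all batches; per-sample library-size factors
    are uniform on [0.7, 1.3]; counts are Poisson. There is no group effect
    anywhere, so any "significant" isoform is a false positive.

    Returns ``(batches, labels)`` where ``batches`` is a list of
    ``(n_isoforms, 2 * samples_per_group)`` count arrays and ``labels`` marks
    the two groups within each batch.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = 10 ** rng.uniform(math.log10(20), math.log10(2000), size=n_isoforms)
    n = 2 * samples_per_group
    batches = []
    for _ in range(n_batches):
        lib = rng.uniform(0.7, 1.3, size=n)
        batches.append(rng.poisson(lam[:, None] * lib[None, :]).astype(float))
    labels = ["control"] * samples_per_group + ["treated"] * samples_per_group
    return batches, labels
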