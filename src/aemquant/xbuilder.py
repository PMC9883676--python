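"""Construction of the starting design matrix from transcript response profiles.

The empirical pipeline, run once per transcriptome:

1. For each transcript, simulate reads with only that transcript expressed
   and map them back, giving its *transcript response profile* (TRP): the
   per-equivalence-class read counts, each class count attributed to every
   member transcript.
2. Filter spurious neighbors: transcripts capturing less than a fraction
   ``H`` (default 2.5%) of the source transcript's reads are false positives
   from sequencing errors and are dropped from the profile.
3. Connect each source to its surviving neighbors; the connected components
   of this graph are the *transcription clusters*, each owning one design
   matrix.
4. Within a cluster, convert each profile's equivalence classes to binary
   occupancy patterns over the cluster's transcripts, unify duplicate
   patterns, and tabulate the source read counts per (pattern, transcript).
5. Normalize every transcript column to sum to one: the starting X.

A final merging step collapses paralogs — transcripts whose columns are so
collinear that the matrix is numerically singular — into single columns,
using the singular-value spectrum to pick the number of k-means clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .matrix import DesignMatrix, ParalogGroup
from .simgen import (
    SimulationConfig,
    SubstringIndex,
    ToyTranscript,
    quasi_map,
    simulate_reads,
)

__all__ = [
    "TRP",
    "NeighborSet",
    "TranscriptionCluster",
    "PatternCounts",
    "build_trp",
    "filter_neighbors",
    "restrict_trp",
    "build_clusters",
    "collapse_patterns",
    "normalize_design",
    "merge_paralogs",
    "build_design",
    "worked_example_trps",
    "DesignMatrix",
    "ParalogGroup",
]

logger = logging.getLogger(__name__)


@dataclass
class TRP:
    """Transcript response profile: eqclass counts when only ``source`` is expressed.

    ``rows`` maps each equivalence class to its read count; the count is
    attributed equally to every member transcript, so a transcript's total is
    the sum of the counts of all classes containing it.
    """

    source: str
    rows: dict[frozenset[str], int]

    @property
    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for eqclass, count in self.rows.items():
            for t in eqclass:
                out[t] = out.get(t, 0) + count
        return out

    @property
    def members(self) -> set[str]:
        return set().union(*self.rows.keys()) if self.rows else set()

    def is_empty(self) -> bool:
        return not self.rows


@dataclass(frozen=True)
class NeighborSet:
    """Transcripts retained in a TRP after the false-positive filter at ``H``."""

    source: str
    neighbors: frozenset[str]
    H: float = 0.025

    def __post_init__(self) -> None:
        if self.source in self.neighbors:
            raise ValueError("source cannot be its own neighbor")


@dataclass(frozen=True)
class TranscriptionCluster:
    """A connected component of the transcript-neighbor graph."""

    transcripts: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = frozenset()


@dataclass
class PatternCounts:
    """Intermediate pattern x transcript count table for one cluster."""

    transcripts: list[str]
    patterns: list[tuple[int, ...]]
    counts: np.ndarray  # (J, T)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)


def build_trp(
    source: ToyTranscript,
    transcriptome: list[ToyTranscript] | SubstringIndex,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TRP:
    """Simulate reads from ``source`` alone, map them, and tabulate the profile."""
    reads = simulate_reads(source, config, rng=rng)
    eqcounts = quasi_map(reads, transcriptome)
    if eqcounts.total_mapped == 0:
        logger.warning("no mapped reads for %s; empty profile", source.id)
    return TRP(source.id, dict(eqcounts.counts))


def filter_neighbors(trp: TRP, H: float = 0.025) -> NeighborSet:
    """Keep neighbors with at least ``H`` x the source transcript's total reads."""
    if not (0 <= H < 1):
        raise ValueError("H must be in [0, 1)")
    totals = trp.totals
    source_total = totals.get(trp.source, 0)
    neighbors = frozenset(
        t
        for t, total in totals.items()
        if t != trp.source and total >= H * source_total
    )
    return NeighborSet(trp.source, neighbors, H)


def restrict_trp(trp: TRP, keep: set[str]) -> TRP:
    """Drop filtered transcripts from the profile's equivalence classes.

    Classes that coincide after the restriction are pooled, so the occupancy
    patterns downstream are computed over the retained transcripts only.
    """
    rows: dict[frozenset[str], int] = {}
    for eqclass, count in trp.rows.items():
        restricted = eqclass & frozenset(keep)
        if restricted:
            rows[restricted] = rows.get(restricted, 0) + count
    return TRP(trp.source, rows)


def build_clusters(neighbor_sets: list[NeighborSet]) -> list[TranscriptionCluster]:
    """Connected components of the source-neighbor graph, one per design matrix.

    Every source becomes a node even when isolated; clusters are returned
    with transcripts in ascending id order, components ordered by their
    smallest member.
    """
    g = nx.Graph()
    for ns in neighbor_sets:
        g.add_node(ns.source)
        for nb in ns.neighbors:
            g.add_edge(ns.source, nb)
    clusters = []
    for component in nx.connected_components(g):
        members = tuple(sorted(component))
        edges = frozenset(
            tuple(sorted(e)) for e in g.subgraph(component).edges()
        )
        clusters.append(TranscriptionCluster(members, edges))
    return sorted(clusters, key=lambda c: c.transcripts[0])


def collapse_patterns(
    cluster: TranscriptionCluster,
    trps: list[TRP],
) -> PatternCounts:
    """Tabulate source read counts per unique occupancy pattern.

    ``trps`` are the (already neighbor-filtered) profiles of the cluster's
    members. Each equivalence class becomes a binary pattern over the
    cluster's transcript order; duplicate patterns are unified. Cell
    ``(pattern, t)`` holds the count of that pattern in transcript ``t``'s own
    profile (0 when absent). Rows are ordered by first occurrence, scanning
    profiles in cluster transcript order.
    """
    order = {t: i for i, t in enumerate(cluster.transcripts)}
    by_source = {trp.source: trp for trp in trps}
    patterns: list[tuple[int, ...]] = []
    index: dict[tuple[int, ...], int] = {}
    cells: dict[tuple[int, int], float] = {}
    for t in cluster.transcripts:
        trp = by_source.get(t)
        if trp is None:
            continue
        col = order[t]
        for eqclass, count in trp.rows.items():
            outside = eqclass - set(cluster.transcripts)
            if outside:
                raise ValueError(
                    f"profile of {t} references transcripts outside the "
                    f"cluster: {sorted(outside)}"
                )
            bits = [0] * len(cluster.transcripts)
            for member in eqclass:
                bits[order[member]] = 1
            pattern = tuple(bits)
            if pattern not in index:
                index[pattern] = len(patterns)
                patterns.append(pattern)
            key = (index[pattern], col)
            cells[key] = cells.get(key, 0.0) + count
    counts = np.zeros((len(patterns), len(cluster.transcripts)))
    for (j, tcol), count in cells.items():
        counts[j, tcol] = count
    return PatternCounts(list(cluster.transcripts), patterns, counts)


def normalize_design(pattern_counts: PatternCounts) -> DesignMatrix:
    """Standardize each transcript column to sum to one.

    Transcripts with no reads in any pattern cannot be placed in the matrix
    and are dropped with a warning (their abundance would be unidentifiable
    anyway).
    """
    counts = pattern_counts.counts
    colsums = counts.sum(axis=0)
    keep = colsums > 0
    if not keep.all():
        dropped = [t for t, k in zip(pattern_counts.transcripts, keep) if not k]
        logger.warning("dropping zero-count transcripts: %s", dropped)
    counts = counts[:, keep]
    transcripts = [t for t, k in zip(pattern_counts.transcripts, keep) if k]
    patterns = [
        tuple(b for b, k in zip(p, keep) if k) for p in pattern_counts.patterns
    ]
    # restriction can orphan or duplicate patterns; pool duplicates, drop empties
    uniq: dict[tuple[int, ...], int] = {}
    rows: list[np.ndarray] = []
    out_patterns: list[tuple[int, ...]] = []
    for pattern, row in zip(patterns, counts):
        if not any(pattern):
            continue
        if pattern in uniq:
            rows[uniq[pattern]] = rows[uniq[pattern]] + row
        else:
            uniq[pattern] = len(rows)
            rows.append(row)
            out_patterns.append(pattern)
    x = np.array(rows)
    x = x / x.sum(axis=0, keepdims=True)
    dm = DesignMatrix(transcripts, out_patterns, x)
    dm.validate()
    return dm


def merge_paralogs(
    X: DesignMatrix,
    sv_threshold: float = 0.02,
    seed: int = 0,
    n_restarts: int = 10,
) -> DesignMatrix:
    """Collapse (near-)collinear columns into merged paralog groups.

    The number of estimable units ``k`` is the number of singular values of X
    above ``sv_threshold`` (exact paralogs contribute zero singular values).
    If ``k`` equals the number of columns the matrix is well conditioned and
    returned unchanged; otherwise columns are k-means-clustered (``k``
    clusters, deterministic seed, ``n_restarts`` restarts) and each cluster
    of two or more transcripts is merged: the merged column is the mean of
    the member columns, renormalized to sum to one, named by joining the
    member ids with ``+``.
    """
    sv = np.linalg.svd(X.x, compute_uv=False)
    k = int(np.sum(sv > sv_threshold))
    if k == 0:
        raise ValueError("design matrix is degenerate: no singular value above threshold")
    T = X.n_transcripts
    if k >= T:
        return X
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X.x.T)
    # group columns by label; order groups by their lowest-id member
    groups: dict[int, list[int]] = {}
    for col, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(col)
    ordered = sorted(groups.values(), key=lambda cols: min(X.transcripts[c] for c in cols))
    transcripts: list[str] = []
    columns: list[np.ndarray] = []
    merged_groups = list(X.merged_groups)
    for cols in ordered:
        member_ids = sorted(X.transcripts[c] for c in cols)
        if len(cols) == 1:
            transcripts.append(member_ids[0])
            columns.append(X.x[:, cols[0]])
        else:
            merged = X.x[:, cols].mean(axis=1)
            merged = merged / merged.sum()
            transcripts.append("+".join(member_ids))
            columns.append(merged)
            members = frozenset(m for mid in member_ids for m in mid.split("+"))
            merged_groups.append(
                ParalogGroup(members, tuple(float(s) for s in sv), sv_threshold)
            )
    x = np.column_stack(columns)
    # recompute patterns: a merged column is occupied where any member was
    raw_patterns = [
        tuple(int(any(p[c] for c in cols)) for cols in ordered) for p in X.patterns
    ]
    uniq: dict[tuple[int, ...], int] = {}
    rows: list[np.ndarray] = []
    patterns: list[tuple[int, ...]] = []
    for pattern, row in zip(raw_patterns, x):
        if pattern in uniq:
            rows[uniq[pattern]] = rows[uniq[pattern]] + row
        else:
            uniq[pattern] = len(rows)
            rows.append(row)
            patterns.append(pattern)
    dm = DesignMatrix(transcripts, patterns, np.array(rows), merged_groups)
    dm.validate()
    return dm


def build_design(
    transcriptome: list[ToyTranscript],
    config: SimulationConfig | None = None,
    H: float = 0.025,
    sv_threshold: float = 0.02,
    merge: bool = True,
    seed: int = 0,
) -> list[DesignMatrix]:
    """Run the full profile -> filter -> cluster -> tabulate -> normalize chain.

    Returns one design matrix per transcription cluster (merged if ``merge``).
    All simulation randomness derives from ``seed`` via a splittable stream.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    index = SubstringIndex(transcriptome, k=config.read_length)
    streams = np.random.SeedSequence(seed).spawn(len(transcriptome))
    trps = [
        build_trp(t, index, config, rng=np.random.default_rng(s))
        for t, s in zip(transcriptome, streams)
    ]
    neighbor_sets = [filter_neighbors(trp, H) for trp in trps]
    filtered = [
        restrict_trp(trp, {ns.source} | set(ns.neighbors))
        for trp, ns in zip(trps, neighbor_sets)
    ]
    by_source = {trp.source: trp for trp in filtered}
    matrices = []
    for cluster in build_clusters(neighbor_sets):
        cluster_trps = [
            by_source[t] for t in cluster.transcripts if t in by_source
        ]
        table = collapse_patterns(cluster, cluster_trps)
        dm = normalize_design(table)
        if merge:
            dm = merge_paralogs(dm, sv_threshold=sv_threshold, seed=seed)
        matrices.append(dm)
    return matrices


def worked_example_trps() -> list[TRP]:
    """The five-transcript shared-exon worked example, frozen as profiles.

    tx1's profile has three equivalence classes (20 / 850 / 130 reads); tx5
    captures only 2% of tx1's reads and is removed by the default 2.5%
    filter, leaving the four-transcript cluster tx1..tx4 whose normalized
    matrix has columns tx1 = (0.02, 0.85, 0.13), tx2 = (0.12, 0.88, 0),
    tx3 = (0, 1, 0), tx4 = (0.15, 0, 0.85).
    """
    f = frozenset
    return [
        TRP(
            "tx1",
            {
                f({"tx1", "tx2", "tx4", "tx5"}): 20,
                f({"tx1", "tx2", "tx3"}): 850,
                f({"tx1", "tx4"}): 130,
            },
        ),
        TRP(
            "tx2",
            {
                f({"tx1", "tx2", "tx4"}): 120,
                f({"tx1", "tx2", "tx3"}): 880,
            },
        ),
        TRP("tx3", {f({"tx1", "tx2", "tx3"}): 850}),
        TRP(
            "tx4",
            {
                f({"tx1", "tx2", "tx4"}): 150,
                f({"tx1", "tx4"}): 850,
            },
        ),
    ]
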