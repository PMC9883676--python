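import numpy as np
import pytest

import aemquant as aq
from aemquant.aem import CountMatrix


@pytest.fixture(scope="session")
def worked_trps():
    """The five-transcript shared-exon fixture (profiles frozen in the package)."""
    return aq.worked_example_trps()


def run_x_chain(trps, H=0.025):
    """Full profile -> filter -> cluster -> tabulate -> normalize chain."""
    neighbor_sets = [aq.filter_neighbors(t, H) for t in trps]
    filtered = [
        aq.restrict_trp(t, {ns.source} | set(ns.neighbors))
        for t, ns in zip(trps, neighbor_sets)
    ]
    clusters = aq.build_clusters(neighbor_sets)
    by_source = {t.source: t for t in filtered}
    matrices = []
    for cluster in clusters:
        table = aq.collapse_patterns(
            cluster, [by_source[t] for t in cluster.transcripts if t in by_source]
        )
        matrices.append(aq.normalize_design(table))
    return matrices


@pytest.fixture(scope="session")
def worked_X(worked_trps):
    (X,) = run_x_chain(worked_trps)
    return X


@pytest.fixture(scope="session")
def cluster3():
    """A one-gene, three-isoform toy cluster built through the empirical chain.

    Identifiable (more patterns than transcripts, all singular values large),
    so abundances can be recovered exactly up to noise.
    """
    tome = aq.make_toy_transcriptome(1, 3, 300, 200, seed=7)
    X = aq.build_design(tome, aq.SimulationConfig(seed=7), merge=False)[0]
    return tome, X


def poisson_counts(X, beta_true, seed):
    y = aq.simulate_multisample_counts(X, beta_true, seed)
    return CountMatrix(X.patterns, y)
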