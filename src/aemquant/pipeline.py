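"""End-to-end orchestration: simulate -> build X -> quantify -> evaluate.

Each stage is a plain function over the library types; the CLI wraps them
one-to-one. All outputs are text files written under one directory together
with the resolved configuration, and every run is deterministic given its
seed (a single seed sequence is split into independent streams per stage).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import aem, de, evalstats, io, simgen, xbuilder
from .matrix import DesignMatrix

__all__ = [
    "simulate_experiment",
    "build_x",
    "quantify",
    "evaluate_estimates",
    "run_pipeline",
    "DEFAULT_EXPRESSION_MODEL",
]

logger = logging.getLogger(__name__)

# Illustrative beta-Poisson expression model used when no calibrated
# parameters are supplied: symmetric Beta(2, 2) burst fraction, rate scale
# 2000, giving a mean of ~1000 reads per transcript per sample.
DEFAULT_EXPRESSION_MODEL = simgen.BetaPoissonParams(alpha=2.0, beta=2.0, lambda1=2000.0)


def _stage(name: str):
    logger.info("[%s] start", name)
    t0 = time.perf_counter()

    def done():
        logger.info("[%s] done in %.2fs", name, time.perf_counter() - t0)

    return done


def simulate_experiment(
    config: io.RunConfig,
    outdir: str | Path,
    expression: simgen.BetaPoissonParams = DEFAULT_EXPRESSION_MODEL,
) -> dict[str, Path]:
    """Generate a toy transcriptome plus per-sample eqclass count files.

    Per sample and transcript, a read count is drawn from the beta-Poisson
    expression model; that many uniformly positioned reads are simulated and
    mapped, and the pooled equivalence-class counts are written in the
    salmon dialect. The realized read counts are the ground truth table.
    """
    done = _stage("simulate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "run_config.json")
    root = np.random.SeedSequence(config.seed)
    tx_seed, read_seed = root.spawn(2)
    transcriptome = simgen.make_toy_transcriptome(
        config.n_genes,
        config.isoforms_per_gene,
        seed=int(tx_seed.generate_state(1)[0] % 2**31),
        read_length=config.read_length,
    )
    fasta = outdir / "transcriptome.fasta"
    io.write_fasta(fasta, transcriptome)
    index = simgen.SubstringIndex(transcriptome, k=config.read_length)
    sim_config = simgen.SimulationConfig(
        base_error_rate=config.base_error_rate, read_length=config.read_length
    )
    rng = np.random.default_rng(read_seed)
    order = [t.id for t in transcriptome]
    truth = np.zeros((len(order), config.n_samples))
    sample_dir = outdir / "samples"
    sample_dir.mkdir(exist_ok=True)
    paths = {}
    for n in range(config.n_samples):
        pooled: dict[frozenset[str], int] = {}
        for i, t in enumerate(transcriptome):
            count = int(simgen.sample_beta_poisson(expression, 1, rng)[0])
            truth[i, n] = count
            reads = simgen.simulate_reads(t, sim_config, rng=rng, n_reads=count)
            for eqclass, c in simgen.quasi_map(reads, index).counts.items():
                pooled[eqclass] = pooled.get(eqclass, 0) + c
        path = sample_dir / f"sample{n + 1:03d}_eq_classes.txt"
        io.write_eqclass_file(path, simgen.EqclassCounts(pooled), "salmon", order)
        paths[f"sample{n + 1}"] = path
    truth_df = pd.DataFrame(
        truth, index=order, columns=[f"s{n + 1}" for n in range(config.n_samples)]
    )
    truth_df.index.name = "transcript"
    truth_path = outdir / "truth_counts.tsv"
    truth_df.to_csv(truth_path, sep="\t")
    done()
    return {"fasta": fasta, "samples": sample_dir, "truth": truth_path}


def build_x(
    fasta: str | Path,
    config: io.RunConfig,
    outdir: str | Path,
) -> Path:
    """Build the (merged) starting design matrix from a transcriptome FASTA."""
    done = _stage("buildx")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "run_config.json")
    transcriptome = io.read_fasta(fasta)
    sim_config = simgen.SimulationConfig(
        base_error_rate=config.base_error_rate, read_length=config.read_length
    )
    matrices = xbuilder.build_design(
        transcriptome,
        sim_config,
        H=config.H,
        sv_threshold=config.sv_threshold,
        seed=config.seed,
    )
    combined = DesignMatrix.block_diag(matrices)
    path = outdir / "X.tsv"
    io.write_design_tsv(path, combined)
    done()
    return path


def quantify(
    x_path: str | Path,
    counts_dir: str | Path,
    config: io.RunConfig,
    outdir: str | Path,
    dialect: str = "salmon",
) -> dict[str, Path]:
    """Load X and per-sample eqclass files, run the alternating EM, write results."""
    done = _stage("quantify")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "run_config.json")
    X0 = io.read_design_tsv(x_path)
    files = sorted(Path(counts_dir).glob("*eq_classes.txt")) or sorted(
        Path(counts_dir).glob("*.tsv")
    )
    if not files:
        raise FileNotFoundError(f"no eqclass files under {counts_dir}")
    samples = [io.read_eqclass_file(f, dialect) for f in files]
    names = [f.stem.replace("_eq_classes", "") for f in files]
    Y = aem.build_count_matrix(X0, samples, names)
    crit = aem.ConvergenceCriterion(rel_tol=config.rel_tol, max_iter=config.max_iter)
    X_hat, beta, diag = aem.aem_fit(
        Y, X0, crit, update_X=config.update_X, literal_eq7=config.literal_eq7
    )
    counts_path = outdir / "isoform_counts.tsv"
    io.write_counts_tsv(counts_path, beta)
    x_out = outdir / "X_updated.tsv"
    io.write_design_tsv(x_out, X_hat)
    diag_path = outdir / "diagnostics.json"
    io.write_diagnostics(
        diag_path,
        diag,
        extra={
            "seed": config.seed,
            "unmatched_classes": int(getattr(Y, "unmatched_classes", 0)),
        },
    )
    done()
    return {"counts": counts_path, "x_updated": x_out, "diagnostics": diag_path}


def evaluate_estimates(
    truth_path: str | Path,
    counts_path: str | Path,
    x_path: str | Path,
    out_path: str | Path,
) -> pd.DataFrame:
    """Median APE per isoform plus a per-category recovery summary."""
    done = _stage("evaluate")
    truth = pd.read_csv(truth_path, sep="\t", index_col=0)
    est = pd.read_csv(counts_path, sep="\t", index_col=0)
    X_hat = io.read_design_tsv(x_path)
    aligned_truth = evalstats.aggregate_truth(
        truth.to_numpy(), list(truth.index), X_hat
    )
    est = est.loc[X_hat.transcripts]
    per_isoform = evalstats.median_ape(est.to_numpy(), aligned_truth)
    report = evalstats.recovery_report(est.to_numpy(), aligned_truth, X_hat)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    detail = pd.DataFrame(
        {"transcript": X_hat.transcripts, "median_ape": per_isoform}
    )
    detail.to_csv(out_path.with_name(out_path.stem + "_per_isoform.tsv"), sep="\t", index=False)
    report.to_csv(out_path, sep="\t", index=False)
    done()
    return report


def run_pipeline(config: io.RunConfig, outdir: str | Path) -> int:
    """Simulate, build X, quantify and evaluate under one seed; returns 0 on success."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "run_config.json")
    sim = simulate_experiment(config, outdir / "sim")
    x_path = build_x(sim["fasta"], config, outdir / "xbuild")
    quant = quantify(x_path, sim["samples"], config, outdir / "quant")
    evaluate_estimates(
        sim["truth"], quant["counts"], quant["x_updated"], outdir / "evaluation.tsv"
    )
    return 0
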