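"""Full pipeline on a simulated toy experiment.

Simulates reads for a small multi-isoform transcriptome, builds the design
matrix from single-transcript profiles, quantifies all samples with the
alternating EM, and evaluates recovery against the known read counts.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aemquant import io, pipeline

config = io.RunConfig(seed=5, n_genes=3, isoforms_per_gene=2, n_samples=10)

with tempfile.TemporaryDirectory() as d:
    out = Path(d) / "run"
    status = pipeline.run_pipeline(config, out)
    print("exit status:", status)
    report = pd.read_csv(out / "evaluation.tsv", sep="\t")
    counts = pd.read_csv(out / "quant" / "isoform_counts.tsv", sep="\t", index_col=0)

print("\nEstimated read counts (first samples):")
print(counts.iloc[:, :4].round(1))
print("\nPer-category recovery report:")
print(report.to_string(index=False))
print(
    "\nmedian_ape is the median of |estimate - truth| / (truth + 1) per isoform\n"
    "across samples; pearson/spearman correlate estimates with the generated\n"
    "counts over all (isoform, sample) cells."
)
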