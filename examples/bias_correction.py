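"""Demonstrate bias correction by updating the design matrix.

Counts for 50 samples are generated from a *distorted* design matrix (an
unknown non-uniformity), but the fit starts from the undistorted one. The
joint alternating-EM fit (X updated) recovers the distortion; the fixed-X
fit cannot.
"""

import numpy as np

import aemquant as aq
from aemquant.aem import CountMatrix, aem_fit

# a one-gene, three-isoform toy cluster built through the empirical chain
tome = aq.make_toy_transcriptome(1, 3, 300, 200, seed=7)
X0 = aq.build_design(tome, aq.SimulationConfig(seed=7), merge=False)[0]

rng = np.random.default_rng(100)
X_star = aq.apply_bias(X0, 0.3, rng)  # the unknown truth
beta_true = rng.uniform(500, 5000, (3, 50))
Y = CountMatrix(X0.patterns, aq.simulate_multisample_counts(X_star, beta_true, rng))

X_hat, beta_on, diag = aem_fit(Y, X0, update_X=True)
_, beta_off, _ = aem_fit(Y, X0, update_X=False)

print(f"Frobenius error of the start X vs truth: {np.linalg.norm(X0.x - X_star.x):.4f}")
print(f"Frobenius error of the updated X:        {np.linalg.norm(X_hat.x - X_star.x):.4f}")
print(f"Median APE with X fixed:   {np.median(aq.median_ape(beta_off.counts, beta_true)):.4f}")
print(f"Median APE with X updated: {np.median(aq.median_ape(beta_on.counts, beta_true)):.4f}")
print(f"(converged in {diag.iterations} iterations)")
print(
    "\nThe updated design matrix moves close to the distorted generating matrix\n"
    "and the abundance error drops: pooling allocations across samples lets the\n"
    "shared X absorb the unknown bias."
)
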