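"""Self-contained tests of a gene set's covariance structure.

Builds a 100-gene data set in which the first 10 genes form a correlated
block (pairwise covariance 0.25), then asks whether that set's covariance
is compatible with the identity using three statistics on the eigenvalues
of the set-restricted scaled covariance matrix: the modified
likelihood-ratio test (MLRT), the Tracy-Widom test on the largest
eigenvalue (TWT), and the Marčenko-Pastur distribution test on the bulk
spectrum (MPDT).
"""

import numpy as np

from rmtgsa import (
    CovarianceSpec,
    build_covariance,
    mlrt_statistic,
    mpdt_statistic,
    sample_mvn,
    twt_statistic,
)

cov = build_covariance(CovarianceSpec(structure="single_block", p=100, g=10, rho=0.25))
X = sample_mvn(cov, n=100, seed=42)

enriched = np.arange(10)  # the correlated block
background = np.arange(50, 60)  # ten uncorrelated genes

for label, idx in [("correlated block", enriched), ("background genes", background)]:
    print(f"\n{label}:")
    for fn in (mlrt_statistic, twt_statistic, mpdt_statistic):
        res = fn(X, idx)
        print(f"  {res.method:4s} statistic = {res.statistic:8.4f}   p = {res.pvalue:.4g}")

print(
    "\nSmall p-values flag departure from an identity covariance: the block's"
    "\ncorrelation inflates the top eigenvalue (TWT), the total trace/log-det"
    "\ndiscrepancy (MLRT) and the spectral distance to the Marčenko-Pastur law"
    "\n(MPDT), while the background set looks like white noise.  The MPDT"
    "\np-value is anti-conservative (dependent eigenvalues) and is best used"
    "\nfor ranking or inside the competitive test."
)
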