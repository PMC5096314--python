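"""Competitive gene set testing by gene resampling.

The competitive null asks whether a set's eigenvalue structure stands out
relative to random same-size gene subsets of the same data matrix.  Here
ten disjoint sets are tested; only the first carries real correlation, so
it should be the only one with a small competitive p-value.
"""

import numpy as np

from rmtgsa import (
    CovarianceSpec,
    GeneSetCollection,
    build_covariance,
    competitive_test_collection,
    sample_mvn,
    sgse_test,
)

p, g = 100, 10
cov = build_covariance(CovarianceSpec(structure="single_block", p=p, g=g, rho=0.25))
X = sample_mvn(cov, n=100, seed=7)
collection = GeneSetCollection.disjoint_blocks(p, g)

table = competitive_test_collection(X, collection, method="TWT", B=500, seed=1)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

print(
    "\nEach p-value is the fraction of 500 random 10-gene subsets whose"
    "\nTracy-Widom statistic strictly exceeds the set's own (p = 0 means no"
    "\nrandom subset beat it).  Only set1, the truly correlated block, is"
    "\ncompetitively enriched."
)

res = sgse_test(X, np.arange(g))
print(
    f"\nSGSE benchmark on set1: p = {res.pvalue:.4g} "
    "(principal-component association combined by the weighted Z-method)"
)
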