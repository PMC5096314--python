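"""Registries of the simulation designs for type-I error and power studies.

Each design fixes a population covariance structure over p = 100 genes with
a designated (or, for the null designs, purely nominal) set size g = 10,
a sample count n, the variance sigma2 and the pairwise covariance rho, a
data family (multivariate normal or correlated Binomial(2, 0.25) mimicking
additively coded SNP genotypes), a replicate count of 1000, B = 500 gene
resampling permutations and a rejection level alpha = 0.05.

Null designs place no set-specific signal anywhere (identity, scaled
identity, or compound symmetry shared by *all* gene pairs), so every one of
the p/g disjoint sets is null.  Power designs concentrate signal in the
first 10 genes (single block, multi-block, anti-correlated multi-block)
except the repeated-block design, where all 10 disjoint sets carry the
block and all are non-null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .covariance import CovarianceSpec, build_covariance

__all__ = [
    "SimulationDesign",
    "TYPE1_DESIGNS",
    "POWER_DESIGNS",
    "population_covariance",
    "BINOMIAL_TRIALS",
    "BINOMIAL_PROB",
]

BINOMIAL_TRIALS = 2
BINOMIAL_PROB = 0.25


@dataclass(frozen=True)
class SimulationDesign:
    """One row of a simulation study table."""

    design_id: str
    cov_spec: CovarianceSpec
    n: int
    data_family: str = "mvn"  # "mvn" or "binomial"
    n_reps: int = 1000
    B: int = 500
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data_family not in ("mvn", "binomial"):
            raise ValueError("data_family must be 'mvn' or 'binomial'")
        if self.n_reps < 1 or self.B < 1:
            raise ValueError("n_reps and B must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    def scaled(self, n_reps: int, B: int) -> "SimulationDesign":
        """Copy of the design with a reduced replicate/permutation budget."""
        return replace(self, n_reps=n_reps, B=B)


def _spec(structure: str, sigma2: float = 1.0, rho: float = 0.0, **kw) -> CovarianceSpec:
    return CovarianceSpec(
        structure=structure, p=100, g=10, sigma2=sigma2, rho=rho, **kw
    )


TYPE1_DESIGNS: dict[str, SimulationDesign] = {
    d.design_id: d
    for d in [
        SimulationDesign("MVN-1", _spec("identity"), n=100),
        SimulationDesign("MVN-2", _spec("scaled_identity", sigma2=2.0), n=100),
        SimulationDesign("MVN-3", _spec("compound_symmetry", rho=0.1), n=20),
        SimulationDesign("MVN-4", _spec("compound_symmetry", rho=0.1), n=50),
        SimulationDesign("MVN-5", _spec("compound_symmetry", rho=0.1), n=100),
        SimulationDesign(
            "MVN-6", _spec("compound_symmetry", sigma2=2.0, rho=0.1), n=100
        ),
        SimulationDesign("MVN-7", _spec("compound_symmetry", rho=0.2), n=100),
        SimulationDesign(
            "Binomial-1",
            _spec("compound_symmetry", sigma2=0.375, rho=0.1),
            n=100,
            data_family="binomial",
        ),
    ]
}

POWER_DESIGNS: dict[str, SimulationDesign] = {
    d.design_id: d
    for d in [
        SimulationDesign("MVN-1", _spec("single_block", rho=0.1), n=100),
        SimulationDesign("MVN-2", _spec("single_block", rho=0.1), n=50),
        SimulationDesign("MVN-3", _spec("single_block", rho=0.1), n=20),
        SimulationDesign("MVN-4", _spec("single_block", rho=0.15), n=100),
        SimulationDesign("MVN-5", _spec("single_block", sigma2=1.10), n=100),
        SimulationDesign("MVN-6", _spec("single_block", sigma2=1.15), n=100),
        SimulationDesign(
            "MVN-7", _spec("multi_block", rho=0.2, block_sizes=(2,) * 5), n=100
        ),
        SimulationDesign(
            "MVN-8",
            _spec(
                "anticorrelated_multi_block",
                rho=0.1,
                rho_between=-0.1,
                block_sizes=(5, 5),
            ),
            n=100,
        ),
        SimulationDesign("MVN-9", _spec("repeated_block", rho=0.1), n=100),
        SimulationDesign(
            "Binomial-1",
            _spec("single_block", sigma2=0.375, rho=0.1),
            n=100,
            data_family="binomial",
        ),
    ]
}


def population_covariance(design: SimulationDesign) -> np.ndarray:
    """Population covariance matrix for a design.

    For binomial designs the returned matrix is the *latent* covariance of
    the Gaussian quantile-transform generator: the design's block structure
    with unit variances.  The generated genotypes have exact
    Binomial(2, 0.25) marginals (variance 0.375, the sigma2 printed in the
    design tables) and dependence inherited from the latent normal.
    """
    spec = design.cov_spec
    if design.data_family == "binomial":
        spec = replace(spec, sigma2=1.0)
    return build_covariance(spec)
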