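"""Samplers for multivariate normal and correlated-binomial data matrices.

The correlated binomial sampler emulates SNP genotypes under additive
coding: each variable is marginally Binomial(trials, prob) and pairwise
covariances are induced through a Gaussian copula.  Two independent latent
multivariate-normal replicates are drawn, each dichotomized at the
upper-``prob`` quantile, and the two Bernoulli indicators summed.  The
latent correlation needed to hit a target binomial covariance is obtained
by root-finding on the analytic orthant probability of the bivariate
normal, so the calibration is deterministic and exact to quadrature
accuracy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .containers import DataMatrix

__all__ = [
    "sample_mvn",
    "sample_mv_binomial",
    "sample_binomial_from_latent",
    "latent_correlation",
    "binomial_covariance_bounds",
]


def _as_rng(seed: "int | np.random.Generator | None") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _psd_factor(cov: np.ndarray, what: str) -> np.ndarray:
    """Square-root factor L with L @ L.T = cov, tolerant of semi-definiteness."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what} must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError(f"{what} must be symmetric")
    w, v = np.linalg.eigh(cov)
    if w[0] < -1e-8 * max(1.0, w[-1]):
        raise ValueError(
            f"eigen factorization of {what} failed: smallest eigenvalue "
            f"{w[0]:.6g} is negative"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def sample_mvn(
    cov: np.ndarray,
    n: int,
    seed: "int | np.random.Generator | None" = None,
    gene_ids: list[str] | None = None,
) -> DataMatrix:
    """Draw ``n`` i.i.d. samples from a zero-mean MVN with covariance *cov*.

    The mean vector is fixed at zero: every downstream statistic operates on
    column-centered data, so a nonzero mean would be invisible anyway.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = _as_rng(seed)
    L = _psd_factor(cov, "covariance")
    z = rng.standard_normal((n, L.shape[0]))
    return DataMatrix(values=z @ L.T, gene_ids=gene_ids or [])


@lru_cache(maxsize=256)
def _induced_binomial_cov(r: float, trials: int, prob: float) -> float:
    """Binomial covariance induced by latent bivariate-normal correlation r."""
    t = stats.norm.isf(prob)  # upper-tail threshold
    orthant = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]], allow_singular=True
    ).cdf([-t, -t])
    return trials * (orthant - prob**2)


def binomial_covariance_bounds(trials: int, prob: float) -> tuple[float, float]:
    """Attainable (min, max) pairwise covariance for the copula construction."""
    lo = _induced_binomial_cov(-0.999999, trials, prob)
    hi = _induced_binomial_cov(0.999999, trials, prob)
    return lo, hi


@lru_cache(maxsize=256)
def latent_correlation(target_cov: float, trials: int = 2, prob: float = 0.25) -> float:
    """Latent normal correlation producing *target_cov* between two binomials."""
    if target_cov == 0.0:
        return 0.0
    lo, hi = binomial_covariance_bounds(trials, prob)
    if not lo <= target_cov <= hi:
        raise ValueError(
            f"target covariance {target_cov} outside the attainable range "
            f"[{lo:.4f}, {hi:.4f}] for Binomial({trials}, {prob}) margins"
        )
    return float(
        optimize.brentq(
            lambda r: _induced_binomial_cov(r, trials, prob) - target_cov,
            -0.999999,
            0.999999,
            xtol=1e-12,
        )
    )


def sample_binomial_from_latent(
    latent_cov: np.ndarray,
    n: int,
    trials: int = 2,
    prob: float = 0.25,
    seed: "int | np.random.Generator | None" = None,
    gene_ids: list[str] | None = None,
) -> DataMatrix:
    """Correlated binomial data via the quantile transform of one latent MVN.

    A single ``n x p`` draw from a zero-mean multivariate normal with
    correlation matrix *latent_cov* (unit diagonal) is mapped through the
    Binomial(trials, prob) quantile function, giving exact binomial
    marginals with dependence inherited from the latent normal.  This is
    the generator behind the SNP-like simulation designs: the design's
    covariance structure is specified on the latent, unit-variance scale
    and the resulting genotype covariances are smaller (for trials=2,
    prob=0.25 a latent covariance of 0.1 induces ~0.026).
    """
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    latent_cov = np.asarray(latent_cov, dtype=float)
    if not np.allclose(np.diag(latent_cov), 1.0, atol=1e-10):
        raise ValueError("latent covariance must have a unit diagonal")
    z = sample_mvn(latent_cov, n, seed=seed).values
    # thresholds of the quantile map: x = #{k <= trials : Phi(z) > F(k)}
    cdf_vals = stats.binom.cdf(np.arange(trials), trials, prob)
    cuts = stats.norm.ppf(cdf_vals)
    x = (z[..., None] > cuts).sum(axis=-1).astype(float)
    return DataMatrix(values=x, gene_ids=gene_ids or [])


def sample_mv_binomial(
    cov_target: np.ndarray,
    n: int,
    trials: int = 2,
    prob: float = 0.25,
    seed: "int | np.random.Generator | None" = None,
    gene_ids: list[str] | None = None,
) -> DataMatrix:
    """Draw correlated Binomial(trials, prob) vectors matching *cov_target*.

    ``cov_target`` must have the exact marginal variance
    ``trials * prob * (1 - prob)`` on its diagonal; off-diagonal entries are
    matched through the calibrated Gaussian copula.
    """
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    cov_target = np.asarray(cov_target, dtype=float)
    p = cov_target.shape[0]
    marginal_var = trials * prob * (1 - prob)
    if not np.allclose(np.diag(cov_target), marginal_var, atol=1e-8):
        raise ValueError(
            f"cov_target diagonal must equal trials*prob*(1-prob) = {marginal_var}"
        )

    # Map each distinct off-diagonal covariance to its latent correlation.
    latent = np.eye(p)
    iu = np.triu_indices(p, k=1)
    offdiag = cov_target[iu]
    for val in np.unique(np.round(offdiag, 12)):
        r = latent_correlation(float(val), trials, prob)
        mask = np.isclose(offdiag, val)
        latent[iu[0][mask], iu[1][mask]] = r
        latent[iu[1][mask], iu[0][mask]] = r

    L = _psd_factor(latent, "latent correlation matrix")
    t = stats.norm.isf(prob)
    rng = _as_rng(seed)
    x = np.zeros((n, p), dtype=float)
    for _ in range(trials):
        z = rng.standard_normal((n, p)) @ L.T
        x += z > t
    return DataMatrix(values=x, gene_ids=gene_ids or [])
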