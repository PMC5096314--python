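"""Self-contained gene set statistics on the partitioned sample covariance.

All three statistics are functions of the eigenvalues of ``C^T C``
restricted to the set's columns, where ``C`` is the column-mean-centered
data matrix; with ``S = (1/n) C^T C`` this restriction is the Wishart-scaled
partitioned covariance ``n S_gg``.  Under the self-contained null (identity
population covariance for the set), ``n S_gg`` is white Wishart with
``n - 1`` degrees of freedom.

* MLRT — the modified likelihood-ratio statistic
  ``n (trace(S_gg) - log|S_gg| - g)``, asymptotically chi-square with
  ``g (g + 1) / 2`` degrees of freedom.
* TWT — the largest eigenvalue of ``n S_gg`` centered and scaled by the
  Tracy-Widom constants; null distribution F1.
* MPDT — the one-sample Kolmogorov-Smirnov distance between the empirical
  eigenvalue distribution (on the ``n - 1`` scale) and the Marčenko-Pastur
  law at ``gamma = g / (n - 1)``.  The nominal KS p-value ignores the
  dependence between eigenvalues and is anti-conservative; the statistic is
  primarily a ranking device and is the input to the competitive test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import DataMatrix
from .rmt import MarchenkoPastur, marchenko_pastur, tracy_widom_goe, tw_scaling

__all__ = [
    "SelfContainedResult",
    "gram_matrix",
    "eigenspectrum",
    "mlrt_statistic",
    "twt_statistic",
    "mpdt_statistic",
    "ks_distance",
    "METHODS",
]

METHODS = ("MLRT", "TWT", "MPDT")

#: symmetric-eigensolver noise floor: eigenvalues in [EIG_CLIP, 0) are
#: clipped to zero, anything more negative is an error
EIG_CLIP = -1e-8


@dataclass(frozen=True)
class SelfContainedResult:
    """Outcome of a self-contained test on one gene set."""

    method: str
    statistic: float
    pvalue: float | None  # None where no calibrated p-value is claimed
    g: int
    n: int
    #: the self-contained MPDT p-value is anti-conservative (dependent
    #: eigenvalues); True marks p-values that should only be used for ranking
    anticonservative: bool = False


def _resolve(X: "DataMatrix | np.ndarray") -> np.ndarray:
    if isinstance(X, DataMatrix):
        return X.values
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a 2-D samples x genes array")
    return arr


def gram_matrix(X: "DataMatrix | np.ndarray") -> np.ndarray:
    """``C^T C`` for column-centered ``C``; equals ``n S`` of the full matrix."""
    arr = _resolve(X)
    c = arr - arr.mean(axis=0, keepdims=True)
    return c.T @ c


def _set_gram(X, set_idx) -> tuple[np.ndarray, int]:
    arr = _resolve(X)
    idx = np.asarray(set_idx, dtype=int)
    if idx.ndim != 1 or idx.size < 1:
        raise ValueError("set_idx must be a non-empty 1-D index set")
    if np.unique(idx).size != idx.size:
        raise ValueError("set_idx contains duplicate gene indices")
    if idx.min() < 0 or idx.max() >= arr.shape[1]:
        raise ValueError("set_idx references genes outside the data matrix")
    cols = arr[:, idx]
    c = cols - cols.mean(axis=0, keepdims=True)
    sumsq = np.einsum("ij,ij->j", c, c)
    if np.any(sumsq == 0.0):
        dead = idx[np.flatnonzero(sumsq == 0.0)]
        raise ValueError(
            f"zero-variance (constant) gene columns in set: indices {dead.tolist()}"
        )
    return c.T @ c, arr.shape[0]


def clip_spectrum(values: np.ndarray) -> np.ndarray:
    """Clip eigensolver noise in [-1e-8, 0) to zero; reject worse."""
    values = np.asarray(values, dtype=float)
    if np.any(values < EIG_CLIP):
        raise ValueError(
            f"eigenvalue {values.min():.6g} below the numerical noise floor "
            f"{EIG_CLIP}; matrix is not positive semi-definite"
        )
    return np.clip(values, 0.0, None)


def eigenspectrum(X: "DataMatrix | np.ndarray", set_idx) -> np.ndarray:
    """Descending eigenvalues of ``n S_gg`` (the set-restricted ``C^T C``)."""
    gram, _ = _set_gram(X, set_idx)
    return clip_spectrum(np.linalg.eigvalsh(gram))[::-1]


# ---------------------------------------------------------------------------
# vectorized kernels on stacked ascending eigenvalue arrays of n S_gg
# (shared by the single-set entry points and the permutation engine)

def _mlrt_from_gram_eigs(eigs: np.ndarray, n: int) -> np.ndarray:
    g = eigs.shape[-1]
    ev = eigs / n  # eigenvalues of S_gg
    with np.errstate(divide="ignore", invalid="ignore"):
        logdet = np.sum(np.log(ev), axis=-1)
    stat = n * (np.sum(ev, axis=-1) - logdet - g)
    return np.where(np.isfinite(logdet), stat, np.inf)


def _twt_from_gram_eigs(eigs: np.ndarray, n: int) -> np.ndarray:
    g = eigs.shape[-1]
    sc = tw_scaling(g, n)
    return (eigs[..., -1] - sc.mu) / sc.sigma


def ks_distance(sorted_values: np.ndarray, cdf) -> np.ndarray:
    """Exact sup distance between the ECDF of sorted values and a CDF.

    Evaluated at the 2g candidate supremum points (both sides of every jump
    of the step function), vectorized over leading axes.
    """
    vals = np.asarray(sorted_values, dtype=float)
    g = vals.shape[-1]
    gx = cdf(vals)
    hi = np.arange(1, g + 1) / g  # ECDF just at/after each jump
    lo = np.arange(0, g) / g  # ECDF just before each jump
    d = np.maximum(np.abs(hi - gx), np.abs(lo - gx))
    return d.max(axis=-1)


def _mpdt_from_gram_eigs(
    eigs: np.ndarray, n: int, mp: MarchenkoPastur | None = None
) -> np.ndarray:
    g = eigs.shape[-1]
    if g > n - 1:
        raise ValueError(
            f"MPDT requires g <= n - 1 (rank-g assumption); got g={g}, n={n}"
        )
    if mp is None:
        mp = marchenko_pastur(g / (n - 1))
    return ks_distance(eigs / (n - 1), mp.cdf)


# ---------------------------------------------------------------------------
# public single-set statistics

def mlrt_statistic(X: "DataMatrix | np.ndarray", set_idx) -> SelfContainedResult:
    """Modified likelihood-ratio test of identity set covariance."""
    gram, n = _set_gram(X, set_idx)
    g = gram.shape[0]
    eigs = clip_spectrum(np.linalg.eigvalsh(gram))
    if np.any(eigs == 0.0):
        raise ValueError(
            f"S_gg is singular (zero eigenvalue; g={g}, n={n}); "
            "the log-determinant is undefined"
        )
    stat = float(_mlrt_from_gram_eigs(eigs, n))
    df = g * (g + 1) // 2
    return SelfContainedResult(
        method="MLRT", statistic=stat, pvalue=float(sps.chi2.sf(stat, df)), g=g, n=n
    )


def twt_statistic(X: "DataMatrix | np.ndarray", set_idx) -> SelfContainedResult:
    """Tracy-Widom test on the largest eigenvalue of ``n S_gg``."""
    gram, n = _set_gram(X, set_idx)
    if n < 3:
        raise ValueError(f"TWT requires n >= 3, got n={n}")
    g = gram.shape[0]
    eigs = clip_spectrum(np.linalg.eigvalsh(gram))
    stat = float(_twt_from_gram_eigs(eigs, n))
    return SelfContainedResult(
        method="TWT",
        statistic=stat,
        pvalue=float(tracy_widom_goe().sf(stat)),
        g=g,
        n=n,
    )


def mpdt_statistic(X: "DataMatrix | np.ndarray", set_idx) -> SelfContainedResult:
    """Marčenko-Pastur distribution test (one-sample KS on the spectrum)."""
    gram, n = _set_gram(X, set_idx)
    g = gram.shape[0]
    eigs = clip_spectrum(np.linalg.eigvalsh(gram))
    stat = float(_mpdt_from_gram_eigs(eigs, n))
    # nominal one-sample KS p-value; anti-conservative because the
    # eigenvalues are mutually dependent
    pval = float(sps.kstwo.sf(stat, g))
    return SelfContainedResult(
        method="MPDT", statistic=stat, pvalue=pval, g=g, n=n, anticonservative=True
    )


_KERNELS = {
    "MLRT": _mlrt_from_gram_eigs,
    "TWT": _twt_from_gram_eigs,
    "MPDT": _mpdt_from_gram_eigs,
}


def statistics_from_gram(
    gram_full: np.ndarray, subsets: np.ndarray, n: int, methods: tuple[str, ...]
) -> dict[str, np.ndarray]:
    """Batch self-contained statistics for many same-size subsets.

    ``gram_full`` is the p x p matrix ``C^T C``; ``subsets`` an integer array
    of shape (m, g).  One stacked eigendecomposition serves all methods.
    """
    for m in methods:
        if m not in _KERNELS:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
    blocks = gram_full[subsets[:, :, None], subsets[:, None, :]]
    eigs = clip_spectrum(np.linalg.eigvalsh(blocks))
    return {m: _KERNELS[m](eigs, n) for m in methods}
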