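"""P-value weighting and weighted Benjamini-Hochberg FDR control.

Unsupervised competitive p-values ``u_i`` for ``f`` gene sets are turned
into mean-one weights

    w_i = -log(u_i) / ((1/f) sum_j -log(u_j)),

which guarantees ``sum w_i = f``.  Supervised p-values ``s_i`` are then
weighted, ``s*_i = s_i / w_i`` (clipped to [0, 1]; a zero weight sends the
weighted p-value to 1), and the ordinary BH step-up procedure applied to
``s*``.  With mean-one weights that are independent of the supervised
p-values under the null, BH on the weighted p-values controls the FDR
(Genovese-Roeder-Wasserman): ``P(s/w <= t) = E[min(t w, 1)] <= t`` for a
null uniform ``s``, so large weights promote a set while the mean-one
constraint pays for it elsewhere.  The multiplicative form ``w_i s_i``
is anti-conservative for the null sets (by Jensen, ``E[1/w] >= 1``) and
is not used.

Competitive p-values can be exactly zero (strict exceedance over B
permutations); by default they are floored at 1 / (2B) before the log so
weights stay finite.  The log base cancels in the ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "floor_pvalues",
    "compute_weights",
    "weight_pvalues",
    "weighted_bh",
    "weighted_fdr_table",
]

MEAN_WEIGHT_TOL = 1e-9


def floor_pvalues(u: np.ndarray, B: int) -> np.ndarray:
    """Floor permutation p-values at 1/(2B) so -log(u) stays finite."""
    if B < 1:
        raise ValueError("B must be >= 1")
    return np.clip(np.asarray(u, dtype=float), 1.0 / (2 * B), None)


def compute_weights(u: np.ndarray) -> np.ndarray:
    """Mean-one weights from unsupervised p-values; sum(w) == f exactly."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 1:
        raise ValueError("u must be a non-empty 1-D array of p-values")
    if np.any((u <= 0.0) | (u > 1.0)):
        raise ValueError(
            "unsupervised p-values must lie in (0, 1]; floor zeros first "
            "(floor_pvalues) or use the plus-one competitive p-value mode"
        )
    neglog = -np.log(u)
    mean = neglog.mean()
    if mean == 0.0:
        raise ValueError(
            "degenerate weights: every unsupervised p-value equals 1, so all "
            "-log(u) are zero"
        )
    return neglog / mean


def weight_pvalues(s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted p-values ``s* = s / w`` clipped to [0, 1]; ``w = 0`` gives 1."""
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_star = np.where(w > 0, s / np.where(w > 0, w, 1.0), np.where(s == 0, 0.0, 1.0))
    return np.clip(s_star, 0.0, 1.0)


def weighted_bh(
    s: np.ndarray, w: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted BH: q-values and rejection flags for s* = s / w.

    The weights must average 1 (the validity condition for weighted FDR
    control); weighted p-values above 1 are clipped before the BH step.
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(w, dtype=float)
    if s.shape != w.shape:
        raise ValueError("s and w must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.mean() - 1.0) > MEAN_WEIGHT_TOL:
        raise ValueError(
            f"weights must have mean 1 (got {w.mean():.12g}); "
            "this is the Genovese validity condition for weighted FDR control"
        )
    reject, qvalues, _, _ = multipletests(
        weight_pvalues(s, w), alpha=alpha, method="fdr_bh"
    )
    return qvalues, reject


def weighted_fdr_table(
    set_ids: list[str],
    u: np.ndarray,
    s: np.ndarray,
    alpha: float = 0.05,
    B: int | None = None,
) -> pd.DataFrame:
    """Full weighting workflow as a tidy table.

    Columns: unsupervised p (``u``), weight (``w``), supervised p (``s``),
    weighted p (``s_star``), BH q-value (``q``) and rejection flag.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (len(set_ids) == u.size == s.size):
        raise ValueError("set_ids, u and s must have equal length")
    if B is not None:
        u = floor_pvalues(u, B)
    w = compute_weights(u)
    q, reject = weighted_bh(s, w, alpha=alpha)
    return pd.DataFrame(
        {
            "set_id": set_ids,
            "u": u,
            "w": w,
            "s": s,
            "s_star": weight_pvalues(s, w),
            "q": q,
            "reject": reject,
        }
    )
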