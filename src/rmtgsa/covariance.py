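"""Population covariance structures for the simulation designs.

Each structure places a designated gene set (the first ``g`` genes) inside a
``p x p`` covariance matrix.  Genes outside the designated set have identity
covariance, except for the compound-symmetry structure (every gene pair
shares the same covariance, irrespective of set membership), the scaled
identity (every variance scaled), and the repeated-block structure (every
disjoint size-``g`` block receives the within-block covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CovarianceSpec", "build_covariance", "STRUCTURES"]

STRUCTURES = (
    "identity",
    "scaled_identity",
    "compound_symmetry",
    "single_block",
    "multi_block",
    "anticorrelated_multi_block",
    "repeated_block",
    "inverted_single_block",
)

#: eigenvalues more negative than this reject the matrix as non-PSD
PSD_TOL = -1e-10


@dataclass(frozen=True)
class CovarianceSpec:
    """Declarative description of a population covariance structure.

    Parameters
    ----------
    structure
        One of :data:`STRUCTURES`.
    p
        Total number of genes.
    g
        Size of the designated gene set (first ``g`` genes).
    sigma2
        Variance of the designated genes (and of all genes for the
        scaled-identity and compound-symmetry structures).
    rho
        Pairwise covariance among designated genes (within sub-blocks for
        the multi-block structures; among all genes for compound symmetry).
    block_sizes
        Sub-block sizes partitioning ``g`` (multi-block structures only).
    rho_between
        Pairwise covariance across different sub-blocks of the designated
        set (anti-correlated multi-block; 0 for plain multi-block).
    """

    structure: str
    p: int
    g: int = 0
    sigma2: float = 1.0
    rho: float = 0.0
    block_sizes: tuple[int, ...] | None = None
    rho_between: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if self.p < 1:
            raise ValueError("p must be positive")
        if not 0 <= self.g <= self.p:
            raise ValueError(f"g={self.g} must satisfy 0 <= g <= p={self.p}")
        if self.block_sizes is not None and sum(self.block_sizes) != self.g:
            raise ValueError(
                f"block sizes {self.block_sizes} do not partition g={self.g}"
            )

    def to_dict(self) -> dict:
        """Flat key-value form, suitable for a TOML/YAML config block."""
        out = {
            "structure": self.structure,
            "p": self.p,
            "g": self.g,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "rho_between": self.rho_between,
        }
        if self.block_sizes is not None:
            out["block_sizes"] = list(self.block_sizes)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "CovarianceSpec":
        data = dict(data)
        if "block_sizes" in data and data["block_sizes"] is not None:
            data["block_sizes"] = tuple(data["block_sizes"])
        return cls(**data)


def _block(size: int, sigma2: float, rho: float) -> np.ndarray:
    b = np.full((size, size), rho, dtype=float)
    np.fill_diagonal(b, sigma2)
    return b


def _multi_block(spec: CovarianceSpec) -> np.ndarray:
    if spec.block_sizes is None:
        raise ValueError(f"{spec.structure} requires block_sizes")
    set_part = np.full((spec.g, spec.g), spec.rho_between, dtype=float)
    start = 0
    for size in spec.block_sizes:
        set_part[start : start + size, start : start + size] = _block(
            size, spec.sigma2, spec.rho
        )
        start += size
    out = np.eye(spec.p)
    out[: spec.g, : spec.g] = set_part
    return out


def build_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Build the ``p x p`` population covariance matrix for *spec*.

    Raises
    ------
    ValueError
        If the requested parameters produce a matrix that is not positive
        semi-definite (possible for extreme ``rho``); the message names the
        offending eigenvalue.
    """
    p, g = spec.p, spec.g
    s = spec.structure
    if s == "identity":
        out = np.eye(p)
    elif s == "scaled_identity":
        out = spec.sigma2 * np.eye(p)
    elif s == "compound_symmetry":
        out = _block(p, spec.sigma2, spec.rho)
    elif s == "single_block":
        out = np.eye(p)
        out[:g, :g] = _block(g, spec.sigma2, spec.rho)
    elif s in ("multi_block", "anticorrelated_multi_block"):
        out = _multi_block(spec)
    elif s == "repeated_block":
        if g < 1 or p % g != 0:
            raise ValueError(f"repeated_block requires g | p, got g={g}, p={p}")
        out = np.zeros((p, p))
        for k in range(p // g):
            out[k * g : (k + 1) * g, k * g : (k + 1) * g] = _block(
                g, spec.sigma2, spec.rho
            )
    elif s == "inverted_single_block":
        out = np.eye(p)
        c = p - g
        out[g:, g:] = _block(c, spec.sigma2, spec.rho)
    else:  # pragma: no cover - guarded by CovarianceSpec
        raise ValueError(s)

    lam_min = float(np.linalg.eigvalsh(out)[0])
    if lam_min < PSD_TOL:
        raise ValueError(
            f"covariance for structure {s!r} is not positive semi-definite: "
            f"smallest eigenvalue {lam_min:.6g}"
        )
    return out
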