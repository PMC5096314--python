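"""Core in-memory containers: the data matrix and the gene set collection.

The data matrix holds measurements for ``p`` genomic variables (columns)
across ``n`` independent samples (rows).  Gene sets are represented as a
binary membership matrix with one row per set, the interchange form used
by GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "GeneSetCollection"]


@dataclass
class DataMatrix:
    """An ``n x p`` numeric matrix of genomic measurements.

    Parameters
    ----------
    values
        Real-valued array of shape ``(n, p)`` with no missing entries.
    gene_ids
        ``p`` column labels.
    sample_ids
        ``n`` row labels.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x genes)")
        n, p = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got n={n}")
        if p < 1:
            raise ValueError("need at least one gene")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample row {bad[0]}, gene column {bad[1]}"
            )
        if not self.gene_ids:
            self.gene_ids = [f"g{j + 1}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def centered(self) -> np.ndarray:
        """Column-mean-centered copy of the values (the matrix C)."""
        return self.values - self.values.mean(axis=0, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
        )


@dataclass
class GeneSetCollection:
    """``f`` gene sets over ``p`` genes as a binary membership matrix."""

    set_ids: list[str]
    membership: np.ndarray  # (f, p) in {0, 1}

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        if self.membership.ndim != 2:
            raise ValueError("membership must be a 2-D (sets x genes) matrix")
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("membership entries must be 0 or 1")
        self.membership = self.membership.astype(np.int8)
        if len(self.set_ids) != self.membership.shape[0]:
            raise ValueError("set_ids length does not match membership rows")
        if len(set(self.set_ids)) != len(self.set_ids):
            dupes = {s for s in self.set_ids if self.set_ids.count(s) > 1}
            raise ValueError(f"duplicate set names: {sorted(dupes)}")
        if (self.membership.sum(axis=1) < 1).any():
            empty = [
                s for s, row in zip(self.set_ids, self.membership) if row.sum() < 1
            ]
            raise ValueError(f"gene sets with no members: {empty}")

    @property
    def f(self) -> int:
        return self.membership.shape[0]

    @property
    def p(self) -> int:
        return self.membership.shape[1]

    @property
    def sizes(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    def indices(self, set_id: str) -> np.ndarray:
        """Gene column indices of the named set."""
        i = self.set_ids.index(set_id)
        return np.flatnonzero(self.membership[i])

    @classmethod
    def from_index_sets(
        cls, sets: dict[str, "np.ndarray | list[int]"], p: int
    ) -> "GeneSetCollection":
        ids = list(sets)
        memb = np.zeros((len(ids), p), dtype=np.int8)
        for i, name in enumerate(ids):
            idx = np.asarray(sets[name], dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= p):
                raise ValueError(f"set {name!r} references gene index outside 0..{p - 1}")
            memb[i, idx] = 1
        return cls(set_ids=ids, membership=memb)

    @classmethod
    def disjoint_blocks(cls, p: int, g: int) -> "GeneSetCollection":
        """The ``p/g`` disjoint consecutive size-``g`` sets used in the studies."""
        if p % g != 0:
            raise ValueError(f"g={g} does not divide p={p}")
        sets = {f"set{k + 1}": np.arange(k * g, (k + 1) * g) for k in range(p // g)}
        return cls.from_index_sets(sets, p)
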