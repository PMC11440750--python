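"""Pedigree container.

The pedigree is the backbone of every relationship matrix in the pipeline:
one row per animal with integer id, sire id, dam id (0 = unknown), year of
birth, flock code and population label.  Rows are kept sorted so that
parents always precede offspring, which is what the tabular relationship
recursions and the gene-dropping simulator require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

UNKNOWN = 0  # id used for a missing parent

REQUIRED_COLUMNS = ["id", "sire", "dam", "year", "flock", "pop"]


@dataclass
class Pedigree:
    """Parents-before-offspring pedigree table.

    Attributes
    ----------
    df:
        DataFrame with columns ``id, sire, dam, year, flock, pop``.
        Ids are positive integers; ``0`` marks an unknown parent.
    """

    df: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"pedigree is missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["id"].to_numpy()
        if (ids <= 0).any():
            raise ValidationError("animal ids must be positive integers")
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate animal ids in pedigree")
        self._index = {int(a): i for i, a in enumerate(ids)}
        sire = self.df["sire"].to_numpy()
        dam = self.df["dam"].to_numpy()
        for i, (a, s, d) in enumerate(zip(ids, sire, dam)):
            for p in (s, d):
                if p == UNKNOWN:
                    continue
                if p == a:
                    raise ValidationError(f"animal {a} is its own parent")
                j = self._index.get(int(p))
                if j is None:
                    raise ValidationError(f"parent {p} of animal {a} not in pedigree")
                if j >= i:
                    raise ValidationError(
                        f"parent {p} listed after offspring {a}; sort parents first"
                    )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def positions(self, ids) -> np.ndarray:
        """0-based row positions of the given animal ids."""
        return np.array([self._index[int(a)] for a in np.atleast_1d(ids)], dtype=int)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam row indices; -1 where the parent is unknown."""
        sire = np.array(
            [self._index.get(int(s), -1) if s != UNKNOWN else -1 for s in self.df["sire"]],
            dtype=int,
        )
        dam = np.array(
            [self._index.get(int(d), -1) if d != UNKNOWN else -1 for d in self.df["dam"]],
            dtype=int,
        )
        return sire, dam

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, sort: bool = True) -> "Pedigree":
        """Build a pedigree, topologically sorting parents-first if asked."""
        if sort:
            df = topological_sort(df)
        return cls(df)

    @classmethod
    def from_csv(cls, path, sort: bool = True) -> "Pedigree":
        df = pd.read_csv(path)
        return cls.from_frame(df, sort=sort)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def topological_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Sort pedigree rows so every parent precedes its offspring.

    Raises ValidationError on parentage cycles.
    """
    ids = df["id"].to_numpy()
    pos = {int(a): i for i, a in enumerate(ids)}
    children: dict[int, list[int]] = {i: [] for i in range(len(df))}
    indeg = np.zeros(len(df), dtype=int)
    for i, (s, d) in enumerate(zip(df["sire"].to_numpy(), df["dam"].to_numpy())):
        for p in (s, d):
            if p != UNKNOWN and int(p) in pos:
                children[pos[int(p)]].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = sorted(np.flatnonzero(indeg == 0).tolist())
    indeg = indeg.copy()
    while stack:
        i = stack.pop(0)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != len(df):
        raise ValidationError("pedigree contains a parentage cycle")
    return df.iloc[order].reset_index(drop=True)
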