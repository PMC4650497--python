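"""Core data containers for repeated-measures omics matrices.

The central object is :class:`LongitudinalMatrix`: an ``N x p`` observation
matrix over ``N = n_animals x n_times`` samples, with per-sample annotations
(animal, time, batch, and optionally sex).  Rows are samples, columns are
features (biological variables, probes or genes).  All pipeline stages accept
and return this container, or plain :class:`pandas.DataFrame` views of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalMatrix",
    "MultilevelDecomposition",
    "DesignError",
]


class DesignError(ValueError):
    """Raised when the sample design violates the balanced-design assumption."""


@dataclass
class LongitudinalMatrix:
    """An N x p observation matrix with animal/time/batch annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples in rows (index = sample ids), features in columns.  Column
        names must be unique.
    animal, time, batch : pandas.Series
        Per-sample annotations, aligned with ``values.index``.  ``time`` is in
        hours relative to the challenge (e.g. 0, 1, 4, 24).
    sex : pandas.Series, optional
        Per-sample sex labels ('F'/'M'), aligned with ``values.index``.
    """

    values: pd.DataFrame
    animal: pd.Series
    time: pd.Series
    batch: pd.Series
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate column name: {dup!r}")
        for name in ("animal", "time", "batch"):
            ann = getattr(self, name)
            if len(ann) != len(self.values):
                raise ValueError(
                    f"annotation {name!r} has length {len(ann)}, "
                    f"expected {len(self.values)}"
                )
            setattr(self, name, pd.Series(np.asarray(ann), index=self.values.index, name=name))
        if self.sex is not None:
            self.sex = pd.Series(np.asarray(self.sex), index=self.values.index, name="sex")

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def animals(self) -> np.ndarray:
        """Unique animal ids in order of first appearance."""
        return self.animal.unique()

    @property
    def times(self) -> np.ndarray:
        """Unique time points, sorted ascending."""
        return np.sort(self.time.unique())

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def is_balanced(self) -> bool:
        """True iff every animal is observed exactly once at every time point."""
        counts = pd.crosstab(self.animal, self.time)
        return bool((counts.values == 1).all()) and counts.shape[1] == self.n_times

    def require_balanced(self) -> None:
        if not self.is_balanced():
            raise DesignError(
                "design is not balanced: every animal must appear exactly "
                "once per time point"
            )

    # ------------------------------------------------------------------ #
    def copy(self, values: pd.DataFrame | None = None) -> "LongitudinalMatrix":
        """Copy, optionally replacing the value matrix (same sample index)."""
        v = self.values.copy() if values is None else values
        return LongitudinalMatrix(
            values=v,
            animal=self.animal.copy(),
            time=self.time.copy(),
            batch=self.batch.copy(),
            sex=None if self.sex is None else self.sex.copy(),
        )

    def subset_features(self, columns: Sequence[str]) -> "LongitudinalMatrix":
        return self.copy(values=self.values[list(columns)].copy())

    def at_time(self, t) -> pd.DataFrame:
        """Value rows at one time point, indexed by animal."""
        mask = (self.time == t).values
        out = self.values.loc[mask].copy()
        out.index = self.animal[mask].values
        return out.sort_index()

    # ------------------------------------------------------------------ #
    def to_long(self) -> pd.DataFrame:
        """Long-format table (animal, time, batch[, sex], variable, value)."""
        meta = {"animal": self.animal, "time": self.time, "batch": self.batch}
        if self.sex is not None:
            meta["sex"] = self.sex
        wide = pd.concat([pd.DataFrame(meta), self.values], axis=1)
        long = wide.melt(
            id_vars=list(meta), var_name="variable", value_name="value"
        )
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "LongitudinalMatrix":
        """Build from a long table with columns animal, time, batch[, sex], variable, value."""
        required = {"animal", "time", "batch", "variable", "value"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        id_cols = ["animal", "time", "batch"] + (["sex"] if "sex" in long.columns else [])
        meta = long[id_cols].drop_duplicates(subset=["animal", "time"]).reset_index(drop=True)
        key = pd.MultiIndex.from_frame(long[["animal", "time"]])
        values = (
            long.assign(_key=pd.factorize(key)[0])
            .pivot(index="_key", columns="variable", values="value")
            .reset_index(drop=True)
        )
        values.columns.name = None
        return cls(
            values=values,
            animal=meta["animal"],
            time=meta["time"],
            batch=meta["batch"],
            sex=meta["sex"] if "sex" in meta.columns else None,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the long-format table as TSV."""
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LongitudinalMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t"))


@dataclass
class MultilevelDecomposition:
    """Split of an observation matrix into offset + between + within parts.

    For a balanced design with ``n`` animals each measured at ``T`` time
    points, the ``N x p`` matrix ``X`` decomposes as

    ``X = offset + between + within``

    where ``offset`` repeats the grand column means, ``between`` carries each
    animal's mean deviation from the grand mean (rows constant within animal),
    and ``within`` carries the deviations of each observation from its
    animal's own mean.  ``within`` is the input to multilevel PCA/PLS: it
    isolates time-related variation from stable inter-individual differences.
    """

    offset: pd.DataFrame
    between: pd.DataFrame
    within: pd.DataFrame
    source: LongitudinalMatrix = field(repr=False)

    def reconstruct(self) -> pd.DataFrame:
        return self.offset + self.between + self.within

    @property
    def within_matrix(self) -> LongitudinalMatrix:
        """The within-animal component as an annotated LongitudinalMatrix."""
        return self.source.copy(values=self.within.copy())

    def variance_fractions(self) -> pd.Series:
        """Fraction of total (centred) variance in the between / within parts."""
        total = ((self.between + self.within) ** 2).values.sum()
        if total == 0:
            return pd.Series({"between": 0.0, "within": 0.0})
        return pd.Series(
            {
                "between": (self.between**2).values.sum() / total,
                "within": (self.within**2).values.sum() / total,
            }
        )
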