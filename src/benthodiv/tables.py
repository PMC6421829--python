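"""In-memory containers for count, environment and function tables.

The orientation convention throughout the package is observations in rows:
samples (sequencing libraries) are rows, zOTUs / environmental properties /
predicted functions are columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountTable", "EnvTable", "FunctionTable", "DistanceMatrix"]

FRACTIONS = ("DNA", "RNA")


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what} label(s): {dups}")


@dataclass
class CountTable:
    """Samples x zOTUs table of non-negative integer read counts.

    Parameters
    ----------
    counts
        Integer matrix of shape (n_samples, n_otus).
    sample_ids, otu_ids
        Row and column labels; must be unique.
    fraction
        Optional per-sample nucleic-acid fraction label ("DNA" or "RNA"),
        used to keep the entire-community and active-community arms separate
        in every statistical model.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    fraction: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x zOTUs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                np.mod(self.counts[np.isfinite(self.counts)], 1) == 0
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"zOTU {self.otu_ids[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"shape mismatch: counts {self.counts.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} zOTUs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "zOTU")
        if self.fraction is not None:
            bad = {v for v in self.fraction.values()} - set(FRACTIONS)
            if bad:
                raise ValueError(f"unknown fraction label(s): {sorted(bad)}")

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Library depth (total reads) per sample."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="depth")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    # -- derived tables ------------------------------------------------
    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = list(keep)
        idx = [self.sample_index(s) for s in keep]
        frac = None
        if self.fraction is not None:
            frac = {s: self.fraction[s] for s in keep if s in self.fraction}
        return CountTable(self.counts[idx], keep, list(self.otu_ids), frac)

    def split_fractions(self) -> dict[str, "CountTable"]:
        """Split into per-fraction tables; requires fraction labels."""
        if self.fraction is None:
            raise ValueError("table carries no fraction labels")
        out = {}
        for frac in FRACTIONS:
            ids = [s for s in self.sample_ids if self.fraction.get(s) == frac]
            if ids:
                out[frac] = self.select_samples(ids)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fraction: Mapping[str, str] | None = None
    ) -> "CountTable":
        return cls(
            df.to_numpy(),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            dict(fraction) if fraction is not None else None,
        )


@dataclass
class EnvTable:
    """Per-sample environmental covariates (latitude, depth, chlorophyll, ...).

    Missing measurements stay NaN and are handled pairwise-complete
    downstream; they are never silently treated as zero.
    """

    data: pd.DataFrame
    fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        _check_unique(list(self.data.index), "sample")
        nonnum = [
            c for c in self.data.columns if not np.issubdtype(self.data[c].dtype, np.number)
        ]
        if nonnum:
            raise ValueError(f"non-numeric environmental column(s): {nonnum}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def properties(self) -> list[str]:
        return list(self.data.columns)

    def aligned_to(self, sample_ids: Sequence[str]) -> "EnvTable":
        """Reindex by label to the given sample order (alignment is always
        by label, never by position)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from environment table: {missing}")
        frac = self.fraction.reindex(sample_ids) if self.fraction is not None else None
        return EnvTable(self.data.reindex(list(sample_ids)), frac)

    def values_for(self, prop: str, sample_ids: Sequence[str]) -> np.ndarray:
        if prop not in self.data.columns:
            raise KeyError(f"unknown environmental property {prop!r}")
        return self.aligned_to(sample_ids).data[prop].to_numpy(dtype=float)


@dataclass
class FunctionTable:
    """Samples x predicted functions, relative abundances >= 0.

    Produced upstream (e.g. by Tax4Fun2) or by the synthetic generator;
    consumed as-is for the function-profile screen.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        _check_unique(list(self.data.index), "sample")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError("function table contains negative abundances")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix tagged with its measure."""

    ids: list[str]
    values: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.measure)
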