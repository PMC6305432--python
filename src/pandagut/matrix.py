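"""Abundance matrices: the universal currency between pipeline stages.

An :class:`AbundanceMatrix` is a non-negative features-by-samples table
(genes, taxa, or functional features on the rows) with an explicit unit
flag: ``"relative"`` columns are proportions summing to at most one,
``"counts"`` columns are raw non-negative values that are never silently
renormalized (richness estimators need untouched counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "read_abundance_matrix", "write_abundance_matrix"]

_REL_TOL = 1e-9


@dataclass
class AbundanceMatrix:
    """Non-negative features x samples table with a unit flag.

    Parameters
    ----------
    data:
        DataFrame with unique row ids (features) and column ids (samples).
    units:
        ``"relative"`` (each column sums to <= 1 + 1e-9) or ``"counts"``.
    """

    data: pd.DataFrame
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.units not in ("relative", "counts"):
            raise ValueError(f"units must be 'relative' or 'counts', got {self.units!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"NaN at row {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance {vals[r, c]} at row "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if self.units == "relative":
            sums = vals.sum(axis=0)
            if (sums > 1 + _REL_TOL).any():
                bad = self.data.columns[np.argmax(sums)]
                raise ValueError(
                    f"relative matrix column {bad!r} sums to {sums.max():.6g} > 1"
                )
        self.data = self.data.astype(float)

    # -- convenience -------------------------------------------------------

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def is_relative(self) -> bool:
        return self.units == "relative"

    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_relative(self) -> "AbundanceMatrix":
        """Column-normalize to proportions; all-zero columns stay zero."""
        sums = self.data.sum(axis=0)
        safe = sums.replace(0.0, 1.0)
        return AbundanceMatrix(self.data.div(safe, axis=1), units="relative")

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)], units=self.units)


def read_abundance_matrix(path: str | Path, relative_flag: bool = False) -> AbundanceMatrix:
    """Read a TSV matrix (header = sample ids, first column = row ids).

    Lines starting with ``#`` are comments.  When ``relative_flag`` is set
    the columns are normalized to proportions on ingest; raw counts are
    never renormalized.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:  # non-numeric cell
        raise ValueError(f"non-numeric value in {path}: {exc}") from exc
    m = AbundanceMatrix(df, units="counts")
    if relative_flag:
        return m.to_relative()
    return m


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (lossless round-trip)."""
    matrix.data.to_csv(path, sep="\t", float_format="%.17g")
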