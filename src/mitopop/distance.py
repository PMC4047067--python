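"""Labeled symmetric distance matrices (sequence differences, Phi-ST, km)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: allowed units for a DistMatrix
UNITS = ("diff_count", "phi_st", "km")


@dataclass
class DistMatrix:
    """Symmetric matrix with row/column labels and a zero diagonal.

    Phi-ST entries may be slightly negative (estimator property); other
    units are non-negative.
    """

    labels: list[str]
    values: np.ndarray
    units: str = "diff_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("matrix diagonal is not zero")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major), as used by correlations."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, labels: list[str]) -> "DistMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistMatrix(list(labels), self.values[np.ix_(idx, idx)], self.units)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, units: str = "diff_count") -> "DistMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), units)
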