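"""Expression-matrix container.

Expression data is held as a samples x genes table of non-negative,
already-normalized values (e.g. RPKM).  The container is a thin wrapper
around a pandas DataFrame that pins down orientation and carries the
condition label through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]

_CONDITIONS = ("control", "perturbed")


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of non-negative expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are genes.  Values must be finite and
        non-negative; gene ids must be unique.
    condition : str
        ``"control"`` or ``"perturbed"``.
    """

    data: pd.DataFrame
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(
                f"condition must be one of {_CONDITIONS}, got {self.condition!r}"
            )
        self.data = self.data.copy()
        self.data.columns = [str(c) for c in self.data.columns]
        self.data.index = [str(i) for i in self.data.index]
        genes = list(self.data.columns)
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        if dupes:
            raise ValueError(f"duplicate gene ids: {dupes}")
        values = self.data.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite/non-numeric expression value at "
                f"sample {self.data.index[i]!r}, gene {self.data.columns[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                "negative expression value at "
                f"sample {self.data.index[i]!r}, gene {self.data.columns[j]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """S x N float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to `genes` (in the given order), keeping sample order."""
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, genes], condition=self.condition)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_samples} samples x {self.n_genes} genes, "
            f"condition={self.condition!r})"
        )
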