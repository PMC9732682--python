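"""Expression-matrix container shared by all pipeline stages.

An :class:`ExpressionMatrix` is a genes x samples matrix of normalized
expression values plus per-sample metadata describing the experimental
design (variety, nitrogen level, water level, replicate).  Downstream
stages assume no missing values and unique gene/sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError

METADATA_COLUMNS = ("variety", "n_level", "w_level", "replicate")


@dataclass
class ExpressionMatrix:
    """Normalized expression values (rows = genes, columns = samples).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    metadata
        DataFrame indexed by sample id with columns
        ``variety, n_level, w_level, replicate``.  Optional for matrices
        that have already been averaged over replicates.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("gene_ids must be unique")
        if self.values.columns.has_duplicates:
            raise DataError("sample_ids must be unique")
        if np.asarray(self.values, dtype=float).size and np.isnan(
            np.asarray(self.values, dtype=float)
        ).any():
            raise DataError("expression matrix contains missing values")
        if self.metadata is not None:
            missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
            if missing:
                raise DataError(f"metadata missing columns: {missing}")
            if not self.metadata.index.equals(self.values.columns):
                # Permit metadata given in any row order.
                if set(self.metadata.index) != set(self.values.columns):
                    raise DataError("metadata rows do not match sample_ids")
                self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise DataError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[gene_ids], self.metadata)
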