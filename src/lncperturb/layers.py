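"""Expression-layer container shared across the pipeline.

An :class:`ExpressionLayer` wraps one RNA class's gene x sample matrix of
log2(x+1) abundances. Gene and sample identifiers must be unique; values are
finite and non-negative once on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

LAYER_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class ExpressionLayer:
    """One RNA class's gene x sample expression matrix.

    Parameters
    ----------
    layer_class:
        One of ``"lncRNA"``, ``"miRNA"``, ``"mRNA"``.
    data:
        DataFrame with genes as the index and samples as the columns.
    is_log2:
        Whether values are already on the log2(x + pseudocount) scale.
    """

    layer_class: str
    data: pd.DataFrame
    is_log2: bool = True

    def __post_init__(self) -> None:
        if self.layer_class not in LAYER_CLASSES:
            raise DataError(
                f"layer_class must be one of {LAYER_CLASSES}, got {self.layer_class!r}"
            )
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers in {self.layer_class}: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample identifiers in {self.layer_class}: {dups}")
        vals = self.data.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise DataError(f"non-finite expression values in {self.layer_class} layer")
        if self.is_log2 and vals.size and (vals < 0).any():
            raise DataError(
                f"negative values in log2-scale {self.layer_class} layer"
            )

    # -- subsetting ----------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionLayer":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(
                f"samples absent from {self.layer_class} layer: {missing[:10]}"
            )
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionLayer":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DataError(f"genes absent from {self.layer_class} layer: {missing[:10]}")
        return replace(self, data=self.data.loc[list(gene_ids)])

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.index:
            raise DataError(f"gene {gene_id!r} absent from {self.layer_class} layer")
        return self.data.loc[gene_id]

    def equals(self, other: "ExpressionLayer") -> bool:
        return (
            self.layer_class == other.layer_class
            and self.is_log2 == other.is_log2
            and self.data.equals(other.data)
        )
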