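"""Sample and gene filtering ahead of triplet inference.

Mirrors the study design the pipeline assumes: restrict to samples with
matched profiles in all three RNA layers, drop low-purity tumors (ESTIMATE
purity strictly above a threshold), work on log2(x+1) abundances, remove
genes that are near-silent in most samples, and keep only genes with enough
cross-sample variability (log2 IQR strictly above a threshold) to carry a
correlation signal.

Quantiles use linear interpolation between order statistics (numpy's
default, the type-7 convention), which makes the IQR boundary exactly
testable.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .exceptions import DataError
from .layers import ExpressionLayer

PURITY_THRESHOLD = 0.8
MIN_LOG2 = 1.0
MAX_FRACTION_BELOW = 0.7
MIN_IQR = 0.58


def match_samples(
    lnc: ExpressionLayer, mir: ExpressionLayer, mrna: ExpressionLayer
) -> tuple[ExpressionLayer, ExpressionLayer, ExpressionLayer]:
    """Restrict all three layers to their common samples, in a shared order.

    The common order follows the lncRNA layer's column order. Raises
    :class:`DataError` if the intersection is empty.
    """
    for layer in (lnc, mir, mrna):
        if layer.n_samples == 0:
            raise DataError(f"{layer.layer_class} layer has no samples")
    common = [
        s
        for s in lnc.sample_ids
        if s in set(mir.sample_ids) and s in set(mrna.sample_ids)
    ]
    if not common:
        raise DataError(
            "no samples shared between the lncRNA, miRNA and mRNA layers"
        )
    return (
        lnc.select_samples(common),
        mir.select_samples(common),
        mrna.select_samples(common),
    )


def filter_by_purity(
    layer: ExpressionLayer, purity: pd.Series, threshold: float = PURITY_THRESHOLD
) -> ExpressionLayer:
    """Keep samples whose tumor purity is strictly greater than ``threshold``."""
    missing = [s for s in layer.sample_ids if s not in purity.index]
    if missing:
        raise DataError(f"samples missing from the purity table: {missing[:10]}")
    keep = [s for s in layer.sample_ids if purity[s] > threshold]
    if not keep:
        warnings.warn(
            f"purity filter removed every sample from the {layer.layer_class} layer",
            stacklevel=2,
        )
        return replace(layer, data=layer.data.iloc[:, :0])
    return layer.select_samples(keep)


def log2_transform(layer: ExpressionLayer, pseudocount: float = 1.0) -> ExpressionLayer:
    """Apply value -> log2(value + pseudocount); guarded against double use."""
    if layer.is_log2:
        raise DataError(
            f"{layer.layer_class} layer is already log2-transformed (is_log2 flag set)"
        )
    vals = layer.data.to_numpy()
    if (vals < 0).any():
        g, s = np.argwhere(vals < 0)[0]
        raise DataError(
            "negative expression value at "
            f"gene {layer.gene_ids[g]!r}, sample {layer.sample_ids[s]!r}"
        )
    data = np.log2(layer.data + pseudocount)
    return replace(layer, data=data, is_log2=True)


def filter_low_expression(
    layer: ExpressionLayer,
    min_log2: float = MIN_LOG2,
    max_fraction_below: float = MAX_FRACTION_BELOW,
) -> ExpressionLayer:
    """Remove genes below ``min_log2`` in strictly more than ``max_fraction_below``
    of the samples."""
    if not layer.is_log2:
        raise DataError("low-expression filter expects log2-scale values")
    frac_below = (layer.data < min_log2).mean(axis=1)
    keep = layer.data.index[frac_below <= max_fraction_below]
    if keep.empty:
        warnings.warn(
            f"low-expression filter removed every {layer.layer_class} gene",
            stacklevel=2,
        )
    return replace(layer, data=layer.data.loc[keep])


def filter_by_iqr(layer: ExpressionLayer, min_iqr: float = MIN_IQR) -> ExpressionLayer:
    """Keep genes whose log2 interquartile range is strictly greater than
    ``min_iqr`` (type-7 quantiles)."""
    if not layer.is_log2:
        raise DataError("IQR filter expects log2-scale values")
    if layer.n_samples == 0:
        return layer
    vals = layer.data.to_numpy()
    q25, q75 = np.percentile(vals, [25, 75], axis=1, method="linear")
    keep = layer.data.index[(q75 - q25) > min_iqr]
    return replace(layer, data=layer.data.loc[keep])
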