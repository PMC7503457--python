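"""Readers and writers for the pipeline's tab-separated file dialects.

All files are UTF-8 text with Unix newlines:

* expression matrix — genes in rows, samples in columns, header row of
  sample identifiers, first column the gene identifier;
* interaction table — columns ``mirna_id``, ``target_id``, ``target_class``
  with ``target_class`` in {``lncRNA``, ``mRNA``};
* purity table — columns ``sample_id``, ``purity``;
* clinical table — columns ``sample_id``, ``time``, ``event``;
* truth table — columns ``lnc_id``, ``mir_id``, ``mrna_id``.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .exceptions import DataError
from .layers import ExpressionLayer

INTERACTION_COLUMNS = ["mirna_id", "target_id", "target_class"]
PURITY_COLUMNS = ["sample_id", "purity"]
CLINICAL_COLUMNS = ["sample_id", "time", "event"]
TRUTH_COLUMNS = ["lnc_id", "mir_id", "mrna_id"]


def _read_table(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in required if c.endswith("_id")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def read_expression(
    path: str | os.PathLike, layer_class: str, is_log2: bool = True
) -> ExpressionLayer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    data.index.name = None
    data.columns = data.columns.astype(str)
    return ExpressionLayer(layer_class=layer_class, data=data, is_log2=is_log2)


def write_expression(layer: ExpressionLayer, path: str | os.PathLike) -> None:
    df = layer.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_interactions(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, INTERACTION_COLUMNS)
    bad = set(df["target_class"].unique()) - {"lncRNA", "mRNA"}
    if bad:
        raise DataError(f"{path}: unknown target_class values {sorted(bad)}")
    return df[INTERACTION_COLUMNS]


def write_interactions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_purity(path: str | os.PathLike) -> pd.Series:
    df = _read_table(path, PURITY_COLUMNS)
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample_id rows")
    purity = df.set_index("sample_id")["purity"].astype(float)
    if ((purity < 0) | (purity > 1)).any():
        raise DataError(f"{path}: purity values outside [0, 1]")
    return purity


def write_purity(purity: pd.Series, path: str | os.PathLike) -> None:
    df = purity.rename("purity").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_table(path, CLINICAL_COLUMNS)
    df = df.set_index("sample_id")[["time", "event"]].astype({"time": float, "event": int})
    if (df["time"] <= 0).any():
        raise DataError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise DataError(f"{path}: event indicators must be 0 or 1")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | os.PathLike) -> None:
    out = clinical[["time", "event"]].rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return _read_table(path, TRUTH_COLUMNS)


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = truth[TRUTH_COLUMNS] if len(truth) else pd.DataFrame(columns=TRUTH_COLUMNS)
    cols.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_frame(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a generic result table (candidates, triplets, prognosis)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
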