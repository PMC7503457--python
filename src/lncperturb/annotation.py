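"""Descriptive annotation layers: conservation, DE and genomic alterations.

Covers exon-averaged per-base conservation scores (phastCons-style tracks),
rank-sum comparison of conservation between gene groups, tumor-vs-normal
differential expression on log2 values, and gene-level copy-number /
mutation frequency summaries.

Coordinates are 0-based half-open throughout; BED is read natively and GTF
converted on input. Exons of a gene are unioned across transcripts so every
base is scored once; strand is ignored (conservation is strand-symmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import bh_fdr
from .exceptions import DataError

MIN_ABS_LFC = 1.0
DE_FDR = 0.05

DE_COLUMNS = ["gene_id", "log2fc", "p", "q", "status"]


@dataclass
class GeneModel:
    """A gene's exon structure as half-open 0-based intervals."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise DataError(
                    f"{self.gene_id}: invalid exon interval [{start}, {end})"
                )

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exon intervals (overlaps and adjacencies collapsed)."""
        merged: list[list[int]] = []
        for start, end in sorted(self.exons):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return [(s, e) for s, e in merged]


class ScoreTrack:
    """Sparse per-base conservation scores in [0, 1], keyed by chromosome."""

    def __init__(self, scores: Mapping[str, pd.Series]):
        self._scores: dict[str, pd.Series] = {}
        for chrom, series in scores.items():
            vals = series.to_numpy(dtype=float)
            if vals.size and ((vals < 0) | (vals > 1)).any():
                raise DataError(f"{chrom}: conservation scores outside [0, 1]")
            self._scores[chrom] = series.sort_index()

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ScoreTrack":
        """Read a bedGraph track (chrom, start, end, value; 0-based half-open)."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
        per_chrom: dict[str, pd.Series] = {}
        for chrom, sub in df.groupby("chrom"):
            positions: list[int] = []
            values: list[float] = []
            for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
                positions.extend(range(start, end))
                values.extend([value] * (end - start))
            per_chrom[chrom] = pd.Series(values, index=positions)
        return cls(per_chrom)

    @classmethod
    def from_bigwig(cls, path: str | Path, chromosomes: Iterable[str] | None = None
                    ) -> "ScoreTrack":
        """Read a bigWig track (requires pyBigWig)."""
        import pyBigWig  # optional dependency, imported lazily

        bw = pyBigWig.open(str(path))
        per_chrom: dict[str, pd.Series] = {}
        for chrom, length in bw.chroms().items():
            if chromosomes is not None and chrom not in set(chromosomes):
                continue
            vals = np.asarray(bw.values(chrom, 0, length), dtype=float)
            mask = np.isfinite(vals)
            per_chrom[chrom] = pd.Series(vals[mask], index=np.nonzero(mask)[0])
        bw.close()
        return cls(per_chrom)

    def chromosomes(self) -> list[str]:
        return list(self._scores)

    def scores_in(self, chromosome: str, intervals: Sequence[tuple[int, int]]
                  ) -> np.ndarray:
        """Scores of covered bases within the intervals (absent = missing)."""
        if chromosome not in self._scores:
            raise KeyError(chromosome)
        series = self._scores[chromosome]
        chunks = [series.loc[start:end - 1].to_numpy() for start, end in intervals]
        return np.concatenate(chunks) if chunks else np.empty(0)


def exon_conservation(model: GeneModel, track: ScoreTrack) -> float | None:
    """Mean per-base score over the gene's exon union; None if uncovered."""
    try:
        scores = track.scores_in(model.chromosome, model.exon_union())
    except KeyError:
        warnings.warn(
            f"chromosome {model.chromosome!r} absent from the score track "
            f"({model.gene_id})",
            stacklevel=2,
        )
        return None
    if scores.size == 0:
        return None
    return float(scores.mean())


def conservation_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided rank-sum comparison of per-gene conservation means.

    Returns ``(p, median_a, median_b)``. Uses the exact Mann-Whitney null
    distribution when sample sizes permit.
    """
    a = np.asarray([v for v in group_a if v is not None and np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in group_b if v is not None and np.isfinite(v)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("conservation comparison needs two non-empty groups")
    # exact null distribution where affordable and tie-free, else asymptotic
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), float(np.median(a)), float(np.median(b))


def tumor_normal_de(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    min_abs_lfc: float = MIN_ABS_LFC,
    fdr: float = DE_FDR,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential expression on log2 values.

    log2FC is the difference of log2 group means; p from a two-sided
    Student's t-test per gene; q by Benjamini-Hochberg across genes. Status
    is ``up``/``down`` for genes with ``|log2FC| > min_abs_lfc`` and
    ``q < fdr`` (both strict), else ``ns``.
    """
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise DataError("tumor and normal each need at least 2 samples")
    genes = tumor.index.intersection(normal.index)
    if genes.empty:
        raise DataError("tumor and normal share no genes")
    t = tumor.loc[genes].to_numpy(dtype=float)
    n = normal.loc[genes].to_numpy(dtype=float)
    lfc = t.mean(axis=1) - n.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(t, n, axis=1).pvalue
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)
    status = np.full(genes.size, "ns", dtype=object)
    sig = (np.abs(lfc) > min_abs_lfc) & (q < fdr)
    status[sig & (lfc > 0)] = "up"
    status[sig & (lfc < 0)] = "down"
    return pd.DataFrame(
        {"gene_id": genes, "log2fc": lfc, "p": p, "q": q, "status": status}
    ).set_index("gene_id")


@dataclass
class AlterationTables:
    """Thresholded copy-number states and a minimal mutation table.

    ``cn_calls``: gene x sample integer matrix with states in
    {-2, -1, 0, 1, 2}; ``mutations``: records (gene_id, sample_id, class)
    with class in {silent, non_silent}.
    """

    cn_calls: pd.DataFrame
    mutations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cn_calls.size:
            states = set(np.unique(self.cn_calls.to_numpy()))
            if not states <= {-2, -1, 0, 1, 2}:
                raise DataError(f"copy-number states outside {{-2..2}}: {sorted(states)}")
        if len(self.mutations):
            required = {"gene_id", "sample_id", "class"}
            if not required.issubset(self.mutations.columns):
                raise DataError(f"mutation table must have columns {sorted(required)}")
            bad = set(self.mutations["class"]) - {"silent", "non_silent"}
            if bad:
                raise DataError(f"unknown mutation classes: {sorted(bad)}")


@dataclass
class SCNAFrequency:
    altered: float
    amplified: float
    deleted: float


def scna_frequency(tables: AlterationTables, gene_id: str) -> SCNAFrequency:
    """Fraction of samples with a nonzero copy-number state for the gene.

    Amplifications (state > 0) and deletions (state < 0) both count as
    altered; per-direction fractions are reported alongside.
    """
    if gene_id not in tables.cn_calls.index:
        raise DataError(f"gene {gene_id!r} absent from the copy-number matrix")
    states = tables.cn_calls.loc[gene_id].to_numpy()
    n = states.size
    return SCNAFrequency(
        altered=float((states != 0).sum()) / n,
        amplified=float((states > 0).sum()) / n,
        deleted=float((states < 0).sum()) / n,
    )


def mutation_frequency(tables: AlterationTables, gene_id: str, n_samples: int) -> float:
    """Fraction of samples with >= 1 non-silent mutation in the gene."""
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    muts = tables.mutations
    if not len(muts):
        return 0.0
    hit = muts[(muts["gene_id"] == gene_id) & (muts["class"] == "non_silent")]
    return hit["sample_id"].nunique() / n_samples


# ---------------------------------------------------------------------------
# gene-model readers

def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models (block fields define the exons)."""
    models: list[GeneModel] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise DataError(f"BED12 line has {len(fields)} fields: {line[:60]}...")
            chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
            sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
            offsets = [int(v) for v in fields[11].rstrip(",").split(",")]
            exons = [(start + off, start + off + size)
                     for off, size in zip(offsets, sizes)]
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def read_gtf_exons(path: str | Path) -> list[GeneModel]:
    """Read exon records from a GTF file, grouped by gene_id.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "feature", "start", "end",
               "score", "strand", "frame", "attributes"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    df = df[df["feature"] == "exon"]
    if df.empty:
        raise DataError(f"{path}: no exon records")
    gene_ids = df["attributes"].str.extract(r'gene_id "([^"]+)"')[0]
    if gene_ids.isna().any():
        raise DataError(f"{path}: exon records missing gene_id attributes")
    models = []
    for gene_id, sub in df.assign(gene_id=gene_ids).groupby("gene_id"):
        exons = [(s - 1, e) for s, e in sub[["start", "end"]].itertuples(index=False)]
        models.append(
            GeneModel(gene_id, sub["chrom"].iloc[0], sub["strand"].iloc[0], exons)
        )
    return models
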