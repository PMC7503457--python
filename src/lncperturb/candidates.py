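"""Candidate triplet construction from miRNA-target interactions.

A lncRNA and an mRNA that share a surprising number of interacting miRNAs
are merged into candidate (lncRNA, miRNA, mRNA) triplets, one per shared
miRNA. Surprise is measured by the hypergeometric upper tail

    P = 1 - sum_{i=0}^{x-1} C(L, i) C(N-L, M-i) / C(N, M)

where ``N`` is the miRNA universe size, ``L`` and ``M`` the numbers of
miRNAs interacting with the lncRNA and the mRNA, and ``x`` the shared count.
P-values are Benjamini-Hochberg corrected across every lncRNA-mRNA pair
tested in the run. Candidates are then gated on a negative all-sample
Spearman correlation between the miRNA and the mRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import spearman
from .exceptions import DataError, DomainError
from .layers import ExpressionLayer

FDR_THRESHOLD = 0.05
NEGATIVE_ALPHA = 0.05

CANDIDATE_COLUMNS = [
    "lnc_id", "mir_id", "mrna_id", "L", "M", "x", "N",
    "p_hyper", "q_hyper", "scc_global", "scc_p",
]


@dataclass
class InteractionSet:
    """miRNA-target pairs with the derived per-target miRNA sets.

    ``universe`` is the set of distinct miRNAs forming the background ``N``
    of the shared-miRNA test.
    """

    pairs: pd.DataFrame  # columns mirna_id, target_id, target_class
    mirnas_per_lnc: dict[str, frozenset[str]] = field(init=False)
    mirnas_per_mrna: dict[str, frozenset[str]] = field(init=False)
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        df = self.pairs
        required = {"mirna_id", "target_id", "target_class"}
        if not required.issubset(df.columns):
            raise DataError(f"interaction table must have columns {sorted(required)}")
        if df.empty:
            raise DataError("interaction set is empty")
        if df.duplicated(["mirna_id", "target_id", "target_class"]).any():
            df = df.drop_duplicates(["mirna_id", "target_id", "target_class"])
            self.pairs = df.reset_index(drop=True)
        by_class = {
            cls: sub.groupby("target_id")["mirna_id"].agg(frozenset).to_dict()
            for cls, sub in df.groupby("target_class")
        }
        self.mirnas_per_lnc = by_class.get("lncRNA", {})
        self.mirnas_per_mrna = by_class.get("mRNA", {})
        self.universe = frozenset(df["mirna_id"])

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def restricted_to(
        self,
        mirnas: Iterable[str] | None = None,
        lncs: Iterable[str] | None = None,
        mrnas: Iterable[str] | None = None,
    ) -> "InteractionSet":
        """Return a copy keeping only the listed identifiers (None = keep all)."""
        df = self.pairs
        if mirnas is not None:
            df = df[df["mirna_id"].isin(set(mirnas))]
        keep_targets = []
        for _, row in df.iterrows():
            if row["target_class"] == "lncRNA":
                keep_targets.append(lncs is None or row["target_id"] in set(lncs))
            else:
                keep_targets.append(mrnas is None or row["target_id"] in set(mrnas))
        df = df[np.asarray(keep_targets, dtype=bool)]
        if df.empty:
            raise DataError("interaction set empty after restriction to expressed genes")
        return InteractionSet(df.reset_index(drop=True))


@dataclass
class TripletCandidate:
    """One (lncRNA, miRNA, mRNA) candidate with its screening statistics."""

    lnc_id: str
    mir_id: str
    mrna_id: str
    L: int
    M: int
    x: int
    N: int
    p_hyper: float
    q_hyper: float
    scc_global: float = float("nan")
    scc_p: float = float("nan")


def shared_mirna_test(L: int, M: int, x: int, N: int) -> float:
    """Upper-tail hypergeometric p-value for ``x`` shared miRNAs.

    ``P(X >= x)`` for ``X`` the overlap of an ``L``-set and an ``M``-set
    drawn from a universe of ``N`` miRNAs. ``x = 0`` returns 1 (empty sum).
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    if not 0 <= L <= N:
        raise DomainError(f"L must lie in [0, N], got L={L}, N={N}")
    if not 0 <= M <= N:
        raise DomainError(f"M must lie in [0, N], got M={M}, N={N}")
    if not 0 <= x <= min(L, M):
        raise DomainError(f"x must lie in [0, min(L, M)], got x={x}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, L, M))


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, position-aligned with the input."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_candidates(
    interactions: InteractionSet,
    lnc_layer: ExpressionLayer,
    mir_layer: ExpressionLayer,
    mrna_layer: ExpressionLayer,
    fdr_threshold: float = FDR_THRESHOLD,
    universe: Literal["expressed", "all"] = "expressed",
) -> list[TripletCandidate]:
    """Merge interaction pairs into FDR-screened candidate triplets.

    Every lncRNA-mRNA pair present in the (restricted) interaction table is
    tested; pairs with ``q < fdr_threshold`` fan out into one candidate per
    shared miRNA that is present in the miRNA expression layer.

    ``universe="expressed"`` restricts the interaction background - and
    hence ``N`` - to miRNAs present in the filtered miRNA layer;
    ``universe="all"`` keeps the full table as background.
    """
    expressed_mir = set(mir_layer.gene_ids)
    if universe == "expressed":
        inter = interactions.restricted_to(
            mirnas=expressed_mir,
            lncs=lnc_layer.gene_ids,
            mrnas=mrna_layer.gene_ids,
        )
        N = len(interactions.universe & expressed_mir)
    elif universe == "all":
        inter = interactions.restricted_to(
            lncs=lnc_layer.gene_ids, mrnas=mrna_layer.gene_ids
        )
        # background stays the full table even when some miRNAs only pair
        # with genes that did not survive preprocessing
        N = interactions.universe_size
    else:
        raise DomainError(f"universe must be 'expressed' or 'all', got {universe!r}")
    lnc_map, mrna_map = inter.mirnas_per_lnc, inter.mirnas_per_mrna
    if not lnc_map or not mrna_map:
        raise DataError("interaction set lacks lncRNA or mRNA targets")

    pairs: list[tuple[str, str, frozenset[str], int, int, int, float]] = []
    for lnc_id, lnc_set in lnc_map.items():
        for mrna_id, mrna_set in mrna_map.items():
            shared = lnc_set & mrna_set
            p = shared_mirna_test(len(lnc_set), len(mrna_set), len(shared), N)
            pairs.append(
                (lnc_id, mrna_id, shared, len(lnc_set), len(mrna_set), len(shared), p)
            )
    qvals = bh_fdr([rec[6] for rec in pairs])

    out: list[TripletCandidate] = []
    for (lnc_id, mrna_id, shared, L, M, x, p), q in zip(pairs, qvals):
        if q >= fdr_threshold:
            continue
        for mir_id in sorted(shared & expressed_mir):
            out.append(
                TripletCandidate(
                    lnc_id=lnc_id, mir_id=mir_id, mrna_id=mrna_id,
                    L=L, M=M, x=x, N=N, p_hyper=p, q_hyper=float(q),
                )
            )
    return out


def negative_pair_filter(
    candidates: list[TripletCandidate],
    mir_layer: ExpressionLayer,
    mrna_layer: ExpressionLayer,
    alpha: float = NEGATIVE_ALPHA,
) -> list[TripletCandidate]:
    """Keep candidates whose all-sample Spearman R(miRNA, mRNA) is negative
    and significant; fills ``scc_global``/``scc_p`` on every candidate."""
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    kept: list[TripletCandidate] = []
    for cand in candidates:
        key = (cand.mir_id, cand.mrna_id)
        if key not in cache:
            mir = mir_layer.gene(cand.mir_id).to_numpy()
            mrna = mrna_layer.gene(cand.mrna_id).to_numpy()
            cache[key] = spearman(mir, mrna)
        r, p = cache[key]
        cand.scc_global, cand.scc_p = r, p
        if np.isnan(r):
            warnings.warn(
                f"dropping candidate {key}: Spearman undefined (constant vector)",
                stacklevel=2,
            )
            continue
        if r < 0 and p < alpha:
            kept.append(cand)
    return kept


def candidates_to_frame(candidates: list[TripletCandidate]) -> pd.DataFrame:
    """Tabulate candidates for TSV export."""
    return pd.DataFrame(
        [[getattr(c, col) for col in CANDIDATE_COLUMNS] for c in candidates],
        columns=CANDIDATE_COLUMNS,
    )
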