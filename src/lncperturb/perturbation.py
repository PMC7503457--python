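"""Detection of lncRNA-perturbated miRNA-mRNA correlation rewiring.

For each candidate triplet, samples are stratified by the lncRNA's
expression into an H-group (top quartile) and an L-group (bottom quartile).
A triplet is *perturbated* when

* the miRNA is down-regulated and the mRNA up-regulated in the H-group
  relative to the L-group (two-sided t-test p < 0.05, linear fold-change
  > 1.5);
* the within-stratum Spearman correlations satisfy Rlow < -0.4,
  Rhigh >= Rlow and |Rlow - Rhigh| > 0.3;
* the rewiring score is larger than that of random stratifications
  (empirical permutation p < 0.01 over m = 100 replicates).

The rewiring score standardises the difference of Fisher-transformed
correlations, F(R) = atanh(R) with variance ~ 1/(n-3) per stratum:

    Z = (F(Rhigh) - F(Rlow)) / sqrt(1/(n_low - 3) + 1/(n_high - 3))
    score = Phi(Z)            ("corrected" convention, the default)

so that a score near 1 means the negative coupling present at low lncRNA is
released at high lncRNA. The "literal" convention returns Phi(-Z), the
complement, and is kept for comparison with formulations that orient the
difference the other way.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rowwise_spearman, spearman
from .exceptions import DataError, DomainError
from .layers import ExpressionLayer

GROUP_FRACTION = 0.25
DE_ALPHA = 0.05
MIN_FC = 1.5
RLOW_MAX = -0.4
MIN_DELTA_R = 0.3
N_PERM = 100
PERM_ALPHA = 0.01

#: clipping bound applied to within-stratum correlations before the Fisher
#: transform when a stratum is perfectly (anti)monotone
CLIP_BOUND = 1.0 - 1e-12

RESULT_COLUMNS = [
    "lnc_id", "mir_id", "mrna_id",
    "de_pass_mir", "de_p_mir", "de_fc_mir",
    "de_pass_mrna", "de_p_mrna", "de_fc_mrna",
    "n_low", "n_high", "r_low", "r_high",
    "f_low", "f_high", "rewiring_score",
    "n_perm", "n_exceed", "p_perm", "passed",
]


@dataclass
class GroupSplit:
    """H/L sample stratification for one lncRNA."""

    lnc_id: str
    h_samples: list[str]
    l_samples: list[str]

    @property
    def n_high(self) -> int:
        return len(self.h_samples)

    @property
    def n_low(self) -> int:
        return len(self.l_samples)


@dataclass
class DEGateResult:
    passed: bool
    p: float
    fc: float


@dataclass
class PerturbationResult:
    """Full per-triplet record; ``passed`` summarises every gate."""

    lnc_id: str
    mir_id: str
    mrna_id: str
    de_pass_mir: bool
    de_p_mir: float
    de_fc_mir: float
    de_pass_mrna: bool
    de_p_mrna: float
    de_fc_mrna: float
    n_low: int
    n_high: int
    r_low: float
    r_high: float
    f_low: float
    f_high: float
    rewiring_score: float
    n_perm: int
    n_exceed: int
    p_perm: float
    passed: bool


@dataclass
class DetectionParams:
    """Tunable thresholds of the detection stage (defaults as documented)."""

    fraction: float = GROUP_FRACTION
    de_alpha: float = DE_ALPHA
    min_fc: float = MIN_FC
    rlow_max: float = RLOW_MAX
    min_delta_r: float = MIN_DELTA_R
    n_perm: int = N_PERM
    perm_alpha: float = PERM_ALPHA
    convention: Literal["corrected", "literal"] = "corrected"
    welch: bool = False
    pseudocount: float = 1.0
    add_one: bool = False
    seed: int = 0


def split_groups(
    lnc_values: pd.Series, fraction: float = GROUP_FRACTION, lnc_id: str = ""
) -> GroupSplit:
    """Sort samples by lncRNA expression (descending); the top
    ``floor(fraction * n)`` form the H-group and the bottom the L-group.

    Ties are broken by sample identifier so the split is reproducible.
    """
    n = len(lnc_values)
    if n < 16:
        raise DataError(f"need at least 16 samples to split, got {n}")
    if not 0 < fraction <= 0.5:
        raise DomainError("fraction must lie in (0, 0.5] so the groups are disjoint")
    k = int(math.floor(fraction * n))
    ids = np.asarray(lnc_values.index, dtype=object)
    vals = lnc_values.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        warnings.warn(
            f"all lncRNA values equal for {lnc_id or '<unnamed>'}; "
            "groups determined by sample-ID tie-break",
            stacklevel=2,
        )
    # descending by value, ascending by sample id on ties
    order = np.lexsort((ids, -vals))
    return GroupSplit(
        lnc_id=lnc_id,
        h_samples=list(ids[order[:k]]),
        l_samples=list(ids[order[n - k:]]),
    )


def group_de_gate(
    values: pd.Series,
    split: GroupSplit,
    direction: Literal["down_in_H", "up_in_H"],
    alpha: float = DE_ALPHA,
    min_fc: float = MIN_FC,
    welch: bool = False,
    pseudocount: float = 1.0,
) -> DEGateResult:
    """Differential-expression gate between the H- and L-groups.

    The p-value is a two-sided t-test on log2 values; the fold-change is the
    ratio of linear-scale group means (back-transformed as
    ``2**v - pseudocount``), oriented so ``fc > 1`` matches ``direction``.
    """
    if direction not in ("down_in_H", "up_in_H"):
        raise DomainError(f"unknown direction {direction!r}")
    missing = [s for s in split.h_samples + split.l_samples if s not in values.index]
    if missing:
        raise DataError(f"values missing for split samples: {missing[:10]}")
    h = values[split.h_samples].to_numpy(dtype=float)
    l = values[split.l_samples].to_numpy(dtype=float)
    if np.ptp(h) == 0 and np.ptp(l) == 0:
        warnings.warn("zero variance in both groups; DE test undefined", stacklevel=2)
        return DEGateResult(False, float("nan"), float("nan"))
    p = float(stats.ttest_ind(h, l, equal_var=not welch).pvalue)
    lin_h = float(np.mean(np.power(2.0, h) - pseudocount))
    lin_l = float(np.mean(np.power(2.0, l) - pseudocount))
    num, den = (lin_l, lin_h) if direction == "down_in_H" else (lin_h, lin_l)
    if den <= 0:
        fc = math.inf if num > 0 else float("nan")
    else:
        fc = num / den
    passed = bool(p < alpha and fc > min_fc)
    return DEGateResult(passed, p, fc)


def fisher_z(r: float, clip: bool = False) -> float:
    """Fisher transformation F(R) = 0.5 * ln((1+R)/(1-R)).

    With ``clip=True``, correlations at +/-1 are pulled to
    ``+/-(1 - 1e-12)`` instead of raising.
    """
    if clip:
        r = float(np.clip(r, -CLIP_BOUND, CLIP_BOUND))
    if not -1.0 < r < 1.0:
        raise DomainError(
            f"|R| must be < 1 for the Fisher transform, got {r}; "
            "pass clip=True to clip at 1 - 1e-12"
        )
    return float(np.arctanh(r))


def rewiring_score(
    r_low: float,
    r_high: float,
    n_low: int,
    n_high: int,
    convention: Literal["corrected", "literal"] = "corrected",
    clip: bool = False,
) -> float:
    """Standard-normal CDF of the standardised Fisher-z difference.

    ``corrected`` (default) returns ``Phi((F(Rhigh) - F(Rlow)) / SE)`` so a
    larger score means stronger release of the low-lncRNA coupling;
    ``literal`` returns the complement ``Phi(-(...))``.
    """
    if n_low <= 3 or n_high <= 3:
        raise DomainError(
            f"group sizes must exceed 3 (got n_low={n_low}, n_high={n_high})"
        )
    if convention not in ("corrected", "literal"):
        raise DomainError(f"unknown convention {convention!r}")
    z = (fisher_z(r_high, clip) - fisher_z(r_low, clip)) / math.sqrt(
        1.0 / (n_low - 3) + 1.0 / (n_high - 3)
    )
    if convention == "literal":
        z = -z
    return float(stats.norm.cdf(z))


def permutation_pvalue(
    mir_values: np.ndarray | pd.Series,
    mrna_values: np.ndarray | pd.Series,
    observed: float,
    fraction: float = GROUP_FRACTION,
    m: int = N_PERM,
    seed: int = 0,
    convention: Literal["corrected", "literal"] = "corrected",
    add_one: bool = False,
) -> tuple[float, int]:
    """Empirical p-value of an observed rewiring score.

    Each replicate draws a uniformly random disjoint (H, L) pair of size
    ``floor(fraction * n)`` (equivalent to re-sorting samples by a permuted
    lncRNA) and recomputes the score. The p-value is the fraction of
    replicates whose score is strictly greater than ``observed``; with
    ``add_one=True`` the (n+1)/(m+1) estimator is used instead. Replicates
    with an undefined correlation contribute no exceedance.
    """
    if m < 1:
        raise DomainError("m must be >= 1")
    if not 0.0 <= observed <= 1.0:
        raise DomainError("observed score must lie in [0, 1]")
    mir = np.asarray(mir_values, dtype=float)
    mrna = np.asarray(mrna_values, dtype=float)
    n = mir.size
    k = int(math.floor(fraction * n))
    if k <= 3:
        raise DataError(f"permutation groups of size {k} are too small (need > 3)")
    rng = np.random.default_rng(seed)
    perms = np.empty((m, n), dtype=np.intp)
    for i in range(m):
        perms[i] = rng.permutation(n)
    h_idx, l_idx = perms[:, :k], perms[:, n - k:]
    r_h = rowwise_spearman(mir[h_idx], mrna[h_idx])
    r_l = rowwise_spearman(mir[l_idx], mrna[l_idx])
    with np.errstate(invalid="ignore"):
        z = (
            np.arctanh(np.clip(r_h, -CLIP_BOUND, CLIP_BOUND))
            - np.arctanh(np.clip(r_l, -CLIP_BOUND, CLIP_BOUND))
        ) / math.sqrt(2.0 / (k - 3))
        if convention == "literal":
            z = -z
        scores = stats.norm.cdf(z)
    n_exceed = int(np.sum(scores > observed))  # NaN never exceeds
    if add_one:
        return (n_exceed + 1) / (m + 1), n_exceed
    return n_exceed / m, n_exceed


def triplet_seed(master_seed: int, lnc_id: str, mir_id: str, mrna_id: str) -> int:
    """Stable per-triplet permutation seed, independent of evaluation order."""
    digest = hashlib.sha256(
        f"{master_seed}:{lnc_id}:{mir_id}:{mrna_id}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def detect_triplets(
    candidates: Sequence,
    lnc_layer: ExpressionLayer,
    mir_layer: ExpressionLayer,
    mrna_layer: ExpressionLayer,
    params: DetectionParams | None = None,
) -> list[PerturbationResult]:
    """Run the full per-triplet perturbation screen.

    Every candidate is reported with all gate flags and statistics; the
    ``passed`` flag is the conjunction of the DE gates, the correlation
    gates and the permutation threshold. Deterministic given the data and
    ``params.seed``: each triplet's permutation stream is derived from the
    master seed by hashing its identifiers.
    """
    params = params or DetectionParams()
    splits: dict[str, GroupSplit] = {}
    results: list[PerturbationResult] = []
    for cand in candidates:
        lnc_id, mir_id, mrna_id = cand.lnc_id, cand.mir_id, cand.mrna_id
        if lnc_id not in splits:
            splits[lnc_id] = split_groups(
                lnc_layer.gene(lnc_id), params.fraction, lnc_id=lnc_id
            )
        split = splits[lnc_id]
        mir = mir_layer.gene(mir_id)
        mrna = mrna_layer.gene(mrna_id)
        de_mir = group_de_gate(
            mir, split, "down_in_H", params.de_alpha, params.min_fc,
            welch=params.welch, pseudocount=params.pseudocount,
        )
        de_mrna = group_de_gate(
            mrna, split, "up_in_H", params.de_alpha, params.min_fc,
            welch=params.welch, pseudocount=params.pseudocount,
        )
        r_low, _ = spearman(
            mir[split.l_samples].to_numpy(), mrna[split.l_samples].to_numpy()
        )
        r_high, _ = spearman(
            mir[split.h_samples].to_numpy(), mrna[split.h_samples].to_numpy()
        )
        if np.isnan(r_low) or np.isnan(r_high):
            results.append(
                PerturbationResult(
                    lnc_id, mir_id, mrna_id,
                    de_mir.passed, de_mir.p, de_mir.fc,
                    de_mrna.passed, de_mrna.p, de_mrna.fc,
                    split.n_low, split.n_high,
                    r_low, r_high, float("nan"), float("nan"), float("nan"),
                    params.n_perm, 0, float("nan"), False,
                )
            )
            continue
        f_low = fisher_z(r_low, clip=True)
        f_high = fisher_z(r_high, clip=True)
        score = rewiring_score(
            r_low, r_high, split.n_low, split.n_high,
            convention=params.convention, clip=True,
        )
        p_perm, n_exceed = permutation_pvalue(
            mir.to_numpy(), mrna.to_numpy(), score,
            fraction=params.fraction, m=params.n_perm,
            seed=triplet_seed(params.seed, lnc_id, mir_id, mrna_id),
            convention=params.convention, add_one=params.add_one,
        )
        corr_ok = (
            r_low < params.rlow_max
            and r_high >= r_low
            and abs(r_low - r_high) > params.min_delta_r
        )
        passed = bool(
            de_mir.passed and de_mrna.passed and corr_ok and p_perm < params.perm_alpha
        )
        results.append(
            PerturbationResult(
                lnc_id, mir_id, mrna_id,
                de_mir.passed, de_mir.p, de_mir.fc,
                de_mrna.passed, de_mrna.p, de_mrna.fc,
                split.n_low, split.n_high,
                float(r_low), float(r_high), f_low, f_high, score,
                params.n_perm, n_exceed, p_perm, passed,
            )
        )
    return results


def results_to_frame(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Tabulate detection results for TSV export."""
    return pd.DataFrame(
        [[getattr(r, col) for col in RESULT_COLUMNS] for r in results],
        columns=RESULT_COLUMNS,
    )
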