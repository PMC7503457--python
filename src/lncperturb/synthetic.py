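"""Synthetic tri-layer cohort generator with planted lncRNA-perturbated triplets.

The generator emulates the statistical structure the detection pipeline
assumes: matched lncRNA/miRNA/mRNA log2 expression matrices in which, for
each *planted* triplet, the miRNA represses the mRNA with a slope that is
attenuated at high lncRNA expression, among fully independent decoys. It
also emits a miRNA-target interaction table, tumor-purity values and
proportional-hazards survival times with known coefficients, plus a registry
of the planted triplets, so every downstream stage can be tested without any
external download.

Generative model
----------------
For each planted triplet, with per-sample lncRNA z-score ``z_l``:

* ``lnc = mu + sd * z_l`` (i.i.d. standard normal ``z_l``);
* ``mir = mu + sd * (-rho * z_l + sqrt(1 - rho^2) * eps)`` — a Gaussian
  copula giving the miRNA a negative rank correlation of about ``rho`` with
  the lncRNA;
* ``mrna = intercept + c(q) * mir + noise``, where ``q`` is the lncRNA's
  within-cohort quantile and ``c`` interpolates linearly from
  ``coupling_low`` (lowest lncRNA) to ``coupling_high`` (highest lncRNA).

Decoy genes are mutually independent draws. Every triplet *unit* (planted or
decoy) additionally receives ``n_support_mirnas`` shared "support" miRNAs in
the interaction table so the unit can pass the shared-miRNA hypergeometric
screen; support miRNAs have independent expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io
from .exceptions import ConfigError, DataError
from .layers import ExpressionLayer

#: baseline hazard so that a sample at the mean linear predictor has a
#: median survival of ~2 years (time unit: days)
BASELINE_HAZARD = np.log(2) / 730.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults define the study conditions used throughout the test-suite:
    strong repression in the low-lncRNA quartile (slope -0.9) fully released
    in the high quartile (slope 0), log2 abundances around 5 +/- 1, moderate
    noise, and survival driven by known Cox coefficients.
    """

    n_samples: int = 200
    n_planted: int = 20
    n_decoy_lnc: int = 30
    n_decoy_mir: int = 30
    n_decoy_mrna: int = 30
    coupling_low: float = -0.9
    coupling_high: float = 0.0
    noise_sd: float = 0.5
    base_expression_mean: float = 5.0
    base_expression_sd: float = 1.0
    mir_lnc_rho: float = 0.4
    purity_mean: float = 0.9
    purity_sd: float = 0.05
    low_purity_fraction: float = 0.0
    survival_coeffs: tuple[float, float, float] = (1.0, -1.0, 0.5)
    censor_rate: float = 0.3
    n_support_mirnas: int = 5
    log2_output: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 32:
            raise ConfigError("n_samples must be >= 32 (quartile groups need n-3 > 0)")
        for name in ("n_planted", "n_decoy_lnc", "n_decoy_mir", "n_decoy_mrna",
                     "n_support_mirnas"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not self.coupling_low < 0:
            raise ConfigError("coupling_low must be negative")
        if abs(self.coupling_high) > abs(self.coupling_low):
            raise ConfigError(
                "coupling_high magnitude must not exceed coupling_low magnitude"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 < self.purity_mean < 1:
            raise ConfigError("purity_mean must lie in (0, 1)")
        if self.purity_sd <= 0:
            raise ConfigError("purity_sd must be positive")
        if not 0 <= self.low_purity_fraction <= 1:
            raise ConfigError("low_purity_fraction must lie in [0, 1]")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigError("censor_rate must lie in [0, 1]")
        if len(self.survival_coeffs) != 3 or not all(
            np.isfinite(c) for c in self.survival_coeffs
        ):
            raise ConfigError("survival_coeffs must be three finite reals")
        if not 0.05 <= self.mir_lnc_rho <= 0.95:
            raise ConfigError("mir_lnc_rho must lie in [0.05, 0.95]")


@dataclass
class SyntheticCohort:
    """Generated tri-layer cohort plus metadata tables.

    All tables share one identical, ordered sample set. ``truth`` lists the
    planted (lncRNA, miRNA, mRNA) identifier triples.
    """

    lnc_layer: ExpressionLayer
    mir_layer: ExpressionLayer
    mrna_layer: ExpressionLayer
    interactions: pd.DataFrame
    purity: pd.Series
    clinical: pd.DataFrame
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        samples = self.lnc_layer.sample_ids
        for layer in (self.mir_layer, self.mrna_layer):
            if layer.sample_ids != samples:
                raise DataError("cohort layers do not share an ordered sample set")
        if list(self.purity.index) != samples or list(self.clinical.index) != samples:
            raise DataError("purity/clinical tables do not match the layer samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.lnc_layer.sample_ids


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``config``.

    Planted triplets follow the attenuated-repression model described in the
    module docstring; decoys are independent draws. The result is
    byte-identical for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    mu, sd = config.base_expression_mean, config.base_expression_sd
    rho = config.mir_lnc_rho
    samples = [f"S{i + 1:04d}" for i in range(n)]

    lnc_rows: dict[str, np.ndarray] = {}
    mir_rows: dict[str, np.ndarray] = {}
    mrna_rows: dict[str, np.ndarray] = {}
    interactions: list[tuple[str, str, str]] = []
    truth_records: list[tuple[str, str, str]] = []

    def support_ids(unit: str) -> list[str]:
        return [f"mir-sup-{unit}-{j + 1}" for j in range(config.n_support_mirnas)]

    # planted units -----------------------------------------------------
    for i in range(config.n_planted):
        lid, mid, rid = f"lnc-p{i + 1:04d}", f"mir-p{i + 1:04d}", f"mrna-p{i + 1:04d}"
        z_l = rng.standard_normal(n)
        lnc = mu + sd * z_l
        z_m = -rho * z_l + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        mir = np.clip(mu + sd * z_m, 0.0, None)
        # within-cohort quantile of the lncRNA drives the coupling strength
        q = np.argsort(np.argsort(lnc)) / (n - 1)
        c = config.coupling_low + q * (config.coupling_high - config.coupling_low)
        intercept = mu + abs(config.coupling_low) * mu
        mrna = np.clip(
            intercept + c * mir + config.noise_sd * rng.standard_normal(n), 0.0, None
        )
        lnc_rows[lid] = np.clip(lnc, 0.0, None)
        mir_rows[mid] = mir
        mrna_rows[rid] = mrna
        interactions.append((mid, lid, "lncRNA"))
        interactions.append((mid, rid, "mRNA"))
        for sup in support_ids(f"p{i + 1:04d}"):
            mir_rows[sup] = np.clip(mu + sd * rng.standard_normal(n), 0.0, None)
            interactions.append((sup, lid, "lncRNA"))
            interactions.append((sup, rid, "mRNA"))
        truth_records.append((lid, mid, rid))

    # decoy units (zipped) and surplus unlinked decoys ------------------
    n_units = min(config.n_decoy_lnc, config.n_decoy_mir, config.n_decoy_mrna)

    def indep() -> np.ndarray:
        return np.clip(mu + sd * rng.standard_normal(n), 0.0, None)

    for i in range(config.n_decoy_lnc):
        lnc_rows[f"lnc-d{i + 1:04d}"] = indep()
    for i in range(config.n_decoy_mir):
        mir_rows[f"mir-d{i + 1:04d}"] = indep()
    for i in range(config.n_decoy_mrna):
        mrna_rows[f"mrna-d{i + 1:04d}"] = indep()
    for i in range(n_units):
        lid, mid, rid = f"lnc-d{i + 1:04d}", f"mir-d{i + 1:04d}", f"mrna-d{i + 1:04d}"
        interactions.append((mid, lid, "lncRNA"))
        interactions.append((mid, rid, "mRNA"))
        for sup in support_ids(f"d{i + 1:04d}"):
            mir_rows[sup] = indep()
            interactions.append((sup, lid, "lncRNA"))
            interactions.append((sup, rid, "mRNA"))

    def build_layer(rows: dict[str, np.ndarray], layer_class: str) -> ExpressionLayer:
        data = pd.DataFrame(rows, index=samples).T
        if not config.log2_output:
            data = np.power(2.0, data) - 1.0
        return ExpressionLayer(
            layer_class=layer_class, data=data, is_log2=config.log2_output
        )

    lnc_layer = build_layer(lnc_rows, "lncRNA")
    mir_layer = build_layer(mir_rows, "miRNA")
    mrna_layer = build_layer(mrna_rows, "mRNA")

    # purity: truncated normal on (0, 1); optionally force a fraction < 0.8
    a = (0.0 - config.purity_mean) / config.purity_sd
    b = (1.0 - config.purity_mean) / config.purity_sd
    purity_vals = stats.truncnorm.rvs(
        a, b, loc=config.purity_mean, scale=config.purity_sd, size=n, random_state=rng
    )
    n_low = int(np.floor(config.low_purity_fraction * n))
    if n_low:
        which = rng.choice(n, size=n_low, replace=False)
        purity_vals[which] = rng.uniform(0.5, 0.8, size=n_low)
    purity = pd.Series(purity_vals, index=samples, name="purity").rename_axis(
        "sample_id"
    )

    # survival driven by the first planted triplet (null model if none)
    if truth_records:
        lid, mid, rid = truth_records[0]
        expr = np.column_stack(
            [lnc_rows[lid], mir_rows[mid], mrna_rows[rid]]
        )
    else:
        expr = np.zeros((n, 3))
    clinical = generate_survival(
        pd.DataFrame(expr, index=samples, columns=["lnc", "mir", "mrna"]),
        config.survival_coeffs,
        config.censor_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    interactions_df = pd.DataFrame(
        interactions, columns=io.INTERACTION_COLUMNS
    ).drop_duplicates(ignore_index=True)
    truth_df = pd.DataFrame(truth_records, columns=io.TRUTH_COLUMNS)
    return SyntheticCohort(
        lnc_layer=lnc_layer,
        mir_layer=mir_layer,
        mrna_layer=mrna_layer,
        interactions=interactions_df,
        purity=purity,
        clinical=clinical,
        truth=truth_df,
    )


def generate_survival(
    expr: pd.DataFrame | np.ndarray,
    coeffs: Sequence[float],
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Draw proportional-hazards survival times from expression covariates.

    Event times are exponential with per-sample hazard
    ``h0 * exp(sum_j coeffs[j] * (x_ij - mean_j))``; censoring times are
    independent exponentials whose rate is solved numerically so that the
    expected censored fraction equals ``censor_rate``.

    Returns a clinical table indexed by sample with columns ``time`` (days)
    and ``event`` (1 = death, 0 = censored). Deterministic per seed.
    """
    if not 0 <= censor_rate <= 1:
        raise ConfigError("censor_rate must lie in [0, 1]")
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ConfigError("survival coefficients must be finite")
    if isinstance(expr, pd.DataFrame):
        index = expr.index
        x = expr.to_numpy(dtype=float)
    else:
        x = np.asarray(expr, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if x.ndim != 2 or x.shape[1] != coeffs.size:
        raise ConfigError(
            f"expression must be (n_samples, {coeffs.size}) to match the coefficients"
        )
    rng = np.random.default_rng(seed)
    lp = (x - x.mean(axis=0)) @ coeffs
    hazards = BASELINE_HAZARD * np.exp(lp)
    event_times = rng.exponential(1.0 / hazards)
    event_times = np.maximum(event_times, 1e-6)

    if censor_rate == 0:
        time, event = event_times, np.ones(x.shape[0], dtype=int)
    elif censor_rate == 1:
        time, event = event_times, np.zeros(x.shape[0], dtype=int)
    else:
        def censored_fraction(theta: float) -> float:
            return float(np.mean(theta / (theta + hazards))) - censor_rate

        hi = hazards.max()
        while censored_fraction(hi) < 0:
            hi *= 4.0
        theta = optimize.brentq(censored_fraction, 0.0, hi)
        censor_times = rng.exponential(1.0 / theta, size=x.shape[0])
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)
        time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": event}, index=index).rename_axis(
        "sample_id"
    )


#: file names emitted by :func:`write_fixture`
FIXTURE_FILES = {
    "lnc_layer": "lnc_expression.tsv",
    "mir_layer": "mir_expression.tsv",
    "mrna_layer": "mrna_expression.tsv",
    "interactions": "interactions.tsv",
    "purity": "purity.tsv",
    "clinical": "clinical.tsv",
    "truth": "truth.tsv",
}


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's tab-separated dialects.

    Returns a manifest mapping logical names to written paths (7 files).
    Round-trips losslessly through the :mod:`lncperturb.io` readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {k: directory / v for k, v in FIXTURE_FILES.items()}
        io.write_expression(cohort.lnc_layer, manifest["lnc_layer"])
        io.write_expression(cohort.mir_layer, manifest["mir_layer"])
        io.write_expression(cohort.mrna_layer, manifest["mrna_layer"])
        io.write_interactions(cohort.interactions, manifest["interactions"])
        io.write_purity(cohort.purity, manifest["purity"])
        io.write_clinical(cohort.clinical, manifest["clinical"])
        io.write_truth(cohort.truth, manifest["truth"])
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return manifest


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort previously written by :func:`write_fixture`."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    return SyntheticCohort(
        lnc_layer=io.read_expression(paths["lnc_layer"], "lncRNA"),
        mir_layer=io.read_expression(paths["mir_layer"], "miRNA"),
        mrna_layer=io.read_expression(paths["mrna_layer"], "mRNA"),
        interactions=io.read_interactions(paths["interactions"]),
        purity=io.read_purity(paths["purity"]),
        clinical=io.read_clinical(paths["clinical"]),
        truth=io.read_truth(paths["truth"]),
    )
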