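"""End-to-end orchestration: preprocessing, candidate screen, perturbation
detection and prognosis, with stage-level reporting and deterministic seeds.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, candidates as cand_mod, io, perturbation, preprocess, prognosis
from .exceptions import DataError, FitError, LncPerturbError
from .layers import ExpressionLayer


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults reproduce the framework's reference settings: purity
    > 0.8, low-expression rule log2 < 1 in > 70% of samples, log2 IQR >
    0.58, shared-miRNA FDR < 0.05, 25% H/L groups, DE p < 0.05 with
    fold-change > 1.5, Rlow < -0.4, |dR| > 0.3, 100 permutations with
    empirical p < 0.01, signature alpha 0.05.
    """

    # input paths
    lnc_expression: str = ""
    mir_expression: str = ""
    mrna_expression: str = ""
    interactions: str = ""
    purity: str = ""
    clinical: str = ""
    output_dir: str = ""
    # preprocessing
    already_log2: bool = True
    pseudocount: float = 1.0
    purity_threshold: float = 0.8
    min_log2: float = 1.0
    max_fraction_below: float = 0.7
    min_iqr: float = 0.58
    # candidate screen
    fdr: float = 0.05
    scc_alpha: float = 0.05
    universe: str = "expressed"
    # perturbation detection
    fraction: float = 0.25
    de_alpha: float = 0.05
    min_fc: float = 1.5
    rlow_max: float = -0.4
    min_delta_r: float = 0.3
    n_perm: int = 100
    perm_alpha: float = 0.01
    convention: str = "corrected"
    welch: bool = False
    # prognosis
    cox_mode: str = "joint"
    signature_alpha: float = 0.05
    run_prognosis: bool = True
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems (empty = valid)."""
    problems: list[str] = []

    def check(cond: bool, message: str) -> None:
        if not cond:
            problems.append(message)

    check(0 <= config.purity_threshold <= 1, "purity_threshold must lie in [0, 1]")
    check(config.min_log2 >= 0, "min_log2 must be non-negative")
    check(0 <= config.max_fraction_below <= 1, "max_fraction_below must lie in [0, 1]")
    check(config.min_iqr >= 0, "min_iqr must be non-negative")
    check(0 < config.fdr <= 1, "fdr must lie in (0, 1]")
    check(0 < config.scc_alpha <= 1, "scc_alpha must lie in (0, 1]")
    check(config.universe in ("expressed", "all"),
          "universe must be 'expressed' or 'all'")
    check(0 < config.fraction <= 0.5,
          "fraction must lie in (0, 0.5] so the H- and L-groups are disjoint")
    check(0 < config.de_alpha <= 1, "de_alpha must lie in (0, 1]")
    check(config.min_fc > 0, "min_fc must be positive")
    check(-1 < config.rlow_max < 1, "rlow_max must lie in (-1, 1)")
    check(0 <= config.min_delta_r < 2, "min_delta_r must lie in [0, 2)")
    check(config.n_perm >= 1, "n_perm must be >= 1")
    check(0 < config.perm_alpha <= 1, "perm_alpha must lie in (0, 1]")
    check(config.convention in ("corrected", "literal"),
          "convention must be 'corrected' or 'literal'")
    check(config.cox_mode in ("joint", "univariate"),
          "cox_mode must be 'joint' or 'univariate'")
    check(0 < config.signature_alpha <= 1, "signature_alpha must lie in (0, 1]")
    check(config.pseudocount >= 0, "pseudocount must be non-negative")
    check(config.seed >= 0, "seed must be non-negative")
    return problems


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    seconds: float
    unit: str


@dataclass
class RunReport:
    """Per-stage record counts and timings for one run."""

    stages: list[StageRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def add(self, stage: str, n_in: int, n_out: int, seconds: float, unit: str) -> None:
        self.stages.append(StageRecord(stage, n_in, n_out, round(seconds, 3), unit))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.stages])

    def to_text(self) -> str:
        lines = [f"lncperturb {self.version} run report"]
        for s in self.stages:
            lines.append(
                f"  {s.stage:<24} {s.n_in:>7} -> {s.n_out:<7} {s.unit:<10}"
                f" ({s.seconds:.3f}s)"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config,
             "stages": [asdict(s) for s in self.stages]},
            indent=2,
        )


@dataclass
class PipelineResult:
    triplets: pd.DataFrame
    prognosis: pd.DataFrame
    report: RunReport
    layers: tuple[ExpressionLayer, ExpressionLayer, ExpressionLayer] | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute preprocess -> candidates -> detection -> prognosis.

    Writes the triplet table, prognosis table and run report under
    ``config.output_dir`` when set. Fully deterministic per master seed.
    """
    problems = validate_config(config)
    if problems:
        raise DataError("invalid configuration: " + "; ".join(problems))
    report = RunReport(config=asdict(config))

    # ---- load --------------------------------------------------------
    lnc = io.read_expression(config.lnc_expression, "lncRNA", is_log2=config.already_log2)
    mir = io.read_expression(config.mir_expression, "miRNA", is_log2=config.already_log2)
    mrna = io.read_expression(config.mrna_expression, "mRNA", is_log2=config.already_log2)
    purity = io.read_purity(config.purity)
    interactions = cand_mod.InteractionSet(io.read_interactions(config.interactions))
    clinical = io.read_clinical(config.clinical) if config.clinical else None

    # ---- preprocess --------------------------------------------------
    t0 = time.perf_counter()
    n_in = max(layer.n_samples for layer in (lnc, mir, mrna))
    lnc, mir, mrna = preprocess.match_samples(lnc, mir, mrna)
    report.add("match_samples", n_in, lnc.n_samples, time.perf_counter() - t0, "samples")

    t0 = time.perf_counter()
    n_in = lnc.n_samples
    kept = preprocess.filter_by_purity(lnc, purity, config.purity_threshold).sample_ids
    lnc, mir, mrna = (layer.select_samples(kept) for layer in (lnc, mir, mrna))
    report.add("purity_filter", n_in, len(kept), time.perf_counter() - t0, "samples")

    if not config.already_log2:
        lnc, mir, mrna = (
            preprocess.log2_transform(layer, config.pseudocount)
            for layer in (lnc, mir, mrna)
        )

    t0 = time.perf_counter()
    n_in = lnc.n_genes + mir.n_genes + mrna.n_genes
    lnc, mir, mrna = (
        preprocess.filter_low_expression(layer, config.min_log2, config.max_fraction_below)
        for layer in (lnc, mir, mrna)
    )
    report.add("low_expression_filter", n_in, lnc.n_genes + mir.n_genes + mrna.n_genes,
               time.perf_counter() - t0, "genes")

    t0 = time.perf_counter()
    n_in = lnc.n_genes + mir.n_genes + mrna.n_genes
    lnc, mir, mrna = (
        preprocess.filter_by_iqr(layer, config.min_iqr) for layer in (lnc, mir, mrna)
    )
    report.add("iqr_filter", n_in, lnc.n_genes + mir.n_genes + mrna.n_genes,
               time.perf_counter() - t0, "genes")

    # ---- candidate screen -------------------------------------------
    t0 = time.perf_counter()
    cands = cand_mod.build_candidates(
        interactions, lnc, mir, mrna,
        fdr_threshold=config.fdr, universe=config.universe,
    )
    report.add("shared_mirna_screen", len(interactions.pairs), len(cands),
               time.perf_counter() - t0, "candidates")

    t0 = time.perf_counter()
    n_in = len(cands)
    cands = cand_mod.negative_pair_filter(cands, mir, mrna, alpha=config.scc_alpha)
    report.add("negative_pair_filter", n_in, len(cands),
               time.perf_counter() - t0, "candidates")

    # ---- perturbation detection -------------------------------------
    t0 = time.perf_counter()
    params = perturbation.DetectionParams(
        fraction=config.fraction, de_alpha=config.de_alpha, min_fc=config.min_fc,
        rlow_max=config.rlow_max, min_delta_r=config.min_delta_r,
        n_perm=config.n_perm, perm_alpha=config.perm_alpha,
        convention=config.convention, welch=config.welch,
        pseudocount=config.pseudocount, seed=config.seed,
    )
    results = perturbation.detect_triplets(cands, lnc, mir, mrna, params)
    triplets = perturbation.results_to_frame(results)
    n_passed = int(triplets["passed"].sum()) if len(triplets) else 0
    report.add("perturbation_detection", len(cands), n_passed,
               time.perf_counter() - t0, "triplets")

    # ---- prognosis ---------------------------------------------------
    models: list[prognosis.RiskModel] = []
    if config.run_prognosis and clinical is not None and n_passed:
        t0 = time.perf_counter()
        passed = triplets[triplets["passed"]]
        for lnc_id, mir_id, mrna_id in passed[["lnc_id", "mir_id", "mrna_id"]].itertuples(
            index=False
        ):
            try:
                models.append(
                    prognosis.evaluate_triplet(
                        lnc_id, mir_id, mrna_id, lnc, mir, mrna, clinical,
                        cox_mode=config.cox_mode, alpha=config.signature_alpha,
                    )
                )
            except (DataError, FitError) as exc:
                warnings.warn(
                    f"prognosis skipped for ({lnc_id}, {mir_id}, {mrna_id}): {exc}",
                    stacklevel=2,
                )
        report.add("prognosis", n_passed, len(models),
                   time.perf_counter() - t0, "signatures")
    prog_frame = prognosis.models_to_frame(models)

    result = PipelineResult(triplets=triplets, prognosis=prog_frame, report=report,
                            layers=(lnc, mir, mrna))
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_frame(triplets, outdir / "triplets.tsv")
        io.write_frame(prog_frame, outdir / "prognosis.tsv")
        (outdir / "report.txt").write_text(report.to_text() + "\n")
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return result
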