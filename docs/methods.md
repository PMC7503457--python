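# Methods

## The model

`lncperturb` detects *lncRNA-perturbated triplets*: (lncRNA, miRNA, mRNA)
trios in which the repressive miRNA-mRNA correlation present at low lncRNA
expression is released at high lncRNA expression. The underlying biological
picture is the sponge/ceRNA mechanism — an abundant lncRNA sequesters a
shared miRNA and thereby de-represses the miRNA's mRNA targets — but the
statistic is agnostic to mechanism: it only asks whether the conditional
miRNA-mRNA correlation is rewired across lncRNA strata.

The pipeline has four stages.

**1. Preprocessing.** Samples must carry matched profiles in all three RNA
layers; tumor samples with ESTIMATE-style purity ≤ 0.8 are removed (strict
`>`), values are log2(x+1), genes below 1 (log2) in strictly more than 70%
of samples are dropped, and genes with log2 IQR ≤ 0.58 are dropped.
Quantiles use linear interpolation between order statistics (the type-7
convention, numpy's default), which makes the 0.58 boundary exactly
testable. The driver applies purity before the low-expression rule; the
order is configurable but low-expression fractions are always computed on
the sample set the filter actually sees.

**2. Candidate screen.** miRNA-lncRNA and miRNA-mRNA interaction pairs are
merged into triplets. For a lncRNA with `L` interacting miRNAs and an mRNA
with `M`, sharing `x` from a universe of `N`, the upper-tail hypergeometric
probability

  P = 1 − Σ_{i=0}^{x−1} C(L,i) C(N−L, M−i) / C(N,M)

is Benjamini-Hochberg corrected across all lncRNA-mRNA pairs tested in the
run; pairs with q < 0.05 fan out into one candidate per shared miRNA that is
present in the miRNA expression layer (a shared miRNA without expression
contributes evidence to `x` but cannot be correlated downstream). The
default universe is the interaction background restricted to expressed
miRNAs, which keeps the test conditional on observable data; `universe=all`
uses the unrestricted table. Candidates are then gated on a negative,
significant all-sample Spearman correlation between miRNA and mRNA
(R < 0, p < 0.05; exact permutation p below n = 10, t-approximation above).

**3. Perturbation detection.** For each candidate, samples are sorted by the
lncRNA (descending, ties broken by sample ID for reproducibility); the top
and bottom `floor(0.25 n)` form the H- and L-groups. Gates:

* miRNA down-regulated in H and mRNA up-regulated in H (two-sided Student's
  t on log2 values — Welch behind a flag — and linear-scale fold-change of
  back-transformed group means strictly above 1.5);
* within-stratum Spearman correlations with R_low < −0.4, R_high ≥ R_low
  and |R_low − R_high| > 0.3;
* a permutation-calibrated rewiring score.

The rewiring score standardises the Fisher-transformed correlation
difference, F(R) = atanh(R), Var ≈ 1/(n−3) per stratum:

  Z = (F(R_high) − F(R_low)) / sqrt(1/(n_low−3) + 1/(n_high−3)),
  score = Φ(Z) ∈ (0, 1).

The default orientation ("corrected") makes large scores mean strong
release of the low-lncRNA coupling, which is the direction every other part
of the procedure assumes (a larger score is more extreme, and the empirical
p counts random scores *larger* than the observed one). The opposite
orientation, Φ(−Z), is retained as `convention="literal"` for comparison
with formulations that print the difference the other way; the two always
sum to 1. Perfectly monotone strata (|R| = 1, possible in small groups) are
clipped to 1 − 1e−12 before the transform inside the pipeline; the public
`fisher_z` raises unless clipping is requested explicitly.

The permutation p draws m = 100 uniformly random disjoint (H, L) pairs of
the same sizes — equivalent to re-sorting samples by a permuted lncRNA —
recomputes only the score (the DE gates are not re-applied), and reports
the fraction of replicates strictly exceeding the observed score. The
estimator is the literal n/m (so p < 0.01 at m = 100 requires zero
exceedances); the (n+1)/(m+1) estimator is available behind `add_one`.
Per-triplet permutation streams are derived from the master seed by hashing
the triplet identifiers, so results do not depend on evaluation order.

**4. Prognosis.** Each passed triplet yields a composite risk score
α·lnc_i + β·mir_i + γ·mrna_i on the pipeline's log2 working scale. By
default (α, β, γ) come from one joint three-covariate Cox proportional-
hazards fit, the standard construction for composite signatures; the
`univariate` mode reuses the three single-covariate coefficients instead,
since either reading is defensible where the source of the coefficients is
ambiguous. Samples are split at the mean risk score (ties go to the low
group) and compared with a two-group log-rank test. A triplet with log-rank
p < 0.05 whose three univariate element fits are all non-significant
(p ≥ 0.05) is classified *functions_together* — joint prognostic value with
no individually prognostic member. Cox fitting, the log-rank test and the
Kaplan-Meier estimator are delegated to `lifelines` (Breslow ties).

**Annotation.** Descriptive layers: exon-averaged per-base conservation
(exons unioned across transcripts so overlapping bases count once; strand
ignored since the scores are strand-symmetric; 0-based half-open coordinates
throughout, BED read natively, GTF converted on input), a two-sided
rank-sum comparison of conservation between gene groups (exact null when
both groups are ≤ 25 and tie-free), tumor-vs-normal DE on log2 values
(|log2FC| > 1 and BH FDR < 0.05, both strict; log2FC as the difference of
log2 means), and copy-number / non-silent-mutation frequency summaries
(amplifications and deletions jointly count as altered, with per-direction
fractions also reported).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset. Per planted triplet, with z the lncRNA z-score:

* lncRNA = μ + σz, i.i.d. normal on the log2 scale (values clipped at 0);
* miRNA = μ + σ(−ρz + sqrt(1−ρ²)ε): a Gaussian copula giving a negative
  rank correlation ≈ ρ with the lncRNA (ρ controls the Spearman target
  directly; default 0.4);
* mRNA = intercept + c(q)·miRNA + noise, where q is the lncRNA's
  within-cohort quantile and c interpolates linearly from `coupling_low`
  (default −0.9) to `coupling_high` (default 0) — the simplest monotone
  attenuation of the repression;
* intercept = μ + |coupling_low|·μ keeps mRNA values positive.

Defaults: μ = 5, σ = 1 (log2 scale), noise_sd = 0.5. Monte-Carlo checks at
n = 400 give within-quartile R_low ≈ −0.78, R_high ≈ −0.24, with the
R_low < −0.4 and ΔR > 0.3 conditions met in ≥ 97% of planted draws and both
DE gates in ≈ 100%; fully independent decoys satisfy them at far below
chance rates. Every triplet unit (planted or decoy) additionally receives
`n_support_mirnas` (default 5) shared "support" miRNAs in the interaction
table, with independent expression: with only one shared miRNA per unit the
hypergeometric q-values would be ≈ 1 for every pair and nothing would
survive the candidate screen, so the supports are what make units
screen-eligible by construction.

Purity is a truncated normal on (0, 1) (default 0.9 ± 0.05), with an
optional forced low-purity fraction to exercise the purity filter. Survival
times are exponential with hazard h0·exp(α·lnc + β·mir + γ·mrna) on
centered expression (h0 set so the median survival at the mean predictor is
about two years, in days); censoring is an independent exponential whose
rate is solved numerically so the expected censored fraction equals
`censor_rate` (the 0 and 1 endpoints are handled exactly). In a generated
cohort, survival is driven by the first planted triplet.

What the generator does *not* emulate: read counts and library-size
effects, batch effects, copy-number-driven expression, multiple miRNAs
coupling into one planted triplet, or the effect-size distributions of real
tumor cohorts.
Passing the recovery and calibration tests therefore demonstrates that the
statistics behave as designed under their own assumptions — not that the
thresholds are optimal for any real cohort.

## Numerical choices and problem sizes

* Hypergeometric tail via `scipy.stats.hypergeom.sf` (log-space internally);
  tests compare it against an exact-rational enumeration oracle over every
  configuration with N ≤ 12 (3,184 cases, max |error| ~ 1e-16).
* Spearman with average ranks for ties in all strata; two-sided p from the
  t-approximation for n ≥ 10 and full rank-permutation enumeration below.
* BH correction via `statsmodels.stats.multitest.multipletests`.
* Degenerate inputs: constant vectors yield undefined correlations and the
  affected candidate is dropped (warning) or the permutation replicate
  contributes no exceedance; an all-tied lncRNA still splits deterministically
  by the sample-ID tie-break (warning).
* Cox fits: lifelines defaults (Newton, Breslow ties); non-convergence is
  surfaced as a fit error and the affected triplet is skipped with a warning
  in the pipeline driver.
* Test and acceptance problem sizes — n = 400 with 20 planted triplets
  among ≈ 600 candidates for recovery, n = 200 with ≈ 480 decoy triplets
  for null calibration, 100 replicates of n = 300 for survival recovery —
  are chosen to give stable Monte-Carlo estimates in minutes on one core.

## Known limitations

* The rewiring statistic is correlational; it cannot distinguish sponge
  activity from co-regulation or confounding by an unobserved stratifier.
* The empirical p at m = 100 has resolution 0.01, so the p < 0.01 threshold
  means "no exceedance in 100"; raise `n_perm` for finer resolution.
* No multiple-testing correction is applied across triplets at the
  permutation stage (by design; the raw empirical p with a 0.01 cut is the
  decision rule).
* The DE gate's fold-change uses back-transformed linear means, which is
  sensitive to the pseudocount for genes near zero.
* Clinical covariate adjustment (stage, age) and time-dependent effects are
  out of scope for the prognosis module.
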