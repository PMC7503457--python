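# Toy fixture: 12 genes x 20 samples, hand-computed survivors

A deterministic miniature cohort whose outcome at every pipeline stage is
derived by hand. Used by the acceptance test that checks exact stage counts.

Layers: 4 lncRNAs, 4 miRNAs, 4 mRNAs over samples S01..S20.

Expected survivors per stage:

| stage | in | out | reason |
|---|---|---|---|
| sample matching | 20 | 20 | all samples shared |
| purity filter (> 0.8, strict) | 20 | 16 | S17 = 0.80, S18 = 0.79, S19 = 0.50, S20 = 0.30 removed |
| low-expression (< 1 in > 70%) | 12 genes | 11 | lnc4 is < 1 in 12/16 = 75% of kept samples |
| IQR filter (> 0.58, type-7) | 11 | 9 | mir4 constant (IQR 0); mrna4 IQR 0.2 |
| shared-miRNA screen (`universe=all`, N = 40) | 4 pairs tested | 1 pair, 3 candidates | (lnc1, mrna1) shares x = 5 of L = M = 5 miRNAs: p = 1/C(40,5) ~ 1.52e-6, q ~ 6.1e-6; the other three pairs share only mir3 (p ~ 0.507). The pair fans out to its 3 *expressed* shared miRNAs (b01, b02 have no expression rows) |
| negative SCC gate | 3 | 1 | mir1~mrna1 R ~ -0.97; mir2~mrna1 is positive; mir3~mrna1 is near zero (p ~ 0.55) |
| detection gates | 1 | 1 | see below |

Detection of (lnc1, mir1, mrna1): lnc1 is strictly descending over S01..S16,
so H = {S01..S04}, L = {S13..S16} (floor(0.25 x 16) = 4 per group).

* miRNA gate (down in H): linear means ~1.02 (H) vs ~7.31 (L), fc ~ 7.2, t-test p << 0.05.
* mRNA gate (up in H): linear means ~34.6 (H) vs ~1.08 (L), fc ~ 32.
* Within-L ranks of (mir1, mrna1) are exactly reversed: R_low = -1
  (clipped to 1 - 1e-12 before the Fisher transform).
* Within-H ranks (2,4,1,3) vs (1,4,2,3): sum of d^2 = 2, R_high = 1 - 12/60 = 0.8.
* Gates: R_low < -0.4, R_high >= R_low, |dR| = 1.8 > 0.3.
* Z = (F(0.8) - F(-1|clip)) / sqrt(2) ~ (1.0986 + 14.1) / 1.414 ~ 10.8, so the
  rewiring score is 1.0 in double precision and no random stratification can
  strictly exceed it: p_perm = 0 for every permutation seed.

The background miRNAs b14..b40 interact only with an unexpressed target
(`mrna-x`); under `universe=all` they enlarge the hypergeometric background
to N = 40 without being testable pairs themselves.

`clinical.tsv` holds arbitrary mixed survival times (10 events / 10 censored)
so the prognosis stage runs; its output is not part of the hand-computed
expectations.
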