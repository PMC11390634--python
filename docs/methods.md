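# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the limitations of `dtmr`.

## Two-sample drug-target MR

The pipeline treats genetic variants near a drug's target genes as
instruments for pharmacological modulation of the exposure (systolic blood
pressure, SBP, in mmHg). For variant *i*, the exposure GWAS supplies an
effect β̂ₓᵢ with SE σₓᵢ, and the outcome GWAS a log-odds effect β̂ᵧᵢ with SE
σᵧᵢ. Three assumptions underpin the causal reading: relevance (enforced
via genome-wide significance and the F > 10 rule), independence from
confounders (supported by the positive-control gate and the confounder
blocklist), and exclusion restriction (probed by the sensitivity battery).

### Instrument construction

* **Gene windows**: a variant is a candidate iff p < 5×10⁻⁸ and its
  position lies within ±100 kb of a target gene on the same chromosome.
  The window is inclusive at both edges — the conservative reading of
  "±100 kb". Coordinates are 1-based inclusive in memory; BED input is
  converted on read.
* **Clumping**: greedy by ascending p-value, accepting a variant iff its
  r² with every already accepted variant is below 0.1 (strict). P-value
  ties break toward the lexicographically smaller variant id, which makes
  the output invariant to input row order. Pairs absent from the LD table
  are treated as unlinked and logged — mirroring reference-panel sparsity —
  so users can audit the assumption.
* **Palindromes**: A/T and G/C variants are excluded unconditionally, with
  no allele-frequency rescue; ambiguity of strand cannot be resolved from
  alleles alone and the cost of dropping them is small at typical panel
  densities.
* **Proxies**: an instrument absent from an outcome dataset may be replaced
  by the available variant with maximal r² subject to r² > 0.80 (strict),
  ties toward the smaller id. The proxy's own exposure record replaces the
  original instrument wholesale (it must be present in the exposure source
  and non-palindromic); keeping the original exposure effect while
  borrowing the proxy's outcome effect was rejected because the allele
  alignment between the two variants is unknowable from an r² table.
* **Strength**: per-SNP PVE = z²/(z²+n) with z = β̂/σ̂, F = (n−2)·PVE/(1−PVE)
  — the standard summary-statistic approximations; both per-SNP values and
  aggregates (total PVE, mean F) are reported since published tables are
  ambiguous about which is meant. The validity flag requires every per-SNP
  F > 10.

### Harmonization

Exposure and outcome effects are aligned to the exposure's effect allele:
identical allele pairs (directly or after complementing both outcome
alleles) are kept as-is; swapped pairs negate the outcome beta; anything
else is dropped with the action recorded (`dropped_mismatch`). Every input
record receives exactly one action tag, and re-harmonizing an already
harmonized set is the identity.

### Estimators

* **Wald ratio** (k = 1): θ̂ = β̂ᵧ/β̂ₓ, SE = σᵧ/|β̂ₓ| (first-order delta
  method; exposure uncertainty ignored, standard for strong instruments).
* **IVW**: zero-intercept weighted regression of β̂ᵧ on β̂ₓ with weights
  1/σᵧ² (second-order weights omitted). Fixed SE = (Σwβ̂ₓ²)^(−1/2);
  the multiplicative random-effects (MRE) model scales it by
  √max(Q/(k−1), 1) — floored at one so underdispersion never tightens the
  interval. Point estimates are identical between models. One pair
  delegates to the Wald ratio.
* **Cochran's Q**: Σwᵢ(β̂ᵧᵢ − θ̂β̂ₓᵢ)², df = k−1, chi-square upper tail.
* **MR-Egger** (k ≥ 3): weighted regression with intercept after orienting
  exposure betas non-negative (pair signs flipped together). Slope and
  intercept SEs scale by √max(Q_egger/(k−2), 1). The intercept's normal
  test is the directional-pleiotropy diagnostic. Collinear exposure betas
  (zero weighted variance) raise an error.
* **MR-PRESSO** (k ≥ 2; outlier test at k ≥ 4): observed RSS uses
  leave-one-out IVW slopes; the null distribution comes from `nsim`
  parametric draws β̂ᵧᵢ* ~ N(θ̂₍₋ᵢ₎β̂ₓᵢ, σᵧᵢ²) with leave-one-out slopes
  recomputed per draw (vectorised in closed form). All p-values use the
  add-one rule (1+b)/(nsim+1) so none is exactly zero. Per-SNP outlier
  p-values are Bonferroni-adjusted by k. The distortion test — its
  bootstrap size is a free design choice, default 1000 — removes random
  size-|outliers| subsets of the non-outlier SNPs and compares the observed
  percentage shift of the slope against that distribution. The corrected
  estimate is IVW-MRE on non-outliers and is reported alongside, never
  instead of, the primary estimate.
* **Steiger**: aggregate r² per trait summed over instruments as
  z²/(z²+n) (independence assumed — reasonable post-clumping); direction
  is exposure→outcome iff r²_exp > r²_out, a single decision per analysis
  rather than per-SNP voting; p from the difference of Fisher-transformed
  correlations with variances 1/(n−3). An exact tie returns "not
  established" with p = 1.
* **Orientation**: published ORs are per 1 mmHg SBP *decline*; the
  orientation step negates every exposure beta (outcome untouched) and is
  an involution.

All confidence intervals are normal-theory at z = 1.959964 and all p-values
two-sided normal (no t-correction), the summary-statistic MR convention.

### Scan and tiering

The Bonferroni denominator is the number of drug classes *originally*
tested, not the number surviving the control gate — with twelve classes the
threshold 0.05/12 displays as 0.0042. Tiering partitions (0, 1]:
strong below the threshold, suggestive in [threshold, 0.05) — the boundary
is taken as inclusive on the suggestive side, since published wording is
ambiguous there — and none at or above 0.05. The control gate requires
p < 0.05 (configurable; no published value exists for this α) *and*
protective direction (OR < 1 per mmHg decline): a significant
harmful-direction hit would contradict the pharmacological rationale the
gate is meant to validate. Cells are computed independently even when
classes share target genes. Per-cell RNG seeds are derived as
CRC32(seed:class:outcome), so results are byte-identical across reruns and
independent of iteration order.

## Synthetic-data generator

`simulate_pair` emulates the two-sample summary-statistic setting directly
— no individual-level genotypes:

* Genes sit 5 Mb apart on one chromosome (windows can never overlap);
  null SNPs live on a second chromosome.
* EAFs are uniform on [0.05, 0.5], keeping SEs realistic and away from
  degenerate frequencies.
* Observed effects are true effects plus normal noise at the GWAS SE
  1/√(2·n·eaf·(1−eaf)). Within an LD block (one block per gene) the noise
  shares a block component so that observed effects correlate at √r²;
  the LD table reports the within-block r² only. This is sufficient to
  exercise clumping and proxy logic without a haplotype model.
* True instrument effects are ±z·SE with |z| uniform on [6.5, 8.5],
  placing per-SNP F-statistics in the ~40–75 range typical of well-powered
  drug-target instruments (selection and clumping push the retained set
  somewhat higher through winner's curse, which the pipeline inherits
  deliberately).
* The outcome's true effect is `true_effect`·β_x plus, for a configurable
  fraction of instruments, a direct effect drawn N(mean, sd) *per
  exposure-raising allele* — the convention under which a non-zero mean is
  directional pleiotropy and shifts the Egger intercept with matching
  sign, while mean 0 leaves it centred.
* Binary-outcome betas are generated directly on the log-odds scale; the
  pipeline consumes summary statistics only, so no case-control
  ascertainment or winner's-curse modelling is attempted.
* `inject_outliers` shifts k valid instruments' outcome betas by
  magnitude·SE and flips their truth flags, giving MR-PRESSO a known
  recovery target.
* Seeds are explicit everywhere; there is no global random state, and the
  same config is byte-identical across runs.

What passing tests on this generator show — and what they do not: the
estimators are correctly implemented and calibrated when the generative
assumptions hold (independent or block-correlated instruments, normal
errors, correct SEs). Real GWAS data add sample overlap, stratification,
winner's curse at selection, allele-frequency mismatch between studies and
LD misestimated from reference panels; none of these is emulated, so
passing here does not certify robustness to them.

## Problem sizes

Calibration checks use 20 independent instruments with n = 100 000 in both
samples: 1000 replicates for the null rejection rate, 500 for coverage and
bias, 50 for MR-PRESSO recovery (nsim = 1000), 200 for the Steiger
direction rate — sizes at which the binomial noise on each rate is well
inside the asserted bands.

## Degenerate inputs and edge rules

Empty harmonized sets are skip conditions, not errors; estimators raise
`InsufficientInstruments` below their minimum k and the sensitivity battery
converts that into a "not computed" note; `se ≤ 0`, `eaf ∉ (0,1)`,
`p ∉ (0,1]` and allele violations are rejected at read time with row-level
diagnostics; missing EAF is permitted (it is needed only for PVE-style
computations, which fail loudly per-record); unknown LD pairs count as
unlinked; simulated p-values are floored at 10⁻³²⁰ to stay inside (0, 1].

## Known limitations

No weighted-median/mode or multivariable estimators (deliberately out of
scope); no VCF parsing, liftover or tabix; LD is always supplied as a
table, never computed from a panel; the drug-class → gene map is a static
config, not a live database query; the confounder screen is a local
blocklist file rather than a lookup service. The Egger intercept p is
reported as *the* pleiotropy p-value of a cell, with MR-PRESSO's global
test reported separately.
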