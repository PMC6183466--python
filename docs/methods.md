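# Methods

This note documents the statistical procedures implemented in `codmix`, the
design choices made where the published analysis left the method open, and
what the synthetic generator does and does not emulate.

## Marker differentiation and panel pruning

Per-locus differentiation between the two reference populations uses Nei's
G_ST for a biallelic locus with equal population weights:
H_S = (2p₁(1−p₁) + 2p₂(1−p₂))/2, H_T = 2p̄(1−p̄) at the mean frequency
p̄ = (p₁+p₂)/2, and G_ST = (H_T − H_S)/H_T (0 when H_T = 0). Allele
frequencies are simple counts over non-missing dosages; a sample-size
weighted variant is available but not the default, since reference sample
sizes are roughly balanced by design.

Composite LD between loci is measured as the absolute Pearson correlation
of genotype dosages after pairwise deletion of missing entries — the
Burrows composite-disequilibrium estimator on unphased data, on the
correlation (|r|) rather than r² scale, which is the common reading of a
0.5 pruning threshold; r² is available via `squared=True`. A locus with
zero dosage variance has undefined LD and is treated as CLD 0 with a
warning. LD is estimated on the pooled reference sample by default; a
per-population max-CLD mode exists because pooling divergent populations
inflates apparent LD.

Panel selection is a single greedy pass in descending G_ST order (ties
broken by input order): a locus is kept iff its CLD to every
already-kept locus is ≤ the threshold, until the panel size is reached.
Loci monomorphic in both references, or unscorable in either, are dropped
first. Raising the threshold can only grow the kept set.

## Assignment

The default per-locus genotype probability is the Rannala–Mountain
Bayesian posterior-predictive with a Dirichlet(½, ½) prior on the two
allele frequencies: with reference counts n₁, n₂ (n = n₁ + n₂),

* heterozygote: 2(n₁+½)(n₂+½)/((n+1)(n+2))
* homozygote for allele a: (n_a+½)(n_a+3/2)/((n+1)(n+2)).

These normalize exactly over the three genotypes and are defined at n = 0.
An HWE plug-in criterion (frequencies clipped at ε = 0.001) is provided
for comparison. Multilocus log-likelihoods sum over loci scored in the
individual — the same locus set for both populations, so missing data
never favours one reference. Scores are normalized likelihoods in percent,
computed in log space; the two scores sum to 100. QC mirrors the survey
protocol and applies in order: fewer than 20 scored loci → unassigned
(`too_few_loci`); best score below 80% → unassigned (`low_score`); a score
of exactly 80% is kept. Reference and query sets are disjoint, so no
leave-one-out correction is applied.

## Coexistence statistics

Groups are formed at four nested levels (total, region, station, haul =
station × year) from assigned fish only. Diversity per group is Simpson's
index 1 − f² − (1−f)², the probability that two randomly drawn fish
differ in type (maximum 0.5 for two types). Scale summaries weight group
diversities by group sample size; the weighted SD uses the population form
√(Σw(d−d̄)²/Σw) (an unbiased variant is available). The minimum-n filter
(default 6) applies only to the both-types co-occurrence proportion;
diversity averages use all groups. The distance analysis regresses
station-level North-Sea fractions (pooled over years, stations with ≥ 5
assigned fish) on distance inland by weighted least squares with station
sample sizes as weights, and reports a two-sided t-test on the slope with
n − 2 df.

## Otolith back-calculation

The biological-intercept method anchors the fish-length/otolith-radius
relation at hatch: L_i = 4.5 mm, O_i = 9 μm. Length at a radius O_a is the
affine interpolation L_c + (O_a − O_c)(L_c − L_i)/(O_c − O_i); per-day
growth is the same slope times each increment width, so the daily vector
telescopes exactly to L_c − L_i and the mean daily rate equals
(L_c − L_i)/age. Age is the increment count plus a configurable onset
offset (default 0: the first increment forms on the hatch day); hatch date
is the capture date minus age. The comparison of ages/growth between
ecotypes and locations is an additive two-factor ANOVA whose omnibus F
tests both 2-level factors jointly against the residual on (2, n−3) df,
with per-factor partial F tests alongside. The age-vs-growth question uses
two-predictor hierarchical partitioning: each predictor's independent
contribution is its incremental R² averaged over the two entry orders,
which sums exactly to the joint R².

## Length model

The response is the natural log of fork length in cm; wave exposure
(significant wave height, m) is also natural-log transformed. Natural
rather than base-10 logs are required for the intercept scale to map back
to observed lengths (exp(2.355) ≈ 10.5 cm, matching the survey's ~9.7 cm
mean). Treatment coding fixes the first sampling year, eelgrass and the
fjord type as reference levels; interactions require their main effects.

The single-random-intercept Gaussian mixed model is fitted by maximizing
the profiled (restricted) log-likelihood over the variance ratio
λ = σ²_region/σ²_residual. For fixed λ the marginal covariance is block
diagonal with V_g = I + λ11′, so Woodbury identities give the GLS
coefficients, profiled residual variance and both log-determinants in
closed form per region; a bounded scalar search (absolute tolerance 1e-8
on λ, with the λ = 0 boundary checked explicitly) completes the fit. At
λ = 0 the fit reduces exactly to OLS. The implementation reproduces
statsmodels MixedLM and R nlme log-likelihoods to ≈1e-5 on reference data
(both are used as independent cross-checks in the tests, never as the
implementation). Coefficient p-values use the Wald normal approximation,
which differs from nlme's within-group t df at small n. AIC is
−2ℓ + 2k with k counting fixed coefficients plus variance parameters
(residual always, region variance when present).

Model selection follows the two-step protocol: step 1 compares REML AICs
of the full fixed structure with and without the region random intercept
(REML AICs are compared only between models sharing a fixed structure);
step 2 compares the nine candidate fixed structures — the literal nested
sequence from the full interaction model down to year alone — by ML AIC;
the winner is refit by REML for inference. Predictions are fixed-effects
only (region effect at 0), exp back-transformed to cm, with Wald intervals
on the linear predictor.

## Synthetic generator

The generator is the package's stand-in for the 14-year survey; its
defaults are the study conditions, not free dials.

* **Reference frequencies.** Each locus receives the target G_ST exactly:
  a midpoint frequency is drawn uniformly in [0.40, 0.60], the symmetric
  gap solved by root-finding (at a centred pair, G_ST = gap², so a target
  of 0.64 yields e.g. 0.1 vs 0.9), midpoints pulled toward 0.5 when the
  target is unreachable there, and the high-allele population randomized.
  Frequencies stay inside (0.01, 0.99), capping reachable targets at 0.95.
  Default: 26 loci at mean G_ST 0.20.
* **Reference genotypes.** Dosages ~ Binomial(2, p): Hardy–Weinberg within
  population, loci independent (no within-panel LD structure is
  simulated). Default 300 per population; optional uniform missingness.
* **Stations.** 125 stations in 15 regions assigned round-robin so each
  region spans the gradient; distances stratified over [0, 25000] m with
  the outermost pinned at 0. Distance units are metres: the printed slope
  −1.85×10⁻⁵ then gives a ≈0.37 drop in North-Sea fraction over 20 km,
  consistent with the described gradient. Wave exposure decays
  log-linearly with distance inland around 0.5 m at the coast; vegetation
  type (eelgrass/macroalgae) and cover (1–5) are uniform. Covariates are
  constant across years.
* **Hauls and fish.** A station is seined in a year with probability 0.26,
  giving ≈455 hauls over 14 years; haul catches are negative binomial
  (mean 14, dispersion 1.0 — heavy-tailed, as the survey's totals imply),
  so ≈6,400 fish in a full run, matching the survey's accounting. Ecotype
  is Bernoulli in the clamped linear mixture probability
  clip(0.55 − 1.85×10⁻⁵ d, 0.01, 0.99) (a logistic option exists; linear
  is default so the printed slope is the generating truth). Genotypes come
  from the ecotype's reference frequencies; log lengths from the published
  coefficient estimates (year effects for the 13 printed non-reference
  years; unlisted years 0) plus a N(0, 0.059) region effect and
  N(0, 0.20) residual. The residual SD is not published; 0.20 log-cm was
  chosen with the region SD 0.059 so the region share is
  0.059²/(0.059² + 0.20²) ≈ 8%.
* **Otoliths.** Hatch dates uniform over Feb 5 – May 3; fish-specific
  growth targets uniform over 0.46–0.86 mm/day; capture length =
  4.5 mm + rate × age, so back-calculation recovers the target exactly;
  increment widths carry lognormal day-to-day jitter on a rising profile
  and sum to the capture radius minus the intercept.

All randomness derives from the single config seed through named
substreams, so outputs are identical across reruns and independent of call
order.

**What the generator does not emulate:** real LD among panel loci
(including the inversion-linked SNPs), genotyping error, spatial
autocorrelation beyond the region intercept, year-to-year station
turnover structure, length-dependent catchability, or any
oceanographic transport of the North Sea type. Passing tests therefore
demonstrate correctness of the estimators under the assumed generating
model, not robustness to these real-data features.

## Problem sizes and numerical conventions

Unit tests run the generator at ≈30–60 stations; parameter-recovery checks
use the full default scale (125 stations, ≈6,400 fish, subsampled to the
survey's modelled 5,730 where the published fit is the comparison). The
acceptance script uses the full default scale with the caller's seed.
Degenerate inputs are errors, not silent results: empty panels, aliased
ANOVA factors, zero-variance partitioning predictors, singular designs and
all-identical distances raise with a message. Lengths travel in cm in
survey tables and mm inside otolith computations; dates are ISO-8601; all
table output is TSV with dot decimals.
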