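# Methods

## Model

Two-sample MR treats each retained SNP *j* as an instrument with estimated
exposure effect γ̂ⱼ (SE σ_γⱼ) and outcome effect Γ̂ⱼ (SE σ_Γⱼ), both on the
log-odds scale for binary traits and expressed for the same effect allele.
Under the instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction) the outcome effects satisfy

    Γⱼ = β γⱼ + αⱼ,

where β is the causal effect of interest and αⱼ is a horizontal-pleiotropy
term that is zero for valid instruments.  The per-SNP Wald ratio is
β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order standard error σ_Γⱼ/|γ̂ⱼ|; exposure-side
uncertainty is ignored, which is accurate when instruments are strong
(every bundled and simulated instrument has F ≫ 10).

### Estimators

- **IVW (fixed effects)** — precision-weighted mean of the Wald ratios with
  wⱼ = 1/ratio-SE²; SE = (Σwⱼ)^(−1/2); normal p-values.  Identical to
  weighted least squares of Γ̂ on γ̂ through the origin with weights 1/σ_Γⱼ²
  and SE de-scaled by the residual SD (the test suite checks this identity
  against statsmodels to 1e-10).
- **IVW (multiplicative random effects)** — same point estimate; SE
  inflated by max(1, √(Q/(J−1))) where Q is Cochran's Q.  Under-dispersion
  never shrinks the SE.
- **MR-Egger** — pairs are oriented so γ̂ⱼ ≥ 0, then Γ̂ is regressed on γ̂
  with an intercept, weights 1/σ_Γⱼ².  The slope is the causal estimate
  under InSIDE (pleiotropy independent of instrument strength); the
  intercept estimates mean directional pleiotropy.  SEs are scaled by
  max(1, residual SD); p-values use t with J−2 df.
- **Weighted median** — interpolates the sorted ratios against cumulative
  weight midpoints pⱼ = Σ_{k≤j} w'ₖ − w'ⱼ/2 at p = 0.5; consistent while
  valid instruments carry > 50% of the weight.
- **Weighted mode** — maximiser of a weighted normal-kernel density over
  the ratios; bandwidth h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (φ = 1 by
  default), evaluated on a 512-point grid spanning [min − 3h, max + 3h].
  When the IQR collapses to zero the SD alone sets the bandwidth; when all
  ratios coincide the common value is returned directly.
- Median and mode SEs come from a parametric bootstrap (default 1000
  replicates): γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ), Γ*ⱼ ~ N(Γ̂ⱼ, σ_Γⱼ), estimate recomputed.
  The bootstrap seed is part of the analysis config, so reports are
  bit-reproducible.

Odds ratios are exp(β̂) with Wald CIs on the log scale; the 95% quantile is
the exact normal value 1.959964, not 1.96.

### Diagnostics

- **Cochran's Q** (IVW, df = J−1) and **Rücker's Q** (Egger, df = J−2),
  chi-square upper-tail p-values.
- **MR-PRESSO** — observed statistic Σⱼ wⱼ(Γ̂ⱼ − b₋ⱼ γ̂ⱼ)² where b₋ⱼ is the
  IVW slope with SNP j left out; the null distribution is built from
  `n_sim` (default 1000) redraws of all summary statistics under the
  no-pleiotropy model, recomputing the statistic identically.  Empirical
  p-values use (r+1)/(n+1); per-SNP outlier p-values are Bonferroni
  corrected.  A distortion statistic (IVW change after removing flagged
  SNPs) is reported without a p-value.
- **Leave-one-out** — IVW (multiplicative random effects by default,
  matching the more conservative sensitivity posture) refitted J times; a
  `driven_by_single_snp` flag fires when the full-set estimate is
  significant but some single exclusion loses significance or flips sign.
- **Funnel data** — ratio vs precision (|γ̂ⱼ|/σ_Γⱼ) pairs; plotting is out of
  scope, tables are plot-ready.

### Power

Binary-outcome power uses the NCP approximation: with case fraction K and
target odds ratio OR, b = K(OR−1)/(1+K(OR−1)), NCP = N·R²·b²/(K(1−K)−b²),
power = Φ(√NCP − z_{1−α/2}).  The second tail is omitted (mRnd convention;
negligible in practice).  The pipeline feeds R² = Σ per-instrument
β²/(β²+se²N) into this formula with each outcome's sample sizes.

## Instrument pipeline

Filter order: significance (p < 5·10⁻⁸, strict) → LD clumping (greedy by
ascending p, remove same-chromosome SNPs within ±10,000 kb with r² ≥ 0.001;
ties in p broken by rsID) → MAF ≥ 0.01 → harmonization with proxy search
(r² > 0.8, strict) for SNPs absent from the outcome → confounder exclusion
list → weak-instrument filter (F ≥ 10 retained).  Each removed SNP carries
exactly the first reason that removed it, and retained + removed always
equals the input count.  R²/F are computed for the final instrument set.
LD is always an input table (synthetic in tests), never computed from a
reference panel.

Harmonization conventions: matching is by rsID; swapped alleles negate the
outcome beta and reflect its EAF; complementary-strand substitution is tried
before declaring alleles incompatible; palindromic SNPs (A/T, C/G) are
dropped by default, since strand cannot be resolved from labels — an
`infer` mode instead orients them purely by allele frequency and drops them
as ambiguous when either EAF falls in [0.42, 0.58].  Proxy substitution
reuses the proxy's outcome association under the target's rsID and assumes
the proxy shares the target's alleles; discordant proxies fall out at the
incompatible-alleles step.

Evidence grading divides α = 0.05 by the number of outcomes in the config
(recomputed, not hard-coded), labelling p below α/m "strong" and p in
[α/m, α) "suggestive".

## Synthetic data

The generator emulates a post-selection instrument panel: EAFs uniform on
the configured MAF range (reflected to either allele), standard errors
1/√(2N·EAF(1−EAF)) on both sides, true γⱼ ~ N(0, 0.1) resampled until the
implied association is genome-wide significant, observed effects with
additive normal noise, and Γⱼ = β γⱼ + αⱼ.  Defaults mirror the
autoimmune-exposure/stroke-outcome setting the package was exercised
against: exposure N = 166,144 (1,462 cases), outcome N = 446,696 (40,585
cases), β = 0.05, 50 SNPs, MAF ∈ [0.05, 0.5], no pleiotropy.

Pleiotropy modes act on a configured fraction of SNPs: `balanced`
αⱼ ~ N(0, 0.01), `directional` αⱼ ~ N(0.02, 0.01), `inside_violating`
αⱼ = 0.5 γⱼ + noise (correlating direct effects with instrument strength,
which breaks InSIDE and hence Egger).  Directional and balanced effects are
injected on the exposure-raising orientation (multiplied by sign(γⱼ)):
MR-Egger orients every SNP to γ ≥ 0 and flips α's sign with it, so a
"directional" mean is only meaningful on that scale — this is the package's
convention for making the intercept-recovery check well-posed.

What the generator does *not* emulate: LD between instruments' effect
estimates (LD enters only as an input table for clumping), case-control
liability-scale effects, allele-frequency differences between the two
samples, and population stratification.  A green simulation test therefore
establishes correctness of the estimators under their stated sampling
model, not robustness to those real-data features.

All randomness flows from a single integer seed; the pipeline spawns one
child seed stream per outcome via `numpy.random.SeedSequence`, so adding an
outcome does not perturb the others.

## Numerical choices and edge cases

- Strict vs non-strict inequalities pinned throughout: p < 5·10⁻⁸,
  r² ≥ 0.001 removed in clumping, MAF ≥ 0.01 kept, proxy r² > 0.8,
  F ≥ 10 kept.
- Zero exposure effects make Wald ratios undefined → error naming the SNP.
- Empirical p-values never reach zero ((r+1)/(n+1) convention).
- `variance_explained` accepts n ≥ 1 (the record-level invariant requires
  n ≥ 2); eaf ∈ {0, 1} is an error.
- Egger demands J ≥ 3, MR-PRESSO J ≥ 4, leave-one-out J ≥ 3; degenerate
  requests raise instead of returning silent NaNs.
- Reports serialise with sorted keys and contain no timestamps, so a fixed
  config + seed yields byte-identical JSON.

## Known limitations

- First-order Wald SEs understate uncertainty for borderline-strength
  instruments (mitigated by the F ≥ 10 filter).
- The weighted-median/mode bootstrap redraws both sides independently; any
  sample overlap between the exposure and outcome GWAS is not modelled.
- Published per-SNP variance-explained values for the bundled instrument
  panel are carried as annotations and are not reproducible from the R²
  formula applied to the published β/SE/EAF; the F statistics are, however,
  internally consistent with the annotated variances via F = R²(N−2)/(1−R²),
  and both routes are exposed.
- Proxy substitution does not remap alleles between proxy and target; users
  supplying real LD proxies should pre-align them.
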