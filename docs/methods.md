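# Methods

This note documents the models, numerical choices and limitations behind
`bpmr`. It is written for a reader who wants to know exactly what each
stage computes and what the synthetic cohort does and does not emulate.

## Cohort simulator

**Genotypes.** Each haplotype is a latent Gaussian vector with AR(1)
correlation `ld_rho` within an LD block (default block size 10, ρ = 0.8),
restarting at block and chromosome boundaries; the allele is 1 where the
latent value falls below the allele-frequency quantile, and the two
haplotypes sum to an additive dosage in [0, 2]. This gives cheap,
controllable LD with an analytic oracle: the expected dosage correlation
of two variants is the phi-coefficient correlation of the thresholded
bivariate normal, computable by direct integration. Regional
allele-frequency drift follows the Balding–Nichols model: region
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral
frequency p (default F = 0.01, ten regions). Hardy–Weinberg holds within
region in expectation because haplotypes are i.i.d. Variants are laid out
on two chromosomes at 5 kb spacing; ancestral frequencies are uniform on
(0.05, 0.5).

**Blood pressure.** Per-variant (SBP, DBP) effects are drawn
bivariate-normal with correlation `rg_sbp_dbp` (default 0.85, matching the
strong genetic correlation of the two traits) at `n_causal` variants
(default 30), then rescaled so the realised genetic variance in the sample
equals h²·sd² exactly (default h² = 0.16 per trait; SD targets 22.3 mmHg
for SBP and 11.6 mmHg for DBP — a representative East Asian biobank scale
for SBP, with the DBP SD roughly half). The genetic value is centred so
the trait mean equals the configured mean (130/78 mmHg). Covariates (age
uniform 30–79 years to match a typical recruitment window, sex, BMI
N(23.7, 3.5), region, and seasonal-uniform regional temperature that
deliberately includes values below the 5 °C analysis floor) enter
linearly with modest defaults; the environmental residual is bivariate
normal with correlation `resid_corr` (default 0.55) and fills the variance
budget sd² = h²·sd² + var(covariates) + var(residual). PP and MAP are
derived exactly, at both phenotype and effect level, so PP = SBP − DBP and
MAP = (2·DBP + SBP)/3 hold to machine precision everywhere.

**Medication.** Hypertension is SBP ≥ 140 or DBP ≥ 90 mmHg; among
hypertensives a seeded coin with probability `treat_prob` (default ⅓)
assigns medication, which lowers the *observed* BP by `treat_effect`
(default 15/10 mmHg — the magnitude of the real reduction is not published
for the emulated cohort, so the defaults mirror the standard +15/+10
adjustment constants and are configurable). Underlying untreated values
are retained as truth. Because medication targets high-BP individuals,
the treated stratum is phenotype-selected and shows attenuated per-allele
effects — the qualitative phenomenon seen in real treated subgroups —
without any explicit effect-modification machinery.

**Outcomes.** Each binary outcome is drawn from
logit(p) = α + Σ_t θ_t·BP_t/5 with θ given per 5 mmHg of the underlying
(untreated) trait; α is calibrated by Brent root-finding on the mean
predicted probability to hit the target prevalence (tolerance 1e-6).
Outcomes are independent given BP; one event per person per disease, one
shared control pool.

## Phenotype preparation

Recorded BP of treated individuals gets +15/+10 mmHg; PP and MAP are
derived from the adjusted values. Exclusion is two-pass: (1) any adjusted
trait > 5 SD from the population mean (SDs computed before any exclusion;
ties at exactly 5 SD retained — the inclusive boundary is the conservative
reading); (2) after regressing each trait on age, age², sex, region
indicators (first level reference — any full-rank coding yields identical
residuals), temperature floored at 5 °C, and optionally BMI, any residual
> 5 SD. The regressions are refitted on the retained rows and those final
residuals are used downstream. The 5-SD screens are applied jointly over
the four traits within each pass ("any trait"). An optional analysis mask
restricts the returned residuals *after* fitting, reproducing designs
where covariate adjustment is done in a full cohort before genetic
analyses. Exclusion is a fixed point: re-running the procedure on its own
output removes nothing further.

## Association and meta-analysis

The scan is simple OLS of the residualised trait on dosage — exact for the
simulator's unrelated individuals; mixed-model (leave-one-chromosome-out)
machinery is intentionally out of scope, and this is the documented
divergence for real, related cohorts. P-values use the normal
approximation (GWAS convention; immaterial at the simulated n).
Monomorphic variants are skipped with a log entry. Genotype sufficient
statistics are cached across traits when the traits share the same
analysed rows. Fixed-effect IVW meta-analysis is
β = Σ(b/se²)/Σ(1/se²), se = (Σ1/se²)^(−½). λ_GC is the median implied
1-df χ² over the null median (≈0.4549). Summary statistics are written in
the GWAS-SSF column vocabulary.

## Loci

Greedy clumping: the unassigned variant with the smallest p < 5e-8 (ties
broken by position, then alt allele — deterministic, otherwise arbitrary)
indexes a clump; unassigned variants within ±10 Mbp with p < 0.05 and
dosage r² > 0.05 join it. LD is the squared Pearson correlation of
dosages on a reference subset (default: all simulated individuals; real
analyses would subsample). The locus spans its members, is extended to
include the index if it falls outside (possible only for externally
supplied clumps), padded 1 kbp each side, and overlapping loci merge —
interval union before padding versus after is an open choice; union is
used. Cross-trait merging takes the transitive closure of interval
overlap; per-trait sentinels are retained and the region sentinel is the
lowest-p sentinel overall. Conditional analysis is exact individual-level
forward selection from the sentinel (adding the smallest conditional-p
member while p < 5e-8, skipping collinear candidates) — equivalent in
expectation to summary-statistic stepwise selection when the LD reference
is the analysis sample. Coordinates are 1-based inclusive internally; BED
export is 0-based half-open.

## Genetic scores

Individuals are split (seeded permutation) into a 70% weight-estimation
subset and a 30% holdout; within the 70%, folds are assigned round-robin
along the permutation into 100 near-equal groups. Per-variant *marginal*
effect sizes are computed from per-fold sufficient statistics
(leave-one-fold-out by subtraction), so the weights cost one pass over the
data regardless of fold count. Holdout individuals receive full-training
weights; training individuals receive their leave-own-fold-out weights —
no one is scored with weights that saw their data. Scores are scaled by
regressing the trait on the score plus BMI, sex, age, age² and region
indicators (the simulator has explicit regions rather than principal
components; PC columns can be supplied instead), and the centred score
times the fitted coefficient is the genetically predicted trait in mmHg.
Strength is partial r² = (SSE_reduced − SSE_full)/SSE_reduced and the
corresponding 1-df F; the conditional versions add the second trait's
score to both models. F = r²/(1−r²)·df holds algebraically and is
asserted in tests.

## Mendelian randomisation

One-sample MR fits logistic regressions of the outcome on the genetically
predicted exposure with sex, age and age² in each region, then combines
regional log-odds by fixed-effect IVW; estimates are reported per 1 SD of
the (medication-adjusted) trait and per 5 mmHg via
exp(ln(OR)·5/SD) — exponent rescaling, numerically identical to re-running
with a rescaled exposure for logistic point estimates. Regions with no
cases, no controls, separation or non-convergence are dropped with a
warning (an error only if all are). Logistic fitting is Newton/IRLS
(statsmodels) with a 100-iteration cap. MVMR puts both predicted
exposures (built at the identical paired variant set — one sentinel per
merged locus, lowest-p rule by default with prefer-A/prefer-B sensitivity
rules) in one model; conditional F below 10 flags the estimate
prominently.

Two-sample estimators operate on harmonised summary statistics (match on
id and alleles, sign-flip on swap, drop strand-ambiguous palindromic
variants): IVW is Σwβ_Xβ_Y/Σwβ_X² with w = se_Y⁻² (the Wald ratio for one
variant); MR-Egger is the weighted regression with free intercept after
orienting exposure betas non-negative, with the intercept as the
pleiotropy test and a multiplicative random-effects scale floored at 1;
two-sample MVMR is weighted regression through the origin on both
exposures' betas. No closed conditional-F is published for the summary
setting, so a Sanderson-style Q form is used:
Q_A = Σ w_j (β_Aj − fitted(β_Bj))², w_j = se_Aj⁻², divided by (L−1), with
the fit through the origin — documented as an approximation.

## Effect-size comparison

Deming regression with error-variance ratio δ = var(err_y)/var(err_x)
(default 1 — the symmetric choice, since the appropriate ratio is rarely
known; a plug-in mean(se_y²)/mean(se_x²) helper is provided). The slope
is closed-form from second moments — central moments normally, raw
moments when forced through the origin — and the two limits δ→∞ / δ→0
recover OLS of y on x and the inverse OLS of x on y. Confidence intervals
are a seeded percentile bootstrap over variant pairs (default 2000
resamples); the method of CI construction is otherwise unspecified in the
source analyses this mirrors. Replication is assessed by directional
concordance and Benjamini–Hochberg step-up FDR (default 5%), counted
separately, with two-sided replication p-values.

## Pipeline and reproducibility

`run_pipeline` executes the declared stages in order; each stage gets a
sub-seed from SHA-256 of `(seed, stage-name)`, so any stage prefix re-run
with the same configuration is byte-identical (asserted in tests).
Artifacts carry a manifest (stage, parameters, sub-seed, SHA-256 of each
output). A schema violation aborts before any stage runs; a stage failure
aborts naming the stage and preserves prior artifacts.

## Problem sizes and what the tests show

The default simulated cohort is 20,000 individuals × 2,000 variants with
30 causal variants — large enough that genome-wide-significant loci form,
scores are strong (partial r² ≈ 0.1–0.2, far above the 2–3.5% of real
sentinel-based scores, because the simulated architecture is concentrated)
and MR sampling error is a few percent, while a full
simulate→prep→scan→clump→score→MR→MVMR cycle stays around six seconds.
The acceptance experiments use: 50 seeded replicates of that cohort for
the MVMR causal-separation check; 20 replicates at 10,000 × 100 for the
jack-knife anti-overfitting check; 200 replicates at 20,000 × 50 for null
CI coverage; 1,500 × 40,000 for λ_GC (the λ estimator's Monte-Carlo error
scales as ~2.3/√m, so 40,000 null variants give ±0.012). The
weak-instrument scenarios set equal per-variant effect variances for SBP
and DBP (sd_dbp = 22.3 with h² = 0.16): with rg = 0.98 the MAP–SBP
instrument pair is tightly collinear (conditional F < 10), while with
rg = 0.85 the SBP–PP pair is near-orthogonal (effect correlation
√((1−rg)/2) ≈ 0.27, conditional F ≫ 10) — emulating the qualitative
collinearity pattern of the real traits, which the simulator's bivariate
architecture cannot produce at realistic variance ratios because PP
inherits most of its effect variance from SBP.

## Known limitations

- The simulator emits unrelated individuals; kinship input is a
  pass-through and mixed-model association is out of scope, so per-allele
  effects on real related cohorts would be mis-calibrated.
- LD is blockwise AR(1): no long-range LD, no allele-frequency–dependent
  architecture, no imputation uncertainty (hard dosages only).
- One-sample MR of a binary outcome estimates a marginal odds ratio; with
  strong causal effects the logistic non-collapsibility over BP variation
  not captured by the score attenuates estimates slightly toward the null
  relative to the conditional simulated log-odds. At the default
  conditions this attenuation is a few percent — within the acceptance
  tolerances — but it grows with effect size and shrinking instrument r².
- Two-sample conditional F uses an approximate Q-statistic form.
- Time-to-event outcomes, genome-wide polygenic scores, LD-aware weight
  shrinkage, and cross-ancestry genetic-correlation estimation are
  non-goals.
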