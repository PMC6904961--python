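# Methods

## Growth models and trait derivation

Two linear mixed models are fitted to log(BMI), one per developmental
window, each with a per-child random intercept u₀ and random linear age
slope u₁ (bivariate normal, unstructured covariance) and i.i.d. residuals:

* **infancy**, measurements in (2 weeks, 18 months], age centered at 0.75
  years: fixed effects 1, a, a², a³, Sex;
* **childhood**, measurements in (18 months, 13 years], age centered at
  7.25 years: fixed effects additionally a·Sex and a²·Sex.

Centering ages are the medians of the two windows, chosen so the intercept
and random effects are interpretable near the trajectory features of
interest (the centering age of the infancy window is close to the average
age at adiposity peak).  Estimation is by maximum likelihood (not REML) via
statsmodels `MixedLM` with a convergence tolerance driven by L-BFGS/BFGS
(maxiter 500); random effects are empirical-Bayes posterior means.  ML is
preferred because fitted log-likelihoods are then comparable across fixed-
effect structures, and the fixed-effect bias of ML is negligible at the
cohort sizes involved (hundreds to thousands of children).  Children need at
least three in-window measurements to enter a model; a model refuses to fit
with fewer than 20 usable subjects.  If the pooled OLS residual variance is
below 1e-12 (noiseless degenerate data) the mixed model is unidentified and
the OLS fit is returned with zero random effects.

Adiposity peak and rebound are the extrema of each child's predicted
log-BMI cubic: candidates are the real roots of the derivative inside the
search window ([0.25, 1.25] years for the peak, [2.5, 8.5] years for the
rebound) plus the window endpoints; ties are broken toward the earliest age,
and a boundary flag records when the extremum sits on an endpoint.  Children
with boundary extrema are *retained* in downstream association by default
(configurable), since discarding them would select on the phenotype.  BMI at
the extremum is exp(predicted log-BMI), exactly.

Peak velocities come from the Reed1 curve y(t) = a + b·t + c·ln t + d/t
(t in months), fitted to measurements in [0, 24] months with ages floored at
0.25 months (~1 week) because ln t and 1/t are undefined at birth; the floor
moves a birth measurement by at most a week, which is below visit-timing
noise.  Rather than a full nonlinear random-effects fit, a two-stage scheme
exploits linearity in the parameters: (1) the shape parameters (c, d) are
shared within each sex stratum and estimated by pooled regression of
within-subject residuals (each child's own intercept and linear trend
partialled out — exact partitioned regression); (2) per-child (a, b) are
estimated by least squares given (c, d).  This honours the three-measurement
minimum, is exactly unbiased for the shared parameters under the model, and
runs in seconds at cohort scale; it does not shrink individual (a, b) toward
the population mean the way a random-effects fit would, which slightly
inflates between-child velocity variance (a conservative choice for
association).  The velocity v(t) = b + c/t − d/t² has stationary point
t\* = 2d/c, an interior maximum iff d > 0; the peak velocity search window
defaults to [0.25, 24] months, and endpoint maxima are flagged.

## Synthetic cohorts

The generator emulates multi-cohort child-growth GWAS data: term-born
singletons (gestational age 37-41 completed weeks, configurable discrete
distribution), a clinic-style visit schedule (birth, 2 weeks, 3, 6, 9, 12,
18 and 24 months, then annually to 8 years plus 10 and 13 years) with 15%
independent dropout per visit, and Hardy-Weinberg genotypes (Binomial(2, MAF), SNPs
independent — no linkage disequilibrium).

The generating fixed effects were chosen once by least-squares fit to
reference median growth: the infancy cubic peaks at BMI ≈ 17.6 kg/m² near
0.76 y, the childhood cubic bottoms at ≈ 15.4 kg/m² near 5.1 y, and the
Reed1 height curve runs 50 → 86.5 cm over 0-24 months with an interior
velocity peak near 0.5 months.  Random-effect SDs (0.08/0.04 infancy
intercept/slope on log-BMI; 0.07/0.006 childhood; 2.0 cm / 0.08 cm·month⁻¹
for Reed1 height) give realistic trait spreads: SD(Age-AP) ≈ 0.06 y,
SD(Age-AR) ≈ 0.6 y, coefficient of variation of BMI-AP ≈ 8%.  Gestational
age shifts the infancy intercept (+0.008 log-BMI per week from 39) and birth
size (+0.7 cm per week) but not the childhood model, so the rebound traits
are GA-independent — matching the covariate rule that adjusts all traits but
the rebound pair for gestational age.  Measurement noise defaults: SD 0.03
on log-BMI and 0.5 cm on height per visit (no per-cohort error magnitudes
are published for such data; both are configurable).  Height is generated
from the Reed1 curve (extended linearly at 0.5 cm/month past 24 months),
BMI from the window-appropriate log-BMI model, and weight as BMI·(height/100)²,
so the three measurements are mutually consistent by construction.

**Effect injection.** Causal SNP effects are specified in SD units of the
derived trait and injected on the *latent* parameters so that parameter
recovery is well defined; the SD used for scaling is the within-study SD of
the pre-injection latent trait on its analysis scale (log except for the two
ages).  The mappings are exact on that scale: intercept shifts for BMI-AP /
BMI-AR (the extremum age does not move); a joint shift of both models'
intercepts for PWV (scaling the whole weight curve scales its velocity, so
log PWV shifts exactly); a per-child Reed1 slope shift of phv·(e^δ − 1) for
PHV; and for the age traits, the random slope is re-solved from the
stationarity condition so the extremum moves by exactly the target amount
(children whose extremum is already on the window boundary are left
unshifted).  Latent PWV is evaluated on the infancy weight curve over
[0.25, 18] months: the two BMI models are independent, so a single smooth
latent weight curve exists only on the infancy window; the velocity peak
sits near 1 month, far from either edge.  Between-study heterogeneity adds a
Normal(0, between_study_sd) perturbation to each causal effect per study.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: linkage disequilibrium and population
stratification (the association model's principal-component hook is unused
on synthetic data), imputation uncertainty beyond a constant info score,
informative visit schedules or dropout, secular trends and cohort effects,
and cross-window correlation of the random effects — infancy and childhood
random effects are drawn independently, so the six traits correlate less
between windows than in real children, where BMI tracks; the effective
number of independent phenotypes on synthetic data is therefore close to
the trait count.

## Association, QC, genomic control

Traits other than the two ages are natural-log transformed, then all are
z-scored within study (sample SD, ddof 1) *before* association; the model
is OLS of the z-score on dosage with sex (0 = female, 1 = male) and linear
gestational age in weeks (the rebound traits adjust for sex only).  P values
use the t distribution with exact residual degrees of freedom.  Monomorphic
SNPs yield flagged records without estimates.  The vectorised scan
residualises the trait and dosages on the covariates (Frisch-Waugh) and is
tested to agree with the single-SNP path to 1e-10.  QC excludes SNPs with
MAF < 1%, imputation info < 0.4 (IMPUTE dialect) or r² < 0.3 (MACH), HWE
P < 1e-4, or call rate < 95%, counting exclusions per criterion.  Genomic
control divides the median association χ² by 0.454936 (the χ²₁ median);
when λ > 1 standard errors are multiplied by √λ and P values recomputed;
λ ≤ 1 leaves statistics untouched (no anti-conservative shrinking).

## Meta-analysis, selection, local fdr

Fixed-effects IVW is the default and the only surface used by the
calibration checks; a DerSimonian-Laird random-effects option exists.  The
combined stage is the IVW of the two stage-level estimates, which equals
pooling all study estimates directly (precision weighting is associative;
property-tested to 1e-12).  "Double" genomic control applies λ once within
each study and once to the meta statistics.  Selection for follow-up:
P < 1e-7, or P < 1e-5 with a candidate-gene flag, or an explicit override
list; candidate knowledge is plain configuration, never a database query.
Tier thresholds (5e-8, 5e-6) are strict inequalities.  Table-style
reproduction of combined estimates rounds half-up to 2 decimals.

The local false discovery rate uses the two-groups model with a theoretical
N(0,1) null: the marginal density f is estimated by Poisson regression of
histogram counts (120 bins spanning the z range) on a cubic B-spline basis
with 7 degrees of freedom (Lindsey's method), and π₀ by central matching —
a quadratic fit of log f − log φ on |z| < 1, exponentiated at 0 and capped
at 1.  fdr(z) = min(1, π₀ φ(z)/f(z)).  The theoretical-null,
central-matching variant was chosen over an empirical-null fit because the
synthetic z-values are exactly standard normal under the null and the
empirical-null MLE adds variance without benefit at these sizes.

## Post-GWAS statistics

* **Variance explained**: h² = β²·2f(1−f) on a unit-variance trait;
  symmetric in f ↔ 1−f.
* **Winner's curse**: the bias-reduced estimate maximises the likelihood of
  the observed β̂ conditional on |β̂/se| > z_c (bounded scalar optimisation,
  tolerance 1e-8, verified against grid maximisation to 1e-4); the
  compromise estimator (naive + MLE)/2 is reported alongside because the
  conditional MLE is known to over-shrink just above the threshold.  The
  bias-reduction simulation fixes the canonical strong-curse regime — true
  effect 0.06 SD, SE 0.02, selection at P < 1e-5 (≈8% power) — where
  selection bias is severe; at high power the MLE's extra variance can
  exceed the naive estimator's bias, and the compromise estimator is then
  the better choice.
* **Effective tests (Li-Ji)**: m_eff = Σ[I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)] over the
  eigenvalues of the trait correlation matrix; eigenvalues are clipped at 0
  and snapped to integers within 1e-9 (⌊·⌋ is discontinuous, so 6 − 1e-15
  must count as 6).  α′ = α/m_eff.
* **GRS**: α̂ = Σ(wβ/se²)/Σ(w²/se²) with se(α̂) = (Σw²/se²)^(−1/2);
  heterogeneity Q on k−1 df; if P_het < 0.05 the SNP with the largest |β| is
  dropped and the score refitted until homogeneous.  h²_grs is defined as
  α̂²·Σw²·2f(1−f) (score variance under HWE and SNP independence on a
  unit-variance trait) — a definitional choice, flagged here because no
  single convention exists.
* **Conditional independence**: a lead-SNP effect is called independent of a
  conditioning proxy iff it changes by ≤ 20% between models and remains
  nominally significant (P < 0.05) in the joint model.
* **Power**: NCP = n·2f(1−f)·β²·r²; power is the upper tail of the
  noncentral χ²₁ beyond the central χ²₁ critical value at α; the minimum
  detectable effect inverts this by root-finding on (0, 5] SD (tolerance
  1e-10).  This is the standard additive-model formula, cross-checked
  against Monte-Carlo simulation in the tests.

## Problem sizes and numerical conventions

Calibration experiments use sizes fixed by the study conditions where those
exist (n = 4,000 with a 0.13 SD injected effect for recovery; 1,000 null
SNPs for the type-I error band) and otherwise sampling-noise arithmetic:
the genomic-control λ estimated from m null SNPs has standard error
≈ 2.33/√m, so the λ checks use m = 20,000 per study (SE ≈ 0.017).  All
randomness flows from explicit integer seeds (default 20190904) through
numpy `SeedSequence`; reruns are byte-identical, and run artifacts carry
provenance headers (stage, study, trait, λ, seed) without wall-clock
timestamps so that identical seeds give identical files.  Floats are
serialised with 12 significant digits; genomic coordinates are 1-based;
dosages count the effect allele (VCF ALT).

## Known limitations

The two-stage Reed1 fit is a deliberate simplification of a nonlinear
random-effects fit (no shrinkage of individual curves).  The generator's
independence of infancy and childhood random effects understates cross-trait
correlation.  PHV in the default parameterisation peaks very early
(interior, ≈0.5 months), so its estimate leans heavily on the earliest
visits.  No X-chromosome handling, no kinship or mixed-model association,
no LD-aware risk scores, and no imputation: dosages are consumed as given.
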