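# Methods

`actiprofiles` implements latent profile analysis (LPA) of children's
accelerometer-measured activity compositions, together with the
accelerometer-processing rules that produce those compositions, the model
selection and measurement-invariance machinery used around the LPA, latent
transition analysis between ages, post-hoc profile annotation, and a
synthetic cohort generator whose truth is anchored to published summary
tables for UK 10-11-year-olds measured before and after the COVID-19
lockdowns.

## The measurement model

Each child contributes a 4-vector

y = (M_wd, S_wd, M_we, S_we),

the proportions of accelerometer wear time spent in moderate-to-vigorous
physical activity (MVPA, M) and sedentary behaviour (S) on weekdays (wd)
and weekend days (we). Light activity is the simplex remainder
(1 − M − S per day type) and is not modelled directly. A K-profile model
is a Gaussian mixture with, for profile k:

* free means μ_k ∈ R⁴;
* a 2×2 within-day-type covariance block
  B_k = [[σ²_Mk, c_k], [c_k, σ²_Sk]] shared by the weekday and weekend
  blocks (variances equal across day types within a profile, free to
  differ between behaviours and between profiles, covariance c_k free);
* zero cross-day-type covariance given the profile (local independence);
* mixing proportions π_k.

This gives 7 free parameters per profile plus K−1 mixing proportions
(n_params = 7K + K − 1). The day-type tying and the single c_k per
profile are the most parsimonious structure consistent with the analysis
being reproduced; alternatives plug in by editing the M-step.

Children missing the weekend block as a whole contribute the weekday-block
marginal density (full-information maximum likelihood under missingness at
random). Any other missingness pattern is rejected with a logged count —
partial day-type blocks do not occur under the processing rules, which
drop or keep a day type wholesale.

### Estimation

EM with closed-form constrained M-steps. The weekend sufficient
statistics of weekend-missing children enter as their conditional
expectations given the current parameters (which, by cross-day-type
independence, are the current weekend means and covariance block). The
log-likelihood is asserted non-decreasing at every iteration; convergence
is a relative change below `tol` (default 1e-6, `max_iter` 1000).
Components are floored at π_k ≥ 1/(2N); hitting the floor or losing
positive-definiteness raises a restart signal.

Multistart (default 50 starts) initialises from k-means on
column-standardised complete cases (standardisation matters: the sedentary
columns otherwise dominate the distance), plus jittered k-means and random
assignments. The best log-likelihood is kept and flagged as replicated
when at least two starts agree within 1e-4. Fitted profiles are returned
in canonical order — descending guideline-weighted MVPA mean
(5·μ_Mwd + 2·μ_Mwe)/7 — to resolve label switching.

A fixed-measurement variant (`fit_with_fixed_profiles`) estimates mixing
proportions and posteriors only, for scoring a sample against profiles
estimated elsewhere.

## Model-fit battery

For K = 2…10: BIC = −2LL + p·ln N and the sample-size-adjusted variant
with ln((N+2)/24); normalised classification entropy
1 − Σᵢₖ(−p_ik ln p_ik)/(N ln K); an adjusted Lo–Mendell–Rubin-style
likelihood-ratio approximation (the LR statistic scaled by
1/(1 + 1/(Δp·ln N)) against χ²_Δp — an analytic approximation to a
non-standard null, reported as advisory only; the unadjusted variant is
exposed too); and a parametric bootstrapped likelihood-ratio test (BLRT)
of K−1 vs K. BLRT replicates are simulated from the fitted (K−1)-profile
model at the observed sample size and weekend-missingness rate; both
models are refitted per replicate with a reduced multistart (default 4
starts vs 10 for the observed statistic, 100 replicates, p-value
resolution 1/(B+1)). Measured under a true 1-class null (60 datasets ×
30 bootstraps, n = 300): empirical size 0.05 at nominal 0.05.

## Measurement invariance across groups

A multigroup model assigns each group a profile set — fixed in advance,
shared, or free — with group-specific mixing. Free parameters: 7K per
free set plus K−1 per group; fixed sets contribute none. The four-model
ladder for a reference sample (profiles fixed from its own fit) and two
new waves:

1. each wave free (least restricted);
2. both waves fixed to the reference profiles (full invariance);
3. second wave fixed to the reference, first free ("recovery");
4. the waves share one free set ("pre/post change").

Models 2–4 are tested against Model 1 by chi-square LRTs (α = 0.05) and
the most restricted unrejected model is selected (ties between Models 3
and 4, which share a df count, go to the higher log-likelihood).

**Known limitation.** With K = 6 weakly separated profiles and waves of
~400 children, each free profile set adds 42 weakly identified
parameters and the LR statistic runs heavier than its nominal chi-square
reference. The ladder therefore over-rejects true restricted models at
these sizes: in simulation the true model is selected in only ~30–60% of
seeds (rejections of genuinely false restrictions are essentially always
correct). The chi-square reference is retained because it is the
standard practice being reproduced; a parametric-bootstrap reference
would fix the size at substantial cost. The corresponding ≥85%
selection check in the acceptance suite documents this honestly by
failing.

## Latent transition analysis

For children observed at two timepoints with both profile sets fixed, EM
estimates initial probabilities α and the row-stochastic transition
matrix τ from
LL = Σᵢ log Σⱼₖ αⱼ τⱼₖ fⱼ(yᵢ,t1) fₖ(yᵢ,t2).
Movement toward lower/same/higher activity is summarised from the
model-implied flows αⱼτⱼₖ (or per-child joint posteriors), using explicit
activity rankings and an explicit t1→t2 profile correspondence for
"same" — profiles may be relabelled between timepoints, so identity is
never assumed.

## Profile annotation

The expected share of profile k meeting the 60-min/day MVPA guideline
treats the guideline-weighted MVPA proportion P = (5M_wd + 2M_we)/7 as
N((5μ_Mwd + 2μ_Mwe)/7, (29/49)σ²_Mk) and reports
P(P ≥ 60/mean wear time), with the cohort's average daily wear time in
minutes. Profiles are ordered most-to-least active by this probability
(ties: weighted MVPA mean, then index). The 5:2 day-type weighting and
the normal family are package choices, visible in the API.

Covariate differences between profiles use the BCH three-step method:
the classification matrix D (d_jt = Σᵢ p_ij 1[modal_i = t]/Σᵢ p_ij) is
inverted and each child weights into every profile by the row of D⁻¹
indexed by their modal class. Per-profile weighted means (proportions
for binary covariates) are compared by a Wald test with a child-level
sandwich variance, df = K−1. A near-singular D raises an error advising
that separation is too low for the correction. Note that BCH estimates
of proportions are unbiased but not range-respecting; for small classes
(a few dozen children) their sampling SD is large — around 14 percentage
points for a 7%-class in a cohort of 436 — and estimates outside [0, 1]
can occur.

## Accelerometer processing

Counts per 10-s epoch from a waist-worn device. Rules: (1) the
00:00–06:00 window is excluded outright; (2) non-wear is any span of
zero-count runs totalling ≥60 min where each non-zero interruption lasts
≤2 min (a total-interruption-budget variant is selectable, since the
prose rule admits both readings; both are oracle-tested); (3) wear epochs
classify sedentary (≤ sed_max), MVPA (≥ mvpa_min), else light — defaults
sed_max 16 and mvpa_min 383 counts/10 s, the widely used children's 15-s
cut-points linearly rescaled, exposed as config; (4) a valid day has
≥500 wear minutes; (5) inclusion needs ≥2 valid weekdays and ≥1 valid
weekend day; excluded children get reason codes. Minutes are conserved
exactly (sed + light + MVPA = wear). A sensitivity mode retains children
with no valid weekend day as weekend-missing rows for FIML instead of
excluding them.

## Synthetic cohort generator

The generator is the package's test bed and its defaults are the study
conditions: profile means and labels, mixing proportions per sample
(pre-COVID; post-lockdown waves 1 and 2), profile-conditional covariate
distributions (probability female, probability no degree-level education
in the household, mean structured/unstructured activity days) are taken
directly from the published tables. Compositions are drawn per profile
from the constrained bivariate-normal blocks with simplex violations
rejected and redrawn (preserving within-profile means); weekend blocks
are blanked missing-at-random (default 15%, inside the reported 6–30%
missingness range); daily wear is N(780, 60²) minutes clipped to
[500, 1080].

Two quantities the tables do not print are set by moment matching:

* **Within-profile variances.** The mixing-weighted mean within-variance
  is pinned by overall variance = within + between, with the between
  part fixed by the printed means and mixing; the overall weekday SD
  targets (0.03 MVPA, 0.07 sedentary pre-COVID; 0.03/0.06 post-lockdown)
  determine it exactly. Its allocation across profiles uses
  s_k ∝ exp(γ·z_k) with z_k the standardised weighted MVPA mean and
  γ = 0.7, normalised to preserve the overall SDs; γ is set so the
  model-implied classification entropy at default conditions matches the
  published 6-profile value (0.547). This allocation also implies a
  near-constant MVPA coefficient of variation (~0.3) across profiles.
  The implied overall *weekend* SDs (≈0.048 MVPA, ≈0.093 sedentary)
  agree with the published 0.05/0.09 without further tuning.
* **Covariance.** c_k = −0.5·σ_Mk·σ_Sk (negative MVPA–sedentary
  association); the reproduced analysis constrains c non-zero but prints
  no value.

Activity-day scores are drawn from a Beta scaled to [0, 6] with the
profile's printed mean and a common SD (moment-matched to the printed
overall SDs); the bounded family avoids the upward mean bias that
clipping a normal at zero would introduce. The two post-lockdown waves
share one measurement model and differ only in mixing (and covariates).

Paired cohorts draw a t1 profile from initial probabilities and a t2
profile from a transition-matrix row. Epoch-stream generation lays down
count streams whose processed compositions round-trip to the target
proportions within epoch rounding, with explicit ≥60-min zero runs and
the 00:00–06:00 zero block, for end-to-end testing of the processing
rules.

What the generator does not emulate: school-level clustering (not
modelled in the reproduced analysis either), device noise and bout
structure beyond class-consistent counts, non-normal within-profile
shapes, and informative (non-MAR) missingness. Passing recovery tests
therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to their violation.

## Problem sizes and numerical choices

Recovery checks run at the published sample sizes (n = 1296 pre-COVID;
393/436 post-lockdown waves; 805 longitudinal pairs; 100 000 children
for generator-moment checks). The test suite scales Monte-Carlo
replication to desk scale as a package choice: BLRT size at 40 null
datasets × 25 bootstraps (n = 300, 2 vs 1 classes), ladder selection at
10 seeds per truth with 8-start fits, transition recovery over 3 seeds.
EM tolerances: 1e-6 relative (1e-8 for fixed-measurement and transition
fits, which are cheap); component floor 1/(2N); k-means inits are
column-standardised; ties in canonical ordering break by weighted MVPA
mean then index. All randomness flows through
`numpy.random.default_rng` seeds; equal seeds give byte-identical
outputs.

At the published sample sizes the free K = 6 MLE is itself noisy: the
least-active profile's share (truth 19%) is recovered with ~2pp SD, the
combined least-active share (truth 34%) with ~3.5pp SD and ~2pp downward
bias. Multistart reaches the truth-basin likelihood (verified against
truth-initialised EM), so this is sampling variation of the estimator,
not an optimisation failure.
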