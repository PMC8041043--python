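# Methods

This note documents the model, the algorithmic and numerical choices, the
synthetic data that the test suite relies on, and known limitations.

## Model

The event-based model treats disease progression as a fixed sequence
S = (s(1), …, s(N)) of biomarker events, where an event is the transition
of one marker from its normal (pre-event) density p(x|¬E) to its abnormal
(post-event) density p(x|E). Every subject sits at an unknown stage
k ∈ {0..N}: events at positions ≤ k have occurred, later events have not.
With cross-sectional measurements xⱼ and a uniform prior over stages, the
sequence likelihood marginalises k per subject:

    P(X|S) = ∏ⱼ (N+1)⁻¹ ∑ₖ ∏ᵢ≤ₖ p(xⱼ,s(i)|E) ∏ᵢ>ₖ p(xⱼ,s(i)|¬E).

Missing measurements contribute a factor of 1 to both products (the subject
is simply uninformative about that marker). The likelihood is computed in
log space with prefix/suffix cumulative sums, O(subjects × N) per sequence,
with all densities floored at 1e-12.

Assumptions worth stating plainly: a single sequence shared by all
patients; monotone, non-remitting progression; subjects sampled
cross-sectionally at independent stages; conditional independence of
markers given the stage.

## Cohort preparation

1. **Risk grouping.** Patients with age at symptom onset ≥ 65 years (the
   `onset_threshold`, configurable) form the high-dementia-risk group
   (PDD-HR); younger-onset patients are PDD-LR. The threshold comparison is
   inclusive (≥).
2. **Control exclusions.** Controls with RBDSQ ≥ 5 (`rbd_cutoff`) are
   removed as probable prodromal REM-sleep-behaviour-disorder cases.
3. **Covariate adjustment.** Every marker is residualised against
   y ~ gender × (age + education), an OLS fit with an explicit 6-column
   design (intercept, male, age, education, male:age, male:education)
   **trained on controls only** and applied to everyone. Downstream,
   "abnormality" therefore means deviation from the control norm at the
   subject's own age, gender and education. Markers are adjusted on
   whatever scale they arrive in the table.
4. **Orientation.** After adjustment, each marker gets a sign (+1 if the
   patient mean exceeds the control mean, −1 otherwise, ties → +1) so that
   larger oriented values always mean more abnormal. Orientation is
   computed after adjustment because the percentile constraint below is
   defined on the adjusted, oriented scale.
5. **Screening.** Markers in the declared `screened_modalities` (by
   default the brain-iron QSM regions, mirroring a setting where a large
   atlas of candidate regions must be pruned) are retained only if a
   two-sided Mann–Whitney U test of PDD-HR vs controls gives p < 0.05,
   uncorrected. The exact null is used for combined samples ≤ 20 without
   ties, the normal approximation with midrank tie correction otherwise.
   Other modalities enter unscreened. UPDRS-style global motor scores are
   excluded by config default: they are abnormal in all patients by
   definition and would trivially dominate the early sequence.

Mixtures are estimated on controls plus PDD-HR patients
(`mixture_groups`); the sequence is estimated on all patients
(`sequence_groups`), under the working assumption that all patients follow
the same cascade. Both sets are configurable.

## Constrained KDE mixture

For each marker the pooled (controls + patients) q-quantile is computed
with the linear-interpolation convention (order statistic h = (n−1)q + 1);
q defaults to 0.90. Controls at or below the threshold are **forced
pre-event** — they can never carry abnormal responsibility; controls
strictly above it, and all patients, are free. This is the model's
interpretability anchor: fitted abnormality is disease-specific deviation
from control normality, with at most the extreme tail of controls allowed
to be called abnormal.

Fitting alternates weighted KDEs with responsibility updates:

- initialise r = 1 for free observations, r = 0 for forced-pre ones;
- f_post = Gaussian KDE weighted by r; f_pre = Gaussian KDE weighted by
  (1 − r) **restricted to controls**;
- bandwidths by Silverman's rule on each component's initial effective
  sample (neff = 1/Σw̃²), then held fixed;
- E-step r ← θ·f_post / (θ·f_post + (1−θ)·f_pre) for free observations,
  forced-pre clamped to 0; M-step θ = mean(r);
- stop when max |Δr| < 1e-4 or after 100 iterations.

Three design choices deserve justification, because the naive alternation
is unstable:

- **Control-anchored f_pre.** If f_pre is refit on all (1 − r)-weighted
  data, the pre-event KDE absorbs the abnormal mode whenever components
  overlap (as they do for late events), and the abnormal weight θ spirals
  to zero even on strongly signal-bearing data. Anchoring f_pre on
  controls both prevents this and matches the model's reading of the
  pre-event component as "normality".
- **Frozen bandwidths.** Refitting Silverman bandwidths each iteration
  creates a feedback loop: a shrinking component gets a smaller effective
  sample, a wider bandwidth, a flatter density, and even less
  responsibility. Freezing the bandwidths at their initial values removes
  the loop and makes each EM iteration a pair of precomputed-kernel
  mat-vecs.
- **Collapse as signal detector.** When the free data are distributionally
  identical to controls, the θ-weighted E-step still drives θ → 0 and the
  fit falls back to a single component (the fallback triggers when a
  component's effective weight drops below two observations). This
  collapse is deliberate and is the primary criterion for "no disease
  signal": on matched null data the marker is excluded in well over 90% of
  simulations, while late-cascade events with true post-fractions down to
  ~7% of the pooled sample survive.

A marker is excluded from the event set when (a) the fit collapsed, (b)
mean abnormal responsibility among patients is < 0.05, or (c) the median
of post-responsible values does not exceed the median of pre-responsible
values on the oriented scale. The precise form of this rule is a package
decision; only its existence is dictated by the modelling approach.

## Sequence inference

Greedy ascent (best improving pairwise swap per sweep, ties broken by
first occurrence in row-major scan order; 10 random restarts by default)
initialises a Metropolis sampler whose proposal swaps two distinct
uniformly chosen positions, accepted with probability min(1, exp Δlog L).
The first 10% of iterations are burn-in; the remaining states are recorded
without thinning (50,000 iterations by default; all settings in config).
The positional density D[e, p] is the fraction of retained samples placing
event e at position p; being an average of permutation matrices it is
doubly stochastic. Rows are displayed sorted by posterior mean position.
Priors are uniform over both sequences and stages. For N ≤ 6 an exhaustive
enumerator over all N! permutations serves as an independent oracle in the
tests, and the greedy+MCMC maximum agrees with it.

## Staging

Each subject receives the stage k maximising the subject's (unnormalised)
stage likelihood under the maximum-likelihood sequence, computed in log
space (essential at N = 42). Ties break toward the lower stage — the
conservative choice, assigning less disease — so a subject with all
markers missing has a flat profile and lands, flagged, at stage 0. Stages
are reported 0-based (0 = no events yet), positions 1-based; both
conventions are stated in every output header.

## Cross-validation and model similarity

Repeated stratified k-fold CV (defaults k = 5, 10 repeats → 50 folds)
refits the covariate model, the mixtures and the sequence on each training
80%, with strata {control, PDD-LR, PDD-HR} preserving the case/control and
risk mix per fold. The event set is fixed on the full data before CV so
fold models are comparable; a marker failing the disease-signal rule only
inside some fold is retained there but flagged in the fold diagnostics.
The final model pools all post-burn-in samples across folds (equivalently
a sample-count-weighted mean of fold densities, still doubly stochastic).

Fold agreement is quantified by BC = 1 − H̄² with H̄ the mean row-wise
Hellinger distance H(p, q) = √(1 − Σᵢ√(pᵢqᵢ)) — without the 1/√2
normalisation, which is what makes identical models score exactly 1 and
row-wise disjoint models exactly 0. The mean and SD of BC over all
unordered fold pairs are reported. The chance floor `randomized_reference`
builds models from uniformly random sequences and reports the mean ± SD of
BC over model pairs; with one sequence per model the analytic expectation
is E[BC] = 2/N − 2/N², and signal-bearing CV similarity must exceed this
floor. Note that the reference rises toward 1 as samples-per-model grows
(every row tends to the uniform distribution), so the single-sequence
reference is the meaningful chance level; its parameters are exposed
rather than hard-coded.

Staging accuracy uses a two-run protocol. Run 1: full CV, fold averaging,
and staging of every subject with full-data mixtures under the averaged
model's consensus sequence (events ordered by posterior mean position) —
the gold standard. Run 2, seeded with seed + 1: fresh CV; each fold stages
its held-out subjects under that fold's own mixtures and sequence; the
error is fold stage minus gold stage, aggregated over all (subject, fold)
test occurrences (subjects × repeats of them).

Cross-cohort comparison averages positional-density rows within modality,
renormalises, computes BC between the modality-level maps, and the Kendall
rank correlation (τ-a; exact two-sided p-value for ≤ 10 items) between the
two modality orderings by mean position.

## Synthetic cohorts

The generator draws exactly the structure the model assumes: a true
sequence S*, per-subject latent stages (controls: stage 0 with probability
0.9, else stage 1 — slight contamination that exercises the constrained
labelling; patients: uniform over 0..N, high-risk patients shifted 2
stages later, capped at N), and marker values N(0,1) pre-event vs N(d,1)
post-event with effect size d = 2 by default. On top it layers the
nuisance structure of real cohort tables: per-marker age/education slopes
and gender offsets (removable by the control-trained adjustment),
group-realistic demographics (control ages ≈ 64.7 ± 9, high-risk onset
≈ 70 ± 4, low-risk onset < 65), floor/ceiling censoring at (−2.5, d + 2)
per modality (producing the pile-ups KDE components exist to absorb), 5%
MCAR missingness, and a random half of markers stored sign-flipped to
exercise orientation. Generated controls keep RBDSQ < 5 so group sizes are
stable by construction.

Two layouts are provided: the discovery-style 42-event layout (8
clinical/cognitive, 6 vision, 4 retinal, 8 cortical-thickness, 4
substantia-nigra, 12 QSM markers; groups 33/64/36) and a 20-event
recovery layout with the same group structure, sized so that repeated
fit/recover experiments run in minutes on one CPU. The acceptance script
and the recovery tests use the 20-event layout with the full 50,000-iteration
sampler for single fits and a reduced (2,000-iteration, 2-restart) sampler
inside the 50-fold CV and the two-run staging protocol; these problem sizes
are the package's reference experiment scale.

What passing recovery tests do **not** show about real data: real effect
sizes are unknown and heterogeneous; real cohorts violate the
single-sequence assumption (subtypes), have non-Gaussian component shapes
beyond simple censoring, and have informative (not MCAR) missingness. The
synthetic study validates the machinery, not the clinical conclusions.

## Numerical conventions

- Quantiles: linear interpolation; "90th percentile" is convention-
  dependent, so this is fixed explicitly. Threshold ties stay forced-pre.
- Density floor 1e-12 everywhere log-likelihoods are formed.
- Orientation ties break to +1; greedy ties to first scan order; staging
  ties to the lower stage; all tie-breaks deterministic.
- All randomness (generation, splits, restarts, MCMC, run-2 seed = seed+1)
  derives from one configured seed via named SeedSequence paths; reruns
  are byte-identical, and numeric CSVs are written at 12 significant
  digits.
- Degenerate inputs: constant markers fall back to a single component and
  are excluded; a control-only or rank-deficient covariate design raises;
  subjects with missing covariates have their markers set missing with a
  warning.

## Limitations

- One sequence for all subjects; no subtyping, no continuous time scale.
- The disease-signal rule and the CV-similarity pairing (all unordered
  fold pairs) are package design decisions; alternatives exist.
- The EM initialisation anchors the abnormal component on everything the
  constraint leaves free; with very small true abnormal fractions the
  component can still collapse, which surfaces as a dropped marker rather
  than a bad density.
- Staging of heavily missing subjects is weakly identified; such subjects
  are flagged rather than silently staged.
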