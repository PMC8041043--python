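# ebmflow

Kernel-density event-based modelling of disease progression from a single
cross-sectional cohort.

## The problem

In slowly progressing neurodegenerative diseases — the motivating case is
Parkinson's disease in patients at elevated dementia risk — there is no
ground-truth axis of "disease time". Longitudinal data take a decade to
collect, and clinical scores suffer ceiling and floor effects that break
parametric models. Yet a single cross-sectional snapshot of patients at
different (unknown) stages already contains ordering information: if some
patients show abnormality in marker A with marker B still normal, but the
reverse pattern never occurs, A most plausibly changes before B.

The **event-based model (EBM)** formalises this. An *event* is the
transition of one biomarker from its normal (pre-event) to abnormal
(post-event) distribution. Assuming every subject follows one monotone
cascade of N events at an unknown stage k ∈ {0..N}, the likelihood of an
event ordering S = (s(1), …, s(N)) given subject measurements x is

    P(X | S) = ∏ⱼ  1/(N+1) ∑ₖ₌₀ᴺ  ∏ᵢ≤ₖ p(xⱼ,ₛ₍ᵢ₎ | Eₛ₍ᵢ₎) · ∏ᵢ>ₖ p(xⱼ,ₛ₍ᵢ₎ | ¬Eₛ₍ᵢ₎)

with a uniform prior over stages. The per-marker densities p(x|E) and
p(x|¬E) come from a two-component mixture whose components are *kernel
density estimates* — robust to the censored, lumpy shapes of clinical
scores — fitted under a **constrained control labelling**: a control
observation may be labelled abnormal only if it exceeds the pooled
(controls + patients) 90th percentile for that marker. The posterior over
orderings is sampled by Metropolis MCMC over permutations and summarised
as an N×N *positional density* (positional variance diagram). Subjects are
assigned the maximum-likelihood stage; robustness is assessed by repeated
stratified 5-fold cross-validation (10 × 5 = 50 fold models, averaged into
the final model), and models are compared with the Bhattacharyya
coefficient

    BC = 1 − H̄²,

where H̄ is the mean row-wise Hellinger distance between positional
densities (BC = 1 for identical posteriors, 0 for disjoint ones).

Because the real cohorts behind this kind of study are not redistributable,
the package ships a first-class synthetic-cohort generator that draws
cross-sectional cohorts from a known latent cascade — with covariate
confounds, floor/ceiling censoring, missing values and randomised marker
polarity — so the entire pipeline is testable end to end and parameter
recovery can be quantified against ground truth.

## Who it is for

Researchers in biostatistics and disease-progression modelling who want a
reproducible, tested EBM pipeline operating on a plain cohort CSV (one row
per subject, one column per biomarker, covariates and group labels), and a
simulation harness for method evaluation.

## Worked example

Generate a synthetic cohort (20-event cascade, 133 subjects: 33 controls,
64 low-risk and 36 high-risk patients, effect size d = 2), fit the full
pipeline and score recovery:

```python
import numpy as np
from ebmflow import PipelineConfig, fit_pipeline, generate_cohort, recovery_metrics
from ebmflow.simulate import default_recovery_config

cfg = default_recovery_config(seed=1)
table, truth = generate_cohort(cfg, seed=1)
pc = PipelineConfig(modality_of=table.modality_of,
                    mcmc_iterations=50_000, greedy_restarts=10)
fitted = fit_pipeline(table, pc, seed=1)

m = recovery_metrics(fitted.density, fitted.ml_sequence_names,
                     fitted.stages, truth)
print(f"Kendall tau vs the true cascade: {m['kendall_tau']:.3f}")
print(f"staging MAE vs true stages:      {m['staging_mae']:.2f} stages")
stages = np.array([s.stage for s in fitted.stages])
print(f"controls at stage 0:             {(stages[:33] == 0).mean():.0%}")
```

prints

```
Kendall tau vs the true cascade: 0.800
staging MAE vs true stages:      1.10 stages
controls at stage 0:             88%
```

i.e. the inferred maximum-likelihood ordering agrees strongly with the
generating cascade (Kendall τ = 0.80 over 20 events), subjects are staged
to within about one stage of their true latent stage on average, and almost
all healthy controls land at stage zero, as they should.

## Command line

```bash
ebmflow simulate --seed 42 --out cohort.csv --truth truth.json
ebmflow fit      --input cohort.csv --config config.yaml --out results/ --seed 42
ebmflow cv       --input cohort.csv --config config.yaml --out results/ --seed 42
ebmflow stage    --input cohort.csv --config config.yaml --out stages.csv --seed 42
ebmflow compare  --model-a a.csv --model-b b.csv --modalities map.yaml
```

`fit` writes the positional-density and cumulative-abnormality CSVs (with
heat maps), per-subject stages, serialized posterior samples and run
metadata; reruns with the same seed are byte-identical.

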