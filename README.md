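# radrepeat

Hierarchical Bayesian test–retest repeatability analysis for lesion-level
quantitative imaging features.

## The problem

When a patient with multifocal disease (e.g. bone metastases on whole-body
MRI) is scanned twice under identical conditions, every delineated lesion
yields a pair of measurements for each quantitative feature — the mean
apparent diffusion coefficient, a fat-fraction percentage, or any of ~100
radiomic texture descriptors.  Before such a feature can be used to monitor
therapy response, one must know how much of the observed variation is
measurement error and how much is real biology.  With only a handful of
patients but many lesions per patient, the naive per-patient or pooled
analyses waste information; a hierarchical model uses all of it.

`radrepeat` is for imaging scientists and biostatisticians running such
test–retest studies: it fits a three-level Bayesian variance-components
model to paired lesion measurements, derives the standard repeatability
statistics with full posterior uncertainty, screens features for redundancy,
and writes tabular Bland–Altman / ICC reports.

## The model

The measurement of lesion *j* in patient *i* at repeat *k* is modelled as

```
x_ij1 ~ N(mu_ij, sigma_r)        x_ij2 ~ N(mu_ij + eps, sigma_r)
mu_ij ~ N(mu_i,  sigma_p)        mu_i  ~ N(mu_0, sigma_0)
```

where `sigma_r` is inter-measurement error, `sigma_p` intra-patient
(between-lesion) variation, `sigma_0` inter-patient variation, and `eps` an
additive second-repeat bias.  SDs carry half-Cauchy(0, 5) priors, `mu_0` and
`eps` carry N(0, 10²) priors, and data are standardised by the baseline-1
mean/SD before sampling.  Posterior draws come from an exact conjugate Gibbs
sampler (3 chains × 2000 iterations, 500 warmup), with the classic
Gelman–Rubin diagnostic and a retry schema requiring R̂ ≤ 1.02 for 99 % of
parameters.  Derived per draw:

- `RC = 1.96·√2·sigma_r` — repeatability coefficient
- `ICCδ = sigma_p²/(sigma_p²+sigma_r²)` — intra-patient ICC
- `ICCΔ = sigma_0²/(sigma_0²+sigma_r²)` — inter-patient ICC
- within-lesion / between-lesion / between-patient coefficients of variation
- `LoA = (e^±1.96√2·sigma_r' − 1)·100 %` — limits of agreement for
  log-transformed features

A closed-form method-of-moments estimator (`radrepeat.oracle`) provides an
independent cross-check of the MCMC fit.

## Worked example

`examples/01_simulate_and_fit.py` simulates 10 patients × 8 lesions × 2
repeats from known parameters and fits the model:

```
simulated 80 lesions, 160 measurements
converged: True (100.0% of parameters with R-hat <= 1.02, 0 retries)
mu0      true  2.00   posterior median  2.022  IQR [1.911, 2.132]
sigma0   true  0.50   posterior median  0.493  IQR [0.414, 0.594]
sigma_p  true  0.30   posterior median  0.313  IQR [0.294, 0.333]
sigma_r  true  0.10   posterior median  0.102  IQR [0.097, 0.108]
epsilon  true  0.00   posterior median  0.004  IQR [-0.007, 0.015]
```

Each generating value is recovered within its interquartile range; the wide
`sigma0` interval reflects that only 10 patients inform the between-patient
SD.  The other examples cover the derived statistics (`02`), the lesion
eligibility / discretisation / first-order feature front-end (`03`), and the
full pipeline with redundancy clustering and reporting (`04`).

A thin CLI wraps the pipeline:

```
radrepeat simulate --config config.yaml --out cohort.csv
radrepeat all --config config.yaml --outdir results/ --reference firstorder_Mean
```

Input tables are long-format CSV with columns
`patient_id, lesion_id, repeat, feature_name, value` and exactly two repeats
per lesion-feature.

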