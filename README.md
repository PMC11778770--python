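# estihiv

Many HIV clinics — especially those with limited IT infrastructure — cannot
report patient-level data on everyone in care, and so cannot construct the
last two stages of the HIV continuum of care: the percentage of people in
care on antiretroviral therapy (ART) and the percentage virally suppressed
(VS). `estihiv` lets such a clinic produce those estimates from a **small
random sample** of its records instead, with a known precision, and tells it
how large that sample has to be and how much data-entry work it implies.

It is aimed at clinic staff and epidemiologists doing surveillance reporting
or self-auditing, and at methodologists who want to validate the sampling
approach on synthetic clinic populations.

## The calculation at its core

For a clinic population of size *N* with an anticipated suppression
proportion *p*, the sample size needed for a 95% confidence interval of
half-width *e* (e.g. ±5 percentage points) is

```
n0 = z² · p · (1 − p) / e²          (z² = 3.84)
n  = n0 / (1 + (n0 − 1) / N)        (finite population correction)
```

rounded up to the next whole person and capped at *N*. Estimates are
proportions with Wald 95% intervals, `p̂ ± 1.96·√(p̂(1−p̂)/n)`, computed on
the **number in care** as the denominator for both ART% and VS%. Two
conservative classification rules apply: a person with no viral-load
measurement counts as *not* suppressed (missing-as-failure), and an unknown
ART status counts as *not* on ART. Suppression means a most recent viral
load below 200 copies/ml by default (configurable, e.g. <500 copies/ml in
settings that use that threshold, or below an assay's limit of detection
when that limit is ≥ the threshold).

## Worked example

A clinic has 104 people in care and believes about 88.5% of them are
suppressed. How many records must it enter for a ±5-point estimate?

```
$ estihiv samplesize -N 104 --p 0.885 --e 0.05
population_size: 104
p: 0.885
e: 0.05
n0: 156.32639999999998
n_adjusted: 62.6929830514749
n_required: 63
workload_hours: 15.75
recommendation: random_sample
```

The infinite-population formula asks for 156.3 people; the finite population
correction shrinks that to 62.7 because the clinic only has 104, and rounding
up gives **63 records** — about **15.75 hours** of data entry at 15 minutes
per record. From an ordered paper file the clinic can then take every
`floor(N/n)`-th record (`estihiv sample --method systematic`), or draw a
seeded uniform random sample (`--method random`).

The full pipeline runs on synthetic data out of the box:

```
$ estihiv synth --profile respond --n 400 --seed 7 --output demo.csv
$ estihiv estimate --input demo.csv
overall: in care 400; on ART 397 (99.2%, 95% CI 98.4-100.0); VS 371 (92.8%,
95% CI 90.2-95.3); missing VL 3.5%
$ estihiv validate --input demo.csv --seed 11
N: 400
derived_p_vs: 0.9275
n_required: 83
...
VS_test: chi_squared
VS_p_value: 0.6403836662839969
```

`validate` sizes a sample from the population's own suppression rate, draws
it, and tests it against the non-sampled remainder — a non-significant
p-value is what a working sampling design should produce, about 19 times in
20. `estihiv simulate` repeats that over many synthetic populations to
verify the 5% type-I error rate, and `estihiv report` exports the Clinic
Continuum of Care table (overall and per risk group, small groups masked) to
CSV or JSON.

The same functionality is available as a library: `required_sample_size`,
`uniform_random_sample` / `systematic_sample`, `estimate_continuum`,
`stratify_continuum`, `generate_population`, and the experiment functions in
`estihiv.validation`. See `docs/methods.md` for the statistical details and
design choices.

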