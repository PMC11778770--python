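# Methods

## Problem and model

A clinic has `N` people in HIV care during a 12-month observation window
(each counted once, at their most recent visit). Two population proportions
are of interest: the fraction on antiretroviral therapy (ART) and the
fraction virally suppressed (VS). When entering all `N` records is
infeasible, a simple random sample of size `n` estimates both proportions;
`n` is chosen so that the 95% confidence interval for the suppression
proportion has a chosen absolute half-width `e`:

    n0 = z² p (1 − p) / e²,     n = n0 / (1 + (n0 − 1)/N),

with `z² = 3.84` and `p` the anticipated suppression proportion. `n` is
rounded **up** (rounding down can under-power; the worked 104-person example
is consistent with ceiling) and capped at `N`. The same `n` serves the ART
estimate: since `p_ART` typically sits further from 0.5 than `p_VS`, its
binomial variance is smaller and the interval narrower, so sizing on VS is
the conservative choice.

The correction divisor `1 + (n0 − 1)/N` is algebraically identical to
solving the exact finite-population Wald half-width
`z·√((p(1−p)/n)·(N−n)/(N−1)) ≤ e` for the smallest `n`, up to the use of
3.84 for z² instead of 1.96² = 3.8416; the test suite verifies agreement
with a brute-force search over the exact half-width to within ±1 person on
a grid of (N, p, e).

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `e` | 0.05 | CI half-width, absolute, 0–1 scale (±5 points) |
| precision presets | 0.025 / 0.05 / 0.10 | "very high" / "high" / "moderate" accuracy; only the ±5-point setting has an external anchor, the other two bracket it (a design choice, exposed so users can pass any `e` directly) |
| `p` | 0.5 if no prior estimate | anticipated VS proportion; 0.5 maximises p(1−p), never under-sizing |
| `z²` | 3.84 | two-figure 95% constant, kept as printed and exposed as a parameter |
| `vs_threshold` | 200 copies/ml | suppression cut-off; e.g. 500 in settings that define it so |
| `lod` | none | assay limit of detection; when ≥ threshold, values below it count as suppressed |
| minutes/patient | 15 | data-entry workload assumption behind `workload_hours` |
| masking minimum | 5 | strata smaller than this are reported counts-only |

## Classification and eligibility rules

* **In care**: seen at least once in the window; one row per person after
  most-recent-visit deduplication (ties on the visit date broken by the
  later viral-load date, then by input order — deterministic, so ingestion
  is row-order independent).
* **Eligible**: ≥ 18 completed years at the visit (birthday arithmetic; the
  18th birthday on the visit day qualifies). Unknown date of birth is a
  counted exclusion, never silently kept. A death dated before the window
  opens excludes the record; someone seen alive in-window who later died
  still counts as in care for that window — the data model carries death
  dates but no authority defines a stronger rule, so this is the package's
  choice and is flagged in the eligibility counts.
* **VS**: measured viral load strictly below the threshold (or below a
  dataset-level LOD ≥ threshold). Missing viral load ⇒ not suppressed.
* **ART**: recorded status "yes"; unknown ⇒ not on ART (mirrors
  missing-as-failure). Both conservative rules are configurable: a
  `complete_case=True` mode restricts each denominator to records with the
  measurement, and is clearly non-default.
* Denominator for both percentages is the full number in care, not the
  cascading denominators of the UNAIDS 95-95-95 framework.

## Sampling

* **Systematic**: interval `k = floor(N/n)` on a caller-supplied ordering
  (consistent with the 200/25 → every-8th guidance). When `n` does not
  divide `N`, the walk wraps past the end of the file until `n` distinct
  records are selected; if the wrapped walk re-enters its own cycle (k and
  N sharing a factor), it shifts one position and continues, so any
  `n ≤ N` is reachable. The start offset is drawn uniformly from `[1, k]`
  under a seed by default (keeps inclusion probabilities equal); a fixed
  start reproduces worked examples exactly.
* **Uniform random**: `numpy` PCG64 sampling without replacement. Ids are
  canonically sorted before drawing, so a given (ids, n, seed) triple yields
  the same sample regardless of file row order. Marginal inclusion
  probability n/N is verified empirically in the tests.

## Synthetic populations

The generator emulates the marginal structure of real clinic populations:
configurable ART coverage, marginal suppression under missing-as-failure,
missing-viral-load fraction, and demographic margins over age bands
(≤30 / 30–40 / >40), CD4 bands (≤500 / >500 / missing), eight gender/risk
categories, and years since diagnosis. Two presets reflect the populations
the method was developed and tested on: a seven-clinic 2017 population
(N=8852, 93.8% ART, 76.7% VS, younger, more recently diagnosed) and a
27-country 2019 cohort population (N=26426, 97.8% ART, 91.5% VS, 3.5%
missing viral load). The cohort preset's missing-VL rate is the reported
3.5%; the seven-clinic preset's is set to 5% — only one of its clinics had
substantial missingness and no overall rate is reported, so this is a
package choice of a realistic middle value. Printed margins that do not sum
exactly to 1 (rounding, structural zeros) are renormalized.

Because the suppression target is the *marginal* classified-suppressed
fraction, the conditional draw probability is rescaled by the non-missing
fraction — and, in the default nested mode (suppressed ⇒ on ART, since
suppression without treatment is rare), by ART coverage as well:
`q = p_vs / (p_art · (1 − p_missing))`. Targets exceeding that capacity
raise an infeasibility error rather than silently truncating.
`exact_counts=True` assigns exactly `floor(N·p)` of each state for
deterministic fixtures. Multi-population ensembles derive per-population
seeds from one master seed via `numpy` `SeedSequence`.

**What the generator does not emulate:** joint structure (CD4 × suppression,
age × risk group, clinic-level clustering), viral-load kinetics (magnitudes
are uniform nuisance values on either side of the threshold), longitudinal
histories, and non-random missingness. Passing tests therefore demonstrate
the estimator's and the sampling design's statistical properties under
clean marginal structure — not robustness to informative missingness or
measurement error in real registries.

## Validation experiments

* **Sample vs population**: size from the population's own realized VS
  proportion at `e = 5%`, draw uniformly, compare sample vs the
  *non-sampled remainder* (two independent groups — the default, and the
  basis of the type-I experiment) or vs the *total* population (provided
  because reports are often phrased that way; the groups overlap, so its
  p-values are descriptive). Pearson chi-squared without continuity
  correction; two-sided Fisher exact (minimum-likelihood definition) when
  any expected cell is < 5; α = 0.05 with no multiplicity adjustment, since
  the design question is precisely whether ~1 in 20 comparisons flags by
  chance.
* **Fixed-p sensitivity**: re-size using 71/80/90% instead of the derived
  estimate; lower p ⇒ larger n (p(1−p) increases toward 0.5).
* **Type-I error**: 2000 independent populations (N=500, p_vs=0.85,
  p_art=0.95), full pipeline each; the VS rejection fraction at α=0.05
  should sit near 0.05 (slightly below when Fisher's conservatism engages).
* **CI coverage**: 1000 populations of N=4000 at p_vs=0.85; the sample Wald
  interval should contain the realized finite-population VS proportion in
  ≈95% of replicates. The interval carries no finite-population correction,
  so it is honest only when the sampling fraction is modest (~5% at these
  settings, where measured coverage is ≈96%); at small N (say 500, where
  the tool-sized sample is ~28% of the population) the uncorrected width
  over-covers by construction (~98%) — a documented conservatism, not an
  error. Wald intervals also under-cover at extreme p̂ with few expected
  failures; the replication sizes above were chosen to keep Monte-Carlo
  error a fraction of the tolerance while the whole suite runs in minutes.

## Numerical and interface choices

* Wald intervals reproduce the printed aggregate CIs this method is anchored
  to (76.7% → 75.8–77.6 at n=8852; 97.8% → 97.6–98.0 and 91.5% → 91.2–91.8
  at n=26426) from rounded p̂ and n, which is why Wald (not Wilson or
  Clopper–Pearson) is the interval of record here; bounds are clipped to
  [0, 100], and z = 1.96 exactly at 95% confidence.
* Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  checks them against a full exact-integer hypergeometric enumeration for
  every 2×2 table with total ≤ 40, and the chi-squared statistic against
  the squared pooled two-proportion z.
* Dates are ISO 8601 in files and `datetime.date` in memory; empty string
  means missing; category labels match case-insensitively with logged
  normalization, unrecognized labels mapping to `unknown`.
* Reports export as CSV (fixed column order) or JSON (numerically exact
  round trip); human-facing output rounds to 1 decimal place, machine
  output keeps full precision.
* CLI exit codes: 0 success, 2 input-validation error, 3 parameter/domain
  error, 4 I/O error. Every seeded command is byte-reproducible, and sample
  selections write a JSON plan sidecar (method, N, n, k or seed, input
  checksum, version) for audit.

## Known limitations

* The entry-method recommendation (`enter_all` when the required sample
  already reaches `N`) has no margin: a clinic of 30 is told to sample 28.
  A cost-aware margin (e.g. enter all when n ≥ 0.9·N) may be more practical;
  the bare rule is kept because it is the defensible primitive.
* Wald intervals are known to misbehave at p̂ near 0 or 1 and small n; no
  alternative interval is offered because the Wald form is the anchor.
* One aggregate ART interval reported alongside the anchors (93.8% at
  n=8852 → 93.3–94.2) is not reproducible from the rounded inputs under
  Wald (which gives 93.3–94.3) or Wilson; the exact count or method behind
  it is unknown, and it is not used as an anchor.
* Stages 1–2 of the continuum (people living with HIV, diagnosed fraction)
  and UNAIDS cascading denominators are out of scope.
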