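# Methods

## Scope and model

`fishres` analyses pesticide multiresidue monitoring data for fishery
products in three stages.

**1. Method validation.** Spiked-recovery experiments (three spike levels —
LOQ, 10×LOQ, 50×LOQ — with five replicates each, per analyte and matrix)
are summarized as

- recovery (%) = mean(replicates) / spike × 100 (accuracy),
- %RSD = sd(replicates) / mean(replicates) × 100 (precision),

using the sample (n−1) standard deviation throughout, matching conventional
%RSD reporting. Calibration series are fit by unweighted ordinary least
squares of response on concentration; R² = 1 − SSres/SStot. The matrix
effect is the Matuszewski-style slope ratio,

    ME (%) = (slope_matrix / slope_solvent − 1) × 100,

interpreted as minimal when |ME| ≤ 20, strong when |ME| > 50, and medium in
between (both boundaries are closed toward the milder category). LOD and LOQ
are the concentrations reaching chromatographic signal-to-noise 3 and 10;
`lod_loq_from_sn` extrapolates them from one observed (concentration, S/N)
pair assuming S/N is linear in concentration near the LOQ — an approximation
that degrades far from the LOQ or when baseline noise is not constant.
Grading follows the Codex windows for multiresidue methods: recovery
70–120 % (inclusive), RSD ≤ 20 %, R² > 0.98 (strict).

**2. Censoring-aware monitoring summaries.** A residue record is either a
detection (concentration ≥ LOQ) or left-censored (below LOQ, concentration
absent). Censoring is an explicit boolean; no sentinel substitution happens
in the data layer. LOD/LOQ lookups resolve species → matrix class
(fish / crustacean / shellfish) → `default`, because only four of the
fifteen species were validated as matrices.

**3. Nine-scenario dietary exposure.** For each detected pesticide,

    EDI (ng/person/day) = DFI (g/person/day) × DPC (ng/g)
    %ADI = EDI / (ADI × body weight × 10^6 ng/mg) × 100

crossing three intake tiers (1 mean; 2 extreme = 99th-percentile intake of
the detected species; 3 extreme across species) with three concentration
estimators for n tests and d detections:

- A: (Σ detections + LOQ·(n − d)) / n — LOQ substituted for non-detects,
- B: Σ detections / d,
- C: max(detections).

A %ADI below 10 % (configurable) is classified minimal risk per FAO/WHO
convention. Options B and C are defined only over detections; with d = 0
those scenarios are emitted as *not evaluable* rather than silently
substituting the LOQ.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| body weight | kg | 60 | average adult consumer assumption |
| n tests per species | — | 20 | survey design (taken from data when records are supplied) |
| risk threshold | %ADI | 10 | FAO/WHO minimal-risk convention |
| tier-1 rule | — | detected-species mean | see "open aggregation" below |
| tier-3 rule | — | sum of per-species extremes | see "open aggregation" below |

**Open aggregation choice.** The tier-2 scenarios are fixed (extreme intake
of the detected species) and reproduce the reported hazard indices exactly.
The aggregation behind tiers 1 and 3 is genuinely underdetermined: no single
natural rule (detected species only, sum over species, with or without
LOQ-based contributions from non-detected species) reproduces the reported
tier-1/tier-3 ranges from the intake table. Both rules are therefore
explicit configuration (`tier1_rule`, `tier3_rule`, each `detected_species`
or `sum_all_species`) with the defaults above, and downstream consumers
should treat tier-1/3 numbers as rule-dependent.

**Consumption imputation.** Species missing from the intake survey are
imputed as half the minimum mean and extreme intake of their similarity
group. "Similar species" is user-supplied; the documented default grouping
is fish / crustacean / shellfish.

## Synthetic data generator

The generator emulates the monitoring study's structure with known ground
truth; its defaults are the study conditions:

- 15 species × 20 samples × 24 pesticides; detections are Bernoulli per
  sample with configurable probability (default 0: the packaged study spec
  instead *plants* one lufenuron detection at exactly 10 ng/g in one eel
  sample, mirroring the survey's single finding);
- detected concentrations are log-normal (median 10 ng/g, geometric SD 1.5)
  truncated below at the LOQ by rejection sampling — residues are positive
  and right-skewed, and truncation mirrors the censoring rule;
- recovery replicates: spike × R*/100 × (1 + ε), ε ~ N(0, CV*/100) — noise
  is multiplicative because CV is relative; defaults R* = 90 %, CV 5 % at
  LOQ and 2 % above, within the validated ranges; negative draws are
  truncated at zero and counted;
- calibration: response = slope·level (+ additive N(0, σ) instrument noise,
  default σ = 0.5 response units at solvent slope 3/ng·g⁻¹), with the matrix
  series scaled by a known factor (default 1.1, i.e. true ME = +10 %); the
  level grid is selected by the analyte's LOQ class from the five printed
  grids (LOQ 3, 4, 5, 7, 10 ng/g).

All draws come from a single integer-seeded `numpy.random.default_rng`
stream, so a fixed seed gives bit-identical output across runs and
platforms.

What the generator does **not** emulate: chromatographic peak shapes,
inter-day and inter-laboratory variation, heteroscedastic calibration noise,
correlated co-detections across pesticides, and species-level clustering of
contamination. Passing tests therefore demonstrate correctness of the
estimators and pipeline plumbing under the stated stochastic model, not
robustness to real instrument pathologies.

## Numerical choices

- R² of a zero-variance response is defined as 0 with a warning (OLS fits a
  flat line exactly; 0 flags the series as uninformative rather than
  perfect).
- Calibration designs with a single distinct level are rejected as
  degenerate; the schema already requires ≥ 3 distinct positive levels.
- Calibration is unweighted (no 1/x weighting): series span ≤ 2 orders of
  magnitude, where weighting changes little.
- The only unit conversion in the exposure chain is
  ADI (mg/kg bw/day) × bw (kg) × 10⁶ = per-person budget in ng/day;
  it is centralized in `percent_adi`.
- %ADI is carried at full float precision and displayed rounded to 4
  decimals (`format_percent_adi`).
- `compute_recovery` raises when the replicate mean is zero (%RSD
  undefined); `matrix_effect` raises on a zero solvent slope.
- Estimator order tie-break: with one detection, options B and C coincide by
  construction.

## Problem sizes in the test suite

The randomized suites use 200 scenario-engine cases against a brute-force
enumeration oracle (1e-12 relative), 100 random calibration designs against
a normal-equations oracle (1e-9 relative), 10⁴ randomized detection
summaries for ordering/monotonicity, and 10⁴ replicates for recovery
parameter-recovery (tolerance 0.2 percentage points ≈ 6.7 standard errors
at CV 3 %). The binomial detection-count check averages 300 seeds of the
20-sample design, a three-standard-error band around the expected single
detection. These sizes keep the full suite under a few seconds while leaving
each tolerance a comfortable multiple of its sampling error.

## Known limitations

- Deterministic point estimates only: no probabilistic (Monte-Carlo)
  exposure modelling, no cumulative multi-pesticide hazard index, no
  age/sex subpopulation stratification.
- Only one pesticide (lufenuron) ships with a packaged ADI; other analytes
  need a user-supplied toxicology table.
- The S/N-scaling LOD/LOQ estimator is a near-LOQ linearization.
- The packaged validation summary covers 4 of 15 species; limit lookups for
  the rest fall back to matrix-class or default rows.
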