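# Methods

This note documents the generative model behind `npcorona.simdata`, the
statistical conventions of the analysis modules, and the design choices
made where several defensible options existed. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## The corona-formation model

**Plasma proteome.** True concentrations `C_i` are drawn log-uniformly and
rescaled so the empirical log10 range equals the configured span exactly
(default 10 orders of magnitude, the span of the circulating plasma
proteome). Log-uniform is the maximum-spread choice per order of
magnitude: it makes "dynamic range" a sharp, testable invariant and
populates every abundance decade equally. Real plasma is closer to a few
dominant proteins plus a long tail; the simulator does not reproduce that
skew, which mainly affects absolute detection counts, not the analysis
contracts tested here.

**Affinities.** Each particle `j` gets an independent affinity vector
`a_ij` with `log10 a_ij ~ Normal(log10_mean, log10_sd)` (defaults −6 and
1.0, inverse-concentration units). Members of a few randomly chosen
annotation terms are multiplied by a bias factor (default 5), emulating
surface chemistries that favor particular protein classes; this is what
makes coronas distinct but partially overlapping, and what the 1D
enrichment analysis is designed to recover. No published per-protein
corona affinities exist to calibrate against, so these parameters are
exposed rather than asserted.

**Adsorption.** Corona composition follows single-site competitive
Langmuir binding:

    B_ij = S_j · a_ij C_i / (1 + Σ_k a_kj C_k)

with surface capacity `S_j > 0`. This is the minimal model with the two
properties the platform exploits: conservation (`Σ_i B_ij ≤ S_j`, asserted
exactly in tests) and affinity normalization of abundance. Note that
within one corona the denominator is shared, so `B ∝ a·C`: the slope
compression seen in log-log fits does **not** come from the binding
isotherm itself but from detection-limit censoring — at low `C` only
high-`a` proteins remain visible, which flattens the regression of
measured intensity on true abundance. Consequently the compression slope
returns to 1 when capacity (equivalently, the intensity scale relative to
the detection limit) grows without bound; the non-saturating limit is
asserted at ±0.02 with ≥ 2000 fitted proteins, matching the ordinary
least-squares standard error at the default affinity spread.

**MS observation.** Replicate intensities are
`I = scale · effect_condition · B_ij · LogNormal(σ)`, and each value is
independently censored with probability
`1 − logistic((log10 I − lod_mid) · lod_slope)`. Multiplicative log-normal
noise is the standard model for linear-scale label-free quantification
intensities; the logistic limit of detection reproduces the
intensity-dependent dropout of real LFQ data smoothly (real missingness
also has a missing-at-random component that is not modeled). Missing is a
sentinel (`NaN` in memory, `NA` on disk) — never zero, because a zero
intensity is physically meaningless and silently poisons downstream CVs
and log transforms.

**Noise calibration.** The dial `noise_cv` is defined as the **median
n-replicate sample CV** the assay reports, not the distributional CV of
the noise law. The identity `σ = sqrt(ln(1+cv²))` links σ to the
distributional CV, but the sample CV of triplicates is biased low (its
median is ≈ 0.83 of the distributional CV at n = 3), so a simulator using
the identity alone would report ≈ 18% when dialed to 22%. `observe_ms`
therefore inflates σ by numerically solving `median-sample-CV(σ) = cv` on
a fixed internal quasi-Monte-Carlo draw (secant iteration, cached,
independent of user seeds). Tests pin the recovery at nominal CVs 5%, 22%
and 50% to within 10% relative.

**Default observation constants.** `capacity = 1`, `intensity_scale =
1e12`, `lod_mid = 4.0` (log10 intensity at 50% detection), `lod_slope =
1.5`. At the default 5000-protein, 10-order proteome these place
1,600–1,900 proteins per particle above the 3-of-3 detection rule with a
visibly censored low-abundance tail — the regime in which a corona panel
is scientifically interesting. They are conventions, not fitted values.

**Perturbations.** Spike-ins multiply one protein's concentration by each
fold level (1× is the unspiked control). Contamination modes: `platelet`
multiplies a planted signature subset (default 2% of proteins) by
`1 + level`; `hemolysate` appends new proteins at level-proportional
concentrations with fixed log-spaced weights; `lipid` adds no proteins at
all — it models non-proteinaceous interference and exists so the pipeline
can demonstrate that protein IDs and quantities are untouched.

**Determinism.** One master seed; every stage derives its generator as
`default_rng([seed, stage, index])`. Simulated tensors are byte-identical
across runs, asserted at the TSV level.

## Analysis conventions

- **Detection**: a protein counts for a (particle, condition) only if
  observed in ≥ `min_replicates_present` replicates (default: all three).
  Relaxing the rule can only grow detected sets (tested as a property).
- **CVs** are sample-sd/mean on **linear** intensities, restricted to
  proteins passing the valid-value filter; the panel summary is the
  arithmetic mean of per-particle median CVs. `count_cv_below` with
  `best_per_protein` uses each protein's minimum CV across particles —
  the particle an assay would actually use for it.
- **Compression fits** regress log10 aggregated intensity (default:
  per-protein maximum across a particle's columns; median optional) on
  log10 reference abundance, with the standard OLS t-interval. Comparing
  particles is only meaningful on a shared protein subset, which
  `compression_fit(..., protein_subset=...)` supports.
- **Panel selection** maximizes unique protein IDs. Exact search
  enumerates combinations (guarded at 200,000; the guard error suggests
  greedy); greedy breaks ties lexicographically for reproducibility. The
  published screen does not state which search was used; exact and greedy
  bracket the possibilities and are cross-checked against each other.
- **Spike regression** is OLS of log10 intensity on log10 concentration.
  Pooled mode fits one slope with per-feature intercepts (peptide
  abundance offsets are nuisance); whether a single shared intercept is
  preferable is not decidable from the design, so both modes exist. A
  Theil–Sen variant is provided for outlier resilience. Intensities
  missing at low spikes are dropped, never imputed.
- **Fisher enrichment** uses the reference database as the universe: the
  2×2 is (in-panel vs not) × (annotated vs not) within the reference.
  Infinite log2 odds are clamped to the extreme finite value observed —
  for reporting only; p-values are never altered. BH adjustment is per
  annotation space (pooling spaces mixes incommensurate term families;
  a pooling flag is available).
- **1D enrichment** operates on difference scores (per protein: median
  normalized log10 intensity on one particle minus the mean of its
  medians on the others, requiring full replicate quantification on at
  least one particle). The score `s = 2U/(n₁n₂) − 1` counts
  member-over-non-member rank wins with ties as ½; the p-value is the
  two-sided Mann–Whitney test (exact when `n₁n₂ ≤ 200` and tie-free,
  normal approximation with tie correction otherwise). "Group size
  greater than 10" is implemented as ≥ 11. Terms are flagged when any
  particle clears the FDR level, mirroring how such heatmaps are
  reported.
- **Platelet index** uses natural logs (unlike the log10 used elsewhere —
  deliberate, following the index's definition) and is **not** invariant
  to global intensity rescaling: multiplying all intensities by `e^c`
  shifts both ln-medians by `c`, changing the ratio. The index is
  meaningful only within a fixed intensity scale; tests pin this exact
  behavior rather than assuming invariance. In the per-sample summary,
  zero-variance particle columns contribute 0 after centering (the
  standardization convention leaves them undefined; 0 is the continuous
  completion).
- **Classification** follows the biomarker-feasibility recipe: drop
  particle features whose protein also appears in depleted plasma, median
  imputation per feature across subjects (the only reading that defines a
  value when a subject misses a protein entirely), natural-log transform,
  no other normalization; stratified 10×10 repeated CV of a random
  forest; AUC per repeat from pooled out-of-fold probabilities;
  label-permutation control (one permutation per repeat) as the
  overfitting check.
- **Power** treats "detect a 50% difference" as a 1.5-fold mean shift on
  the log scale with `σ = sqrt(ln(1+cv²))`, two-sided two-sample t-test,
  per-test α = α/m, noncentral-t with df = 2n−2 and noncentrality
  `ln(Δ)/σ · sqrt(n/2)`. The sample size is interpreted **per group** —
  n = 25 total cannot reach 85% power at any plausible assay CV, so the
  per-group reading is the only self-consistent one. All assumptions
  (paired design excluded, equal variances, log-normal noise) are
  exposed as `PowerSpec` parameters.

## Problem sizes

Simulated experiments in the tests and the acceptance script use 300–6,000
proteins, 1–43 particles, 3 replicates and cohorts of 80–100 subjects:
large enough that every asserted property (CV calibration within 10%,
compression-slope ordering, ≥95% spike-slope recovery, FDR-controlled
planted-signal detection, permutation AUC within [0.45, 0.55]) has
comfortable statistical margin, and small enough to run on one CPU in a
few minutes.

## Known limitations

- Protein-group inference, peptide-level effects, digestion/ionization
  physics and retention time are not modeled; the simulation is at
  protein-group granularity.
- Log-uniform abundance and independent log-normal affinities understate
  the correlation structure of real plasma (e.g. lipoprotein families
  co-varying); passing tests demonstrate the correctness of the analysis
  contracts, not field performance on real coronas.
- Cohort-level empirical figures from real studies (classifier AUC on a
  real cohort, specific spike slopes such as 0.90, specific per-particle
  median CVs) depend on the underlying biological data and are outside
  what a simulation can or should reproduce; the corresponding recovery
  properties (true-slope recovery, planted-signal AUC, permutation
  control) are the testable surface.
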