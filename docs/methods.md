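# Methods

## The analysis pipeline

`lnmap` implements lesion network mapping (LNM): given a cohort of patients
with focal brain lesions and a behavioural outcome, it derives the brain
circuit whose connectivity to a lesion predicts that outcome, using a
normative connectome — a reference set of healthy-subject resting-state
scans — to estimate each lesion's whole-brain functional connectivity.

The chain is:

1. **Seed connectivity.** For each connectome subject, voxel timecourses
   are standardized (zero mean, unit variance over time) and the seed's
   reference timecourse is the (positive-weight) mean of its voxel
   timecourses. The map value at voxel *v* is the Fisher transform
   `z = atanh(r)` of the Pearson correlation between the reference and
   *v*, with `|r|` clipped at `1 − 1e−6` so z stays finite. Per-subject
   maps are aggregated across the connectome as a one-sample t statistic
   (`tmap`, the default) or as the mean z (`mean_z`). The aggregation rule
   is not dictated by the source method description; the t-map matches the
   wider LNM literature and `mean_z` is kept for sensitivity analyses.
2. **Circuit derivation.** At each analysis voxel the partial Pearson
   correlation between lesion connectivity and outcome is computed across
   patients, controlling for lesion size and depression severity (BDI) by
   default (residualize both variables on the covariates by least squares,
   then correlate the residuals). The map is negated so that positive
   values mark *protective* connectivity — connections whose presence in a
   lesion's network predicts lower outcome scores. Voxels with zero
   connectivity variance are set to 0 and flagged rather than failing.
3. **Validation.** Split-half reproducibility (spatial correlation between
   circuits derived in disjoint random halves), a permutation null that
   re-pairs connectivity maps with other patients' outcomes, out-of-sample
   prediction of held-out outcomes from lesion overlap (or connectivity
   correlation) with the half-derived circuit, leave-one-out prediction,
   network similarity profiling, and an a-priori ROI overlap test.
4. **Non-lesion generalization.** Within-circuit connectivity as a
   weighted-seed scalar per subject, linear association models against
   diagnosis, rank-transformed specificity models across control networks,
   and a connectome-wide association study by multivariate distance matrix
   regression (MDMR) with a circuit-enrichment odds ratio.
5. **Targeting.** Whole-brain normative connectivity to the circuit (the
   targeting atlas; positive peaks are candidate excitatory TMS targets),
   individualized circuit maps on a single patient's own scan, and
   peak/cluster-based target selection with 26-connected components.

## Statistical conventions

- Every permutation p-value uses the add-one convention
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, one-sided in the stated
  direction, so p is never 0 and the stored null makes p recomputable.
- Permutations shuffle outcome rows (covariates travelling with them)
  against connectivity maps, never the maps themselves; the lesion-to-map
  step is permutation invariant, so resampling reuses one cached map
  matrix per cohort.
- The split-half permutation null holds the split-allocation RNG fixed
  (same splits as the observed statistic), so null iterations differ only
  in the map-to-outcome pairing.
- Family-wise error control uses the max-statistic permutation
  distribution; cluster extent inference thresholds at a quantile of the
  pooled permutation null and compares observed cluster sizes against the
  null distribution of the largest cluster.
- VLSM uses a pooled-variance (Student) unpaired t, oriented as
  spared − lesioned so positive t marks protective voxels, with a
  minimum-overlap threshold of 4 lesioned and 4 spared subjects by
  default (configurable; the source description is silent on both counts —
  pooled-variance is chosen for determinism with tiny groups, Welch is
  available by flag). When the pooled variance is exactly zero with a
  nonzero mean difference (perfect separation), the t is set to a signed
  cap of ±100 rather than 0, preserving the direction of unbounded
  evidence.
- MDMR: profile distance `d = sqrt(2(1 − r))` on whole-brain profile
  correlations (the standard CWAS choice; the metric is not pinned down by
  the source), Gower centring `G = −½ H D² H`, partial pseudo-F from hat
  matrix traces, and Freedman–Lane residual permutation for
  covariate-adjusted inference (simple effect-column permutation by flag).
  The enrichment odds ratio applies Haldane–Anscombe +0.5 to all cells
  when any cell is empty; its permutation p re-ranks each stored null F
  map within the remaining ensemble, avoiding MDMR re-runs.
- The two-timepoint TMS trial model is the change-score regression
  `ΔPCL% ~ arm + Δconn + arm×Δconn [+ ΔIDS]`, with percent improvement
  `100·(pre − post)/pre`. A random-intercept backend fits the equivalent
  two-timepoint trajectory with each covariate entered both as a main
  effect and interacted with time; with that parameterization, the
  REML interaction estimate equals the change-score coefficient exactly
  and the t statistics agree to two decimals on constructed fixtures.
- Grids are never resampled implicitly: congruence (equal shape, affine
  elements within 1e−4 mm) is enforced on every binary operation, and an
  explicit `resample` (trilinear for maps, nearest-neighbour for masks)
  must be invoked by the caller. Masks binarize at strictly nonzero; NaN
  voxels leave the analysis mask.

## The synthetic world

Because the clinical datasets behind this method are not publicly
deposited, the `synthetic` module generates every input at desk scale with
the statistical structure the analyses assume. Defaults (all in
`SimConfig`): an 18×22×18 grid of 3 mm voxels with an ellipsoidal brain
mask (~3,300 voxels), a 40-subject normative connectome of 150-timepoint
runs (TR 2 s), and 5 latent networks.

- **Networks.** Voxels receive soft network memberships via a softmax
  (sharpness 3) over smooth Gaussian random fields (σ = 2.5 voxels). A
  subject's BOLD data are `coupling · (memberships @ network signals) +
  noise`, with coupling 0.6 and unit-variance noise.
- **Noise.** Observation noise carries mild spatial autocorrelation
  (Gaussian σ = 0.7 voxels, rescaled to unit marginal variance;
  `noise_sigma=0` recovers white noise). Real preprocessed BOLD noise is
  locally correlated, and this term matters structurally: with strictly
  white noise every lesion network map is exactly rank-K in the K network
  patterns, which makes split-half null spatial correlations geometrically
  wide and unrepresentative of real maps.
- **Planted circuit.** The first network's membership map, thresholded to
  its core support (membership ≥ 0.25).
- **Lesion cohort.** 120 spherical lesions (radius 2–5 voxels) at uniform
  in-mask centres. Each lesion's circuit score is the inner product of its
  aggregated connectivity map with the planted circuit; the latent
  liability is `−β·score + γ·BDI + ε` with β = 0.3725 and γ = 0.40,
  calibrated (by large-sample simulation of the liability model) so the
  ordinal outcome's partial correlation with the score is ≈ 0.30 and with
  BDI ≈ 0.30 after the 0/1/2 discretization. Outcomes cut the liability at
  Gaussian quantiles matching 48 % / 20 % / 32 % prevalence, so realized
  counts stay multinomial.
- **Non-lesion patients.** Same generative model; a PTSD patient's
  coupling within the planted network is multiplied by
  `1 + diagnosis_effect` (default −0.3). Comorbidity flags use the base
  rates of the emulated cohort (PTSD 34 %, TBI/subconcussive 56 %,
  depression via BDI ≥ 20 at roughly one quarter).
- **TMS trial.** Ten subjects per arm with pre/post scans; active-arm
  post-treatment circuit coupling shifts by a per-subject random factor
  (N(−0.4, 0.4), floored at 0) and percent PCL-5 improvement equals
  `10 · (−Δcircuit-z)` plus N(0, 2) noise; the sham arm improves by
  N(1, 2) noise alone. PCL-5 is clipped to [0, 80].

What the generator does *not* emulate: haemodynamics, distance-dependent
connectivity, head motion or physiological artefacts, realistic lesion
morphology, scanner/site effects, or item-level psychometrics. Passing
tests therefore demonstrate that the estimators recover the structure this
model plants at these sample sizes — not performance on real data.

## Calibration and power at desk scale

Under the global null (β = 0, diagnosis effect 0) the four permutation
tests — split-half similarity, max-statistic FWE peak, ROI overlap, and
MDMR — reject at α = 0.05 at rates inside [0.02, 0.10] across 100 seeded
null replicates (`lnmap.workflows.calibration_rejection_rates`, run on a
12×14×12 world with 50 lesions and an 8-subject connectome; MDMR on 30
seed voxels with 20 patients).

Power at the default effect size is a different matter. With an
outcome-score partial correlation of ~0.3, 120 lesions, and 5 latent
networks, the derived circuit recovers the planted one reliably
(spatial r ≥ 0.6 in 18 of 20 fresh-world replicates, typically 0.7–0.9)
and the CWAS enrichment OR exceeds 1 in 20/20, but the mean split-half
permutation test rejects in only ~14 of 20 replicates. The limiting
factor is structural: each outcome draw induces a pseudo-circuit in the
span of the K = 5 network patterns whose split-half correlation does not
shrink with more splits, so the permutation null of the mean split-half r
has a standard deviation of ~0.33 regardless of the Monte-Carlo budget.
Detecting the planted topography against that null at this effect size
has roughly 70 % power. The tests and the reproduction script report
these quantities as measured.

Monte-Carlo budgets were reduced from the source analyses' 1,000–10,000
resamples to 10–200 per test (identical estimators, smaller budgets);
problem sizes for each study are stated above and in the test code.

## Known limitations

- The connectome aggregation default (`tmap`) and the weighted-seed
  definition (timecourse averaging over positive weights; within-circuit
  score as the weighted mean of z over circuit voxels, seed voxels
  included) are documented choices where the source is ambiguous; both
  alternatives are exposed.
- `region_exclusion_robustness` assumes region granularity fine enough
  that excluding a region's lesions leaves most of the cohort; excluding
  lesions touching an entire latent network removes so many subjects that
  re-derived circuits are noisy.
- Cluster-level inference pools the permutation null across voxels when
  setting the detection threshold; with strongly non-stationary statistics
  a voxel-wise null would be preferable.
- The CLI holds whole connectomes in memory; cohorts at real MNI
  resolution (~200k voxels, 1000 subjects) need a streaming backend that
  is out of scope here.
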