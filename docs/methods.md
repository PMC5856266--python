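# Methods

## Forward model

Every voxel's time course in a simulated run is

    y(t) = Σ_c a_c(v) · (boxcar_c ⊛ h)(t) + drift(t) + ε(t)

where `a_c(v)` is the planted mean amplitude of condition `c` at voxel
`v`, `boxcar_c` is the union of that condition's epochs sampled on a
microtime grid of TR/16, and `h` is the canonical double-gamma HRF
(peak gamma shape 6, undershoot shape 16, dispersion 1 s, undershoot
ratio 1/6, 32 s support, rescaled to unit peak — the conventional
parameterization; the kernel peaks near 5 s). The GLM stage builds its
condition regressors with the same code, so the model is well specified
by construction: a noise-free simulate → fit round trip recovers the
planted amplitudes to ≤ 1e-6 (observed ~1e-15), which the tests assert.

Noise `ε` is Gaussian with marginal sd `sigma` (default 1.0, the unit in
which all effect sizes are expressed), optionally AR(1) with coefficient
`ar1_rho` (stationary; 50-sample burn-in). Drift is an optional Legendre
polynomial (off by default). Six motion traces are generated as random
walks (step sd 0.02) and included as nuisance regressors; by default
they do **not** contaminate the signal — a `motion_mix` coefficient
exists to test regressor efficacy.

## Task structure

Two sessions, four runs each. A run is a shuffled sequence of blocks;
each block is a rule-discovery epoch (one of verbal/spatial ×
separate/parallel search) followed by a confirmation and a
working-memory control epoch of the same domain, so all eight task
conditions occur in every run — the leave-one-run-out decoder requires
the four conditions of interest in every fold. Epoch durations are
uniform within ±30% of the session mean (17 s in session 1, 10 s in
session 2, reflecting practice effects); every epoch is preceded by a
blank drawn from the 2–8 s grid in 250 ms steps. One error epoch per
session lands in a random run; the design matrix simply has no column
for a condition absent from a run, and the error condition's rarity
exercises that path.

## Ground-truth scene

ROIs are non-overlapping ellipsoids (default six, sized from ~30 to
~490 voxels on a 36×36×30 grid). Inside every ROI all task conditions
respond, with rule discovery (1.0) > confirmation (0.6) > control (0.3)
> error (0.2), scaled by a per-voxel multiplicative gain (sd 0.3, shared
across conditions and sessions) so regions have a realistic response
topography; outside ROIs all amplitudes are equal. Three roles:

* **localizer-only** — activates, carries no domain information;
* **pattern-carrier** — adds a zero-mean multivoxel domain code of sd
  `sigma_pat` (default 0.5) to the rule-discovery conditions of the
  matching domain. Codes are drawn **per subject**: voxel-level codes do
  not align across participants (which is why the analysis decodes
  within subject), and sharing one code across subjects would make
  subjects statistically dependent and distort group-level calibration.
  Codes are constant across runs within a session; with `session_remap`
  (default on) they are redrawn independently per session, so
  within-session decoding succeeds while cross-session transfer sits at
  chance;
* **magnitude-confound** — verbal rule-discovery amplitudes uniformly
  exceed spatial ones by `confound_delta` (default 0.48) with no
  multivoxel structure. An unnormalized classifier decodes this region
  above chance; the mean-beta confound table exposes it, and the
  class-mean pattern correlation stays ≈ 1 (same response profile, only
  the gain differs).

The behavioral generator models exemplars-to-discovery as 1 + Gamma
(shape 4) with lognormal subject and subject-by-session gains
(cv 0.3 / 0.4), keeping every value ≥ 1 by construction; session grand
means default to 2.1 and 1.3 with small additive domain/search effects.

## Estimation and inference

**GLM.** Concatenated-run OLS with one condition column per
(condition, run), six motion columns and one constant per run. Residual
variance is RSS/(n − rank X); rank deficiency falls back to the
pseudoinverse with a logged warning. Contrast weights are stated per
condition and split evenly over that condition's run columns (so the
localizer contrast — each rule-discovery condition +1, each control −2 —
is invariant to how many runs a condition appears in). The group model
is a voxel-wise one-sample t over subjects' contrast estimates
(df = n − 1): for a single directional contrast this tests the same null
as a factorial group model but without the machinery. Exact
zero-variance voxels are flagged ±inf/0 rather than NaN.

**ROI definition** uses session-1 data only; masks are reused for
session 2. Peaks at one-tailed p < 0.001 under t(df); connected
components with 18-connectivity by default (6/26 configurable); labels
deterministically ordered by descending size then peak coordinate.
Cluster-extent control is a sign-flipping permutation: per iteration
each subject's contrast map is multiplied by a random ±1, the group t is
rebuilt and thresholded, and the maximum cluster extent recorded. The
returned threshold is the smallest integer k with
P_null(max extent ≥ k) ≤ α — defined through the tail probability rather
than a quantile so that, with the discrete, tie-heavy max-extent null,
keeping clusters of extent ≥ k genuinely controls family-wise error at α
(a ceiling-of-the-95th-quantile rule can be anti-conservative under
ties). Clusters below 25 voxels are discarded regardless (multivoxel
decoding needs features). Recovered clusters are renamed after the
best-Jaccard-overlapping ground-truth mask when that overlap ≥ 0.1.

**Decoding.** Linear SVM (`sklearn.svm.SVC`, C = 1.0 — unremarkable
default, configurable) on unnormalized betas; a `normalize` flag
z-scores each pattern for sensitivity analysis. Decision ties are broken
toward the lexicographically first class and logged. Leave-one-run-out:
4 folds, 6 training / 2 test samples each; subject accuracy is the fold
mean, group SEM is sd/√n.

**Permutation null.** Exchangeability is within run within subject:
each run's verbal/spatial pair is swapped or not, uniformly — this
preserves the run structure the cross-validation relies on. With four
runs a subject's 8-sample subset has exactly 2⁴ = 16 distinct
relabelings, so the implementation precomputes the LORO accuracy for all
16 and lets each of the (default 1000) permutations sample one per
subject — an exact reformulation, not an approximation; across 13
subjects the group null ranges over 16¹³ combinations. The critical
value is the empirical 95th percentile with "higher" interpolation, and
significance requires strictly exceeding it — both choices conservative.
Null distributions are stored in the run report so every significance
flag can be re-derived from the artifact.

**Cross-session transfer** trains on all 8 samples of one session's
subset and tests on all 8 of the other, both directions reported
separately. **Feature curves** evaluate subset sizes 10–100 (step 10),
10 uniform without-replacement draws per size, averaged within then
across subjects; sizes exceeding the ROI are skipped with a warning.

**Statistics.** The 2×2 repeated-measures ANOVA uses the standard
within-subject decomposition, each effect tested against its own
subject-by-effect interaction (df 1, n−1); sphericity corrections are
moot for 2-level factors; sums of squares below 1e-12 of the total are
snapped to zero so all-equal inputs report F = 0 exactly. The paired t
flags zero-variance differences (detected by exact equality, immune to
floating-point mean-rounding) as degenerate instead of raising.

## Determinism and seeds

One master seed. Every stochastic unit derives its generator from
`SeedSequence([master, crc32(tag), …key])` with a typed key (subject,
session, run, permutation stream, draw index), so any unit is
reproducible in isolation and simulating a subject subset reproduces
exactly the volumes those subjects get in a full run. Re-running a
pipeline with the same config and seed reproduces the report
bit-for-bit; the config is serialized verbatim into the output tree and
hashed into the provenance block.

## Scale of the shipped checks

The test suite and the calibration script run the full analysis path on
a reduced scene chosen to keep repeated simulation studies cheap while
preserving the study conditions that matter statistically: a 12×12×10
grid holding one ~50-voxel ROI, 13 subjects, 4 runs, the session-1 epoch
structure, noise sd 1. Chance calibration uses 50 replicate null
studies; the type-I-error check uses 100 null studies with
500-permutation nulls; planted-pattern recovery uses 50 seeds at
`sigma_pat/sigma = 0.5`. The end-to-end pipeline test uses a 16×16×12
grid, 8 subjects, three planted ROIs (one per role).

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: epoch
timing and jitter, nine regressors, run structure, session-specific
epoch lengths, a localizer-detectable response, a per-subject domain
code confined to one ROI, a uniform magnitude confound in another, and
session remapping. It does **not** emulate vascular or physiological
noise, spatial noise correlations or smoothing, inter-subject anatomical
variability, stimulus content (letters are abstracted to epochs),
reaction times, or realistic motion artifacts. Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated under its
assumed model — not that any particular real dataset satisfies those
assumptions. TR (2 s), grid size, and the noise model are explicit
stand-ins chosen as the smallest model that exercises every stage, not
reconstructions of any acquisition protocol.

## Known limitations

* No temporal filtering or prewhitening; AR(1) noise, when enabled,
  stresses robustness rather than being modeled.
* Random-field-theory cluster correction is intentionally replaced by
  the permutation scheme above; results can differ from SPM-style FWE.
* The ANOVA handles only the 2×2 within-subject layout the report
  needs.
* Ellipsoidal ROIs and equal-amplitude background are idealizations;
  cluster shapes in real data are irregular and background activation
  is structured.
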