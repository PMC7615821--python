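# Methods

## The problem and the pipeline

Category verbal fluency (naming as many animals as possible in 60 s) is
usually scored by the number of correct answers. The sequence of answers,
however, also carries information about *how* semantic memory is searched:
people who retrieve semantically related animals in runs produce answer
sequences whose consecutive words are close in meaning. `semfluency`
quantifies this with word-vector geometry and carries the statistic through
to cohort-level and brain-structure-level regressions.

The chain is:

1. **Semantic space.** Each word is a vector in a K-dimensional space;
   cosine similarity of two vectors measures similarity of meaning, and the
   Euclidean norm of a vector ("vector length", arbitrary units) tracks how
   specific or unusual a word is (very frequent words end up with shorter
   vectors). A space is either loaded from a word2vec-style text file (e.g.
   a pretrained German-Wikipedia LSA space of 526,004 words x 400
   dimensions) or built from a corpus by latent semantic analysis:
   term-document counts, log-entropy weighting
   `w[t,d] = log(1 + n[t,d]) * (1 - H(t)/log(D))`, then truncated SVD.
2. **Transcript scoring.** Every answer is normalized (NFC, lowercase,
   surrounding punctuation stripped) and NA-coded: disallowed answers
   (category names, breeds), later repetitions, and out-of-vocabulary words.
   Three statistics summarize a participant: the count of valid answers
   `n_correct`; the mean vector length of valid answers; and the **mean
   adjacent cosine similarity** — the average cosine over consecutive
   positions where both answers are valid. An NA between two valid words
   removes both of its pairs; the flanking valid words are *not* bridged.
3. **Cohort regression.** OLS of each fluency statistic on self-rated
   language interest (SAMQ language item, Likert -3..+3), `n_correct`, age
   and gender, with classical SEs and two-sided p-values on n - p residual
   degrees of freedom.
4. **Voxelwise GLM.** Gray-matter volumes (one aligned 3-D map per
   participant) are regressed voxel by voxel on the coherence score plus
   nuisance covariates (SAMQ, `n_correct`, age, gender, total intracranial
   volume). Voxel-level family-wise error is controlled by permutation.

## Scoring conventions

* **Order of checks:** disallowed -> duplicate -> out-of-vocabulary. A
  repeated disallowed word is disallowed both times; a repeated OOV word is
  OOV once and a duplicate afterwards.
* **Duplicates:** by default only occurrences *after* the first are NA (the
  second naming is the error; the first remains a correct answer). The
  strict reading — every occurrence of a repeated word is NA — is available
  via `duplicates="all"`.
* **Undefined scores:** a participant with no valid answer (undefined mean
  length) or no valid adjacent pair (undefined coherence) raises a
  participant-labelled error; the pipeline logs and excludes such rows
  rather than imputing.
* **Disallowed lexicon** is an input (one token per line); the rule was a
  manual instruction in the original task, so no lexicon is hard-coded into
  scoring. The sequence simulator ships a small German category-word list
  for injection testing.

## Builder conventions for the semantic space

Word vectors from the builder are rows of `U_k @ diag(s_k)`, i.e. term
coordinates scaled by singular values, so vector length reflects term
salience. At `k = rank` this representation is an isometry of the weighted
row space: pairwise cosines equal those of the weighted matrix (tested at
1e-10). SVD signs are fixed by making the largest-magnitude entry of each
left singular vector positive. `k > rank` is an error — no zero-padding, so
geometric claims stay honest. Pretrained spaces may follow other
normalization conventions; the loader is agnostic and the absolute
vector-length scale is therefore only comparable within one space.

The text format is the word2vec dialect: optional `"<n> <k>"` header
(validated when present), then `token v1 ... vk` per line, UTF-8. Written
files use 17-significant-digit decimals by default so a load/write round
trip is bit-identical; an 8-digit compact mode is idempotent after one
round trip.

## The synthetic generators: what they emulate, and what not

Real transcripts, questionnaires and MRI volumes from the study cannot be
redistributed, so the generators reproduce the *statistical shape* of each
input at the study's scale:

* **Clustered space** (`ClusterSpaceSpec`, defaults 8 clusters x 16 words,
  K = 40, separation 4): cluster members are isotropic clouds around
  centroids whose expected distance is `separation` within-cluster spreads.
  All vectors share a positive common component (`common_strength = 0.65`)
  so random word pairs have cosine ~0.2-0.3, as real distributional spaces
  do — without it the achievable coherence range would not include the
  study-scale mean of 0.364. Norms are drawn independently of direction
  around 2.811 (SD 0.48), matching the study's vector-length scale; the
  frequency-norm coupling of real LSA spaces is *not* modelled.
* **Retrieval model** (`RetrievalPolicy`): a single organization parameter
  lambda. At each position the next answer is the nearest-by-cosine
  unvisited word to the previous answer (probability lambda) or a uniform
  unvisited word (1 - lambda). This is the minimal model realizing the
  organized-vs-random retrieval dichotomy, adopted as an interpretive
  choice; it makes expected coherence monotone in lambda (tested on a
  lambda grid) but is not a cognitive-process model (no frequency effects,
  no fatigue, no within-minute time course). NA-triggering answers (OOV,
  repetition, category word) are injected per position with configurable
  probabilities.
* **Cohort** (`CohortSpec`, defaults n = 101): SAMQ histogram over -2..+3
  of 5/9/19/18/32/18; age truncated-normal 24.34 (SD 5.34) on [16, 40];
  23/101 male (gender is the male indicator; female is the reference
  level); item counts truncated-normal 25.62 (SD 5.479) on [14, 41],
  rounded to integers. Fluency scores follow a linear model in
  (SAMQ, items, age, gender) whose default coefficients are the study's
  point estimates (coherence model: intercept 0.374, SAMQ 0.004, items
  0.000, age -0.001, gender -0.005; length model: intercept 3.047, SAMQ
  -0.007, items -0.007, age -0.001, gender -0.012). Residual SDs (0.023
  and 0.09) were fixed once so that the implied t-ratios under these
  marginals sit at the study's reported scale (e.g.
  `SE(beta_SAMQ) ~ sigma / (sqrt(n) * SD_SAMQ) ~ 0.0016`, putting the SAMQ
  t-ratio near 2.4). Scores are either *injected* directly into the table
  (isolating the regression stage) or *realized* through transcripts by
  inverting the lambda-to-coherence calibration curve; the inversion is a
  calibration device only, not a claim about how language interest causes
  organized retrieval.
* **Volumes** (`VolumeSpec`): baseline intensity plus a spherical effect
  region whose intensity scales with the participant's centred score, plus
  Gaussian noise, smoothed at 6 mm FWHM on a 1.5 mm grid. No anatomy,
  tissue classes or registration error — passing tests show the GLM and FWE
  machinery behaves correctly, not that it would survive real preprocessing
  artefacts.

Because the synthetic conditions are idealized (exchangeable Gaussian
errors, exact alignment, linear effects), green tests demonstrate
correctness of the statistical machinery under the model, not robustness of
the scientific conclusion to real-data violations.

## Cohort statistics

`fit_ols` is a first-principles least-squares fit (QR-based solve,
classical covariance `sigma^2 (X'X)^-1`, two-sided p from the t
distribution with n - p dof); tests verify it against closed-form normal
equations and an independent library implementation to 1e-10. The df and
denominator conventions of the original analysis software are not
published; the classical convention used here is checked against the
printed t -> p consistency (t = 2.417 at 96 dof rounds to p = 0.018).
Exclusion filtering keeps rows with no missing-data flag and age <= 40
("over 40" excludes 41+, consistent with the study's reported age maximum
of 40). No multiple-testing correction is applied across the two cohort
models, mirroring the original analysis.

## Voxelwise GLM and FWE

Smoothing uses a separable Gaussian with
`sigma_vox = FWHM / (voxel_size * 2 sqrt(2 ln 2))`, nearest-boundary
handling (value range never exceeded), kernel truncated at 6 sigma so the
discrete kernel matches the closed-form Gaussian below 1e-6. The analysis
mask keeps voxels with mean intensity above an absolute threshold (default
0.1) and nonzero variance. ICV is the integral of the supplied intensity
map (sum x voxel volume); with synthetic volumes it is a head-size stand-in
covariate, not a tissue-based estimate.

Family-wise error is controlled by **Freedman-Lane max-T permutation**
rather than the random-field theory of the SPM tradition: nuisance
covariates are partialled out of the data and the regressor of interest
(Frisch-Waugh-Lovell, so the observed statistic equals the full-model
contrast t), residual rows are permuted, the permuted data are
re-residualized on the nuisance space, and each voxel's |t| is referred to
the permutation distribution of the image-wide maximum:

    p_fwe(v) = (1 + #{perm : max|T| >= |t(v)|}) / (1 + n_perm)

The test is two-sided. This choice is exact under exchangeability of
errors and requires no smoothness assumptions; on identical data it yields
slightly different adjusted p-values than a random-field correction, so
the validation target is nominal-level FWER control under a global-null
simulation (empirically <= alpha + 2 MC SE over 500 datasets) rather than
any single reported p-value. Contrasts are restricted to single-coefficient
selectors, which covers every design in this pipeline. Default 1000
permutations; fewer than 100 is rejected. Clusters are 26-connected
components (6/18 available) of supra-threshold in-mask voxels; peaks are
cluster maxima with ties broken by the lexicographically smallest voxel
index, reported in voxel indices and in world mm through the stack's
affine. For synthetic volumes the affine frame is arbitrary; no anatomical
labels are claimed.

## Orchestration and reproducibility

A run is configured by one YAML file and one master seed; each stochastic
stage draws a sub-seed as `sha256(stage_name:master_seed)` (stable across
platforms), and every output file gets a `.meta.json` sidecar with the
config hash and seed. Calibration of lambda to a target cohort-mean
coherence uses bisection with common random numbers (the same per-replicate
seeds at every lambda), making the Monte-Carlo objective deterministic and
monotone so the bracket is maintained; targets outside the achievable
interval [f(0), f(1)] are rejected with that interval reported.

## Problem sizes used in validation

Monte-Carlo suites run at sizes chosen to keep the full validation suite
fast while leaving Monte-Carlo error well below the tolerances they check:
parameter recovery and calibration use 200 replicate cohorts of n = 101;
the null FWER study uses 500 datasets of 40 volumes on a 12x12x12 grid with
500 permutations each; retrieval-monotonicity uses 200 sequences per lambda
on a 128-word space. Each tolerance is stated next to its test together
with the Monte-Carlo standard error it allows for.

## Known limitations

* The retrieval model is deliberately minimal; clustering/switching
  analyses in the neuropsychological tradition are out of scope.
* Vector length in a *loaded* pretrained space depends on that space's
  construction; cross-space comparisons of the length statistic are not
  meaningful.
* The VBM stage starts from aligned, normalized gray-matter maps;
  segmentation, spatial normalization and atlas labelling are out of scope.
* Permutation FWE assumes exchangeable errors across participants; it does
  not model temporal or family structure.
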