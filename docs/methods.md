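# Methods

## Setting and assumptions

The package operates on *response matrices*: per-subject GLM beta
coefficients arranged as stimuli × voxels, with string or integer
stimulus identifiers labelling the rows. All estimators assume the rows
of the two subjects being aligned are matched one-to-one by stimulus —
both subjects saw the same images — and that any repeat presentations
have already been collapsed by `average_repeats` (arithmetic mean per
stimulus). Matrices are validated on construction: unique ids, finite
entries, row/id agreement. No normalization is applied implicitly; both
alignment estimators expose a `center` flag (off by default, since the
fitted objectives contain no translation term) that fits per-voxel means
on the common set and re-applies them consistently at transform time.

Where data arrive as 4-D volumetric images, `mask_volumes` reduces them
to matrices through a boolean ROI mask. Voxels are linearized in C order
over axes `(x, y, z)` — last axis fastest — and this order is part of the
container contract: `scatter_to_volumes` inverts it exactly.

Stimulus ordering everywhere follows one deterministic rule
(lexicographic for strings, numeric for integers), so matching, decoder
fitting and evaluation are reproducible without recording permutations.

## Alignment estimators

**Anatomical baseline.** The identity map, valid only when both subjects
share a voxel grid. It represents what template registration alone
provides and is the control against which functional alignment is judged.

**Scaled orthogonal Procrustes.** Minimizes `‖c S R − T‖²_F` over
orthogonal `R` and scalar `c`. The closed form is `R = U Vᵀ` from the SVD
of `SᵀT`, then `c = tr(Tᵀ S R)/tr(Sᵀ S)`. Equal source/target voxel
counts are required and enforced (no dimension-matching scheme is
defined for the orthogonal case). For inputs with repeated singular
values the SVD minimizer is not unique; one valid minimizer is returned.
A rank-0 source matrix is an error. Fitted rotations satisfy
`‖RᵀR − I‖_max < 1e−8` (tested to machine precision in practice).

**Ridge voxel map.** Each target voxel is a linear combination of all
source voxels: minimize `‖S Wᵀ − T‖²_F + α‖W‖²_F`. `W` is stored with
one row per target voxel and may be rectangular (source and target voxel
counts can differ). The solution is the multi-output closed form
`Wᵀ = (SᵀS + αI)⁻¹SᵀT`; at `α = 0` the pseudo-inverse (minimum-norm
least squares) is used so rank-deficient designs do not fail. The
penalty is selected from the grid `[0, 1, 10, 10², 10³, 10⁴]` by k-fold
cross-validation (default 5 folds): a seeded shuffle followed by
contiguous splitting, scored by the coefficient of determination averaged
across target voxels, ties broken toward the larger penalty. Folds whose
validation split has fewer than two rows are skipped, since R² is
undefined there. The final map is refitted on the full common set at the
selected penalty.

**Subsampling for fraction sweeps.** `floor(fraction · n)` rows drawn by
a seeded uniform shuffle without replacement, identical rows for source
and target; fraction 1.0 returns the set unchanged. The floor convention
is a fixed choice; at the reference size of 952 common stimuli it gives
95 / 238 / 476 rows for the 10/25/50% fractions.

## Decoding and rendering

The decoder is a multi-output ridge regression from target-space voxels
to stimulus embeddings (default `α = 10`, same closed form as above,
optional intercept via mean-centering, off by default). Embeddings are a
single concatenated target space; the package does not weight sub-spaces
separately. Because generative image reconstruction is out of scope, a
fixed linear renderer (a seeded `k × h·w` Gaussian matrix, frozen at
creation) maps embeddings to small images. This keeps pixel-level metrics
meaningful — rendering is exactly linear, so image-space comparisons
reflect embedding-space fidelity — while making no claim about
photorealistic reconstruction.

## Metrics

*PixCorr* is the mean per-item Pearson correlation of flattened pixels; a
zero-variance image scores 0 with a warning. *SSIM* uses the standard
windowed formulation (Gaussian window 11, σ = 1.5, population
covariance, `C₁ = (0.01 L)²`, `C₂ = (0.03 L)²`), computed via
scikit-image; the dynamic range `L` defaults to the observed max − min of
the true images because synthetic stacks are not 8-bit. Images smaller
than the window require an explicit whole-image fallback flag that
evaluates the same formula on global statistics. *2-way identification*
is exhaustive: every ordered pair of distinct test items is a trial,
correct when the prediction for item *i* is more similar (Pearson by
default, cosine available) to its own ground truth than to the
distractor's; ties score 0.5, making chance exactly 0.5 under
exchangeability. Exhaustive pairing was chosen over sampled distractors
because it is deterministic and needs no pairing protocol choice.
Feature-space identification accepts pluggable extractors; the shipped
ones are identity-on-pixels and a fixed seeded random projection, which
are slot-compatible stand-ins for pretrained-network feature spaces.

## Synthetic cohorts

The generator draws a latent stimulus code `E ~ N(0, 1)` (n × k), mixes
it into target voxel space through a seeded `k × v` Gaussian matrix `A`,
and adds i.i.d. Gaussian noise. The source subject is derived from the
clean target signal per mode: a scaled rotation (`orthogonal`, with scale
`c0`, default 1.7), an arbitrary invertible linear map (`linear`), an
independent mixing of the same latent code (`independent_mixing`), or a
voxel permutation (`permuted_voxels`). Each subject sees the common block
plus its own disjoint unique block (ids are constructed so common ids
sort first). Default configuration: 1,200 stimuli per subject of which
400 are common, `k = 10`, `v = 60`, noise sd 0.5 — the clean signal has
per-voxel sd near `√k ≈ 3.2`, so this is a high-SNR regime in which the
estimators' asymptotic behavior is visible at small problem sizes chosen
to keep a full sweep under a few seconds on one CPU.

What this emulates — and what it does not: the generator reproduces the
*structural* premise of cross-subject alignment (shared latent stimulus
code, per-subject linear voxel mixing, shared + unique stimulus design).
It has no hemodynamics, no spatial voxel correlations, no session or
repeat structure, and Gaussian noise only. Passing tests therefore
demonstrate correctness of the estimators and pipeline under their own
model assumptions, not performance on real fMRI.

A point that matters for interpreting the baseline: composing the
decoder with a *fixed* wrong map (e.g. one drawn permutation of voxels)
gives an identification accuracy that fluctuates around 0.5 across
cohort draws but is fixed within one cohort — chance behavior is a
property of the ensemble, not of a single draw. Chance-level assertions
are therefore made on means over cohort seeds.

## Experimental designs

`run_fraction_sweep` trains the decoder once, on the target's unique
stimuli only (disjointness from every test set is asserted at runtime),
then for each method × fraction × seed: subsamples the alignment set,
fits the alignment, transfers the source's test rows, decodes and scores.
By default the test set at fractions < 1 is the common rows unused by the
alignment subsample; at fraction 1.0 the full common set is scored even
though those rows also fitted the alignment — when every shared stimulus
is spent on alignment, no untouched shared rows remain, and the decoder
itself has still never seen them. A `strict_test` mode instead reserves a
seeded quarter of the common set from alignment at every fraction. The
30-image visual hold-out of the reference design maps onto the
`exclude_ids` argument applied before matching. A failed cell (e.g. a
fraction too small to fit) is logged and recorded as NaN rather than
aborting the sweep. Results are long-format records (method, fraction,
seed, metric, value) aggregated as mean ± sd; the within-subject ceiling
(target decoded on its own test rows) is included as its own row.

`run_pair_grid` evaluates every source × target combination over the
cohort's shared stimuli, each target decoded by its own decoder —
diagonal cells are within-subject decoding, off-diagonal cells
cross-subject. `build_pseudo_common_set` ranks all cross-dataset cosine
similarities and greedily accepts one-to-one pairs above a threshold;
greedy (rather than optimal-assignment) matching is deterministic,
testable against a brute-force matcher, and mirrors simple retrieval.

## Numerical choices and limitations

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical seeds give
  bit-identical datasets, fits and sweep records.
- Containers are single-file `.npz` with named arrays (`betas`,
  `stimulus_ids`, `subject_id`; models carry a `kind` tag); roundtrips
  are bit-exact. NIfTI input is supported for volumes and masks.
- `α = 0` ridge uses minimum-norm least squares; tolerances in recovery
  tests are 1e−6 on constructed noiseless problems and 1e−8 on
  closed-form agreement.
- Procrustes with equal voxel counts only; ridge is the estimator to use
  across unequal grids.
- The identification score compares items within the test set only; it
  is not a retrieval-from-gallery accuracy.
- The decoder regularization (α = 10) is a fixed default, not tuned per
  dataset; cross-validating it is possible through the library but not
  done in the shipped experiments.
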