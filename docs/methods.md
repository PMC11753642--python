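# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the toolkit.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Moth-Flame Optimization core

The optimizer maintains N moth positions in a box `[Lb, Ub]^D` and an
elitist archive of N flames sorted ascending by objective value
(everything minimizes; callers with a score to maximize negate it).

Per iteration `t = 1..T`:

1. evaluate all moths;
2. rebuild flames as the best N of (previous flames ∪ current moths),
   using a stable sort so ties preserve first-seen order (flames before
   moths) — this guarantees the best-so-far fitness is non-increasing;
3. compute the flame count `R = round(N − t(N−1)/T)`, clamped to `[1, N]`,
   with .5 rounded half away from zero.  `R` is non-increasing and equals
   1 at `t = T`;
4. move each moth on a logarithmic spiral
   `x' = D·e^{bk}·cos(2πk) + f`, coordinate-wise, where `f` is moth i's
   own flame for `i ≤ R` and flame `R` otherwise, `D = |f − x|`
   per coordinate, and one `k = (a−1)u + 1, u ~ U[0,1]` is drawn per moth
   per dimension with `a = −1 − t/T`;
5. clamp to the box coordinate-wise (clamping, not reflection: the
   simplest repair that guarantees bounded positions).

Parameters: `n_moths` (N ≥ 2), `max_iterations` (T ≥ 1), `spiral_b`
(default 1 — the spiral shape constant has no canonical published value,
so it is exposed in the config), `seed`.  A single seeded NumPy generator
per run draws, in fixed order, the initial positions (moth-major, then
dimension) and the per-iteration k matrix, so identical (config, space,
seed) triples are bit-reproducible.

A moth exactly at its flame has `D = 0` and does not move; coordinates
clamped to a bound shared with their flame likewise freeze.  This is the
canonical behavior and contributes to premature convergence on highly
discrete landscapes (see Limitations).

## Wrapper feature selection

Selection searches `[0,1]^d` with MFO; a position becomes a mask by
`position > 0.5` (strict).  An all-false mask is repaired to the argmax
coordinate (lowest index on ties) so the search space stays closed.
Fitness is

    α · err_CV(mask) + (1 − α) · |mask|/d

with `α = 0.99`: classification error dominates and the size term only
breaks ties toward smaller subsets.  `err_CV` is the stratified k-fold
error (default 5 folds) of an inner classifier (default 1-NN: fast and
parameter-free) on the masked columns; the fold assignment derives from
the fitness seed, making fitness a pure function of (mask, data, spec).
Because many continuous positions map to the same mask, fitness values
are memoized per mask inside one selection run — a pure speed
optimization with no effect on results.

Two features of the design were genuinely open and decided here: the
fitness form (any monotone combination of error and size is defensible;
the α-weighted sum is the standard wrapper objective) and the
interpretation that selection runs once per extractor table, with fusion
applied to the two selected tables afterwards.

Default search budgets: N = 20 moths with T = 50 iterations for
small-dimensional problems (d ≈ 10); the d = 50 recovery study uses
T = 100, doubling the iteration budget in proportion to the larger
search space.

The exhaustive oracle enumerates all `2^d − 1` nonempty masks and refuses
d > 15 (32 767 CV evaluations is the practical ceiling); ties resolve to
the lowest enumeration index (mask bits little-endian in column index).

## Serial fusion

Fusion is plain column concatenation — no rescaling by default, because
the fused representation is meant to preserve each source's values
exactly (an optional per-column z-score standardizer exists but is off).
Alignment is enforced: equal row counts always, and row-for-row equality
of an explicit sample-id column when one is present, failing with the
first offending row.  Per-column provenance (source table, original
index) makes the fusion order auditable and the round-trip lossless.

## Augmentation

Three deterministic, label-preserving ops: 90° rotation
(counter-clockwise — the direction is not canonical anywhere, and
classification is direction-invariant), vertical flip, horizontal flip.
`augment_dataset` emits original + 3 transforms per image per repeat
(4× per repeat).  Published augmented dataset sizes are often not
integer multiples of the originals; `expand_to` therefore cycles the
eight dihedral-group compositions of the ops to reach any target count
deterministically rather than guessing an undocumented procedure.

## Extraction

Deep backbones are an adapter contract only (any callable or external
program producing a fixed-width feature table); the built-in extractor
cuts an RGB image into a g×g block grid (remainder pixels absorbed by the
last block row/column) and emits per-block, per-channel mean and standard
deviation: dimension `6g²`, values within [0, 255] for 8-bit input.  It
is a pure function of the pixels, so extraction is bit-reproducible.

## Classifier presets and metrics

The ten preset ids map to the widely used point-and-click semantics:
cubic/quadratic/medium-Gaussian SVM, LDA, subspace-discriminant ensemble
(bagged LDA on half-width random feature subspaces, 30 learners), kernel
naive Bayes, and fine (k=1) / weighted (k=10, inverse distance) / cosine
(k=10) / cubic (k=10, Minkowski p=3) KNN.  The abbreviation expansions
circulating for several of these presets are mutually inconsistent; the
registry docstring records the conflict and every hyperparameter is
overridable.  Kernel naive Bayes is implemented in-package as a per-class,
per-feature Gaussian KDE with Scott bandwidth (floored at 1e−9 for
constant features) because no suitable implementation exists in the
dependency stack.

Metrics use the one-vs-rest reading of the K×K confusion matrix; all
values are percentages, rounded only at presentation.  Undefined metrics
(zero denominators, e.g. precision of a never-predicted class) are NaN
and flagged, never coerced to 0 — coercion silently inflates or deflates
macro averages on small folds.  The evaluation protocol reports two
surfaces side by side — 10-fold CV on the stratified 80% training split,
and the untouched 20% holdout — because mixing them is a common source of
irreproducible accuracy claims.

## Synthetic data

`gen_features` plants `d_informative` signal columns among `d_noise`
N(0,1) noise columns.  Class means sit at the vertices of a regular
simplex (all pairwise distances equal to `separation`, in units of the
within-class σ = 1 — this makes recovery thresholds well defined),
rotated by a seeded random orthonormal matrix so every informative column
carries signal generically, then hidden by a seeded column permutation.
Ground truth (the informative indices) is always returned.  Defaults —
3 classes × 60 samples, 5 informative + 45 noise, separation 2σ — are the
reference study conditions used by the recovery tests.

`gen_images` renders a class-specific lesion (distinct shape + color
signature per class: disc/ring/streak in distinct colors) at a seeded
random position on a uniform leaf-green background, adds Gaussian pixel
noise (default sd 8), and clips to [0, 255].  Defaults: 4 classes × 40
images of 64×64 RGB.  What it does *not* emulate: real lesion texture,
scale and illumination variation, occlusion, background clutter, or
correlated noise — so passing pipeline tests demonstrate the plumbing and
the selection/fusion logic, not field-ready accuracy on real imagery.

## Pipeline and reproducibility

The orchestrator runs augment → extract (two block-stat extractors,
g = 3 and g = 5 by default) → select per extractor → fuse → evaluate
(F-KNN and Q-SVM by default), writing a config echo, ISO-8601-stamped
log, per-stage tables, selection audit records, and JSON reports.  One
global seed fans out through stage-name-hashed offsets
(`seed·1000003 + crc32(stage)` mod 2³¹), so stages are independently
re-runnable and a full run is reproducible from its config echo.

Problem sizes throughout the test suite (e.g. 10 optimizer seeds on the
5-D sphere, the d = 10 oracle study, the d = 50 recovery study, 5
pipeline seeds) were chosen as the smallest sizes at which the studied
effects are stable across seeds.

## Known limitations

- On near-discrete landscapes (thresholded selection), clamping plus the
  zero-distance fixed point lets much of the population coalesce onto
  flames; a 1020-evaluation run typically visits only a few hundred of
  the 1023 possible d = 10 masks, so the search can settle on local
  optima 2–4% above the exhaustive optimum when the CV error surface is
  rugged at moderate class separation.
- The inner CV error is a noisy estimate; with α = 0.99 the fitness
  landscape inherits that fold noise, which both creates spurious local
  optima and makes "global optimum" itself fold-assignment dependent.
- No constraint handling beyond box bounds, no parallel evaluation, no
  other metaheuristics.
- Multiclass AUC is intentionally not computed.
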