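# Methods

This note documents the models, numerical choices, and defaults behind
`flowimpute`, and what the synthetic test panels do and do not establish
about real instrument data.

## FCS reading and writing

The reader supports FCS 3.0 and 3.1 list-mode files with `$DATATYPE` `F`
(float32), `D` (float64), or `I` (unsigned integers of 8/16/32/64 bits,
widened to float), and both `$BYTEORD` orders. DATA offsets are taken from
the HEADER and cross-checked against `$BEGINDATA`/`$ENDDATA`; any
disagreement is an error naming both values, as is a `$TOT`/`$PAR`
combination inconsistent with the DATA segment's byte length. All TEXT
keywords are preserved verbatim; delimiter characters inside values follow
the doubling escape of the standard. ASCII data (`$DATATYPE=A`) and FCS
2.0 are deliberately unsupported — both are rare in modern cytometers. If
a file chains several datasets (`$NEXTDATA ≠ 0`) only the first is read,
with a warning. The writer always emits FCS 3.1, float32, little-endian,
one TEXT segment; offsets embedded in TEXT are resolved by fixed-point
iteration since their digit count feeds back into the segment length.

Channel identity across files is resolved in a fixed order — exact `$PnN`,
exact `$PnS`, case-insensitive `$PnN` — and every fallback match is logged.
`$PnE` log-amplification scaling is never applied implicitly: modern
float-mode files are already linear, and silent de-logging would corrupt
them.

## Transforms

The logicle transform is the inverse of the biexponential
`B(y) = a·e^{by} − c·e^{−dy} − f` parameterized by top-of-scale `T`, total
display decades `M`, linearization width `W` (decades), and extra negative
decades `A`. With `w = W/(M+A)`, `x₂ = A/(M+A)`, `x₁ = x₂ + w`, and
`b = (M+A)·ln 10`, the decay rate `d` solves
`2(ln d − ln b) + w(b + d) = 0` (Brent's method on `(0, b]`; `d = b` when
`W = 0`), and the remaining constants pin `B(x₁) = 0` and `B(1) = T`.
Below `x₁` the curve is the point reflection of the upper branch about
`(x₁, 0)`, which keeps it strictly increasing and C¹ through zero. The
forward transform inverts `B` per element by 60 rounds of vectorized
bisection on the display-scale bracket (grown adaptively for off-scale
values) followed by a Newton polish, to `|B(y) − x| ≤ T·10⁻¹⁰`; measured
round-trip error is ~10⁻¹⁵ relative.

Defaults: `T = 262144`, `M = 4.5`, `A = 0`; `W` is estimated per channel
from the 5th percentile `r` of the negative events as
`W = (M − log10(T/|r|))/2`, clamped to `[0.25, M/2]` (0.25 when a channel
has no negative events). Fluorescence channels get logicle; scatter and
time channels stay linear; arcsinh (`asinh(x/cofactor)`, default cofactor
150) is available per channel or globally. Regression runs on the
logicle-transformed scale by default; this choice is documented rather
than inherited, since transform scale interacts with the squared-error
objective (errors in the high decades would otherwise dominate).

Z-score normalization uses the sample standard deviation (n−1); a constant
vector maps to zeros with a warning. It is applied per channel *per source
file* when enabled, and is **disabled by default**: on panels whose files
differ in population composition, per-file standardization re-centers each
file on its own mixture, so identical raw backbone values map to different
model inputs in different files. The test suite quantifies this on a
two-file panel with identical marker biology and a 20%/80% vs 80%/20%
population split: predictions for identical backbone inputs diverge ~4-6×
more with z-score than without.

## Imputation

One XGBoost regressor (squared-error objective, `tree_method=hist`) per
(file, exploratory channel) pair; a file annotated with k exploratory
channels yields k independent models. Defaults: 500 boosting rounds,
learning rate 0.05, max depth 6, subsample 1.0, single thread. These are
the package's own defaults, chosen to reach the noise floor on
cytometry-sized problems (10–30 predictors, 10⁴ training events) in about
a second per model on one core; all are exposed in config.

Events are split 50/50 into training and validation halves, uniformly at
random without replacement; `|train| = round(fraction·n)` with round-half-up.
Validation MSE and MAE are both computed and stored on the regression
scale (reporting layers may log10 the MSE for plotting). Per-model seeds
derive from SHA-256 of `(run seed, file name, marker name)`, so adding or
removing a capture never perturbs the other models' splits or fits, and
single-threaded training makes runs bit-reproducible.

The surrogate-backbone evaluation trains one model per held-out measured
channel using only a designated subset of channels as predictors,
reporting MSE/MAE and Pearson r against the truly measured values — a
ground-truth self-benchmark requiring no synthetic assumption.

## Isotype background correction

For each marker m assigned an isotype-control column iso (via the
annotation's `isotype_group`; the control capture is the marker named
`isotype_<group>`), ordinary least squares fits `m = α + β·iso` across the
pooled events and subtracts `max(β̂, 0)·iso`. The slope is clamped at zero
because an isotype, measuring nonspecific binding, cannot legitimately
*add* signal back; a negative fit reflects sampling noise or confounded
population structure and is reported (with the raw slope) rather than
applied. The intercept is retained so correction shifts covariation with
background, not the marker's location. Whether the original workflow also
removes the intercept is not determinable from its description; the choice
here is fixed, and the fit report records (α̂, β̂ raw and clamped, R²) per
marker so the decision is auditable. Correction operates on the regression
(transformed) scale, where the imputed values live. Zero-variance isotype
columns are skipped with a warning; unassigned markers pass through
bitwise-unchanged.

## Assembly and export

Pooling mode samples `n_per_file = 10 000` events (default) from each
file's *validation* half, without replacement, deterministic per seed —
training events never enter the final object, keeping imputed values
out-of-sample. A shortfall takes all available validation events with a
warning. Reference mode instead uses every event of a separate
backbone-only FCS file, carrying its non-backbone channels along as
passthrough features. Feature order is fixed — backbone (transformed),
imputed, passthrough — and every event records its source file and
original row index. Export: h5ad (AnnData), feather, or CSV with
`meta_`-prefixed metadata columns; values are stored float32 on the
regression scale (raw-scale recovery is possible via the stored transform
parameters in `uns['run_meta']`).

## Downstream analyses

`embed_and_cluster` standardizes features (for the embedding only), runs
PCA (default 30 components, clamped to the feature limit with a warning),
a kNN graph (default 15 neighbours), Leiden community detection (default
resolution 1.0), and UMAP — all through scanpy, all seeded. Labels are
relabelled contiguously from 0 in decreasing cluster-size order.
`subcluster` reruns the stack on one cluster's events, namespacing child
labels `parent.child` and never touching labels outside the parent.
Defaults are the community-standard values for single-cell matrices of
this width; nothing downstream feeds back into imputation.

MarkerFinder is implemented in its single-pass form: each feature's
Pearson correlation against every cluster's 0/1 membership indicator, the
feature assigned to its argmax cluster (ties to the lowest cluster id),
ranked within clusters by descending r, top-n reported. Published
descriptions of the algorithm also include iterative-exclusion variants;
the single-pass form is the one fixed and tested here, and it agrees
exactly with a naive double-loop oracle on random matrices.

Label transfer is a deliberate nearest-centroid simplification of
community-alignment approaches (cellHarmony-style): per-event Pearson
correlation against reference centroids over name-mapped shared features
(≥ 3 required), argmax label, lexicographic tie-break with a warning, and
an `unassigned` floor at correlation 0.1. It is documented as a
simplification, not a reimplementation, of the full alignment algorithm.

## Synthetic panels

The generator emulates the multi-well study design: events drawn from a
mixture of multivariate-normal populations on the raw intensity scale
(channels independent given the population — the population structure
itself supplies the between-channel dependence that imputation exploits),
clipped at zero as a digital cytometer reports (a no-clip variant
exercises the logicle negative domain). Each exploratory channel is
`link(backbone) + N(0, σ) + β·isotype_background`, with link functions
spanning easy and hard regression regimes: linear, logistic (switch-like
expression), and two-channel interaction. Isotype-control files carry the
background signal alone. Population means default to 500–30 000 intensity
units with 30% CV, three populations at weights 0.5/0.3/0.2, noise at one
third of each marker's signal sd (signal-to-noise 3), and — when isotype
controls are generated — a planted background slope of 0.3 riding on a
backbone channel unused by the marker links. The 21-channel surrogate
panel derives 10 channels from 11 base channels with known links at the
same noise level, mirroring the measured-channel hold-out design at
20 000 events.

For additive independent noise the attainable imputation correlation is
`sd(link)/√(sd(link)² + σ²)`, estimated by Monte-Carlo from the generator;
imputation tests require each channel's validation r to reach this ceiling
within 0.05 and its MSE to stay within 1.2× the injected noise variance.

**What passing these tests does not show:** the generator produces no
spectral spillover, no compensation artifacts, no acquisition-time drift,
no doublets or debris, and population-conditional independence is an
idealization of real covariance structure. Accuracy on real captures
therefore still needs the surrogate-backbone self-benchmark on the data in
question, which the package provides.

## Problem sizes and determinism

Default test and acceptance runs use 3-file panels at up to 20 000 events
per file and the 21-channel surrogate panel at 20 000 events — sizes at
which every reported check, including full-pipeline runs, completes in
seconds to a few minutes on one core while using the workflow's actual
default hyperparameters. All randomness flows from a single run seed
through named SHA-256-derived sub-seeds; two runs with identical config
and seed produce bit-identical exported matrices.

## Known limitations

- No compensation/spillover handling; files are assumed compensated.
- FCS ASCII data type and FCS 2.0 are not read; multi-dataset files are
  read first-dataset-only.
- Isotype correction is global (one linear fit per marker across all
  pooled events), not per population.
- Label transfer is nearest-centroid only; no community alignment or
  per-cluster differential statistics.
- Exports are in-memory; no streaming/out-of-core path for datasets that
  exceed RAM.
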