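# Methods

This note records the models, conventions, and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
problem sizes the test suite and acceptance script run at.

## Group inference

Two-sample comparisons are two-sided throughout; published work in this
area reports Student t-tests for animal-level comparisons and a
Welch-modified t-test for microarray fragments, and we follow that split.
Welch degrees of freedom use the Welch–Satterthwaite approximation. When
both groups are internally constant but differ in mean, the tests report
t = ±∞ with p = 0 under an explicit `ZeroVarianceWarning` rather than
failing; fully identical inputs are a contract violation.

`t_from_summary` recomputes t from printed group moments,
t = (m_a − m_b) / √(sem_a² + sem_b²). It deliberately returns t alone: a
printed mean ± SEM determines the difference and its standard error but
published p-values are not reliably recoverable from those moments (the
motor-cortex worked number in the field's literature prints a p that does
not match any df consistent with its printed n), so attaching a p here
would imply more than the inputs contain.

BH adjustment is the standard step-up estimator, implemented directly (a
few lines) and cross-checked in the suite against
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` so the
implementation and its oracle stay distinct.

## Noise floor on the CV–mean curve

The noise floor is the linear-scale intensity below which the coefficient
of variation of a fragment across all samples (both groups pooled) starts
rising — additive scanner/background noise dominating a shrinking signal.
CV is computed on linear intensities (2^log2), since the phenomenon is a
linear-scale property, with sample standard deviation (ddof = 1).

Detection: LOWESS of CV on log2(mean), with three robustifying
iterations so genuinely regulated fragments — CV outliers when groups are
pooled — do not bend the curve. The fit is evaluated on a 40-point grid
spanning the observed log2-mean range, and sliding windows of 8 grid
points are tested for local linearity: a window passes when the residual
sum of squares of a straight-line fit is below
max((1 − R²_min)·SS_tot, n·tol²), with R²_min = 0.99 and
tol = 0.02 × the curve's range (never less than 2% of a tenth of the
typical CV, so a globally flat curve — linear with zero slope, where R²
itself is ill-conditioned — passes). Scanning from the highest mean down,
the floor is taken where the first failing window appears. Monte-Carlo
calibration on changepoint profiles of known corner location showed the
transition lies within one grid step **above** the first passing window's
start (the flatness guard admits the corner's mild upper tail), so the
reported floor is the midpoint of that one-step bracket, snapped to an
observed fragment mean. Defaults (span 0.08, window 8, grid 40) localize
the changepoint to within one grid step (≈ 0.28 octaves) across 40
generator seeds; all four knobs are exposed because no published protocol
fixes them.

Fragments with no value above the floor are discarded; surviving values
below the floor are set to it exactly (idempotent by construction).

## Differential expression

Welch tests run fragment-wise on log2 values; BH runs across all
fragments surviving the floor filter, not only annotated genes. Group
means are reported as linear-scale geometric means (2^mean-log2),
consistent with log2FC = mean log2(CSD) − mean log2(HC). The signed fold
change maps log2FC to the ±ratio convention (|FC| ≥ 1; down-regulation is
the negative reciprocal). Significance is the conjunction q < α and
|signed FC| > threshold (defaults 0.05 and 1.20); the order of the two
gates is immaterial under AND semantics. Category percentages round
half-up (68.52 → 69). Sample clustering uses 1 − Pearson correlation and
average linkage; scipy's deterministic lowest-index tie-breaking makes
the dendrogram reproducible given input order.

## ΔΔCt

Replicates are averaged on the Ct scale; ΔCt subtracts the
reference-gene (GAPDH) mean per sample; ΔΔCt subtracts the control-group
mean ΔCt per gene; fold = 2^(−ΔΔCt) with amplification efficiency fixed
at 2.0. Folds are formed per sample so a dispersion (SEM of per-sample
folds) can be reported; the group-level fold is the **geometric** mean of
per-sample folds — the fold scale is multiplicative, the geometric mean
is unbiased on the log scale, and it makes the control-group fold exactly
1 by construction. Parameter recovery at the generator defaults
(replicate sd 0.2 cycles, n = 6/5) carries ≈ 7% sampling noise per draw,
so recovery is assessed on across-seed means.

## FISH quantification

The vicinity rule reads "a circle with twice the diameter of the DAPI
staining" as a disc concentric with the nucleus — the only geometrically
coherent reading — of radius equal to the equivalent diameter (disc
factor 2.0, exposed). The boundary is inclusive, distances are
center-to-center, and calling is nucleus-centric: one spot may mark
several crowded nuclei, since cells are counted, not spots. ROI
membership uses the nucleus center (avoids partial-cell ambiguity),
boundary inclusive; membership and polygon validity go through shapely.
Coordinates are μm, origin top-left, y downward; 16 μm sections are
treated as projected planes. Area fractions threshold with Otsu by
default (no published threshold rule exists for the dense housekeeping
signal) or a fixed value, and report percent of in-box pixels at or above
threshold.

## Stereology

The counting surface is the closed hemisphere boundary: spherical cap
(2πr²) plus equatorial disc (πr²), S = 3πr². For an isotropic fiber
field, crossings of any closed convex surface satisfy E[Q] = ½·L_V·S
(Cauchy projection), so L_V = 2·ΣQ / (n·S) with no shape-specific
constant; the dense-sampling oracle in the test suite confirms the
counts and the 10-seed recovery run confirms the constant (mean absolute
error ≈ 2% at ~600 probes). A curved-surface-only variant (S = 2πr²)
remains selectable for comparison with instruments that count on the cap
alone. The flat face sits at z = guard with the dome pointing down,
mirroring guard-zone usage of 2 μm above and below the probe; z is not
randomized. Probe placement is a dx × dy lattice with one uniform random
offset per section, half-open at the far edges (a k·dx × j·dy rectangle
holds exactly k·j probes at zero offset, and the expected count equals
area/(dx·dy) exactly). Intersections are exact per-segment quadratic
roots on the cap (z ≥ z_face) plus segment–plane crossings inside the
open equatorial disc; tangential touches (double roots) count once; a
crossing exactly on the equator circle is measure-zero and attributed to
the cap. Section sampling enters only through the supplied reference
volume Σ(ROI area × thickness); there are no hidden fractionator
constants.

The estimator is exact only under isotropy: on an all-vertical fiber
field the closed-hemisphere estimate runs ≈ +33% high
(E[Q] = 2·L_V·πr² against S = 3πr²). `bias_report` computes and flags
this deviation rather than hiding it, and the suite asserts the flag.

## Synthetic generators

All generators are pure functions of their parameters and a seed; one
global seed fans out to named independent substreams
(`SeedSequence([seed, crc32(name)])`), so adding a generator never
perturbs existing fixtures. Truth tables serialize losslessly to JSON.

**Expression.** Linear intensities are lognormal around fragment-specific
levels drawn log-uniformly over 8–16384 (effect-carrying myelin fragments
over 128–8192, where well-expressed myelin genes sit). The CV is an exact
piecewise function of the expected level: cv_base = 0.12 above the floor
m0 = 32, inflating as (m0/level) below it. A changepoint model was chosen
over literal additive noise because additive noise yields a smooth CV
hyperbola with no well-defined corner, making "recover the floor" an
ill-posed target; the piecewise model reproduces the same low-intensity
CV inflation with an exactly known changepoint. Defaults: 2000 fragments,
100 myelin fragments with signed FC uniform in (−1.8, −1.2), n = 6 per
group. The 12% base CV gives per-gene standardized effects large enough
that a −1.6 FC is recovered with recall ≳ 0.95 at BH q < 0.05 — i.e. the
planted effects are unambiguous, as the strongly down-regulated myelin
genes are in real arrays. Not emulated: probe-level structure, batch
effects, inter-fragment correlation, RMA itself.

**FISH fields.** Nuclei are uniform in the ROI at 6 × 10⁻⁴ cells/μm²
(≈ 294 per 700 μm box) with truncated-normal diameters 8 ± 1 μm;
per-animal positive fractions jitter with sd 0.03 (≈ ±9 counts across
animals, matching published SEMs of 3–4 at n = 5). Planted-positive cells
get a zero-truncated Poisson(3) number of target spots inside their own
calling disc; negatives get none, but a neighbour's spot can fall inside
their disc, so measured fractions exceed planted ones, as in crowded
tissue. Planted fractions (HC 0.128, CSD 0.110) were calibrated once by
regressing measured counts on planted fractions so the measured box
means land near 45 (HC) and 39 (CSD). Not emulated: spot detection
errors, optical sectioning, nucleus segmentation failures, hard-core
(non-overlapping) nucleus packing.

**Fiber phantoms.** Chords of length 150 μm with directions uniform on
the sphere are centered uniformly in the slab dilated by half a chord
length — making length density stationary inside the slab — and clipped
to it (analytic Liang–Barsky for rectangular ROIs, shapely for general
polygons); the last chord is trimmed so total length hits
L_V × volume exactly. An all-vertical mode supports the anisotropy bias
check. Not emulated: curvature, fiber bundling, staining artifacts.

**Ct tables.** Per-sample global shifts (sd 0.3 cycles) model loading and
efficiency differences and cancel under reference normalization;
replicate noise has sd 0.2 cycles; a planted fold f shifts CSD target Ct
by −log2(f). Default folds mirror the array stage's planted myelin
magnitudes plus one strongly induced gene.

## Problem sizes and determinism

The suite runs its recovery checks at: 40/20-seed noise-floor profiles of
2000 fragments; 20-seed DE simulations; 10 replicates of 3 × 200
stereology probes (≥ 500 per replicate) with Lv = 0.05 μm/μm³ in
2000 × 2000 × 16 μm sections, plus a 30-replicate small-ROI unbiasedness
run; 100 random FISH fields against the all-pairs oracle; 20-seed ΔΔCt
recovery. These sizes put every Monte-Carlo assertion several standard
errors inside its tolerance while keeping the full suite around half a
minute. `scripts/acceptance.py` reruns the same computations from scratch
at comparable sizes under a user-supplied seed. Every random draw in the
package flows through `numpy.random.Generator` seeded from explicit
arguments; reruns with the same seed are byte-identical.

## Known limitations

- The noise-floor detector is calibrated against the generator's
  changepoint model; on real arrays whose CV–mean curve bends gradually,
  the "floor" is a band, not a point, and the reported value inherits the
  grid resolution (≈ 0.28 octaves at defaults).
- ROI polygons are user-supplied; no atlas registration is provided.
- FISH inputs are detected spot/nucleus coordinates; raw-image
  segmentation is out of scope, as are probe chemistry and confocal
  stack handling.
- The stereology stage assumes straight polyline segments between
  phantom vertices and isotropic fibers for unbiasedness; anisotropy is
  flagged, not corrected.
- qPCR assumes a common amplification efficiency of 2.0; no
  efficiency-corrected (Pfaffl-style) model is implemented.
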