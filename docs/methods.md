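# Methods

`rbploc` quantifies where an RNA-binding protein (RBP) sits inside cultured
neurons — nucleus, perinuclear cytoplasm, or neurites — from multi-channel
immunofluorescence z-stacks, and tests whether that distribution differs
between experimental groups. This note records the measurement model, the
synthetic data it is validated against, and the numerical and design
choices that were genuinely open.

## Measurement model

Each field of view is a confocal z-stack with three (or more) channels:
DAPI (nuclei), βIII-tubulin (somata and neurites) and one or more protein
channels. The stack is reduced to a per-channel maximum-intensity
projection; all intensity measurements are taken on the unrescaled
projection.

**Nuclear mask.** The DAPI projection is linearly pre-scaled to a fixed
0–500 range (detection only — measurements never use rescaled data),
smoothed (Gaussian, σ = 1 px), Otsu-thresholded, hole-filled and
size-filtered (≥ 10 µm²). Touching nuclei are split by marker-controlled
watershed on the Euclidean distance transform, with seed maxima separated
by at least one typical nucleus radius (4 µm). Border-touching nuclei are
flagged, not removed.

**Neuron gating.** Detected nuclei are kept if area ∈ [25, 300] µm²,
eccentricity ≤ 0.95 and mean DAPI intensity falls inside a configurable
gate. This is an explicit, auditable stand-in for per-object neuron
classifiers used by commercial HCS software; every gate value and each
cell's pass/fail record is logged in `params_used`.

**Perinuclear ring (cytoplasmic compartment).** For each nucleus, the ring
is the set of background pixels within 1.5 µm (converted to whole pixels;
5 px at the 0.3 µm/px default) of that nucleus and nearer to it than to
any other nucleus. Distances are exact Euclidean between pixel centers;
contested pixels go to the nearest nucleus with ties broken toward the
lower label id. The implementation (per-label distance transforms +
argmin) is pixel-identical to an exhaustive all-pairs distance
computation, which the test suite verifies directly.

**Neurite mask.** Tubulin foreground (Otsu by default, fixed threshold
optional; σ = 1 px smoothing; speckles < 20 px removed) minus every pixel
within 30 px (Euclidean) of any nucleus. The 30 px expansion is kept in
pixel units deliberately — it is an acquisition-specific convention, and
its physical size therefore scales with pixel size (9 µm at 0.3 µm/px),
which removes somata entirely for the cell geometries considered here.

**Ratios.**

- Per cell: `N:C = mean(protein | nucleus k) / mean(protein | ring k)`.
  Cells with an empty ring carry a QC flag and no ratio; border-touching
  cells are measured but flagged, and both classes are excluded from N:C
  aggregation while still contributing pixels to field-level pooling.
- Per field: `Nu:Ne = pooled mean(protein | all selected nuclei) /
  mean(protein | neurite mask)`. Pooling is pixel-weighted (a field-level
  mask measurement), not an average of per-cell means; the suite checks
  the equivalence `pooled mean = pixel-count-weighted mean of per-cell
  means`.
- Both ratios are invariant to any positive rescaling of the protein
  channel. No background subtraction is applied by default (an optional
  constant offset exists), so measured ratios include the (small) additive
  background.

**Compartment attribution.** A change in N:C or Nu:Ne does not say which
compartment moved. The marker channels are therefore measured through the
identical masks, and each protein compartment mean is referenced to its
marker: nuclear/DAPI and neurite/tubulin. Comparing these marker-referenced
means between conditions yields a per-compartment relative change; a
compartment is called changed when |relative change| ≥ 5% (configurable).
The threshold is far below the effect sizes of interest (20–50%) and far
above the sampling noise of pooled field means (~1–2%).

## Aggregation and statistics

Values ascend the nesting cell → field → well → line by **unweighted
means** at each step. Comparisons are run at the level matching the
assay's plotting conventions: N:C per well, Nu:Ne per field (both
configurable). Per-line means are emitted as display overlay points only
and never enter the tests.

Before testing, every value is divided by the mean of the untreated
control group within its experimental repeat, making each repeat's control
mean exactly 1 and rendering values comparable across repeats. The
operation is idempotent, and a repeat without control rows is a hard
error.

Two-group comparisons are gated on normality: D'Agostino–Pearson omnibus
at α = 0.05 per group (Shapiro–Wilk below n = 8, where the omnibus
moments are unstable; groups under n = 3 cannot be gated and force the
rank test, logged). If both groups pass, an unpaired two-tailed
pooled-variance Student's t-test is used (Welch by flag); otherwise a
two-sided Mann–Whitney test. For pooled n ≤ 12 the Mann–Whitney p is
exact: the null distribution of U over all C(n_a+n_b, n_a) group
assignments is built by dynamic programming over doubled midranks (so ties
are handled exactly), and the two-sided p is the probability of
min(U, n_a·n_b − U) at least as extreme as observed. Above n = 12 the
normal approximation with tie correction is used. Significance stars at
0.05 / 0.01 / 0.001.

**No multiple-testing correction is applied across proteins** — each
protein's comparison is reported on its own, as is conventional for this
assay style. Users screening many targets should correct downstream.

## Synthetic data

Because validation requires pixel-level ground truth, the generator builds
scenes of n non-overlapping circular nuclei (radius 3.5–5 µm by default)
inside circular somata (6.5–9.5 µm, constrained to leave a cytoplasm
annulus wider than the 1.5 µm ring), each with 1–3 neurites grown as
smoothed random-walk polylines from the soma boundary (40–80 µm long,
1.5 µm wide). Ground-truth nuclear / soma-cytoplasm / neurite masks are
disjoint by construction. Placement is rejection-sampled with a bounded
budget; an infeasible density raises a "field too crowded" error.

Rendering: each channel's in-focus plane is background plus the
per-compartment means painted on the truth masks, convolved with a
Gaussian PSF (σ = 0.2 µm, near-diffraction-limited confocal); out-of-focus
slices attenuate the signal by a Gaussian falloff in z (σ = 1.5 µm,
1 µm z-step), so the noise-free max projection equals the in-focus slice
exactly; per-slice noise is scaled-Poisson plus additive Gaussian
(sd = 5 a.u.), clipped at zero. Default intensities: protein
200/100/50 a.u. (nucleus/cytoplasm/neurite, so true N:C = 2 and
Nu:Ne = 4), DAPI 300, tubulin 150/120, background 1 a.u. The background
is deliberately small relative to signal: measured ratios include it
(no subtraction by default), and with these values the additive bias on
the true ratios is ≲ 1.5%, comfortably inside the recovery tolerances
while keeping a physical noise floor. An optional per-cell lognormal
brightness factor models staining variability (off by default; when on,
`SceneTruth` accounts for it in the field-level truth so ground truth
stays exact). Pixel size defaults to 0.3 µm/px, typical of a ×40
high-content objective; all µm widths convert to pixels by rounding to
the nearest integer ≥ 1.

Plate-scale experiments replicate the nesting of a screening assay:
lines (each labelled with a condition) × repeats × wells × fields, with
per-condition, per-channel compartment multipliers. The canonical
mislocalization preset (`MUTANT_EFFECT`: nuclear ×0.8, cytoplasm ×1.2,
neurite ×1.5) reproduces the disease-like pattern of reduced N:C and
Nu:Ne driven by nuclear loss plus cytoplasm/neurite gain.

What the generator does **not** emulate: staining chemistry,
photobleaching, spatially varying illumination, out-of-focus light from
other z-planes (true 3-D PSF), autofluorescence texture, or realistic
neurite morphologies (fasciculation, branching is off by default).
Passing recovery tests therefore demonstrates correctness of the
measurement and inference chain under a faithful geometric/noise model,
not robustness to every real-world artefact.

## Validation problem sizes

The validation suite uses a compute-friendly field preset (`sim_params`):
192×192 px (57.6 µm), 4 cells with slightly compacted geometry
(nuclei 3–4 µm, somata 5.5–7.5 µm, neurites 20–40 µm), 3 z-slices —
chosen so that full-pipeline simulation studies run in minutes while
every stage (blur, defocus, noise, watershed splitting, ring and neurite
masking, aggregation, gating) is exercised. The headline checks:

- ring mask pixel-identical to the brute-force all-pairs distance oracle
  (20 random fields, 128×128);
- exact Mann–Whitney equal to full permutation enumeration (200 random
  tied draws, group sizes ≤ 6);
- ratio recovery: mean absolute relative error ≤ 2% noise-free and ≤ 10%
  at default noise over 50 fields (observed ≈ 0.6%/1.4% clean,
  ≈ 7%/1.5% noisy — the noisy N:C error is dominated by PSF bleed of
  nuclear signal into the ring, a real feature of ring-based cytoplasmic
  sampling);
- type-I calibration of the full pipeline on 200 null experiments
  (2 groups × 4 wells × 3 fields) within [0.02, 0.09] at α = 0.05 for
  both metrics;
- ≥ 80% power for the mutant preset (6 wells/group × 3 fields) with a
  second, unaffected protein channel in the same images flagged in ≤ 10%
  of 100 runs;
- attribution pattern exactly recovered (nuclear loss only / neurite gain
  only / both) in ≥ 95% of 100 seeded field pairs.

## Numerical conventions and edge cases

- 0-based pixel indices; masks are pixel-area sets, no subpixel contours.
- Distance comparisons use exact Euclidean metrics on integer pixel
  grids; `d ≤ w` decisions are exact because squared distances are
  integers represented exactly in floats.
- Constant images: Otsu is undefined, so an all-flat DAPI or tubulin
  image yields zero labels / an empty mask rather than an error; a
  constant image rescales to the lower bound of the target range.
- Degenerate statistics: two groups whose pooled values are all identical
  return t = 0, p = 1; constant-but-different groups fail the normality
  gate and fall to the exact rank test.
- Empty neurite mask → flagged field record without a ratio; empty ring →
  flagged cell record; both are excluded from ratio aggregation and the
  exclusions are visible in the output tables.
- Determinism: every stochastic step (scene sampling, rendering noise,
  plate generation) derives from an explicit integer seed;
  identical parameters and seed reproduce bit-identical scenes and
  stacks.

## Known limitations

- The ring samples cytoplasm immediately at the nuclear boundary, so PSF
  bleed biases N:C toward 1 by a few percent at realistic blur; this is
  inherent to the ring convention, not an implementation artefact, and it
  largely cancels in between-group comparisons of the same geometry.
- Nuclei are modelled and segmented as convex blobs; heavily clumped or
  irregular nuclei are outside the generator's scope and the watershed's
  validated regime.
- The 30 px nuclear expansion assumes somata smaller than ~9 µm beyond
  the nuclear rim at the default pixel size; larger somata would leak
  proximal cytoplasm into the neurite mask.
- Simple averaging plus two-group tests ignores the nested correlation
  structure (cells within fields within wells); mixed-effects modelling
  is intentionally out of scope.
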