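# Methods

This note documents the measurement conventions, the generative model
behind the synthetic-data module, the calibration of its presets, and
the numerical design choices. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and measurement conventions

Tracks are point lists in micrometres with time in minutes; frame
indices are 0-based. x is the medial–lateral axis, y the
anterior–posterior axis. All motility metrics are computed in the x–y
plane; z is carried through I/O and can enter the path length behind a
flag (`use_z`), but net displacement and direction stay planar.

Two corrections precede every metric:

1. **Drift correction.** Whole-embryo translation is estimated from a
   single anatomical landmark (the notochord tip) tracked through the
   movie, and `reference(f) − reference(f₀)` is subtracted from every
   cell position at frame `f`. Translation against one landmark is the
   only correction derivable from a single reference point; no
   rotational or deformable registration is attempted. The operation is
   exactly invertible and leaves metrics invariant under any
   per-frame offset applied to cells and reference alike.
2. **Side canonicalization.** The bilateral populations move toward the
   midline in opposite x directions; right-side tracks are mirrored
   about the midline (`x → 2·midline − x`) so medial movement is +x for
   all cells. The mirror preserves |Δy| and path length exactly and is
   an involution. A track with points on both sides of the midline
   must be assigned a side explicitly.

**Direction angle.** `atan(|Δy|/Δx)·180/π`, i.e. the folded angle of
the net displacement with respect to the medial axis; anterior and
posterior are never distinguished. The exact conversion factor 180/π
(57.29578) is used rather than the truncated 57.295 sometimes quoted;
the difference is below 0.01° everywhere. For net-lateral cells
(Δx < 0) the quantity is extended to (90°, 180°] by reflection
(`180° − atan(|Δy|/|Δx|)`), which makes the folded direction equal to
the absolute signed angle of the net displacement on [0°, 180°]. Cells
with Δx = 0 map to 90°. Counts of net-lateral cells are reported
alongside embryo summaries (`n_lateral`).

**Averaging.** Direction is averaged arithmetically on the folded
[0°, 180°] scale, not as a circular mean, because per-embryo and
per-condition averages of this folded quantity are conventionally plain
means. Per-embryo summaries are unweighted means over cells with
SEM = sd/√n; single-cell embryos carry SEM = NaN rather than a
fabricated 0. Elapsed time uses recorded timestamps, not frame × nominal
interval, so ~4-min acquisition jitter does not bias speeds.

**Protrusions.** Orientation is the full circular angle of the
base-to-tip vector, counterclockwise from medial (+x); forward =
[270°, 360°) ∪ [0°, 90°), backward = [90°, 270°). The half-open sectors
give every angle exactly one class (90° → backward, 270° → forward);
a closed definition of both windows would double-classify the
boundaries. Morphology ties (length == width) are classed thin — a
deterministic rule for a measure-zero case. Persistence is
`(end_frame − start_frame + 1) × frame_interval`; events still active at
the movie's last frame are flagged censored, count toward frequency,
and are excluded from mean persistence by default (including them would
bias persistence low since their full lifetime is unobserved).

**Rose histograms.** Closed-open bins; cell-direction roses default to
6 bins over [0°, 90°) with net-lateral cells in a separately reported
overflow bin; protrusion roses default to 12 × 30° over the full
circle (the bin count is configurable; any divisor of 360 is accepted).
In-range percentages plus the overflow percentage sum to 100.

## Statistical layer

- **Fisher's exact test** (two-sided) sums hypergeometric probabilities
  of all tables with the observed margins whose probability is at most
  the observed table's, with a relative tolerance of 1e-7 on the
  inclusion comparison (the convention of R's `fisher.test`). All
  arithmetic is in log space with exact log-factorials (`gammaln`), so
  p-values at the 1e-31 scale retain more than three significant
  figures; a naive float summation of hypergeometric terms is not
  trusted at that magnitude. The test suite checks the implementation
  against exact rational-arithmetic enumeration on hundreds of random
  tables and against an independent library implementation.
- **t-tests** default to Welch's unequal-variance form (the default of
  the R function used for such comparisons); the pooled-variance
  variant is available behind `equal_var=True`. The unit of analysis
  (individual cells vs per-embryo means) is an explicit parameter and
  is recorded in every result; embryo-level is the default for group
  comparisons, since cells within an embryo are not independent.
- **One-way ANOVA** is followed by Tukey HSD (studentized-range
  adjusted p-values via statsmodels) and a compact-letter display whose
  letters are the maximal cliques of the non-significance graph,
  assigned alphabetically; ties in presentation order are broken by
  group label.
- **Box-whisker summaries** use type-7 (linear-interpolation) quartiles
  and whiskers spanning the full data range.
- Immunoblot ratios are `p_signal/total_signal` normalized by the mean
  control ratio, so the control mean is 1 by construction; the
  proliferation index is the fraction of reporter-positive cells that
  are double-positive.

## The synthetic-data generator

The generator emulates the imaging experiments so the pipeline can be
exercised and validated end to end: ~3 h of frames every 4 min with
20–25 tracked cells per embryo for motility, 1.5-min frames for
protrusion movies, and a two-channel reporter image for line profiles.

**Track model.** A biased persistent random walk. Per cell, the step
direction is

    d_t = normalize( p·d_{t−1} + (1−p)·( b·m̂ + (1−b)·û ) )

with persistence `p ∈ [0, 1)`, bias `b ∈ [0, 1]`, heading axis `m̂`,
and `û` uniform on the circle; the step length is
`mean_step_speed · Δt · (1 + ε)` with ε ~ N(0, 0.1) clipped at −0.9.
This is the simplest model exposing independent speed / direction /
persistence knobs for recovery testing. The heading axis is the medial
direction rotated anteriorly by `initial_axis_deg` (mirrored for
right-side cells); an optional two-phase program rotates it a further
60° anteriorly after `phase_switch_time`, emulating the reported stage
dependence of medial movement (off by default). A configurable drift
velocity translates all cells *and* the reference landmark identically,
and cells are placed on both sides of the midline so canonicalization
does real work. An embryo-level random rotation of the heading axis
(`embryo_axis_sd_deg`, default 0) is exposed for studying between-embryo
heterogeneity, since no distributional information about it is
available.

**Preset calibration.** The condition presets are fixed from the
published summary statistics of the two imaging groups:

| quantity | control | PI3K-inhibited |
|---|---|---|
| mean speed (µm/min) | 0.2334 | 0.1879 |
| mean net direction (deg) | 31.1 | 60.6 |
| cell-level direction SD (deg, from SEM·√n at n = 96/125) | ≈ 16 | ≈ 19 |
| protrusion rate (h⁻¹·cell⁻¹) | 20.3 | 17 |
| protrusion lifetime (min) | 2.3 | 3.23 |
| forward protrusion fraction | 77.25 % | ≈ 50 % (unpolarized) |

`mean_step_speed` maps directly to mean speed (the length noise has
mean 1). The direction mean and spread jointly identify the heading
axis and the (bias, persistence) pair: the printed means with their
tight dispersions imply cells sharing a consistent anteromedial heading
(control ≈ 31° from medial, tight spread) rather than a noisy purely
medial walk, and the inhibited group a heading rotated to ≈ 60° with a
wider spread and weaker bias — matching the description of inhibited
tracks as coherent but angular-anterior and less efficient. The fitted
presets are control b = 0.45, p = 0.6, axis 31°, and inhibited
b = 0.28, p = 0.6, axis 60°; with these, simulated efficiency emerges
at ≈ 0.92 (control) vs ≈ 0.80 (inhibited) without being targeted
directly. The von Mises concentration of the control protrusion preset
(κ = 0.9634) solves P(|θ| < 90°) = 0.7725; the inhibited preset uses
κ = 0 (uniform), whose implied forward fraction of 50 % is within the
reported uncertainty of the inhibited group's 46 ± 11.6 %. Protrusion
movies default to 60 min: recording lengths were not reported, and one
hour gives event counts per cell on the scale of the published totals.

**Protrusion model.** Event onsets follow a homogeneous Poisson process
per cell at `rate_per_hour`; lifetimes are geometric on frames with the
configured mean (minimum one frame), because protrusion persistence is
scored from discrete 1.5-min frames; orientations are von Mises(0, κ)
about the medial axis; thin/wide classes are Bernoulli(`thin_fraction`)
with dimensions drawn consistently with the class. Events overlapping
the movie end are truncated and flagged censored.

**Reporter images.** Channel A is a uniform cytoplasmic fill inside the
cell radius; channel B is a Gaussian-profile membrane ring (σ = 0.5 µm
by default) over a uniform background, with optional additive Gaussian
noise clipped at 0. The ground-truth center and radius are returned for
recovery tests.

**What the generator does not emulate.** Cells are independent — there
is no cell–cell junction coupling, no collective tissue mechanics, no
endoderm, and no interaction between track and protrusion streams.
Tracking is noiseless (no localization error or missed frames), drift
is purely translational, and timestamps are exact. Passing recovery
tests therefore demonstrates that the measurement code is correct under
the assumed generative model, not that the model captures every feature
of real embryos.

## Determinism and seeding

All stochastic stages draw from `numpy` generators seeded explicitly.
Per-embryo and per-condition substreams are derived by SHA-256 hashing
of the base seed and a label (truncated below 2³¹), so adding an embryo
or condition never perturbs the others, and rerunning a pipeline config
with the same seed reproduces every CSV/JSON output byte for byte. For
that reason the run provenance block records the package version,
config hash and seed but no wall-clock timestamps.

## Problem sizes in the test suite

The acceptance-level checks use the study's sample sizes: 5 (control)
and 6 (inhibited) embryos of 20–21 cells for track contrasts, 11
protrusion-scored cells per condition, 50 simulated cell-hours for
rate/persistence recovery, 500 random tables for Fisher oracle
equivalence, 2000 null datasets for t-test calibration, 10⁴ random
tracks for metric invariants, and 100 seeded replicates for the
control-vs-inhibited contrast detection rates. Line-profile and image
checks run on 64 × 64 grids at 0.25 µm/pixel.

## Known limitations

- The direction scale is folded; a condition that reversed the
  anterior/posterior sign of movement would be invisible to it (as it
  is to the published quantification).
- Orientation Fisher tests pool events across cells and embryos within
  a condition, treating events as independent; per-cell forward
  fractions are also reported so a stratified view is available.
- The compact-letter display is presentation-only and not a joint
  inference procedure.
- Line profiles use bilinear interpolation with pixel centers at
  integer coordinates; sub-pixel peak localization is limited to the
  3-sample moving-average argmax (no model fitting).
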