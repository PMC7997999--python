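# Methods

This note documents the models, estimators and numerical choices behind
melanotrack, and what the synthetic-data tests do and do not establish about
real recordings.

## Acquisition model and coordinate conventions

All analyses assume 2D positions sampled at a fixed cadence. The default
`AcquisitionSettings` are one frame per 0.5 s, 601 frames (a 300 s
recording) and a 0.16 μm pixel; all three are configurable. Internally
positions are in μm with 0-based integer frame indices; unit and column-name
variation of track tables is confined to the I/O dialect layer. Trajectories
may carry frame gaps only when the reader is explicitly asked to tolerate
them; descriptor sums then skip gap-spanning steps, and MSD-based analyses
require contiguous tracks outright rather than silently interpolating.

## Motion processes simulated

The simulator composes the elementary processes that superpose to produce
intracellular cargo motion. Discretization is exact in all cases, so
closed-form ensemble laws hold at any frame interval and are used as test
oracles:

| process | update | closed-form check |
|---|---|---|
| brownian | increments N(0, 2DΔt) per axis | MSD(τ) = 4Dτ |
| directional | r(t) = r₀ + V·t·û | MSD(τ) = V²τ² exactly |
| brownian_drift | sum of the two above | MSD(τ) = 4Dτ + V²τ² |
| tethered | exact discrete Ornstein–Uhlenbeck about a fixed point: decay e^(−kΔt), innovation variance (D/k)(1−e^(−2kΔt)) | long-lag plateau 4D/k |
| confined | Brownian proposal folded (mirror reflection, per axis) into a square of side L | long-lag plateau L²/3 |

Reflection by folding preserves the uniform equilibrium distribution in the
box, which is what makes the L²/3 plateau (twice the per-axis variance
2·L²/12, summed over two endpoints) exact. Localization error is additive
Gaussian noise per coordinate (offsetting the 2D MSD by 4σ² at every
positive lag), applied after the process; pixel quantization (rounding to
the nearest 0.16 μm multiple) comes last, mirroring the imaging chain.
Populations are generated from one root seed via spawned per-trajectory
child streams, so regeneration is bit-reproducible.

Magnitudes are not prescribed by the acquisition settings, so the defaults
were chosen once on realism grounds: D in the 10⁻⁴–10⁻² μm²/s range and V
in the 0.01–0.1 μm/s range give per-track total distances of roughly 10–25
μm over 5 minutes and mostly sub-pixel steps (hence high pause fractions),
the regime manual tracking of melanosomes operates in. The two phenotype
presets are `wt_like_spec()` (60 Brownian at D = 2.5×10⁻⁴ μm²/s + 15
drift-plus-diffusion tracks at V = 0.04 μm/s) and `knockdown_like_spec()`
(30 Brownian + 45 drift tracks at V = 0.06 μm/s). Directed tracks always
retain the diffusive background — pure deterministic constant-velocity
tracks would put a physically meaningless point mass at α = 2.

## Kinematic descriptors

Total distance is the sum of consecutive-frame step lengths; Euclidean
distance is first-to-last displacement; the average distance divides the
total by the *frame count* (601), reproducing the tracking tool's literal
definition — the per-step divisor is available via `divisor="steps"` since
the two differ by 1/601. Pauses are steps whose pixel-quantized displacement
is exactly zero, implementing "movement below one pixel is static" as
nearest-pixel rounding; a raw-threshold mode (< one pixel, or any
user-supplied threshold) is provided as an alternative. Net
centrifugal/centripetal direction compares first and last radial distance to
the nucleus centroid with a one-pixel tie tolerance (a per-step majority
mode exists); the centroid is used as the radial reference because it is the
only geometry-free choice.

## MSD and the power-law exponent

The per-trajectory MSD is time-averaged over all overlapping ordered pairs
(maximizing pairs at 601 frames), computed for integer lags up to a quarter
of the recording by default — long-lag values exist but are increasingly
noisy. The power law b·τ^α is fitted by least squares of log MSD on log τ.

The fit window matters. The relative sampling variance of the overlapping
time-averaged MSD of a diffusive track grows like 2m/(3(N−m)) with lag index
m, and E[log X] < log E[X] for a noisy X, so including long lags bends the
log–log curve downward and biases α low: with unweighted OLS over all lags
up to N/4 at N = 601, the ensemble mean fitted α of pure Brownian motion is
≈ 0.977 rather than 1. The default fit therefore uses the **first 10
positive lags** (τ ≤ 5 s at the default cadence), the short-lag convention
standard in single-particle tracking, which centres the diffusive ensemble
at α ≈ 0.998 (sd ≈ 0.046 at 601 frames) while leaving exact power-law data
(e.g. noiseless directed motion) fitted to machine precision. For
sensitivity analysis the full window (`n_lags=None`), pair-count weighting
(`weights="npairs"`) and inverse-variance weighting (`weights="invvar"`,
weights 3(N−m)/(2m)) are available; none of these changes α for exactly
collinear log–log data. Zero-valued lags are excluded from the log fit and a
trajectory with fewer than 3 positive lags in the window is reported
`degenerate` (α = NaN) rather than coerced — a perfectly stationary track is
the canonical case.

Fitted exponents are collected per population into an empirical CDF;
populations are compared with the two-sided unpaired rank-sum test.

## Classification against a Brownian reference

Each trajectory is reduced to (μ2S, μ2L), its time-averaged MSD at a short
and a long lag — defaults τ_S = 5 s and τ_L = 40 s, sitting well inside the
300 s window with ratio τ_L/τ_S = 8. The discriminating statistic is the
log-moment gap s = log10 μ2L − log10 μ2S. For diffusion MSD ∝ τ, so s is a
pivot — its distribution is independent of D and concentrates near
log10 8 ≈ 0.90 — while directed motion (MSD ∝ τ²) pushes s towards
2·log10 8 ≈ 1.81. Two slope-1 frontier lines in the (log10 μ2S, log10 μ2L)
plane are placed at the q_low = 0.50 and q_high = 0.95 quantiles of s over a
simulated Brownian reference population (n ≥ 1000, default 2000), simulated
with the same noise and quantization as the data so tracking artifacts are
reflected in the boundary. Labels: D above the upper frontier, ND below the
lower, intermediate between (both boundary lines inclusive to the
intermediate band); zero-moment tracks are ND. The D count of a population
is reported as the range [n_D, n_D + n_intermediate]. One calibration is
shared by all populations under comparison — never recalibrated per group.

By construction a pure-Brownian population yields ≈ 1 − q_high = 5% false D
labels; this is the classifier's operating point, verified against binomial
bounds, and mixture-recovery accuracy is assessed with intermediate counted
as non-directional. The frontier construction is this package's documented
re-derivation of a Brownian-referenced decision rule and is stated as such
wherever it appears.

## Perinuclear quantification

Particles are centroid + size records; only structures ≥ 150 nm (inclusive)
are counted by default. The perinuclear band is
(dilate(nucleus, w) − nucleus) ∩ cell with w = 2 μm by default, computed
with shapely on polygon outlines (circles are approximated at 256 vertices
per quadrant; at 720 total vertices polygonal areas agree with analytic
annuli to better than 0.1%). Counting is centroid-in-region with inclusive
boundaries, and the density is count per μm² of band area; both the raw
count and the density are reported. The melanosome cross-section formula
length·width·π is reproduced verbatim as used for the original
measurements, with the true ellipse area (×1/4) available via
`corrected=True`.

## Statistics

The rank-sum test uses exact enumeration of group assignments for combined
n ≤ 20 (mid-ranks for ties; two-sided p is twice the smaller tail, capped at
1) and the tie-corrected normal approximation with continuity correction
otherwise. Two samples that are entirely one tied value give p = 1. The t
test is the classic unpaired equal-variance test. "Mann–Whitney" and
"Wilcoxon" both denote the unpaired rank-sum test here. No multiple-testing
correction is applied by default, matching per-comparison reporting;
Bonferroni and Benjamini–Hochberg adjusters are provided.

## Pipeline determinism

`run_pipeline` executes reading/simulation → descriptors → MSD →
classification → optional spatial stage → comparisons, writes per-population
tables plus a manifest of every parameter and seed, and is a pure function
of (inputs, config, seed). Per-population and calibration seeds are derived
arithmetically from the root seed. Failures abort with stage-labelled
errors; config-declared track exclusions are applied and logged, never
hard-coded.

## Problem sizes used in the test suite

Ensemble checks run at sizes chosen to keep Monte-Carlo error well below the
effects being verified while remaining desk-scale: 2000 trajectories for the
diffusion-law ratio and classifier calibration/false-positive bounds, 500
for the diffusive-exponent ensemble, 400 for tethering/confinement plateaus,
and 75 per group (the tracked-population size the acquisition design
targets) for phenotype contrasts. Oracle-equivalence checks use 50 seeded
inputs at 81 frames, where brute-force double loops are cheap.

## Known limitations

* The simulator emulates statistical structure, not images: no
  photobleaching, illumination drift, detection/linking errors, or 3D
  motion projected to 2D. Passing tests show the estimators are correct for
  the stated processes, not that real melanosome data satisfy those
  processes.
* Trajectories are stationary in regime: no within-track switching between
  motor-driven runs and pauses beyond what the elementary processes produce;
  accordingly there is no changepoint or hidden-state segmentation.
* The α estimator is slightly biased for finite tracks whatever the window;
  the default 10-lag window makes the diffusive bias negligible (≈ −0.002)
  but short windows raise variance for strongly subdiffusive tracks.
* Classification lags, quantiles and the frontier rule are principled
  defaults, not measurements; conclusions about borderline trajectories
  should quote the intermediate band, which exists for exactly that reason.
* Perinuclear counting treats particles as points; structures comparable in
  size to the band width are counted by centroid only.
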