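# Methods

This note records the models implemented in smfretkit, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic-data tests demonstrate.

## Signal model and trace generation

A molecule occupies one of K conformational states with FRET efficiencies
`E_i ∈ [0,1]`; transitions follow a continuous-time Markov chain with the
configured per-second rate matrix (Gillespie simulation). The camera
integrates over each frame, so the per-frame efficiency is the
occupancy-weighted average `E_f` of the states visited during the frame —
not a mid-frame sample. Ideal detected signals are

```
D* = I·(1 − E_f)          A* = γ·I·E_f
```

with `I` the total detected intensity per frame and γ the detection/
quantum-yield imbalance of the two channels. Channel crosstalk is applied
in the forward direction as

```
I_A = A* + β·D*           I_D = D* + α·I_A
```

which is constructed as the exact inverse of the leakage correction
`D_c = I_D − α·I_A`, `A_c = I_A − β·D_c` (the mixing map is linear and
invertible whenever αβ ≠ 1). Gaussian read noise of SD `noise_sd` is added
last, independently per channel and frame. On noiseless traces the full
correction chain therefore returns the ground-truth `E_f` to machine
precision, which the test suite asserts over a grid of (α, β, γ).

Both dyes bleach in a single step at exponential times. After the
acceptor bleaches, `A* = 0` and `D* = I`: all excitation energy reports in
the donor channel. This convention is what makes the photobleaching-step
ratio equal γ exactly (see below). After the donor bleaches both channels
sit at background. Bleaching takes effect at the first frame boundary
after the drawn time, so step edges are clean at the frame resolution;
truth records both the continuous times and the frame indices.

Defaults mirror the emulated acquisition: 10 Hz frame rate, 1000 frames
(100 s), α = 0.165, β = 0.017. Where the experiments' reports leave values
unstated, the generator fixes them once:

| parameter | default | rationale |
|---|---|---|
| `total_intensity` | 1000 counts/frame | typical EMCCD single-molecule signal scale |
| `noise_sd` | 60 counts | gives per-molecule efficiency-histogram SDs ≈ 0.12–0.15, the width scale of measured cohorts |
| `acceptor_bleach_rate` | 0.02 s⁻¹ | mean bleach at 50 s, mid-trace, as photobleaching-step analysis requires |
| `donor_bleach_rate` | 0.005 s⁻¹ | donor typically outlives the acceptor |
| `efficiency_jitter_sd` | 0 (off) | optional static molecule-to-molecule heterogeneity, drawn from a truncated normal (rejection sampling — clipping would pile mass at E = 0 and 1) |

Noise is additive Gaussian rather than Poisson: at these count levels the
approximation is good and it keeps the corrections linear. Blinking,
triplet dynamics, spectral fluctuations and direct acceptor excitation
are not modelled.

Binding-burst traces alternate exponential dwells (bound exit rate
`k_off`, unbound exit rate `k_on·[ligand]`); the acceptor reports a
constant bound level with camera integration across partial frames, and
the donor stays constant, as appropriate when the donor-labelled partner
is in solution excess. Truth records exact event times plus the
majority-occupancy discretized path for fair frame-level comparisons.

## Bleach-step detection and γ estimation

Changepoints are scored by the difference of window means (default window
10 frames) against a robust noise SD estimated from the median absolute
first difference (step-immune). The acceptor bleach is the largest drop
exceeding 4 SD of the window-mean difference with a simultaneous donor
rise (> 2 SD); the donor bleach is a ≥ 4 SD donor drop after which both
channels sit at background. Step sizes are means over the window on each
side. The window length around the step is not dictated by the emulated
protocol; 10 frames is the default and is configurable.

γ is estimated per molecule as (acceptor drop)/(donor rise) across the
acceptor bleach, **measured on the leakage-corrected channels**. On the
corrected channels the ratio equals γ identically under the signal model
above; on the raw channels it would be biased by the leakage itself
(algebraically `γ_raw = (γ−β)/(1+αβ−αγ)`, a ~35 % error at γ ≈ 1.66 with
α = 0.165). The cohort γ is the mean of the per-molecule values, and the
γ-corrected efficiency mode uses that mean.

Single-pair selection keeps molecules whose channels each show at most
one significant downward bleaching step (a dye surviving the record is
consistent with a single dye; two steps indicate a double label) and
whose pre-bleach leakage-corrected efficiency exceeds a small floor
(FRET actually observed). Step *counting* uses a 5 SD threshold — a
1000-frame scan at 4 SD produces occasional noise flukes, while genuine
second-dye steps are an order of magnitude larger. Every rejection is
logged with a reason and the pipeline asserts input = kept + dropped.

## Population decomposition

Each molecule contributes the mean of its per-frame corrected
efficiencies over the first 50 frames (5 s), a window chosen to end well
before typical bleaching; molecules bleaching inside the window are
dropped with a logged reason. Efficiencies are deliberately not clipped
to [0,1], and the default histogram range [−0.2, 1.2] at bin width 0.02
admits the noise-driven tails; clipping would distort the Gaussian fits.

The histogram is fit by least squares with a sum of two Gaussians.
Initialization: means at the 25th/75th percentiles of the samples, SDs at
half the sample SD, equal amplitudes; components are ordered low/high by
mean (by SD on ties) after convergence. The fit is flagged *degenerate*
when a component's area falls below 1 % of the total or when the means
are separated by less than twice the larger component SD — in either case
the data are effectively single-population and area ratios are not
meaningful as a two-state decomposition. Population percentages are
`100·area/(area_low + area_high)`, so the two components always sum to
100 %. An unbinned EM mixture fit (scikit-learn) serves as an independent
cross-check in the tests, not as the estimator.

Uncertainty is the split-half SD: molecules are randomly partitioned
(seeded, recorded) into two equal halves, the statistic is computed on
each, and the SD of the two values is reported.

## Dwell-time kinetics

Idealization fits a two-state Gaussian-emission HMM by EM (hmmlearn)
with emissions initialized at the 10th/90th percentiles, sticky
transitions (0.9 diagonal), and a convergence flag; the most probable
path is decoded by Viterbi, with state 1 the higher-mean state. Two
degenerate guards return a single-state path with a warning: a series
with no spread, and a fitted model whose level separation is below twice
the larger emission SD — without the second guard, traces with no binding
events are shredded into spurious noise-driven dwells. On ≤ 12-frame
series the decoded path is checked against exhaustive enumeration of all
2¹² paths.

Dwells are idealized run lengths × frame interval. The first and last
runs of each trace are censored and excluded from the dwell arrays (and
hence from dwell histograms), but their durations are accumulated, and
the first run's observed exit counts as an event. Rate estimation then
uses the censoring-aware exponential MLE,

```
rate = (observed exits) / (total state time − exits·Δ),   Δ = Δt/2,
```

equivalent to the canonical Markov-chain rate estimator. This matters: at
the slow rates typical of these binding assays (mean dwells ~8 s in a
100 s record) the interior-dwell mean is biased ~10 % short because long
dwells preferentially collide with the observation window. The plain
per-dwell estimator `rate = 1/(mean − Δ)` remains available and is the
documented contract of `fit_dwell_rate`; Δ is the half-frame correction
for camera discretization (a dwell is observed only when it claims a
frame, so observed durations are biased long by about half a frame). The
histogram estimator fits a single exponential to binned dwell counts with
bin edges aligned to the frame grid — unaligned bins alias the discrete
durations and can inflate the rate by tens of percent.

Dwells of a single frame are retained; no missed-event (dead-time)
correction is applied. The recovery bias this causes grows as dwells
approach the frame interval (tested at three dwell/frame ratios); rate
recovery to within a few percent holds for mean dwells of roughly four
frames and above, and the recovery-invariant tests run in the slow-dwell
regime the binding assays occupy. `k_on` is the unbound exit rate divided
by the ligand concentration (μM⁻¹s⁻¹) and `K_D = k_off/k_on` (μM) by
construction.

## Structure-based FRET prediction

Dyes are modelled geometrically: candidate positions uniform in the
sphere of linker length 2.0 nm about the attachment atom (Cβ, falling
back to Cα for glycine), rejected when within dye radius 0.5 nm + clash
allowance 0.17 nm of any atom outside the labelled residue, until the
requested sample count (default 100) is accepted. The prediction is the
Förster efficiency at the distance between the two mean accepted
positions, R0 = 5.1 nm, with κ² orientation effects not modelled. This
approximates the mean dye position that a fixed-protein dye-dynamics
simulation would give; agreement is only claimed to about ±0.1 in
efficiency, and dye-pair distance *distributions* are deliberately out of
scope (mean-position convention only). Predictions are symmetric in site
order and, with no obstructions, converge to the Förster value of the
attachment-atom distance as the cloud grows (verified at n = 10⁴ within
0.01). All structure tests run on small constructed synthetic PDB
fixtures; no downloaded coordinates are required.

## Imaging round trip

Movies are a constant background plus isotropic Gaussian PSFs integrated
over pixels (erf-based), one donor/acceptor spot pair per molecule across
a left/right dichroic split with a known offset — no general registration
is attempted. Detection averages the first frames, takes local maxima
above background + k·robust SD (k default 4), refines by
intensity-weighted 5×5 centroid, deduplicates plateau ties within 2 px
(two spots closer than ~1 PSF width merge into one detection, by design),
and pairs channels through the split offset. Extraction sums a circular
aperture minus the annulus-median background. The render→detect→extract
round trip recovers input intensities within 2 % RMS when spots are
separated enough for the aperture and annulus to be uncontaminated;
detection counts are monotone non-increasing in the threshold.

## Pipelines, configuration, provenance

The two end-to-end pipelines (conformation: correction → selection →
per-molecule E → two-Gaussian decomposition → percentages ± split-half
SD; binding: idealization → dwells → rates → K_D) are driven by a single
nested config (YAML or dict). Unknown keys are rejected — silent typos
corrupt analyses. All randomness flows from one root seed through
documented SeedSequence spawning, and each run writes a manifest with the
config snapshot, seed, and SHA-256 of every output file; identical
configs reproduce outputs hash-identically. A binding condition with too
few usable dwells is reported as "no binding observed" rather than as
rates.

## Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale, chosen so
each check's statistical resolution comfortably exceeds its tolerance:
mixture decompositions at 2000 molecules (20 seeds for bias checks), γ
recovery on 200 traces of 1000 frames, rate recovery on ~2000 dwell
events, image round trips on ≤ 320×128 px fields. Passing these tests
shows the chain is self-consistent and statistically calibrated under the
stated signal model. It does not certify behaviour under photophysics the
generator omits (blinking, spectral dynamics, Poisson shot noise at low
counts), under drifting or flat-field-distorted optics, or for dye pairs
whose orientational freedom violates the κ² assumptions behind a fixed
R0.
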