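# Methods

This note documents the models, estimators, and numerical choices in
`poselab`, and what the synthetic-data generator does and does not emulate.

## Task design (`poselab.design`)

The stimulus grid crosses 8 tilts (0–315°, 45° steps), 5 slants (0–60°,
15° steps), and 4 distances (37, 57, 97, 137 cm; fixation at 57 cm).
Because tilt is undefined at slant 0, the grid has
8 × 4 + 1 = 33 unique orientations and 132 unique poses. A block contains
(8 tilts × 4 nonzero slants + 8 frontoparallel repeats) × 4 distances =
160 plane trials plus 8 × 4 = 32 saccade trials, shuffled by a single
seeded stream per block. Frontoparallel tilt is stored as NaN (a sentinel,
not 0°) so no tilt statistic can silently ingest it; two frontoparallel
poses at the same distance compare equal regardless of nominal tilt.
Reward: 1 for the correct tilt report on slanted trials, 0 otherwise,
0.125 on tilt-ambiguous frontoparallel trials.

## Behavioral model (`poselab.behavior`)

Report errors ΔTilt live on the eight bins {0, ±45, ±90, ±135, 180}.
Sensitivity fits maximize the multinomial likelihood whose cell
probabilities are the von Mises density evaluated at the bin centers and
renormalized (not bin integrals; at 45° bins the difference is below the
multinomial noise at feasible trial counts, and the generator shares the
convention so recovery is exact in expectation). κ is bounded in
(0, 18] — 18 being the largest concentration resolvable with 45°
sampling — with a capped flag at the bound; µ is estimated jointly but
surfaced only (downstream analyses use κ). Optimization is L-BFGS-B with
eight µ restarts; a least-squares mode on binned proportions exists for
sensitivity analysis. Tilt enters linear models via cos/sin components
(`linearize_tilt`) because it is circular.

## Synthetic data (`poselab.synth`)

The generator defines the study conditions for every test:

- **Behavior**: per-(slant, distance) κ defaults rise with slant
  (≈2.2 → 9.5 at 57 cm) and fall away from fixation
  (weights 0.55/1.0/0.45/0.30 at 37/57/97/137 cm), mirroring the
  qualitative structure of measured sensitivity maps; lapse rate 0.02.
  Choices are drawn from the discretized von Mises and condition the spike
  generator (sensory → choice causality).
- **Spiking**: inhomogeneous Poisson with piecewise-constant rate (no
  refractoriness — sufficient for every estimator under test). A plane
  trial is baseline until the visual latency (default 50 ms), then
  baseline + DC + g·H(θ)·F(D); after the choice onset (default 200 ms) the
  evoked component is multiplied by exp(κc·(cos(choice − pref) − 1)) —
  multiplicative gain, so orientation and distance tuning shapes persist.
  A step at onset is the default; a linear ramp is configurable because
  the within-trial dynamics of choice activity are not constrained by the
  data the package emulates. H is a Bingham function of the pose normal
  (unit peak), F a nonnegative distance profile (unit max). The
  inseparability knob shifts the preferred slant by a fixed number of
  degrees per distance step behind fixation.
- **Saccades**: the pre-saccadic rate ramps linearly from baseline,
  starting `saccade_lead_frac` (default 0.75) of the drawn latency before
  saccade onset and reaching a common threshold (default 42 spikes/s,
  scaled by von Mises direction tuning) exactly at onset — slope ∝
  1/latency by construction. Latencies are normal (mean 137 ms, sd 25,
  redrawn if ≤ 40 ms). Eye traces are noiseless raised-cosine speed
  pulses (amplitude 11°) scheduled so the first ≥150°/s sample falls at
  the scheduled onset; both eyes move identically (no vergence noise, no
  microsaccades, no correlated noise across neurons — passing tests
  therefore say nothing about those features of real data).

## Spike processing (`poselab.spikes`)

The SDF kernel α(t) = α*·[e^(−τd·t) − e^(−τr·t)] uses τd = 0.05 and
τr = 1.05 interpreted as rate constants in ms⁻¹ (decay ≈ 20 ms, rise
≈ 1 ms); α* = 1/(1/τd − 1/τr) ≈ 0.0525 ms⁻¹ normalizes to unit area, and
the discrete 1 ms taps are renormalized to unit sum so the SDF integral
equals the spike count exactly. The kernel peaks at
ln(τr/τd)/(τr − τd) ≈ 3.04 ms and has group delay 1/τd + 1/τr ≈ 21 ms.
Traces should start before stimulus onset (e.g. −300 ms) so the causal
kernel has history at t = 0; the boundary-truncation dip otherwise biases
early time points low.

**Visual latency** is the first post-onset millisecond at which the rate
differs from the baseline (last 150 ms of fixation, per-neuron mean for
subtraction; per-trial available by flag) for ≥ 30 consecutive ms, the
per-ms comparison being a two-group test (a two-level ANOVA is t²).
Because the kernel correlates adjacent milliseconds, the run rule alone
admits ≈18% false positives on unresponsive neurons; detection is
therefore gated on a single whole-epoch responsiveness test whose
false-positive rate is exactly the nominal α. Eye velocity uses a 5 ms
boxcar before central differences (configurable); saccade onset is the
first sample with either eye ≥ 150°/s.

**Z-scoring** standardizes baseline-subtracted frontoparallel responses
within each (neuron, distance) cell; zero-variance cells are flagged and
excluded downstream.

## Tuning quantification (`poselab.tuning`)

TDI uses 2·sqrt(SSE/(N − M)) in the denominator — the discrimination-index
convention of the literature this index comes from — with the literal
2·SSE/(N − M) form available behind `literal_denominator` (the two
disagree except when sqrt(SSE/(N−M)) = 1; the default is the conventional
form). TDI is invariant to adding a constant and to positive rescaling.

Bingham fits model rate = offset + amplitude·exp(nᵀ M Z Mᵀ n) with
Z = diag(λ1, λ2, 0), λ1 ≤ λ2 ≤ 0, and M orthonormal with third column the
preferred-pose normal; the first two columns are rotated by an axis angle
ψ. Multi-start least squares (restarts at the empirical peak and
45°-spaced tilts; λ bounded in [−20, 0]; ties broken by lowest residual
then lowest |λ1|); λ1 ≈ λ2 flags the axis unidentifiable. The fitted
preference may lie beyond the 60° sampled slant. Both λ1 and λ1 − λ2 are
available as elongation statistics.

Von Mises direction fits (choice and saccade curves) are nonlinear least
squares on mean rates of baseline + amplitude·exp(κ(cos(θ − pref) − 1)),
with an additive baseline because firing rates have nonzero background.
HWHH = arccos(1 + ln(½)/κ) for κ ≥ ln2/2, else capped at 180°.

Gates: per-distance orientation ANOVA with Bonferroni–Holm over the four
distances; a two-way orientation × distance model for the distance gate;
a four-way linearized model (slant, distance, tilt-cos, tilt-sin) on
slanted trials for slant/distance gates; choice gate on z-scored
frontoparallel responses; saccade gate on baseline-subtracted rates.
Neurons require five complete blocks.

## Separability (`poselab.separability`)

For fixed DC the best g, H, F are the truncated rank-1 SVD of R − DC, so
the fit reduces to a 1-D search over DC on [0, max(R)]. The objective can
be multimodal in DC; a 101-point coarse grid locates the basin and a
bounded scalar search (tolerance 1e−8) refines it, with the DC = 0
boundary checked explicitly. Gauge: unit-norm H and F, g ≥ 0, F
nonnegative at its largest-magnitude entry. Tolerance correlates observed
columns with full per-distance predictions (identical to correlating with
H except sign when F(D) < 0); degenerate distances are excluded and
counted. The additive model solves the 132-cell linear system with
sum-to-zero effects and a ridge weight chosen on a log grid (including 0)
by training error norm, giving it one more effective parameter. Model
comparison reports residual norms and a cell-wise paired sign-flip
permutation test on squared residuals (seeded, default 10,000 flips).

## Pose geometry (`poselab.geometry`)

n = (cos T sin S, sin T sin S, cos S). The principal orientation is the
leading eigenvector of the second-moment matrix Σ nᵢnᵢᵀ (not the mean
vector: slants ≤ 90° keep all normals in one hemisphere and the
eigen-form matches the clustering definition), sign-fixed to z ≥ 0, then
x ≥ 0 if z ≈ 0; tied eigenvalues are flagged with a smallest-index
tie-break. The pole rotation rT(Tp)·rS(−Sp)·rT(−Tp) maps the principal
normal to (0,0,1) and preserves all pairwise angles; deviations are
Δ∡ = arccos z′ and ΔΨ = atan2(y′, x′). Preferences are unweighted in the
eigen computation (fit-quality weights available). Per-neuron principals
come in SD-window-only and both-window variants. The equal-area display
uses the Lambert azimuthal projection about the pole (equator → radius
√2); lower-hemisphere input is reflected.

## Event timing (`poselab.timing`)

The choice-onset loop: assign each neuron's preferred choice from mean
z-rates in the current window (initially the full 1 s; updated each
iteration, with a freeze flag), build the eight relative-choice population
curves, find the first millisecond where the across-curve ANOVA rejects at
p < 0.05, re-window from that time, and iterate to a fixed point
(cap 20; a 2-cycle reports the midpoint, flagged non-converged). The
divergence test's persistence is configurable: 1 ms reproduces the literal
first-divergence rule but, being uncorrected per-ms testing, yields false
onsets ≈1/α ms into the scan under the null; cohort-level analyses
default to a 30 ms sustained run, which recovers a 200 ms injected onset
at 207 ms over 200 simulated neurons. The saccade-activity start runs the
same loop backward with windows [start, saccade onset].

The latency-quartile analysis splits preferred-direction trials into
latency quartiles, shifts SDFs earlier by the kernel group delay (≈21 ms,
an a-priori kernel constant — without it the measured threshold is biased
low by slope × delay), smooths the quartile mean time courses with a
15 ms boxcar, takes the initiation threshold as the rate at the time in
[−50, 0] ms minimizing across-quartile variance (the deterministic
operationalization of "the time courses approximately intersect"; the
window is exposed in config), detects each quartile's activity start as
the first sustained (20 ms) deviation from that trial group's own
baseline, and fits the growth rate as the least-squares slope from
activity start to threshold crossing. The growth-rate vs mean-latency
regression is reported with its p-value; shuffling latency labels is the
negative control.

Alignment statistics use signed circular differences in (−180, 180], a
circular median with a sign test against 0, circular variance, a
Wallraff-style rank test for concentration differences between groups
(angular deviations from each group's own median compared by
Mann–Whitney), and a two-sample Kolmogorov–Smirnov test for deviation
CDFs. These live in `poselab.circstats`, written in-package.

## Pipeline (`poselab.pipeline`, `poselab.cli`)

`simulate → analyze → report`, each stage reading/writing CSV/JSON under
one directory with content hashes in `manifest.json`; a rerun with an
unchanged config subsection reuses cached outputs (the analyze stage
dominates runtime). Defaults are desk-scale — 8 neurons × 5 blocks — so a
full run completes in well under a minute; the README example uses
12 neurons × 6 blocks, at which size the population choice onset is
reliably recovered. Test-suite simulations use 20–200 neurons per
experiment, chosen so each estimator's sampling error is small relative
to the tolerance being asserted.

## Known limitations

- The generator's rate profiles are piecewise constant; estimators that
  assume smooth rate changes see step edges smeared only by the SDF
  kernel.
- The choice-onset estimator's literal (1 ms) divergence rule is unusable
  without a persistence requirement; this is a property of uncorrected
  per-ms testing, not of the implementation.
- Bingham fits on single noisy curves occasionally land in local optima
  (~1 in 10 at moderate noise shows >5° preference error); cohort
  statistics are robust to this, single-neuron fits should check `fit_r`.
- The vergence covariate control and spike sorting are out of scope; eye
  traces carry no vergence signal by construction.
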