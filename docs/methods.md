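# Methods

This note documents the models and procedures implemented in `ethophys`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Head-pose estimation and posture covariates

The four head markers form a rigid body. The template is the frame whose
pairwise marker distances are closest (least squares) to the session
average; its origin is the centroid of the four points. Each frame is then
aligned to the template with the closed-form Kabsch solution. Two gauge
freedoms remain and are fixed globally:

* **Origin re-basing.** The point of the head coordinate system whose room
  trajectory minimizes Σₜ‖o(t−20) − o(t+20)‖² (frames at 120 Hz) is taken
  as the origin — an estimate of the head's axis of rotation. The
  minimization is linear in the offset and solved in closed form.
* **Axis calibration.** A fixed rotation of the template frame aligns the
  head z axis with the room vertical and the head x axis with the running
  direction (horizontal displacement of the origin over ±50 frames),
  combining both objectives in one orthogonal-Procrustes fit. Only frames
  with *sustained* running above 10 cm/s contribute (the speed mask is
  eroded by 0.8 s): frames where the speed gate is crossed mid pose-swing
  otherwise tilt the gauge by 2–3°. Component-wise medians of the anchor
  vectors are used for the same reason.

**Euler-angle conventions.** The generic intrinsic X-Y-Z decomposition is
exposed as `euler_xyz` (gimbal lock at |θ_y| = 90° resolves to a zero third
angle, flagged). The *named* head angles (pitch, azimuth, roll) use the
azimuth-first intrinsic Z-Y′-X″ (yaw-pitch-roll) decomposition: with the
room z vertical this is the only convention in which a change of heading
adds to azimuth and leaves pitch and roll untouched, which in turn makes
"egocentric azimuth = allocentric azimuth − body direction" an exact
identity for a level trunk. The egocentric frame yaws with the horizontal
body direction and pitches with the elevation of the 3D tail-root → neck
axis, so egocentric and allocentric pitch decouple when the trunk tilts
(rearing, head-down search).

Other conventions: angles in degrees wrapped to (−180, 180]; derivatives
are central differences at ±10 frames on unwrapped series; running speed is
the chord displacement of the neck point over a ±250 ms window; self-motion
is speed times the unit vector of the body-direction change over ±15
frames; neck elevation is measured above the 5th percentile of neck height
(the recording floor is not part of the data, so the session itself defines
it); back angles are measured from the back-marker → neck segment relative
to the body direction and re-centered on the session's circular mean.
Missing-marker gaps up to 5 frames are linearly interpolated; longer gaps
propagate as missing features. At frame rates other than 120 Hz all frame
stencils rescale proportionally (with a warning).

## Ethogram

Seven signals (egocentric head pitch/azimuth/roll — or their
exponential-map parameterization, available via `signals=` — back pitch and
azimuth, neck elevation, running speed) are detrended with cubic
least-squares splines (knots every 2 s). Morlet wavelet magnitudes
(`cmor1.5-1.0`) are evaluated at 18 geometrically spaced frequencies from
0.5 to 20 Hz; the square root of the power is centered per frequency and
divided by the variance of the smoothed signal. That divisor is floored at
5% of the raw-signal variance: a signal whose slow component is nearly
constant would otherwise amplify its wavelet block by orders of magnitude
and drown the informative dimensions (with rich natural signals the floor
never engages). The z-scored smoothed signal is concatenated with the 18
wavelet rows → 133 dimensions per frame.

For embedding, rows are decimated (not averaged) to 1 Hz and pooled across
sessions. PCA keeps the smallest number of components reaching 97%
variance. t-SNE (Euclidean, perplexity 200, fixed seed, PCA
initialization) gives 2D coordinates; perplexity is reduced automatically
(with a warning) when fewer than 3 × perplexity rows are available. The
occupancy histogram on a 60×60 lattice — padded by 2 cells so no mass sits
on the border — is smoothed with a σ = 1-cell Gaussian, normalized to a
PMF, and segmented by an 8-connected watershed of −PMF. New frames are
labeled by the nearest training point in the retained PC space (ties break
to the lower index). The fitted map persists to HDF5 so labels are
reproducible without re-running t-SNE.

Watershed on desk-scale data (10³–10⁴ embedded points) over-segments
relative to the dozens of actions seen with pooled multi-animal data; this
does not affect label purity, which is scored by majority-regime
assignment per region.

## Tuning curves and shuffle nulls

Binning: 5° for head angles and body direction (full circle for azimuths),
2.5° for back angles, 1 cm for neck elevation, 6.67 cm for position,
3 cm/s for self-motion; movement variables use 36 equal bins over a range
trimmed until the terminal bins hold ≥ 400 ms. Rates are counts over
occupancy; bins under 400 ms are masked; smoothing uses a σ = 1-bin
Gaussian renormalized over valid bins so it cannot bleed across unoccupied
regions. Information per spike is Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) over valid bins
(defined as 0 for silent cells).

The null model circularly rotates the spike train by a uniform draw from
±[15, 60] s — free-uniform over both signs; circular wrapping preserves
the rate and ISI structure. Stability is the Pearson correlation of
even- versus odd-minute curves (wall-clock minutes from session start)
over jointly valid bins, compared with the 95th percentile of the same
statistic under the shuffle. Sessions shorter than twice the maximal shift
shrink the shift range with a warning.

## Action encoding and decoding

A unit encodes an action if its within-action rate is outside the
two-sided α = 0.01 empirical null Bonferroni-corrected by the number of
actions tested **and** both within-action halves (even/odd frame parity
inside the action) fall outside the 2.5/97.5% envelopes on the same side.

The decoder holds out 20 non-overlapping 400 ms windows (50 bins of
8.33 ms) per action with > 16 s occupancy, drawn from bouts of at least 50
bins; the rest trains per-cell Bernoulli rates p̂ (floored at half a count
per training bin). A window's posterior is the product of per-cell
Binomial(50, p̂) likelihoods times a categorical prior from action
occupancies of other sessions; in single-session synthetic runs the prior
defaults to the training occupancy and the result is flagged. The
prior-only baseline decodes every window as the a-priori most likely
action. Transition matrices are bout-level (consecutive identical labels
collapsed), so self-transitions are structurally excluded.

## Bernoulli GLM and model selection

Spike trains are binarized in 8.33 ms bins. Each behavioral covariate is
factorized into a one-hot block: 15 occupancy-balanced (quantile) bins for
1-D features (equal-width available via `binning="width"`), joint 2-D
grids of 10 cm for position and 5 cm/s for self-motion (a 1-D alternative
is exposed). The registry holds 22 covariates: nine postural features,
their nine derivatives, body direction, speed, position and self-motion; a
23rd (body-direction derivative) can be added by passing a custom
covariate list. Rows with any missing covariate are excluded from all
folds. The design never materializes as a matrix — per-covariate bin codes
make the linear predictor a gather and the gradient a `bincount`.

Fitting maximizes the Bernoulli log-likelihood minus λ Σ|β| with λ = 10⁻⁴
(intercept unpenalized; the printed link is read as the inverse logit, the
only interpretation with p ∈ (0,1)). The optimizer is a damped Newton
iteration on the per-observation-scaled objective — the one-hot structure
makes the Hessian a set of diagonal blocks plus small cross-block tables —
with backtracking line search, convergence at a gradient sup-norm of 10⁻⁶
within 500 iterations, and the smooth surrogate √(β² + ε²), ε = 10⁻⁶, for
the (numerically negligible) penalty term. Results are deterministic.

Selection uses 10 contiguous equal time blocks as folds (no shuffling).
Step 1 ranks candidates by the fold-average of
(ℓ(M|yᵃ) − ℓ(M₀|yᵃ)) / n_spikesᵃ; folds without test spikes are dropped
and flagged. Step 2 admits the best candidate only if the exact one-sided
Wilcoxon signed-rank test on the paired held-out log-likelihoods rejects
at α = 0.01 (zero differences dropped). Cells with fewer than 100 spikes
are unclassified by construction. rLLR uses fold-averaged out-of-sample
log-likelihoods; for a single-covariate model it is identically 1, and for
duplicated covariates it collapses toward 0. Pseudo-R² is the fold average
of 1 − ℓ(M|yᵃ)/ℓ(M₀|yᵃ); folds with ℓ(M₀|yᵃ) = 0 are dropped and flagged.
At exact score ties the candidate earlier in the registry wins.

## Sensory modulation and ensemble decoding

PETHs: 50 ms bins over ±10 s around onsets, trials clipped by the session
edge dropped with a warning, Gaussian smoothing σ = 3 bins along time.
Indices are computed from **raw** window rates (smoothing is for display
and ensemble averaging): SMI contrasts 500–1000 ms post-onset with
500–1000 ms pre-onset; LMI contrasts dark with light1 over ≤ 2 s
quiescence windows (speed ≤ 5 cm/s, greedily extracted, non-overlapping)
matched in count by subsampling to the scarcest session, gated on light1
vs light2 showing no difference (p > 0.05). Significance is the paired
trialwise Wilcoxon test at p < 0.05. Both indices negate exactly under a
window swap.

The nearest-neighbor decoders smooth 10 Hz spike counts with a σ = 1-bin
Gaussian and assign each test population vector the condition of its
maximally Pearson-correlated training vector (ties to the earliest
training index; zero-variance test vectors are skipped and counted). The
sound variant uses 3 folds and a circular-shift null; the luminance
variant trains on the last quarter of light1 plus the first quarter of
dark, tests on the second half of light2, and permutes training vectors
across time for its null (time shifts cannot remove a session-wide rate
offset). Because Pearson correlation discards the vector mean and scale,
these decoders need heterogeneous rate profiles across cells — a
homogeneous population is undecodable by construction, which the synthetic
ensembles respect.

## Functional connectivity

CCGs count post spikes around each pre spike in 0.4 ms bins over ±20 ms
(101 bins). The slow baseline convolves the CCG with a Gaussian of
σ = 25 bins whose central weight is scaled by (1 − 0.6), renormalized,
with mirror-reflected edges (hollow fraction 0 reduces exactly to plain
Gaussian smoothing). Each bin is tested against the baseline with
continuity-corrected Poisson tails via the regularized incomplete gamma
functions: P(X ≥ n) ≈ P(n − ½, λ), P(X ≤ n) ≈ Q(n + ½, λ). A synaptic
call requires two consecutive bins beyond the 10⁻⁶ tail strictly inside
the 1.6–4 ms window of either lag sign, no crossing inside 0–1.6 ms, and
physiological plausibility (RS presynaptic for excitatory, FS for
inhibitory, from 2-means on spike width, peak-to-trough ratio, FWHM and
end slope — the narrower-waveform cluster is FS). An extremum inside
0–1.6 ms with two passing bins is common input. When both directions
qualify, the extremal p wins (ties to the lower pre id). Baseline-zero
bins are skipped (no Poisson rate can be formed). Synaptic strength is the
baseline-subtracted extremal count over min(n_pre, n_post).

Functional labels take each unit's best single-covariate model by mean
cross-validated per-spike LLR against the intercept model (≤ 0 →
unclassified), grouped into 11 categories and, for connection-pair
statistics, into movement/posture/sensory. The category null redraws as
many excitatory and inhibitory pairs as observed, uniformly over
physiologically plausible ordered pairs within the maximal observed
anatomical distance, 1000 times; the functional vector concatenates the
per-covariate scores with the SMI/LMI values and p-values (26-dimensional
with the default 22-covariate registry).

## Cohort statistics

Pearson χ² goodness-of-fit (with an optional expected ≥ 5 guard that
directs the caller to the exact binomial test), exact upper-tail binomial
probabilities, and the anatomical gradient analysis: per-unit axis
positions pooled across animals into 1 mm segments (7 by default; the
count adapts to other extents), tuned-cell counts expressed as proportions
of all cells in the segment, each tuning class tested against uniformity.

## Synthetic sessions

The generator emulates the statistical structure each stage assumes, not
rat biomechanics. The trunk is a confined planar random walk (speed: OU
noise around critically damped regime targets; heading: 0.5 rad·s^−½
random walk with wall-avoiding steering); the spine bends laterally and
arches (OU, σ = 8°); the head is a rigid four-marker body above the neck
whose Euler angles track piecewise-constant regime targets through a
critically damped second-order filter (pitch/roll ω = 8 s⁻¹, speed
ω = 1.5 s⁻¹ — poses settle faster than speed, so gauge-anchor frames are
clean) with OU jitter on top; all markers carry 0.5 mm isotropic Gaussian
noise (motion-capture class). The default script alternates five
foraging-like regimes (level running, head-down search, rearing, lateral
scans, mean bout 4 s); the two-regime script for segmentation tests uses
10–40 s bouts, long against the ~1 s transition blur of the 2 s-knot
spline detrending. Spikes are Bernoulli draws per frame from
σ(b₀ + Gaussian log-odds bumps on the *extracted* covariates) — so
generated tuning refers to the same covariate values the analysis sees —
with uniform spike placement within the frame. Waveform features come
from two well-separated clusters (RS-like broad, FS-like narrow). Coupled
pairs transmit with a Gaussian latency jitter of σ = 0.2 ms around the
nominal lag: with a delta latency all induced coincidences would fall in
a single 0.4 ms bin and the two-consecutive-bin rule could never fire;
real synaptic latencies jitter at this scale. Inhibitory couplings delete
post spikes in ±0.8 ms around the lag. Stimulus trains are 5 s events
with inter-onset gaps of 15 s plus an exponential excess (mean 5 s), so
all inter-stimulus intervals exceed 10 s. A single integer seed drives
everything; per-unit substreams are derived from (seed, unit id) so
outputs are bit-identical and stable under unit reordering.

What the generator does **not** emulate: tracking dropouts and marker
swaps, non-stationary rates and electrode drift, bursting and refractory
structure, correlated population noise, and realistic action repertoires
beyond the scripted regimes. Passing recovery tests therefore shows the
estimators are correct and calibrated under their own assumptions, not
that they are robust to every artifact of recorded data.

## Problem sizes and runtime

The validation suite and the reproduction script run the batteries at the
package's standard study sizes: GLM recovery with 20 cells at T = 144,000
bins (20-minute sessions, the recording schedule's session length) and 50
noise cells at T = 36,000 (the size of the selection test does not depend
on T); 50 coupled pairs and 1000 independent pairs at 5 Hz × 600 s;
ethogram recovery on a 600 s two-regime session embedded at 2 Hz
(perplexity 100); decoding with 60 cells over 6 actions × 600 s; stability
calibration with 100 Poisson cells × 300 s at 250 shuffles (the test's
level is set by exchangeability, not the shuffle count). A full
`scripts/acceptance.py` run takes about five minutes on one CPU.

## Known limitations

* The axis-calibration gauge needs genuine running epochs; sessions
  without sustained locomotion fall back to a vertical-only anchor over
  all frames, leaving the azimuth gauge undetermined up to the session
  mean of the head-body offset.
* Watershed region counts are sensitive to embedding density;
  downstream statistics use region labels only through purity-style
  majority mapping.
* The Wilcoxon gate in forward selection is exact for 10 folds but the
  step-1 argmax introduces a mild selection bias that the null-calibration
  battery quantifies empirically rather than analytically.
* `category_shuffle_null` enumerates plausible pairs densely (O(n²) in
  units); cohorts beyond ~2000 units would need a sparse rewrite.
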