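# Methods

## Scope and model

`dendrospt` analyzes single-particle-tracking (SPT) recordings of
quantum-dot-labelled neurotransmitter receptors diffusing on dendritic
membranes, and provides a matched synthetic-data generator so that every
estimator can be validated against known ground truth. The physical picture
is lateral Brownian motion on a thin, elongated membrane strip, locally
slowed ("trapped") inside synaptic compartments, observed at 20 Hz with
~40 nm localization error and interrupted by quantum-dot blinking.

### Motion model

Positions evolve in the dendrite's local frame (longitudinal coordinate
`u` along the main extension, transversal coordinate `v` across it) by one
update per camera frame:

    u(t+dt) = u(t) + sqrt(2 D_long dt) φ + μ_long dt
    v(t+dt) = v(t) + sqrt(2 D_trans dt) φ + μ_trans dt

with `φ ~ N(0,1)` i.i.d. This is the standard convention: per-axis step
variance `2 D dt`, planar MSD `4 D t`. A `paper_convention` switch replaces
the step variance by `D dt` throughout (simulator, MSD fit, Gaussian-fit
estimator `D = σ²/dt`, FPT simulator), reproducing the literal update rule
used by some legacy SPT scripts; on the same data the two conventions
differ exactly by a factor 2 in D, which the test suite asserts. All
shipped defaults use the standard convention.

Dendrite edges are *reflecting* (receptors stay on the membrane strip).
When trapping is inactive and drift is zero, the simulator generates the
whole free path vectorized and folds it into the domain — for symmetric
increments the folded walk has exactly the law of the per-step reflected
walk. Under drift, folding is not law-preserving, so the per-step loop is
used instead.

### Trapping

Synaptic trapping is a two-parameter phenomenological model (none of the
common SPT papers constrain a mechanism at this timescale):

* inside a synaptic compartment the receptor's D is multiplied by
  `trap_D_factor` ∈ (0, 1];
* each frame a trapped receptor escapes with probability
  `trap_escape_prob`; after a successful escape it diffuses at full D until
  it leaves the compartment (otherwise, with a slowed D, it would be
  re-trapped on the next frame and escape would be unobservable); re-entry
  re-traps it.

This produces the two signatures the analysis is meant to detect: reduced
D and elevated dwell time at synapses, with dwell time monotone in
`1/trap_escape_prob` (asserted in tests).

### Blinking and localization noise

Visibility is a two-state Markov chain per frame (`blink_off_prob`,
`blink_on_prob`), giving geometrically distributed dark periods — the
minimal model that exercises the linker's 25-frame dark-period cap.
Emitted localizations are the visible true positions plus isotropic
Gaussian error (`loc_noise_sd`, default 40 nm per axis), applied after
blinking.

### Defaults

Recording defaults emulate 1-minute acquisitions: 1200 frames at 20 Hz
(`dt` = 50 ms), 160 nm camera pixel, 40 nm localization error. The demo
scenario uses a 12 μm dendrite, half-width 1 μm (segment widths are not
constrained by published measurements; the half-width is a free parameter),
three inhibitory synapses with consecutive spacings drawn from 2–4 μm and
0.2 μm puncta, receptor D_long = 0.08 / D_trans = 0.02 μm²s⁻¹ spanning the
commonly reported 0.01–0.15 μm²s⁻¹ range, `trap_D_factor` 0.25,
`trap_escape_prob` 0.02 (expected trapped residence 50 frames = 2.5 s),
blink off/on 0.1/0.4 (≈ 9% dark frames, mean dark run 2.5 frames).

## Track linking

Per-frame localizations are reconnected greedily: at each frame, candidate
(open track, localization) pairs are those with Euclidean displacement
≤ `max_disp` pixels (default 4 px × 160 nm = 0.64 μm, *not* scaled by gap
length) and with `f − f' − 1 ≤ max_gap` missing frames (default 25,
i.e. 1.25 s at 20 Hz). Pairs are committed in increasing distance; ties are
broken by older track then lower track index, so output is deterministic;
exact-tie ambiguities are counted and surfaced as a warning. Unmatched
localizations open new tracks. No motion model or multi-hypothesis search
is used — the experimental protocols this mimics rely on dilute labelling,
and tests verify that greedy linking equals the global
minimal-total-displacement assignment whenever particles stay farther
apart than twice the displacement cap.

## MSD and instantaneous D

The MSD at lag `n` frames is the mean of squared displacements over all
ordered pairs of localizations exactly `n` frames apart. Lags are
frame-indexed, so pairs spanning blink gaps count whenever both endpoints
exist; per-lag pair counts are reported. The instantaneous D is the slope
of an ordinary least-squares line through the MSD at lags 1–4, divided
by 4. The fit includes an intercept, which absorbs the static
localization-noise offset (≈ 4σ² ≈ 0.0064 μm² at σ = 40 nm) — the tests
confirm both the intercept value and that the slope-based D stays
calibrated under 40 nm noise. Under `paper_convention` the line is forced
through the origin instead. Non-positive slopes clamp D to 0 and set a
`confined` flag (tolerance 1e-12 μm²s⁻¹ to absorb floating-point noise on
exactly flat curves). A mobile/immobile threshold of D > 0.0075 μm²s⁻¹ is
applied for "mobile fraction" summaries; no published cutoff exists, so it
is configurable.

The MSD steady state (confinement readout) is the mean MSD over a late-lag
window, by default the last quarter of computed lags; a plateau flag is
cleared when the MSD still rises by more than 10% of the window mean
across the window.

## Compartments, dwell, transitions

Synaptic compartments are puncta dilated by 2 camera pixels (2 × 160 nm),
modelled as disks (the structuring element of the original mask dilation
is not constrained; a rasterized membership oracle cross-checks the disk
rule in tests). Membership is boundary-inclusive; overlaps resolve to the
nearest centre. A *dwell episode* is a maximal synaptic run of
localizations; its duration is the run length × dt, so a single-frame
visit lasts 50 ms, and dark frames are not counted (whether blink gaps
inside a synapse should count toward dwell time is genuinely undecidable
from frame-based data; the choice to count only visible frames is
documented, not guessed). An *inter-synaptic transition* A→B is emitted
when a synaptic run at A is followed — possibly after extrasynaptic
frames, but with no visit to any third synapse — by a run at B ≠ A; the
transition time runs from the last frame in A to the first frame in B.
Excursions returning to the same synapse emit nothing.

## Anisotropic (Gaussian-fit) estimation

Trajectories are decomposed along a longitudinal and a transversal
direction: the known geometry axis when available, otherwise the major
axis of the point cloud's second-moment ellipse. The linearity score
(major-axis variance fraction, 1.0 collinear / 0.5 isotropic) gates
axis-from-cloud estimation at 0.8 by default — an operational stand-in for
"fairly linear dendrite" selection, configurable because no quantitative
criterion is published. Only consecutive-frame steps enter the fits
(the update rule is a per-dt relation; gap-spanning displacements mix
timescales). The Gaussian fit is by sample moments (the ML estimate:
mean m, population variance σ²), giving drift `μ = m/dt` and
`D = σ²/(2 dt)` (standard) or `σ²/dt` (`paper`); a binned least-squares
curve fit is available as an alternative for fidelity to
histogram-fitting workflows, and agrees with moments to a few percent at
large n. Note the single-step variance estimator is *not* noise-corrected:
with 40 nm localization error it overestimates D by `σ_loc²/dt`
(0.032 μm²s⁻¹ at the defaults) — visible in the demo output and documented
here rather than silently subtracted; recovery tests therefore use
noise-free synthetic data, and drift estimates are reported but not used
downstream.

## First-passage-time model

Inter-synaptic passages are modelled as 1D Brownian motion from 0 to an
absorbing boundary at the inter-synaptic distance L, simulated at the
experimental dt (50 ms) with 5000 replicates by default, each capped at
the *chance time* — the recording time remaining after the receptor left
the source synapse; replicates not absorbed in time are censored. Crossing
is detected at discrete steps (first frame with position ≥ L), matching
frame-based observation; this biases passage times upward by at most one
frame plus undetected within-step excursions. An optional Brownian-bridge
correction (crossing probability `exp(−2(L−x₀)(L−x₁)/var)` per step)
quantifies that bias; it is off by default. One boundary is used by
default (the target synapse); a symmetric two-boundary mode exists. The
drift-free simulator is validated against the closed form
`F(t) = erfc(L/(2√(Dt)))` within the Dvoretzky–Kiefer–Wolfowitz band plus
a one-frame discretization allowance, against the L²/D scaling law, and
against dt-refinement (50 ms vs 5 ms).

The *f-FTP* (fastest first time passage) is the mean of the smallest
`⌈0.01 n⌉` passage times, with n the number of uncensored passages by
default (a percentile of a censored ensemble is undefined beyond the
censoring point; an `attempts` base is available as a switch). The
*percentile intercept* of an observed transition time is
`100 × (# simulated passages ≤ observed) / n_sim`, censored replicates in
the denominator, so it saturates at the uncensored fraction × 100. As a
consequence, probability-integral-transform calibration checks divide
intercepts by the uncensored fraction before comparing to Uniform(0,1) —
observed events are themselves conditioned on passage within the chance
time.

## Reporting

Skewed SPT quantities are summarized as median ± IQR (25th–75th
percentiles, linear interpolation between order statistics — the "type 7"
rule, named because quartile conventions differ across software). Group
comparisons delegate to scipy.stats: two-tailed Mann-Whitney U (unpaired),
Wilcoxon signed-rank (paired), two-sample Kolmogorov-Smirnov (cumulative
distributions), Welch t; significance stars at 0.05/0.01/0.001; raw
p-values, no multiple-comparison correction (noted in output). The
pipeline (`dendrospt run`) chains simulate → link → analyze → anisotropy →
FPT-match → report, writing per-stage CSVs, a JSON summary (floats rounded
to 6 decimals for byte-stable regeneration) and a run log; a fixed seed
reproduces every output byte-for-byte.

## Problem sizes and limitations

Validation runs use 200–500 trajectories of 300–1200 frames and FPT
ensembles of 1000–5000 replicates — sizes at which median estimators are
well inside the asserted tolerances while the full suite runs in well
under a minute of compute. What the synthetic generator does *not*
emulate: point-spread-function rendering and detection failures (inputs
are localizations, not movies), quantum-dot multivalency, curved or
branched dendrites (the geometry is a straight rectangle; the PCA axis
handles gently curved data only approximately), spatially varying
localization error, and receptor internalization/exocytosis. Passing tests
therefore validate the estimators against the stated motion model, not
against every artifact of real recordings. Known numerical choices:
boundary-inclusive compartment membership with a 1e-12 μm slack; greedy
linking ties broken deterministically; negative fitted D clamped at 0;
FPT crossing without sub-step correction by default.
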