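# Methods

## Model

Each member of a tapping dyad is a *unit* of two phase oscillators, a
perception oscillator and an action oscillator. The phase of oscillator
*n* evolves by the Kuramoto equation with pairwise coupling matrix K (in
1/s) and additive Gaussian phase noise,

    dθ_n/dt = ω_n + Σ_p K[n,p] · sin(θ_p − θ_n) + ξ(t).

Within a unit, perception and action are coupled bidirectionally with
weight *i*; between units, each action oscillator drives the partner's
perception oscillator unidirectionally with weight *e* (the auditory link:
one hears the partner's taps). Oscillators are ordered (unit-1 perception,
unit-1 action, unit-2 action, unit-2 perception); rows of K are receivers.
A reduced control variant keeps a single oscillator per unit with
reciprocal weights e1/e2 placed off-diagonal (a diagonal placement would be
dynamically inert, since sin(θ_n − θ_n) = 0).

Assumptions worth making explicit: coupling is continuous in time (real
auditory information arrives in discrete taps); the noise is white in
phase; intrinsic frequencies are constant within a trial; and the system
has the mirror symmetry (unit 1 ↔ unit 2) ⇔ (i1,e1 ↔ i2,e2), which the
lag statistics inherit as a left/right flip.

## Numerical integration

Explicit Euler–Maruyama with step `dt` (default 25 ms for exploration runs,
10 ms for validation-grade runs). Weights are stored in 1/s and multiplied
by `dt` inside the update, so their meaning is resolution-independent.
Initial phases are Uniform[0, 2π) per oscillator; intrinsic frequencies are
drawn per trial from Normal(2 Hz, 0.2 Hz), expressed in rad/s. Phases are
recorded every `sample_interval` (500 ms for exploration — one nominal tap
— or equal to `dt` for validation) and never wrapped, so tap extraction
can count 2π crossings directly. Non-finite phases abort with the step
index. Trajectories are bit-reproducible given (spec, config, seed).

### Noise calibration

The printed noise levels (0.2513 rad for the musician dataset, 0.4335 rad
for the non-musician dataset) are the phase-noise SD accumulated over one
nominal 500 ms tap interval: 0.2513 rad = 20 ms × 2π × 2 Hz. The per-step
injection is `noise_sd · sqrt(dt / 0.5 s)`, which makes the accumulated
variance per tap independent of `dt`. Anchoring to the fixed 500 ms
reference (rather than to the sampling interval) keeps the physical noise
identical between exploration and validation resolutions. Simulated at
10 ms resolution, an uncoupled 2 Hz oscillator then shows pooled ITI SD of
19.9 ms (34.5 ms at the higher calibration) — i.e. the printed millisecond
equivalents correspond to the SD of the intertap intervals; their IQR is
1.35× larger (Gaussian factor). At 500 ms sampling, linear interpolation
between coarse samples averages part of the noise and the apparent ITI SD
drops to ≈ 16 ms; calibration checks therefore use fine sampling.

## Tap statistics

A tap is the linearly interpolated crossing time of an unwrapped action
phase through each successive multiple of 2π; with noise the sampled phase
can dip locally, so only the first upward crossing of each multiple is
emitted (running-maximum guard) and tap series are strictly increasing.
Taps in the first 2 s of a trial are discarded (the empirical task paced
participants with a metronome for the first two seconds). ITI series are
successive tap differences; an ITI series whose range is below 1 ns is
treated as constant and its correlations as undefined (this occurs only in
noise-free degenerate runs). The two units' ITI series are truncated to
their common length from the start — simulated taps are near-synchronous,
so index k aligns with index k.

The lag pattern is the Pearson correlation triplet at lags −1, 0, +1 with
the convention r_k = corr(a_t, b_{t+k}) for unit-1 intervals a and unit-2
intervals b: positive r_{+1} reads "unit 2 follows unit 1 by one tap".
Note that which unit *functionally* follows is governed by the product of
the path weights (e·i into that unit's action), not by either weight
alone. The synchronization index is the mean resultant length of the
relative phase R = |⟨exp(i(θ_a − θ_b))⟩| ∈ [0, 1] (1 − circular variance),
computed between the two action oscillators over post-discard samples.

## Coupling sweep and the critical-coupling plateau

The sweep raises all coupling terms equally from 0.1 to 30 1/s in steps of
0.1 with 200 twelve-second trials per step and reports the mean
action-pair synchronization index per step. The resulting curve rises
steeply below ≈ 5 1/s and then saturates into a very flat plateau
(index ≈ 0.994–0.995 across roughly 10–30 1/s at the default noise level).
On such a plateau the literal argmax is ill-determined, so two statistics
are reported: the weight maximizing a centered 5-step moving average of the
curve, and the smallest weight whose smoothed value is within one standard
error of that maximum (the plateau onset). In our runs the smoothed argmax
falls at ≈ 24–26 1/s; linear analysis explains why: around the synchronized
state the discrete Euler map damps each coupling-graph mode by
(1 + λ·K·dt), the per-mode noise variance keeps shrinking until K
approaches the stiffest mode's stability edge 2/(3·dt) ≈ 26.7 1/s at
dt = 25 ms, and beyond it the index collapses. A previously reported
maximum at 15.5 1/s lies on this plateau (its onset region) rather than at
a detectable interior maximum; users comparing against that figure should
look at the plateau onset statistic and treat any single argmax draw from
the plateau as noise-dominated.

## Clustering of lag patterns

Mean lag patterns (one per coupling combination; per-trial patterns are
averaged with undefined trials excluded) are clustered with complete
linkage under Euclidean distance on the raw (r_{−1}, r_0, r_{+1})
triplets. Distinctness is decided by a similarity-profile (SIMPROF)
permutation test applied from the dendrogram root downwards: for a node's
data matrix the profile is the sorted vector of pairwise distances, the
null shuffles each variable independently across the node's members
(1000 permutations for the expected profile, 999 for the p-value, per the
R package defaults), the statistic is the summed absolute deviation from
the mean null profile, and a node with p ≤ α (α = 0.001, applied per node)
is split further. Each node uses an independent substream derived from its
dendrogram id, so p-values are recursion-order-free and tightening α can
only reduce the cluster count. Two consequences of the column-permutation
null worth knowing: a two-member node can never be split (within-column
swaps leave the pair's distance unchanged), and groups separated along a
*single* variable are invisible to the test (the null preserves each
column's marginal) — separation must be multivariate.

The two standard designs are the 66-combination reciprocal-coupling sweep
of the reduced variant (e1 = 0…10, e2 = e1…10, step 1) and the
256-combination four-oscillator design over weights {1, 5, 9, 13}⁴, both
with 200 trials per combination. At these scales the four-oscillator
design yields ≈ 12 significant clusters (10–14 across seeds) while the
reduced variant yields ≈ 4–6 clusters that are all either strongly
lag-0-dominated or flat — the one-oscillator-per-unit control cannot
produce strategy-like asymmetric patterns.

## Fitting coupling weights

The fit to a target lag pattern is a two-step consecutive grid search.
Every combination on a coarse grid (full protocol: 1–15 1/s in steps of 1,
300 trials each) is scored by the numeric distance between its mean
simulated pattern and the target mean; the distance is L1 over the three
lag coefficients (robust and scale-free on [−1, 1]; L2 available). The
winner seeds a local search at offsets −0.9…+0.9 in steps of 0.2 per term
(clipped at 0). The refined winner is re-simulated (full protocol: 2000
trials at 10 ms step and sampling) and scored with the Bhattacharyya
coefficient BC = Σ √(p·q) between the per-trial simulated lag coefficients
and the target samples, per lag on 20 equal-width bins over [−1, 1] (BC
depends on binning, so the bin count is configurable), averaged over the
three lags. Each combination runs on its own counter-derived seed
substream, making rankings reproducible and order-independent.

Identifiability: the map from four weights to a three-number pattern is
many-to-one. What the lag triplet chiefly constrains is each unit's
cross-path *product* e·i (the gain from the partner's action into this
unit's action, via perception), so fits wander along e/i ridges of
near-identical distance and Bhattacharyya overlap: a flat target pins the
products to be small but leaves individual terms free, and even
mutual-adaptation targets admit ridge solutions that swap a unit between
low-i/high-e and high-i/low-e at matched product. Per-term weight
recovery is therefore reliable only for strongly asymmetric targets;
recovered *products* are stable much more broadly. Desk-scale recovery
experiments (grid 1–8, 50 coarse trials, 500-trial targets) show exactly
this pattern, and the strict per-term recovery check in the acceptance
suite documents the ridge by failing at the median-one-step bound.

## Synthetic targets

Because the two empirical datasets are not deposited, validation targets
are synthesized two ways. Model targets simulate a known weight vector and
package its per-trial lag patterns (ground truth for recovery tests).
Profile targets draw per-dyad lag triplets from independent Normals around
a strategy-signature centre, clipped to [−1, 1]; the six preset centres
(flat; one dominant off-lag, mirrored; three mutual-adaptation variants
with positive off-lags and negative lag 0 at decreasing strength) and the
per-lag SD of 0.1 are plausibility calibrations chosen here — consistent
with the published signature descriptions but not published numbers.
Synthetic tap logs are model runs at the 500 ms nominal period with
dataset-matched noise, emitted in the tap-log CSV schema. What these
fixtures do *not* emulate: per-dyad tempo drift, serial correlation of
empirical ITIs beyond the model's own, missed/extra taps, and the true
dyad counts and dispersions of the original studies — so passing tests
demonstrate pipeline correctness and model behaviour, not empirical
goodness of fit.

## Default problem sizes

Exploration runs use dt = 25 ms with 500 ms phase sampling and 12 s trials
(2 s discarded); validation-grade runs use 10 ms for both. The package's
test suite and the acceptance script run the sweep and both clustering
designs at their full published sizes (300 × 200 and 256 × 200 simulations
respectively, a few minutes on one CPU) and the recovery experiments on
reduced grids (8⁴ combinations × 50 trials), the package's chosen
desk-scale protocol.

## Known limitations

- Continuous coupling inflates the simulated lag-0 correlation relative to
  tap-discrete information flow; mutual-adaptation fits are weakest at
  lag 0.
- At the published best-fit weights for the weakest mutual-adaptation
  subgroup (i1 = 1, e1 = 5, i2 = 1.3, e2 = 3.3) the model produces an
  essentially flat mean pattern (off-lags ≈ 0): the cross-unit path gains
  e·i are too small to transmit tap-to-tap structure. The mutual-adaptation
  signature at such weights could not be reproduced here.
- The critical-coupling argmax is plateau-dominated (see above); only the
  plateau onset is a stable summary.
- Euler–Maruyama is first-order; near the stability edge (K·dt approaching
  2/3 per the stiffest mode) discretization, not physics, shapes the
  dynamics. This matters above ≈ 20 1/s at dt = 25 ms.
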