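# Methods

## Model

gazesim simulates gaze over a talking face as a discrete-time stochastic
process on four zones (Eyes, Mouth, rest of face, Other). At each step the
sampling distribution is the renormalized elementwise product of three
zone distributions — bottom-up saliency, top-down task knowledge, and the
inverted selection-history belief. Multiplicative fusion corresponds to
conditioning on "coherence" connector variables being closed; opening the
memory connector instead yields the inversion operator
`(1 − b_i)/(z − 1)`, which is how the belief over *visited* zones becomes a
vote over zones to *visit*. With z = 4 the inverted vector sums to one
identically, and probabilities are kept in linear space throughout —
four-element vectors at these magnitudes cannot underflow.

Assumptions worth stating explicitly:

- The model is representationally agnostic: it tracks *where* attention
  goes, not what is processed there. The memory component is therefore a
  plain 4-state Bayesian filter, not content-addressed.
- No oculomotor dynamics: one fused draw per normalized time step, no
  saccade latency or fixation durations. Simulated trajectories are only
  meaningful after aggregation into looking-time proportions.
- Trials are independent: the memory belief resets to uniform at each
  trial start (trials are separated by an attention-getter), and the gaze
  starts on the Eyes zone. Learning across trials enters only through the
  top-down component's closed-form exposure dependence.

## Time axis

Trial time is normalized: 100 steps for the Speech Event and 100 for the
Non-speech Event (1% of each event per step), so trials with different
real durations align. The anticipatory analysis window is the last 50% of
the Speech Event (steps 50–99), the detection window the whole Non-speech
Event (steps 100–199). Event onset t_ER = step 100. Millisecond gaze
records are mapped to steps by proportional binning per event.

## Parameters

| name | meaning | domain | default |
|---|---|---|---|
| β | strength of top-down learning | ≥ 0 | fitted; grid [0.1, 0.5, 1, 2, 3, 4, 5] |
| γ | anticipation speed, steps advanced per exposure | ≥ 0 | fitted; grid [0.1, 0.5, 1, 1.5, 2] |
| θ | weight of static saliency in the bottom-up mix | [0, 1] | fitted; grid [0, .05, .1, .25, .5, .75, 1] |
| ε | memory dilution leak per step | (0, 0.25) | 0.05 |
| p_hit | observation probability of the viewed zone | (0.25, 1] | 0.9 |

ε and p_hit are fixed, not fitted: the memory component's qualitative role
(recently visited zones become transiently less attractive, relaxing back
to uniform) is insensitive to their exact values, and 0.05 / 0.9 give a
relaxation time of a few steps at the 100-steps-per-event resolution.
Exposures are counted as T = trial − 1, so trial 1 shows neither learning
nor anticipation; the alternative convention T = trial is selectable
(`TopDownConfig(count_first_trial=True)`) for sensitivity checks. γ is in
normalized steps per exposure: at the grid maximum γ = 2, trial 19
anticipates 36 steps, inside the 50-step anticipatory window.

## Within-step scheduling

The factorization fixes dilute-before-observe inside the memory update but
not the placement relative to sampling. gazesim uses: after X^t is drawn,
the belief assimilates it (dilute, then observe); the fused distribution
that generates X^{t+1} then uses that posterior (inverted), the top-down
distribution at step t, and the bottom-up distribution of frame t. X^0 is
the Eyes zone and the belief starts uniform, then assimilates X^0 before
the first draw.

## Bottom-up dialect

The static channel is intensity-only center-surround: Gaussian smoothing
at center scales σ = 1, 2, 4 px against surrounds at 4× and 8× the center
(six pairs), absolute differences max-normalized per scale and summed.
Color, orientation and flicker channels are omitted — the stimuli are
gray-scale. The dynamic channel is `|f_t² − f_{t−1}²|`; the sign-free
convention is ours. Per-zone *means* (not sums) make the aggregation
independent of AOI area. An all-zero frame (e.g. the first frame of a
sequence, which pairs with itself) falls back to a uniform distribution
rather than erroring. These are documented choices; the center-surround
literature fixes the idea but not the constants, and none of the package's
conclusions depend on the exact pyramid.

## Synthetic data

The generator emulates the experimental protocol: 19 test trials,
two conditions (eyebrow-raise ER / lip-protrusion LP), 20 virtual
participants per condition, Speech Events fixed at their 1800 ms mean
(optionally sampled uniformly over the printed 1180–2200 ms range),
Non-speech Events at 1880 ms, 25 frames/s. The schematic face is
geometric: permanent high-contrast eye blobs (sclera/pupil), a mouth bar
whose intensity oscillates at ≈ 5 Hz during speech, and event motion
confined to the eyebrow region (ER) or the mouth (LP). A small motion
floor (0.05) in every zone stands in for sensor/compression noise of real
video and keeps the dynamic distribution full-support. The analytic
fast-path streams reproduce the same per-phase argmax structure as the
rendered-pixel path (cross-checked in the tests), modulo the single
transition frame at the speech/event boundary, which on the pixel path
carries the mouth-relaxation transient.

Behavioral datasets are model-generated trajectories in a long gaze-table
format, with optional step-independent Bernoulli "away" lapses to exercise
the missing-data paths. What passing tests therefore show is that the
pipeline is correct and that parameters are recoverable *when the model is
true*; they cannot show that real infant gaze follows the model, that away
looks are independent across time, or that real stimulus saliency matches
the schematic face.

## Analysis and fitting conventions

PTLT denominators contain on-face time only (Eyes + Mouth + RoF); Other
and away samples are excluded, and a window with zero on-face time yields
a missing value, which is dropped (never imputed) downstream. Baseline
correction maps per-trial preference scores through the branch-wise
rescaling against trial 1; the tie EM_tn = EM_t1 falls in the second
branch (giving exactly 0, continuously), and the doubly degenerate
EM_t1 = EM_tn = −1 case is defined as 0.

The grid-search fit compares regression endpoints of the **raw** group-mean
anticipatory preference series (trials 1–19) on both sides. This is a
deliberate design choice: baseline correction removes the trial-1 level of
the series, and that level carries most of the information about θ —
fitting corrected curves leaves θ nearly unidentified (parameter-recovery
simulations find optima at θ ∈ {0, 1} with near-zero error regardless of
the generating θ), while the raw-series fit recovers generating parameters
to within one grid step. Corrected series (per-participant or group-level
baseline) remain available and are the convention for displaying learning
curves and for the learning-direction checks. The MSE averages over all
(condition × {start, end}) pairs jointly — 4 pairs for a two-condition
design, 2 for an ER-only design.

Simulation noise is controlled across grid points by common random
numbers: one uniform schedule per (condition, participant, trial), derived
from the protocol's master seed via `SeedSequence(master_seed,
condition_code, participant, trial)`, is reused at every grid point, so
MSE differences reflect parameters rather than fresh sampling noise, and
grid evaluation is order-independent and bit-reproducible. Argmin ties
break lexicographically (lowest β, then γ, then θ).

## Numerical choices

- Zone distributions validate to 1e-9 on construction and are defensively
  renormalized after every arithmetic operation; oracle comparisons in the
  tests hold to 1e-12.
- Degenerate fusion (disjoint supports) raises an error rather than
  returning an arbitrary distribution.
- Per-scale max-normalization in the static channel skips numerically flat
  maps (peak ≤ 1e-12) instead of amplifying floating-point residue.
- Rectangles are 0-based, half-open, origin top-left; boundary points
  belong to the lower-indexed zone (Eyes before Mouth before RoF).

## Problem sizes

Default experiments simulate 2 × 20 × 19 × 200 zone draws (≈ 0.1 s); a
full 245-point grid search with the default protocol takes ≈ 10 s. The
parameter-recovery study in the test suite runs 10 replicate full-grid
fits; stationary-distribution and sampling-soundness checks use 60 000 and
100 000 draws respectively.

## Known limitations

- Only z = 4 zones are supported and tested, and learning applies to the
  Eyes zone in the ER condition only; the LP condition uses static priors
  throughout.
- β and γ trade off against each other in the fit: the anticipatory-window
  gain depends on both the learned-mass saturation (β·T) and the window
  coverage (γ·T), so occasional two-step misses along that ridge occur
  even at the default design size. θ is well identified by the raw-series
  fit.
- At the smallest grid value β = 0.1 the model still learns visibly
  (the Eyes prior reaches (0.1·18 + 1)·0.45 → 0.70 after 18 exposures);
  a truly flat learning curve requires β·T ≪ 1.
- The time axis is normalized; nothing is claimed about real-time
  dynamics, saccade programming, or fixation statistics.
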