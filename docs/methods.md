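# Methods

## Signal model and feature chain

A recording is a matrix of non-negative per-sensor vertical forces at a
fixed rate (100 Hz by default), with sensor planar coordinates in a shared
body frame: x medio-lateral, y anterior-posterior, metres. Ground-truth
labels may arrive at a different rate (a motion-capture reference typically
runs at 30 Hz); `synchronize` maps them to the force grid by normalized
time between the start/end trigger marks with nearest-neighbour selection —
labels are categorical, so linear interpolation of a 0/1 stream would be
meaningless.

The feature chain per sample:

1. Per-foot and combined COP as the force-weighted mean of sensor
   positions. A foot whose force sum does not exceed `cop_min_force`
   (default 5 N) has an undefined COP: the COP of a nominally unloaded
   foot is sensor noise amplified into violent apparent motion, not
   posture. Undefined samples hold the last valid value; samples before
   any valid value take the foot's sensor centroid.
2. COP gradient `θ = arctan((COP_RY − COP_LY)/L)` in radians; its arctan
   image respects the required (−π/2, π/2] range by construction. `L` is
   hip width, `0.191 × height` by default (a standard anthropometric
   ratio), configurable.
3. `cop_dot`: backward difference of θ times the sampling rate, reported in
   deg/s to match the natural scale of the thresholds; the first sample is
   0. The derivative form is used rather than "θ divided by the sampling
   rate": only a rate of change has the right units and behaviour for a
   motion factor.
4. `cop_w`: trailing-window sum of |cop_dot|, window 0.25 s by default.
   Magnitudes are summed — this is the waveform-length feature of the EMG
   literature; a signed sum cancels to ≈0 over a symmetric stride and
   carries no state information (a `signed=` mode exists for comparison).
   The window is causal: only past samples inform the current decision.
   0.25 s was chosen as a compromise between noise averaging and stop
   latency: the window is the dominant term of the stop-of-walking delay,
   so a window much larger than ~0.3 s would push that delay well beyond
   what a rehabilitation-robot controller could absorb.

## Classifiers

**GRF threshold (TAM).** Threshold at the 10% point of the min–max range of
the per-foot GRF sums of the fitting data, fitted per subject group (the
dynamic range differs between groups). Classification is per-foot: standing
only when *both* feet exceed the threshold. A strict two-foot-total variant
is available (`rule="total"`) but is nearly vacuous during gait — the total
almost never drops below 10% of its range because one foot always bears
load.

**COPw threshold.** Aligned histograms of the standing- and walking-labelled
`cop_w` training samples (Freedman–Diaconis bin width on the pooled sample
unless given); the overlap region is the set of bins where both class
probabilities are positive, and the threshold is the centre of the bin
maximizing the overlap density `min(p_standing, p_walking)` — for unimodal
classes, the histogram crossing point. We deliberately do not place the
threshold at the bin with the highest *total* probability inside the
overlap: transition samples (walking-labelled samples just after gait
onset whose window has not yet filled) put a little walking mass inside the
standing bulk, and a total-probability rule then collapses onto the
majority-class mode, destroying standing accuracy. The `min` rule is
robust to such strays and reduces to the same midpoint answer when the
classes are disjoint. Ties at the threshold classify as walking (the rule
is `cop_w ≥ threshold`).

**Neural classifier.** 10 inputs → 20 sigmoid hidden units → 1 sigmoid
output. Inputs are divided by their per-feature training maxima of |x|
(magnitude rather than signed maximum, because two features — the left-foot
COP x and the gradient — span both signs and a signed maximum can be
arbitrarily close to zero). Training is full-batch gradient descent on mean
binary cross-entropy with momentum 0.9, learning rate 0.5, 600 epochs by
default, initialized from a seeded generator; identical seed and data
reproduce identical weights bit-for-bit. The experiment pipeline trains on
every third sample (`sample_stride=3`): the decision surface is smooth in
time at 100 Hz, so the stride cuts cost without materially changing the
fit. The single hidden layer is a requirement, not a simplification: it is
what makes Garson's importance decomposition applicable. Garson importances
are non-negative and sum to 100% for any weights; hidden units whose
incoming weights are all zero contribute nothing.

**Approximate entropy.** Literal finite-N estimator
`Φ^m(r) − Φ^{m+1}(r)` with Chebyshev template distance and self-matches
included (which keeps the estimator non-negative); a sample-entropy-style
exclusion is available behind a flag. Defaults m = 2, r = 0.2·SD of the
series — standard practice. Exact O(N²); callers decimate long series.

## The synthetic cohorts

The simulator is a statistical stand-in for clinical insole recordings,
not a forward-dynamics model: it reproduces the features the classifiers
consume — force thresholds crossed, COP geometry, event timing — and is
deterministic given the seed.

A trial is stand → walk 5 m → stand. Group-level defaults: healthy
0.83 m/s, cadence 1.6 steps/s, stance 58% of stride; patient 0.29 m/s,
cadence 0.9, stance 68%, plus a swing-foot shuffle residual of 20% of body
weight, an exaggerated pre-gait weight shift to the unaffected side, and
larger sway. Cohorts jitter subject parameters around these values
(heights/weights drawn per sex for the healthy group; walking speeds with
the SDs of the emulated protocol: ±0.08 healthy, ±0.06 patient).

Construction choices that matter:

* Stance force is a smooth M-shaped (double-bump) profile that is exactly
  zero at its edges; standing force blends with it by `max`, so a clean
  swing foot carries exactly zero force (plus noise). Any smooth M-shape
  would do — the classifiers consume thresholds and COP geometry, not the
  curve family.
* The stance-phase COP advance is piecewise: heel dwell during loading,
  steady mid-stance advance, fast push-off roll, with the dwell/roll
  fractions tied to the double-support fraction of stance. This makes the
  COP-gradient advance at a uniform rate over the whole gait cycle —
  walking COP motion never pauses, which is the property that separates it
  from standing and holds for arbitrarily slow gait. A rate-scaled
  balance-correction micro-motion is superimposed.
* Foot force is distributed to sensors by linear interpolation between the
  two sensors bracketing the load centre in y, so the per-foot COP tracks
  the intended trajectory exactly (up to noise) and stance COP advance is
  monotone by construction.
* Healthy gait initiation includes an anticipatory postural adjustment
  (COP excursion toward the swing-foot heel) and a push-off roll in the
  last ~150 ms before toe-off; patients instead shift weight to the
  unaffected foot over ~0.6 s. Both give the early (negative) start
  detection characteristic of window-based factors.
* After the final foot-down a decaying post-stop wobble (6 mm, ~0.3 s time
  constant) models the body settling; together with the window memory it
  produces the positive stop-of-walking delay of the COPw threshold.
* Sensor noise is additive Gaussian, SD 0.5 N, truncated at zero.
* The patient shuffle residual (a raised-cosine bump on the swing foot,
  default 20% of body weight) is calibrated to the *phenomenon* — swing-foot
  force crossing the GRF threshold so that the GRF rule misreads walking as
  standing — not to a clinical force magnitude, which is not publicly
  documented.

What the simulator does **not** emulate: kinematics and joint kinetics,
turning or terrain, sensor drift/hysteresis/saturation, within-trial speed
changes, and the spectral richness of real postural sway. Passing tests on
these cohorts therefore demonstrate the internal consistency and the
qualitative mechanisms of the method (shuffling robustness, window-induced
lag), not clinical performance.

## Known limitations and observed divergences

* The approximate-entropy factor screen on the synthetic cohorts does
  *not* rank the COP-gradient derivative among the most transfer-stable
  factors: differentiating at 100 Hz amplifies the white sensor noise, and
  the groups' different signal-to-noise ratios dominate the ApEn of the
  derivative (it ranks last under every screening protocol we tried). The
  underlying gradient-family factors (θ and the per-foot COP y positions)
  do transfer best, and the tests assert that. On real recordings, where
  noise structure differs, the derivative can rank differently.
* Histogram "percentile" summaries report the ascending fraction of the
  pooled two-state sample at or below the state mode; other conventions
  exist, and published tables of this kind do not always state theirs.
* Per-state accuracies are pooled over held-out samples (not averaged per
  trial), so long trials weigh more.
* Detection delays use a 50 ms persistence (debounce) rule; event-level
  delay statistics are sensitive to this choice for noisy threshold
  classifiers, and missing transitions are reported as missing rather than
  imputed.

## Problem sizes

The cohort experiment uses 28 healthy subjects × 10 trials (split 200/80)
and 4 patients × 10 trials (split 30/10) at 100 Hz with 3–5 s standing
segments, ~0.4 M feature samples in total; it completes in about a minute
on one CPU. The `quick` scale (4×3 and 2×3) exists for smoke tests and the
determinism check.
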