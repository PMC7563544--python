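# Methods

This note documents the models, the parameter choices that matter, what the
synthetic generator does and does not emulate, and the numerical decisions
taken where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signals and derivations

Kinematics are ten upper-body sensors sampled nominally at 240 Hz, each
providing 3-D position (m) and a scalar-first Hamilton unit quaternion.
Linear speed is the Euclidean norm of the central-difference velocity
(one-sided at endpoints; second-order accurate, no phase shift).  Angular
speed (deg/s) comes from the log-map of consecutive relative rotations,
accumulated into a rotation-path angle and differentiated centrally; sign
continuity across the quaternion double cover is enforced first, so the
result is invariant under `q → −q` of any frame.  Angular acceleration is
the derivative of the scalar angular speed, `d|ω|/dt` — the waveform whose
peaks and valleys feed the spike extraction.  The alternative `|dω/dt|`
(norm of the angular-velocity-vector derivative) is available behind
`angular_acceleration_from_quaternions(variant="vector")`; the two coincide
for fixed-axis rotation and the scalar form is the default because the
spike analysis needs a scalar waveform with peaks and valleys.

Spike extraction operates on nonnegative waveforms (angular-acceleration
magnitudes, pairwise absolute differences, rectified filtered ECG).  A
consequence worth stating: because both flanking minima lie below the peak,
every standardized amplitude `p/(p + (m1+m2)/2)` of a nonnegative waveform
lies in (1/2, 1]; the [0, 1] bound is attained only in the limit of zero
minima.  Any amplitude model must therefore place its mass there.

## Trial segmentation

"Near zero" speed is operationalized as 5% of the per-trial peak speed — a
scale-free rule that transfers across participants with different speed
ranges.  The forward reach runs from the last sub-threshold frame before
the distance to the target begins its monotone decrease to the frame where
the hand pauses at the target (speed below threshold with distance within
the 2 cm touch radius); the backward retraction runs from the next
super-threshold rise to the next rest.  Intervals are half-open, 0-based.
Trials whose distance never enters the touch radius are invalid
(`no_touch`); trials containing a single-frame position jump above 10 cm on
any sensor are invalid (`sensor_noise`) — a per-trial adaptation of the
participant-level 10 cm accuracy criterion, since no per-trial rule is
otherwise defined.  An optional symmetric moving-average smoothing of the
speed for crossing detection exists (`smooth_frames`) but is off by
default; at the default noise level it is unnecessary.

Segmentation runs on the native 240 Hz series.  Resampling to the ECG rate
(piecewise cubic splines per channel, quaternions interpolated
componentwise after sign-continuity correction and renormalized) is applied
only where joint heart–kinematics analysis needs a shared grid; segment
indices are rescaled by rounding.

## Gamma fitting and EMD

The two-parameter Gamma family (no location shift: amplitudes are strictly
positive and bounded) is fitted by full MLE; the NSR equals the fitted
scale exactly.  95% confidence intervals use the observed Fisher
information transformed to (log shape, log scale) — asymptotically normal
on the log scale, respecting positivity and always containing the point
estimate:

    var(log â) = 1 / (n a (a ψ₁(a) − 1)),   var(log b̂) = ψ₁(a) / (n (a ψ₁(a) − 1)).

Histograms use the Freedman–Diaconis rule (bin width `2·IQR·n^(−1/3)`,
square-root fallback when the IQR vanishes), each histogram keeping its own
edges.  EMD between normalized 1-D histograms is computed as the integral
of the absolute CDF difference over the merged support of the bin centers;
the explicit transport linear program (flow constraints, cost normalized by
total flow) is retained as an independent oracle and agrees to 1e-9 in the
acceptance checks.  Minimum sample size for fitting/histogramming is 100
spikes (configurable); study-scale cells pool thousands.

## Connectivity

Body–body edges: normalized cross-correlation with biased normalization
(dividing by the series length, which tapers estimates at extreme lags) over
a ±1 s lag window — the stated bound on inter-device lag.  The edge weight
is the maximal |r| and the signed lag of that maximum is stored
antisymmetrically; ties resolve to the smallest |lag|, then the positive
one.  Edges are computed on the **concatenated** per-segment intervals of
all valid trials rather than per-trial-then-median: with ~0.45 s segments
and a ±1 s window, even white-noise pairs would reach per-trial max |r| of
about 0.3, so short-window maxima statistics — not coupling — would set the
floor.  Concatenation pools the full segment sample and makes an
uncoupled-null median weight fall below 0.2.

Clustering uses the geometric-mean triangle-intensity form: with weights
normalized by the maximum weight, `t_i = Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}` and
`C_i = 2 t_i / (k_i (k_i − 1))` over the nonzero-edge degree `k_i`
(`C_i = 0` for `k_i < 2`).  This is the standard weighted form in which the
pair count `k_i(k_i−1)/2` normalizes the unordered triangle sum; it matches
exhaustive enumeration to 1e-12 and the established graph-library
implementation exactly.

Heart–body edges follow the per-trial-then-median scheme: for each valid
trial, the ECG amplitude envelope is slid over a ±0.4 s window against the
part's segment speed; the per-trial maximal **signed** correlation and its
lag are collected and summarized by medians.  Signed rather than absolute,
because only co-activation is a meaningful envelope–speed match — |r|
maxima otherwise lock onto envelope troughs anticorrelated with the speed
bump.  The window is ±0.4 s rather than the generic 1 s because adjacent
movement segments sit ~0.65 s apart and their envelope bumps are
shape-identical to the target's; a wider window would alias the match to
the neighboring segment.  When the inter-device clock offset is unknown
(up to ±1 s), lags are interpretable only as within-session differences;
the absolute lead/lag pattern requires aligned clocks (see Limitations).

The envelope itself: analytic-signal magnitude of the 5–30 Hz zero-phase
Butterworth-filtered ECG, with beat transients removed — the cardiac period
is estimated from the autocorrelation of a >4 Hz high-passed copy of the
envelope (the high-pass prevents locking onto the task rhythm), one beat
per cycle is located, ±0.10 s around each beat is masked and bridged by
band-limited inpainting (iterative 3 Hz low-pass projection), and the
beat-locked residual template (median across beats, edge-anchored) is
subtracted to remove ringing tails.  Every step is time-symmetric, so no
lag bias is introduced; zero-phase filtering throughout is essential since
a single-pass IIR filter would inject a frequency-dependent delay directly
into the lead/lag estimates.

## Aggregation and the consistency grid

Per participant, each metric is reduced to medians per (segment × side)
cell: NSR over nodes and over pairs separately (pairs are side-labeled only
when both endpoints share a side; mixed pairs enter segment marginals
only), cross-correlation over edges, clustering over nodes, EMD and
lead/lag over heart edges.  Marginal cells (a segment pooled over sides, a
side pooled over segments) are **balanced**: the unweighted mean of the
cross-cell medians over the pooled factor.  The median of a pooled bimodal
set is an unstable order statistic — it sits between two clusters and flips
with small per-part jitter — whereas balanced marginalization keeps each
cell's weight fixed.  Deltas (forward − backward; performing −
non-performing; each also conditionally within the other factor's levels)
are computed per participant; missing cells yield NaN, never zero.

Across participants, a metric × contrast receives `o` when the delta sign
is unanimous, `Δ` when strictly more than half agree, `-` otherwise ("most"
is deliberately a bare majority — no stronger quantification is defined).
The lead cells report which signal leads (EKG for positive median lag, LS
for negative) with the same consistency symbols.  No null-hypothesis tests
are attached to the grid; a two-sided sign-test utility exists but is not
used by the summary.  Midline sensors (forehead, T7) carry no side and
never enter side contrasts.  Side assignment mirrors with handedness.

## The synthetic generator

The generator's defaults are the emulated study conditions: 180 trials,
240/256 Hz, ten sensors (dominant-side scapula/upper arm/forearm/index
finger = performing; mirror set with contralateral hand = non-performing;
forehead and T7 midline), reaches of ~0.35 m lasting ~0.45 s with ~0.5 s
retractions, 72 bpm heart rate.  What it injects, and how:

* **Reach geometry.**  Minimum-jerk end-effector trajectories (bell speed,
  monotone distance decrease), with a band-limited (6–12 Hz) fluctuation
  whose per-segment speed-ripple RMS is pinned exactly to the configured
  amplitude (defaults 0.6 mm forward, 1.5 mm backward — the spontaneous
  retraction is the more variable segment).  The fluctuation splits evenly
  between the movement direction (perturbing speed at first order) and the
  transverse direction (path wiggle).  Position measurement noise is 10 Hz
  low-passed white noise of 0.2 mm — the static-accuracy scale of a
  vendor-filtered electromagnetic tracker; segmentation-boundary jitter
  scales directly with this value.
* **Spike laws.**  Each sensor's orientation stream is constructed so that
  the angular-acceleration magnitudes recovered by the analysis equal a
  designed oscillation exactly: the analysis' central-difference operators
  decouple on even/odd frame lattices, which the generator inverts by
  double cumulative sums per lattice (a constant baseline rotation rate
  keeps the angle strictly increasing so the quaternion log-map never folds
  it).  Valley/peak knots at 3–5 frame gaps realize spike amplitudes drawn
  from the configured cell law: Gamma(shape 250; scales 0.00320 / 0.00292 /
  0.00284 / 0.00256 for forward-performing / forward-non-performing /
  backward-performing / backward-non-performing; midline cells average the
  sides), truncated to the representable interval (0.52, 0.999).  Cell
  means 0.64–0.80 sit ≥ 4 standard deviations below the amplitude ceiling
  at 1, keeping the truncation mass (and hence the MLE bias it would
  otherwise induce) negligible: a ≥ 2500-spike session recovers the
  configured parameters within the 95% CIs.
* **Coupling.**  Non-end-effector sensors displace along fixed per-sensor
  directions as attenuated copies of the reach profile with per-(segment ×
  side) amplitudes (defaults 0.85 / 0.70 / 0.65 / 0.50), plus a continuous
  band-limited background sway at 20% of the coupled peak speed.  The
  background is deliberately *not* movement-locked so that an uncoupled
  sensor is genuinely uncorrelated with the task; its level is chosen so
  the injected lead structure dominates within segments while the coupling
  ordering still separates the cells.
* **Heart lead/lag.**  The ECG is a strictly periodic template QRS train
  (Gaussian R wave with Q/S dips) plus a 12 Hz band-limited component whose
  amplitude follows minimum-jerk bumps, one per movement segment, centered
  `heart_lead_ms` before (positive) or after (negative) that segment's
  speed peak — defaults +150 ms forward, −50 ms backward.  Side structure
  comes from an anticipatory advance of the non-performing side (100 ms;
  midline 50 ms): supporting body parts begin moving before the end
  effector, so the four cross cells realize lags of +150 / +50 / −50 /
  −150 ms and all four marginals carry the observed pattern — heart leading
  deliberate and performing-side motion, kinematics leading spontaneous and
  non-performing motion.  A symmetric ±150 default with no side structure
  would make the side marginals exactly ambiguous.
* **Clocks.**  The ECG clock offset is configurable; the default is 0
  (clocks aligned, as after timestamp-based alignment).  Passing
  `clock_offset_s=None` draws uniform(−1, 1) s per session to emulate
  unsynchronized devices, under which absolute lead directions are
  unrecoverable by construction.

Everything injected is reported in the `GroundTruth` sidecar.  Generation is
bitwise deterministic in (seed, trial index).

What the generator does **not** emulate: physiologically detailed ECG
morphology (P/T waves, RR variability — beats are strictly periodic),
biomechanically articulated limb motion (sensors move along fixed
directions rather than a jointed skeleton), movement errors (every trial
touches the target), electromagnetic interference or sensor dropout beyond
white position noise, and any perceptual-response behavior.  Passing tests
therefore demonstrate that the analysis recovers known structure of this
statistical form at study scale — not that real recordings contain that
structure, nor robustness to artifacts the generator never produces.  The
carrier-borne autonomic modulation in particular is a deliberate
simplification: amplitude modulation of sustained in-band activity is the
cleanest vehicle for a controllable, sub-sample-recoverable lead, whereas
modulating beat amplitudes alone would sample the envelope at the ~1.2 Hz
heart rate and could never support ±2-sample lag recovery from half-second
windows.

## Problem sizes

Default test problem sizes are chosen as the smallest that exercise each
property at study-relevant statistics: unit tests use 8–30-trial sessions;
spike-law CI recovery uses 240 trials (≥ 2500 spikes in the tested cell);
lag recovery uses 50 seeds of 12-trial three-sensor sessions; the
end-to-end pattern check runs the full eight-participant, 180-trial cohort
(two left-handed participants, mirrored side assignment), as does the
acceptance script.

## Known limitations

* The Gamma cells of real MMS data need not share a common shape; the
  generator varies only the scale across cells, so shape-driven effects are
  untested.
* Pair-difference (edge) NSR is an emergent quantity of the generator, not
  directly injected; its side ordering follows from the node-level
  injection but with a smaller margin than node NSR.
* The ±0.4 s heart lag window assumes leads well under the inter-segment
  spacing; grossly offset clocks require re-alignment first, and absolute
  lead directions are meaningless without it.
* Envelope beat-removal assumes beats are the dominant periodic transient;
  heavily arrhythmic or low-SNR ECG would degrade the lag estimates before
  the medians break.
* `TrialSegmentation.at_rate` rounds interval endpoints independently, so
  rescaled intervals can differ by one sample from exact rescaling.
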