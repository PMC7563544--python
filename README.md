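# intentnet

Multilayer analysis of **motor intent** from upper-body kinematics and ECG.

During a pointing task, every trial contains a deliberate, goal-directed
forward reach (high motor intent) and an uninstructed, spontaneous backward
retraction (low motor intent); likewise the performing side of the body acts
with higher intent than the non-performing side.  `intentnet` quantifies how
these levels of intent separate in the *moment-to-moment fluctuations* of
biorhythmic signals, and in the connectivity between the body's sensors and
the heart:

* **Micro-movement spikes (MMS).**  A nonnegative waveform with peaks and
  valleys (here the angular-acceleration magnitude of each sensor, pairwise
  absolute differences between sensors, and the rectified filtered ECG) is
  reduced to unitless spike amplitudes

  `a = p / (p + (m1 + m2)/2)  in [0, 1]`,

  each local peak `p` standardized by the mean of its flanking minima.  The
  standardization is exactly invariant under positive rescaling, removing
  allometric (body-size and unit) effects.
* **Noise-to-signal ratio (NSR).**  MMS amplitudes are fitted by a
  two-parameter Gamma(shape, scale) via maximum likelihood with 95% CIs; the
  fitted **scale** is the NSR — larger scale, more dispersed fluctuations.
* **Earth mover's distance (EMD).**  Amplitude histograms
  (Freedman–Diaconis bins) are compared by the 1-D Wasserstein transport
  distance — a proper two-sided metric on probability space — to measure
  stochastic shifts between each body part and the heart.
* **Connectivity networks.**  Pairwise maximal normalized cross-correlations
  of linear-speed waveforms define a weighted undirected graph over the ten
  body sensors; per-node weighted clustering coefficients
  `C_i = 2 t_i / (k_i (k_i − 1))`, with `t_i` the geometric-mean triangle
  intensity of max-normalized weights, quantify self-emerging kinematic
  synergies.
* **Heart lead/lag.**  Per trial, the amplitude envelope of the 5–30 Hz
  band-passed ECG is cross-correlated with each body part's linear speed;
  the signed lag of the maximal correlation (positive = heart leads the
  movement) is summarized by its median.

A full **synthetic session generator** emulates the recording setup (ten
electromagnetic sensors at 240 Hz with positions and orientation
quaternions; single-channel ECG at 256 Hz; ~180 pointing trials) and injects
every statistical structure the analysis measures — per-(segment × side)
Gamma spike laws, cross-body coupling levels, signed heart leads — so the
entire pipeline is testable end-to-end against known ground truth.

## Worked example

Generate a three-participant synthetic cohort, analyze each session, and
summarize consistency across participants:

```python
from intentnet.synthetic import SessionConfig
from intentnet.pipeline import run_cohort
from intentnet.compare import format_summary

configs = [SessionConfig(n_trials=60, seed=40 + i) for i in range(3)]
metrics, comparisons, summary = run_cohort(configs)

c = comparisons[0].cells
print(c["nsr_aa"][("forward", "all")])   # median NSR, forward segments
print(format_summary(summary))
```

Output (participant 0's cells, then the cohort grid):

```
nsr_aa    forward=0.003118 backward=0.00264 performing=0.003133 non_performing=0.002694
xcorr     forward=0.9438   backward=0.8674  performing=0.9578   non_performing=0.8827
cc        forward=0.9435   backward=0.8882  performing=0.9289   non_performing=0.9053
heart_lag forward=0.09603  backward=-0.1029 performing=0.04932  non_performing=-0.05859

Kinematics (AA) network
metric        Forward     Backward    Performing  Non-Perf
nsr_aa        o                       o
nsr_aa_diff   o                       o
xcorr         o                       o
cc            o                       o
Kinematics (LS)-heart network
emd                       o                       o
heart_xcorr   o                       o
lead          EKG (o)     LS (o)      EKG (o)     LS (o)
```

Reading the numbers: the median NSR of angular-acceleration MMS is higher on
forward segments (0.00312 vs 0.00264) and on the performing side, i.e.
deliberate motion carries *more* amplitude dispersion; speed
cross-correlations and clustering coefficients are likewise higher under
higher intent (stronger, more synergistic coupling across the body); and the
heart's envelope *leads* the kinematics by ~96 ms on forward segments while
it *lags* by ~103 ms on backward ones.  In the grid, `o` marks a direction
shared by every participant, `Δ` by most, `-` none; the lead row names the
leading signal (EKG vs. LS, linear speed) per cell.

The same workflow is available from the shell:

```
intentnet simulate --out session0/ --seed 1 --n-trials 60
intentnet run --session session0/ --out results0/
intentnet summarize --results results0/ --results results1/ --out summary.json
```

## Layout

| module | contents |
| --- | --- |
| `intentnet.synthetic` | session generator: configs, trials, ECG, ground truth |
| `intentnet.preprocessing` | 240→256 Hz cubic-spline resampling, 5–30 Hz zero-phase Butterworth, speed/distance trial segmentation, noisy-trial flags |
| `intentnet.kinematics` | linear speed, quaternion angular speed, angular acceleration |
| `intentnet.mms` | peak/valley detection, spike standardization, Freedman–Diaconis histograms |
| `intentnet.stochastic` | Gamma MLE + Fisher-information CIs (NSR), EMD with LP oracle |
| `intentnet.network` | cross-correlation adjacency, weighted clustering, heart–body edges |
| `intentnet.compare` | side assignment, per-participant cells/deltas, consistency grid |
| `intentnet.pipeline` | end-to-end session analysis and cohort runner |
| `intentnet.io`, `intentnet.cli` | CSV/JSON/YAML schema, `intentnet` command |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
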