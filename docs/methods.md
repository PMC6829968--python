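# Methods

## Signal conditioning

Raw sEMG is processed per channel as: fifth-order Butterworth high-pass at
20 Hz (removes motion artifacts and baseline drift), full-wave rectification,
fifth-order Butterworth low-pass at 32 Hz (keeps the contraction-rate
envelope), then standardization.

Three choices here were genuinely open and are the package's own:

* **Zero-phase filtering** (forward–backward, `sosfiltfilt`) is the default.
  Envelope timing must be identical on both body sides for the power
  comparison to be fair, and causal filtering would delay both envelopes by a
  frequency-dependent lag.  Consequence: the −3 dB point of a single pass
  becomes −6 dB for the two-pass response.  Single-pass behavior is available
  via `FilterSpec(zero_phase=False)` and is what the cutoff-gain checks use.
* **Negative-overshoot clipping.** The low-pass of a rectified signal can dip
  slightly below zero near sharp transients; envelopes are clipped at exactly
  0 so downstream powers are nonnegative.
* **Standardization scope.** "Median over the whole set of channels" could
  mean per-channel medians or one pooled median.  The default is ONE pooled
  session-global scalar (the median of all envelope samples across channels
  and time): dividing each channel by its own median would erase the
  between-muscle power ratios that the coordination coefficients are built
  from.  A `per_channel` mode exists for sensitivity analysis
  (`PreprocessConfig.standardization_mode`).  Standardization is applied at
  the end of the chain; a `rectified` envelope stage (no low-pass) is
  switchable for the same reason.  Both ESB and MCS are invariant to the
  standardization scalar — it cancels in the ratio and in the correlation —
  which the test suite asserts numerically.

Edge transients: the first and last second of each trial (`edge_trim_s`,
default 1.0 s) are excluded from power integration; the protocol's 20-s
trials leave 18 usable seconds.

## Power extraction and the indexes

Muscle power per second is the RMS of the envelope over consecutive,
non-overlapping 1-s windows (trailing partial second dropped).  The trial
power `P_i` is the **mean** of the per-second values — robust to trials of
slightly different usable length; a sum would scale both sides equally and
change neither index.  Side totals are plain sums over the nine muscles;
coefficients are `a_i = P_i / P_r` and `b_i = P_i / P_l`.

`ESB = (P_r − P_l)/(P_r + P_l)` is bounded in [−1, 1] by construction and
antisymmetric under side exchange.  `MCS` is the Pearson product-moment
correlation of the nine (a_i, b_i) pairs, implemented in the summation form
`(nΣab − ΣaΣb)/…` and cross-checked in tests against an independent
correlation implementation to 1e−12.  Degenerate cases are explicit rather
than silent: a trial with one silent side yields ESB = ±1 with MCS flagged
undefined (`None`, serialized `NA`); a constant coefficient vector (e.g.
single-muscle activity) makes the MCS denominator vanish and is flagged the
same way; a trial silent on both sides is rejected with a diagnostic.
Rounding can push the correlation past |1| by ~1e−16; the returned value is
clamped to the mathematical bound.

Activity prints (per-muscle coefficient distributions) use quartiles by
linear interpolation between order statistics, Tukey fences at 1.5 IQR with
whiskers clipped to the most extreme non-outlier points.  Sides are mapped to
roles — *reference* (dominant arm of healthy subjects, non-paretic arm of
patients) and *affected* — via subject metadata rather than an assumption
about handedness.

## Synthetic data

The generator emulates only the statistical features the pipeline consumes;
it is not a physiological simulation.  Each channel is amplitude-modulated
band-limited Gaussian noise: `gain_side · w_i · E(t) · G(t) + floor · G'(t)`
with `E(t)` a train of raised-cosine (Tukey, α = 0.5) bursts at the 0.25 Hz
pacing frequency (duty 0.5 of the cycle, Gaussian onset jitter sd 0.05 s) and
`G, G'` unit-variance noise carriers band-limited to 20–450 Hz.  Defaults
follow the recording protocol: 20-s trials at 1000 Hz, 18 channels.  Because
trial power is an RMS amplitude, it is linear in the gain: a side-gain ratio
g maps to an expected ESB of (g−1)/(g+1), and the recovered coefficients
approach the programmed weights — the parameter-recovery tests confirm mean
ESB within ±0.05 of the analytic value for g ∈ {1, 1.5, 2, 4} and a
monotone MCS decline under coordination perturbation with ESB held near 0.

* **Coordination weights** default to an elbow-flexion-like profile (elbow
  flexors BR/B dominant) and a steering profile (shoulder girdle loaded);
  both sum to 1 over the canonical muscle order.
* **Noise floor** defaults to 0.005 of the unit side gain per channel.
  Active channel amplitudes are `gain · w_i` with nine weights summing to 1,
  so this puts baseline (electrode/amplifier) noise at a few percent of a
  typical channel's burst amplitude — a clean clinical recording.  The floor
  is additive on every channel and therefore biases coefficients slightly
  toward uniform and ESB slightly toward 0; at the default level the bias is
  below 0.015 in ESB.
* **Impairment profiles** are a monotone severity ladder (SIAS-like levels
  5 → 1): affected/reference strength-ratio mean 0.90 → 0.35 with sd
  0.03 → 0.28, coordination-perturbation sd 0.02 → 0.25 (additive Gaussian on
  the weight vector, floored at 0, renormalized).  No quantitative per-level
  effect sizes exist to calibrate against — the underlying patient recordings
  are not publicly deposited — so these defaults are **illustrative**: they
  encode the qualitative pattern (larger offsets *and* larger between-subject
  dispersion with severity) rather than measured effect sizes.
* **Randomness** is split into separate streams (`SeedSequence.spawn`) for
  subject-level draws and trial-level noise, so cohort structure is
  reproducible independently of trial count.  Identical seeds give
  bit-identical output end to end.

What passing tests on synthetic data do *not* show: robustness to electrode
displacement, crosstalk between channels, mains interference, non-stationary
fatigue effects, or trial-quality problems that real recordings required
manual discarding for.

## Cohort statistics

Per (index, motion) panel, every pair of severity groups is compared with a
two-sided Wilcoxon rank-sum test at α = 0.05: exact enumeration of the
permutation null for combined n ≤ 20 without ties, otherwise the normal
approximation with midrank tie correction and continuity correction (the two
branches agree within 0.01 at n = 10 vs 10).  An entirely tied pooled sample
short-circuits to p = 1 (its tie-corrected variance is zero).  The
Bonferroni–Holm step-down correction is applied per panel; ESB enters as
|ESB| so the summary is invariant to which arm is paretic (asserted by a
side-flip test).  Group dispersion is the sample SD (n−1).  Trials with
undefined MCS are dropped from MCS panels (counted), kept in ESB panels;
groups with fewer than 3 defined values are excluded with a warning.  The
comparison family is all-vs-all by default and restrictable via
`pair_family`.

**Limitation — clustered trials.** Repeated trials of one subject share that
subject's drawn parameters and are positively correlated; the trial-level
rank-sum test assumes independent observations and becomes anti-conservative
under strong clustering.  The type-I control check therefore uses an
exchangeable null cohort (no between-subject spread), which tests the
machinery under its own assumptions; on real data, subject-level aggregation
or cluster-aware tests would be the conservative route.

## Problem sizes in the test suite

Parameter-recovery checks run 50 trials per condition at full protocol scale
(20 s, 1000 Hz).  Cohort-level replicate checks (type-I control, severity
sweep) shorten trials to 6 s at 250 Hz with no rest periods: the indexes need
only a few usable seconds per trial, and the severity pattern lives in the
between-subject draws, not the trial length.
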