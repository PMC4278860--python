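# Methods

## Signal model and feature chain

Raw neural data are treated as channels × samples in microvolts at
1 kHz, synchronized with 3-D hand position (height, depth, lateral; cm) at
100 Hz. The feature chain is:

CAR → per-band zero-phase FIR filtering → downsample to 100 Hz → square →
1-s bidirectional moving average → log(·+ε), plus the LMP (2-s
bidirectional moving average of the CAR signal, decimated to 100 Hz).

Choices that needed fixing where the procedure admits more than one
reading:

- **Filter order.** "Order 400" is realized as 401 taps (order = number of
  delay elements). Filters are Hamming-windowed `firwin` designs; the delta
  band is a 0–4 Hz low-pass because a 0 Hz band edge is not realizable as a
  band-pass. At 1 kHz these designs have ≥ 0.9 gain at every band centre
  and ≤ 10⁻³ gain at 60 Hz.
- **Pipeline order.** The default follows filter → downsample → square →
  smooth → log even though decimating the 130–200 Hz band to 100 Hz aliases
  the carrier: aliasing preserves variance, so the smoothed power envelope
  is still valid. An `envelope_first` option (square and smooth at 1 kHz,
  then decimate) is provided; on band-limited noise the two agree to within
  estimation error (interior correlation > 0.95 in tests).
- **Downsampling** takes every 10th sample starting at sample 0, with no
  extra anti-alias filter beyond the band filter itself.
- **Smoothing** is a causal boxcar applied forward then backward, i.e. a
  zero-phase triangular kernel of half-width w−1 summing to 1. Edge samples
  carry the zero-state startup transient; `extract_features` therefore
  trims `trim_margin_s` (default 2 s, the widest smoothing window) from
  both ends of features and kinematics jointly.
- **log guard** ε = 1e−12 µV² keeps silent channels finite (log ε).
- Everything is deliberately **non-causal** (zero-phase); a causal mode is
  out of scope.

## Decoding

Per fold (five contiguous blocks; the held-out block is 20%):

1. z-score kinematics with training mean/sd (sample sd, ddof 1); fit the
   3×3 PCA on the normalized training kinematics only. PCA rows are flipped
   so the largest-|loading| element is positive — the sign is arbitrary and
   must be stable across folds for decoders to be comparable.
2. score every (channel, feature type) by Pearson r against the target at
   lags −1000…+1000 ms in 50 ms steps (41 lags), pooling only sample pairs
   whose indices both fall inside a training segment; take the top
   `n_inputs` by |r| (|r| because desynchronizing features carry
   information with negative sign). Ties break by smaller |lag|, then lower
   channel index and feature-type order.
3. build the lag-aligned design matrix (rows restricted so that every
   lagged index stays inside the same block — no sample ever crosses the
   train/test boundary), z-score columns with training statistics, fit OLS
   with intercept.
4. evaluate Pearson r on the held-out block; Fisher z uses the number of
   evaluated test samples.

Contiguous blocks rather than random-sample folds are essential: the 1–2 s
integrators leave features autocorrelated over seconds, and sample-wise CV
would leak that memory across the split. A dedicated test mutates held-out
samples and asserts the trained selections and weights are bit-identical.

Lag convention: r(ℓ) correlates feature(t+ℓ) with target(t), so a feature
that *leads* the movement peaks at negative ℓ (motor-like) and one that
follows peaks at positive ℓ. The cross-lag tables are computed with one
BLAS product against a bank of shifted targets plus prefix sums, exact to
the direct per-lag formula at < 1e−12.

## Chance calibration and tests

`shuffle_null` decouples features from kinematics *before* selection and
training, then reruns the entire cross-validation per shuffle. Default mode
is `circular_shift` (each trace rotated by a uniform offset ≥ 5 s from
identity): it preserves each feature's autocorrelation, which sample-wise
permutation of heavily smoothed traces would destroy, making chance look
unrealistically easy to beat. A literal `permute` mode is provided for
comparison. The null stores both per-shuffle medians and per-fold
accuracies; the Wilcoxon rank-sum test compares observed fold accuracies
against the null's *fold* accuracies, because a fold accuracy and a median
over folds have different spread and mixing them makes the test
anti-conservative (observed directly during calibration).

The reference shuffle count is 1024; calibration experiments here use 256
(and small sessions), which bounds the resolvable tail at ~0.4% — adequate
for 95% intervals and max-separation statements.

Other machinery: Dunn–Šidák per-test level 1−(1−α)^(1/m); two-way
fixed-effects ANOVA on Fisher-z accuracies (statsmodels, type-II sums) with
Welch-t Dunn–Šidák post-hocs; saturation via Kruskal–Wallis with
Conover-style least-significant-difference comparisons on rank means — the
saturation point is the smallest model order no larger order significantly
beats (one-sided, uncorrected by design: LSD).

## Surrogate sessions

`SynthConfig` defaults are the emulated study conditions: 16 channels, 40
reaches of 2–5 s separated by 0–16.7 s rests (≈ 8 min), 1 kHz/100 Hz rates,
three informative channel-band pairs — high gamma 1 at gain +0.8 (lag
−100 ms), mu −0.75 (−50 ms), beta −0.75 (+100 ms) — over 15 µV-RMS pink
noise with 8 µV-RMS band carriers.

- **Trajectories** are minimum-jerk (10τ³−15τ⁴+6τ⁵) out-and-back segments
  to targets drawn uniformly in the workspace box; rests hold a home
  position (low height/depth corner, laterally centred by default, so
  reaches go up-and-forward but vary left/right — which is what leaves PC2
  dominated by bidirectional lateral motion and undecodable from a
  PC1-encoding drive). `home_fraction` moves the home point; placing it at
  a full corner pins the reach direction and with it the PC1 loadings
  across folds, the regime used for the near-noiseless consistency checks.
- **The latent drive** d(t) is PC1 of the z-scored clean kinematics,
  min-max rescaled to [0, 1]; carriers of informative bands are multiplied
  by max(1+gain·d(t−lag), 0), LMP information enters as an additive slow
  offset (5 µV per unit gain·drive), and an optional 60 Hz line sinusoid
  exercises the band definitions.
- **Default gains** were calibrated once so that end-to-end PC1 decoding of
  the default session lands in r ≈ 0.7–0.85 — the upper half of the
  0.5–0.8 range the method reports on real recordings — because weaker
  encodings let best-lag estimates drift beyond one or two 50-ms grid
  steps; the exact signal-to-noise of real features is unknown and this
  value is a modelling choice, not a claim about cortex.

What the generator does *not* emulate: volume conduction and inter-channel
correlation of the background, EMG/eye artifacts, non-stationary noise
floors, cross-frequency coupling, and trial-to-trial variability of the
encoding itself. Passing tests therefore demonstrate internal consistency
of the analysis chain and its statistics under the assumed encoding — not
performance on real ECoG.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks use scaled-down sessions chosen as the smallest
that keep the relevant statistics stable: chance calibration uses 20 (tests)
or 10 (script) four-channel ~50 s sessions with 256-shuffle nulls;
PC-ordering uses 12-channel, 12-reach sessions across 20 seeds with
32-shuffle bands; the separation check uses the full default session with a
256-shuffle null. The fivefold accuracies on a ~47 000-sample session give
fold test sets of ~9 400 samples.

## Known limitations

- The per-fold best lag is re-estimated per fold; with moderate SNR it can
  move by one 50-ms step between folds.
- Fisher z uses the raw test-sample count n, ignoring autocorrelation of
  the smoothed traces; z values are comparable between conditions but are
  not calibrated standard normals.
- The saturation rule inherits LSD's permissiveness by construction; it is
  a "first order at which gains stop" locator, not a multiplicity-corrected
  test.
- EDF files can be read (via MNE) but not written; CSV and HDF5 are the
  interchange and canonical formats.
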