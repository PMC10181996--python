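# Methods

## The pressure model

The package's generative and analytical core is a transit-time model of
arterial pressure.  A Moens–Korteweg-style relation links pulse wave
velocity to pressure, `BP = K1·ln(1/PWV + K2)` (natural log; any other base
is absorbed into K1).  Pulse pressure is stroke volume over compliance; with
stroke volume proportional to the pre-ejection period and a
Womersley-number correction for pulsatile flow of a viscous fluid,

    PP  = k_pp · D,      D = (PEP / (PIR · PTT²)) · (1 − 0.56/(√2·α))⁻²
    DBP = a·ln(D) + b
    SBP = PP + DBP,      MAP = (2·DBP + SBP)/3

The driving term `D` is dimensionless; `k_pp`, `a` and `b` are explicit
constants that make the two proportionalities generative (no values for them
are established in the literature, so they are package parameters).  The
Womersley factor is undefined at α ≤ 0.56/√2 and all log arguments must be
positive; the implementation raises on violation rather than returning
non-finite values.  Assumptions worth keeping in mind: the model treats the
artery as a long Newtonian-flow tube, collapses compliance and stroke-volume
physiology into scalar constants, and takes PEP, PIR and α as independent
latent quantities.

## Synthetic cohorts

`SynthConfig` fixes the study conditions.  Two presets exist:

* **ICU-style cohort** (default): 31 subjects contributing 126 five-cycle
  measurement windows (at most 5 per subject), one finger-PPG channel plus
  chest ECG and an invasive arterial channel at 125 Hz, 60 % male, ages
  35–85.
* **Wrist cohort**: 23 subjects, one window each, two PPG channels 5 mm
  apart at 400 Hz (no arterial line), 52 % male, ages 25–60, with the extra
  demographics waist, weight and temperature.

Per record the generator draws, uniformly from configured ranges chosen to
give a plausible adult pressure distribution (typical SBP ≈ 90–160,
DBP ≈ 65–95 mmHg): heart rate 60–100 bpm, PTT 0.18–0.28 s, PEP 0.07–0.11 s,
PIR 1.8–2.6, α 2.5–3.5, systolic-rise fraction 0.25–0.35 of the cycle, and
peak amplitude 0.8–1.5 a.u.  The pressure constants default to k_pp = 32
mmHg, a = 20 mmHg, b = 78 mmHg.  Labels are the model-implied SBP/DBP/MAP
plus independent Gaussian noise of SD `noise_sd_bp` (default 2 mmHg,
emulating reference-measurement error); with zero noise the MAP identity
holds exactly row-wise.  Demographics are drawn independently of the labels:
the package makes no claim about demographic→pressure coupling, so the
demographic columns act as null features.

Waveforms are stylized: the ECG is a spike train (only R-peak timing matters
to the features), each PPG beat is a half-cosine rise to the peak followed
by an exponential decay (time constant Td/5, so the pulse returns to < 1 %
of its amplitude by the next foot), and the arterial channel repeats the
beat shape scaled to swing exactly between DBP and SBP.  Beat timing is
quantized to the sample grid and the ground truth reports the realized
(quantized) values, which is what makes exact roundtrip tests possible.
What the generator deliberately does **not** emulate: dicrotic notches,
motion artefacts, arrhythmia, baseline wander, and any morphology→pressure
coupling beyond the equations above.  Passing tests therefore demonstrate
the pipeline's internal correctness, not clinical performance on real
recordings.

## Feature extraction

R peaks are local maxima above half the robust spike height (median of the
top-k samples with k = the plausible beat count at 40 bpm, so a single
artefact cannot inflate the threshold) separated by a 250 ms refractory
period.  Per cardiac cycle the PPG systolic peak is the maximum inside the
following beat interval and the foot the latest minimum in the preceding
0.6-beat span, never searching before the previous systolic peak.  The
five-cycle analysis window is the first run of five consecutive cycles whose
R–R lengths have a coefficient of variation below 10 % and whose pulse
amplitudes below 20 % (an automated stand-in for manual artefact-free
selection; thresholds are parameters).  R–R intervals are used for the
length criterion because the PPG foot sits on the flat diastolic tail and
its sample position is not noise-stable.

Averaged over the window: PAT (R peak → PPG peak, following the
peak-to-peak convention), PTT (proximal → distal PPG peak, dual-channel
records only), pulse rate 60/mean(Tc), and the eight morphology features
(Ts foot→peak, Td peak→next foot, Tc = Ts+Td, Vp the foot-to-peak
*amplitude*, Vs = Vp·Ts/Tc, dVs = Vp/Ts, Vd = Vp·Td/Tc, dVd = Vp/Td).
Reference SBP/DBP are the means of the per-cycle arterial maxima/minima and
MAP follows the weighted identity.  Two conventions were genuinely open and
are resolved as: the PPG cycle start is the local minimum (not a
tangent-intersection foot), and Vp is an amplitude, not a duration (the
duration reading would duplicate Ts).

## Estimators

Five families, each with the published five-row trial grid and the
lowest-LOO-error-SD selection rule (ties to the earlier row):

* **Elastic net** — the grid's "alpha" 0.6–0.8 is the lasso↔ridge mixing
  weight; the penalty strength is not specified anywhere, so it is chosen by
  internal 3-fold cross-validation over a 30-point path (eps 1e−6), or
  passed explicitly for exact-recovery tests.
* **Boosted regression trees** — gradient boosting with the grid's
  (splits, cycles) mapped to per-tree leaf budget and number of trees;
  learning rate 0.1.
* **SVR** — RBF kernel with gamma = 1/scale², epsilon fixed at 0.1 mmHg,
  features z-scored.
* **Feed-forward network** — one hidden layer of 20 log-sigmoid units,
  linear output, trained full-batch by L-BFGS (a quasi-Newton stand-in for
  Levenberg–Marquardt) for the grid's epoch budget; features and target
  z-scored.
* **Single-step LSTM** — each feature vector is a length-1 sequence.  With
  zero initial state the forget gate multiplies zero and drops out, leaving
  the closed form `h = σ(W_o x)·tanh(σ(W_i x)·tanh(W_g x))` with a linear
  read-out, implemented in numpy with manual gradients and full-batch Adam
  (learning rate 0.01, 140 hidden units); features and target z-scored.
  Deterministic under a fixed seed.

Separate models are trained per target.  MAP is learned directly; the
published grid marks winning rows only for SBP and DBP, so MAP reuses the
DBP selection (MAP is two-thirds DBP by the identity) — overridable.

## Protocols, grading, statistics

Signed error is estimate − truth in mmHg.  Leave-one-out produces one error
per row, each from a model trained on the other n−1; holdout splits use a
seeded permutation with floor(ratio·n) training rows and accept the study's
80:20 and 70:30 ratios unless explicitly overridden.  Summaries report bias
(mean), sample SD (n−1 denominator), and a normal-approximation 95 % CI
bias ± 1.96·sd/√n — the normal quantile (not Student-t) reproduces 51 of
the 60 published intervals exactly at 2-decimal rounding (the other nine
differ by one hundredth, consistent with rounding of the printed μ/SD), at
both n = 23 and n = 126.  Report rounding is half-away-from-zero.  Accuracy
grading is inclusive: |bias| ≤ 5 mmHg and SD ≤ 8 mmHg.  Bland–Altman limits
are mean difference ± 2 SD.

Method comparison treats the benchmark as a balanced 5 × 3 two-factor
layout.  Mean differences: classical two-way ANOVA (statsmodels OLS;
balanced, so the sums-of-squares type is immaterial), reporting F, numerator
df (feature 2, method 4, interaction 8) and denominator df.  Spread
differences: the two-factor Levene test — the same ANOVA applied to absolute
deviations of each error from its cell mean (mean centering is the classical
Levene; median centering is exposed as an option).  Post hocs: two-group
F-tests on means, restricted by default to the combined feature set (where
the feature factor shows no effect), and two-sample t-tests on the Levene
deviations across all 15 cells for spread; both Holm-corrected within the
family of one target and one measure.  The winner of a significant pair is
the group with the smaller error measure (|mean| for means, mean deviation
for spread).  Rows from the same subject are treated as independent, as the
benchmark design assumes; this is replicated, not endorsed.

## Numerical and scale choices

* Degenerate inputs: flat signals, empty cells, constant targets and
  constant Levene deviations all take explicit guarded paths (errors or
  exact zero statistics) rather than relying on floating noise.
* The Holm step-down enforces monotonicity with a running maximum and caps
  at 1; it is cross-checked in tests against a literal brute-force oracle
  and against statsmodels.
* Problem sizes: the test suite and the acceptance script run the 45-cell
  grid with leave-one-out on small tables (24 rows) or with the 80:20 split
  on the 126-row cohort, plus leave-one-out for representative cells; the
  full-grid leave-one-out benchmark is available via
  `analysis/03_benchmark_models.py --loo`.  Roundtrip checks use 100
  single-record subjects; parameter recovery uses 500; ANOVA null
  calibration uses 1000 replicates of 8 observations per cell.
* Feature-set subsets: the temporal-only and morphology-only views each
  retain age and sex so every view is a self-contained predictor set; pulse
  rate is counted as temporal, not morphology.

## Known limitations

The generator's morphology features do not influence pressure, so
morphology-only models succeed only through the shared demographics and
noise structure — unlike real pulse-wave data, where contour carries
pressure information.  Wrist-cohort PTT over a 5 mm path is sub-millisecond
at physiological pulse-wave velocity; at 400 Hz it quantizes to a couple of
samples, and the generator's configurable channel delay makes this explicit
rather than resolving it.  The PEP is a latent additive offset
(PAT = PTT + PEP), never an extracted feature, mirroring its unavailability
in monitor data.
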