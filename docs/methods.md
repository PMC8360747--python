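# Methods

## Problem and pipeline

The package classifies blood pressure (BP) as normal or abnormal from a
photoplethysmogram (PPG) alone. A paired arterial blood pressure (ABP)
waveform provides ground truth during dataset construction: within each
fixed-length window, systolic pressure (SBP) is the mean of detected ABP
peak values and diastolic pressure (DBP) the mean of trough values, and the
2017 ACC/AHA thresholds turn (SBP, DBP) into one of four categories —
normal, elevated, stage-1 or stage-2 hypertension — binarized as normal
vs abnormal (elevated or worse). The PPG window is transformed into a
time–frequency scalogram image by a continuous wavelet transform (CWT) and
fed to a small convolutional network. A grid experiment compares six mother
wavelets and nine segment lengths (100–500 samples at 125 Hz, i.e.
0.8–4.0 s), plus a no-CWT baseline.

## Synthetic waveform generator

Clinical waveform databases cannot ship with the package, so a synthetic
generator defines the study conditions. It makes no hemodynamic claims; it
is a controlled fixture whose ground truth is exact.

**ABP.** A quasi-periodic beat train at sampling rate 125 Hz. Each beat is a
raised-cosine systolic upstroke over the first ~30% of the beat followed by
an exponential decay (rate 3 per beat) back to the trough; complete beats
attain the profile's `sbp_target` and `dbp_target` exactly before noise.
Beat periods follow the profile heart rate with ±2% per-beat jitter so
segments are not perfectly periodic.

**PPG.** Beat boundaries are recovered from the ABP troughs; each beat is a
sum of two Gaussian bumps — a systolic wave at 30% of the beat and a
dicrotic wave at 70%. The systolic width is affine in SBP
(0.08 + 8·10⁻⁴·(SBP−110), clipped to [0.05, 0.20] beat fractions) and the
dicrotic amplitude affine in DBP (0.25 + 5·10⁻³·(DBP−72), clipped to
[0.05, 0.60]). This coupling guarantees the two BP classes differ in pulse
morphology, so a classifier can in principle separate them; it is the
declared mechanism behind every end-to-end recovery result below. Optional
sinusoidal baseline wander (respiratory band, 0.1–0.5 Hz) and white
Gaussian noise are added on top, both expressed as fractions of the unit
pulse amplitude.

**Artifacts.** `inject_artifact` plants flatlines, dropouts (zeros) or
large spikes (10× signal range) to exercise quality control.

**Cohorts.** `generate_dataset` apportions records over the four categories
by largest remainder; the default mix (25.6 / 27.2 / 42.0 / 5.2%) mirrors a
published ICU cohort's proportions. Per-category (SBP, DBP) boxes are chosen
strictly inside the category boundaries so intended and recovered labels
agree in the noiseless limit. Per-record seeds are `base_seed + index`;
everything is bit-reproducible given the base seed.

**What passing tests do and do not show.** Noiseless synthetic recovery
demonstrates that the pipeline is wired correctly end to end and that the
CWT features carry the planted morphological signal. It says nothing about
accuracy on real PPG, where BP-morphology coupling is weaker, confounded
and subject-dependent.

## Preprocessing and labeling

- Smoothing: centered moving average, window 5 samples (40 ms at 125 Hz);
  edges use the shortened available window.
- Detrending: subtraction of a 2-s centered moving-average trend. The
  boxcar residual gain at frequency f is 1 − sin(πfW/fs)/(W·sin(πf/fs))
  (≈ 1 − sinc(fT)); at 0.25 Hz this removes ~87% of the power while the
  1.25 Hz pulse band loses ~13% amplitude. Tests assert this closed form
  rather than a rounder figure, because a 2-s boxcar cannot do better at
  0.25 Hz; stronger suppression would require a different detrender.
- Peak detection: `scipy.signal.find_peaks` with minimum inter-peak
  distance 0.33 s (≤180 bpm) and prominence ≥25% of the window range;
  exactly one trough (the minimum) between consecutive peaks.
- Quality control (replacing a manual screen): `no_signal` when a channel's
  standard deviation falls below 10⁻⁶ of its range or the range is zero;
  `missing_peaks` when no beats are found or an inter-peak gap exceeds 2 s;
  `artifact` when any sample deviates from the channel median by more than
  8 robust scales, where the robust scale is the MAD-consistent sigma
  1.4826·MAD — a raw MAD is too tight, since a clean pulsatile beat train
  legitimately reaches ~8 raw MADs at its systolic peaks. All thresholds
  live in `PreprocessConfig`.
- ACC/AHA thresholds, precedence stage-2 → stage-1 → elevated → normal:
  stage 2 if SBP ≥ 140 or DBP ≥ 90; stage 1 if SBP ≥ 130 or DBP ≥ 80;
  elevated if SBP ≥ 120; otherwise normal. Abnormal pools elevated with
  both hypertension stages; the pooled-group mean pressures this implies
  are consistent with published cohort statistics, which is the reason the
  binary boundary sits between normal and elevated.
- The moving-average filter is applied to PPG only; ABP is used raw for
  labeling, so labels are never affected by the smoothing choices.

## Wavelets and the CWT

Six mother wavelets, implemented from their closed forms (sinc is
sin(πx)/(πx) throughout):

| name | ψ(t) | parameters |
|---|---|---|
| fbsp | √F_b · sinc(F_b t / m)^m · e^{2πi F_c t} | m=1, F_b=15, F_c=1 |
| shan | √F_b · sinc(F_b t) · e^{2πi F_c t} | F_b=15, F_c=1 |
| cgau1 | C₁ d/dt(e^{−it} e^{−t²}) = C₁(−i−2t)e^{−it−t²} | C₁=(2π)^{−1/4} |
| morl | e^{−t²/2} cos 5t | — |
| mexh | (2/(√3 π^{1/4})) e^{−t²/2}(1−t²) | — |
| gaus1 | C₁ d/dt(e^{−t²}) = −2C₁ t e^{−t²} | C₁=(2/π)^{1/4} |

C₁ is fixed analytically so the continuous 2-norm equals 1 (verified
numerically to 10⁻³ by trapezoidal integration in the tests). The printed
shan parameterization (F_b=15, F_c=1) violates the sufficient admissibility
condition F_c > F_b/2; it is implemented as specified and a `UserWarning`
is raised when the spec is constructed.

The transform uses the L2 convention W(a,b) = a^{−1/2} Σ_t x[t] ψ*((t−b)/a)
with scales in samples and unit sample spacing. The fast path evaluates one
FFT convolution per scale (`scipy.signal.fftconvolve`), with the kernel
truncated where |ψ| < 10⁻⁸ of its peak; the slowly decaying sinc tails of
fbsp/shan are capped at ±8 carrier periods. The signal is implicitly
zero-padded and coefficients are returned for the original time span only.
A literal double-loop oracle (`cwt_oracle`) evaluates the same sum naively;
the two agree to ~10⁻¹⁵ relative error, and the test suite enforces 10⁻⁶
on random signals for all six wavelets.

Scale grids are 64 geometrically spaced scales covering pseudo-frequencies
20 Hz down to 0.5 Hz via f = F_c_eff · fs / a, spanning the respiratory
band through pulse harmonics. F_c_eff is the wavelet's nominal center
frequency: the explicit F_c parameter for fbsp/shan (their spectrum is flat
across the F_b band, so a spectral argmax would be arbitrary) and the
spectral peak of a densely sampled ψ otherwise.

## Scalogram rendering

Images are rendered directly from the coefficient matrix — per-image
min–max normalization, bilinear resize to 224×224 (PIL), viridis colormap
(dark blue → bright yellow), 8-bit RGB — never through a plotting canvas,
so rendering is bit-reproducible, margin-free and needs no training-set
statistics. Complex wavelets render |W| by default, real wavelets the
signed real part; both are selectable. Constant matrices map to the
colormap midpoint. Row 0 is the smallest scale (highest pseudo-frequency);
time runs left to right; orientation and normalization bounds are recorded
in a JSON sidecar next to each PNG. The no-CWT baseline tiles the
normalized 1-D segment across 224 rows as a grayscale image replicated over
three channels.

## Dataset construction

Windows are consecutive, non-overlapping, starting at sample 0; the
remainder is discarded (311,000 samples at length 100 give exactly 3110
segments). The randomized 90/10 split shuffles segment indices with a
seeded generator and takes the first ⌊0.9n⌋ as training (3110 → 2799/311).
The split randomizes at segment level by default; a record-level option
exists for leakage-aware experiments. A segment is dropped only when its
ABP window yields no usable peaks; drops and QC exclusions are logged and
counted in the run config. The CSV manifest carries image path, split,
record id, window, SBP/DBP, category, binary label, wavelet and seed.

## The classifier

The network is the fixed stack: conv 64@3×3 (stride 1, same padding, ReLU)
→ max-pool 2×2 stride 2 → conv 128@5×5 (same, ReLU) → max-pool → dense 256
(ReLU) → dense 128 (ReLU) → dense 1. At the canonical 224×224×3 input the
feature maps are 224×224×64 → 112×112×64 → 112×112×128 → 56×56×128 →
flatten 401,408 → 256 → 128 → 1 (conv1 has 1,792 trainable parameters).
It is implemented in numpy: im2col/col2im GEMMs in float32, manual
backprop (verified against central finite differences in float64), sigmoid
output trained with numerically stable binary cross-entropy on logits, Adam
(β₁=0.9, β₂=0.999, ε=10⁻⁸). Pixel inputs are scaled to [0,1]; accuracy uses
threshold 0.5; ROC/AUC come from a score sweep (sklearn `roc_curve`,
trapezoidal AUC, independently recomputed in tests). Training is
single-process and fully seeded: identical seeds reproduce identical
weights bit for bit.

**Problem sizes.** Training hyperparameters are deliberately conventional
and exposed in `TrainConfig`: Adam, batch 32, binary cross-entropy;
lr 10⁻⁴ for the full-resolution configuration. The package's own
experiments train at a reduced input resolution of 32×32 (the loader
bilinearly downsamples the stored 224×224 scalograms) with lr 10⁻³ — one
forward/backward pass at 224×224 costs ~100× more than at 32×32, and the
coarse time–frequency layout that distinguishes the synthetic classes
survives downsampling. The reference experiment is a balanced noiseless
cohort of 50 records × 12 segments = 600 segments of 2.4 s, cgau1
scalograms, 90/10 split, 30 epochs; it reaches validation accuracy ≥ 0.85
(typically 1.0 — the noiseless classes are fully separable). The grid
comparison runs the same configuration per (wavelet, length) cell with
shared seeds.

## Numerical and degenerate-input choices

- Peakless or flat segments raise `LabelingError` (labeled-failure),
  distinct from record-level QC failure.
- A single-beat segment uses its global minimum as the lone trough.
- Constant series: moving average returns the constant; detrending returns
  zeros; rendering maps to the colormap midpoint; peak detection returns
  empty lists.
- Non-finite CWT coefficients abort rendering with the offending location.
- Odd spatial dims under pooling pad with −∞ (same padding, ceil shapes).
- Single-class training sets and empty validation splits are rejected.

## Known limitations

- The synthetic PPG-BP coupling is affine and noise-free by default;
  separability results are upper bounds, not clinical estimates.
- The WFDB reader for PhysioNet records is a stub requiring the optional
  `wfdb` package; real-data preprocessing (calibration, gaps, pairing) is
  out of scope.
- The CNN is CPU-bound numpy; it is suited to the package's experiment
  sizes, not to full-resolution training on large cohorts.
- Transfer learning (e.g. GoogLeNet) and generalized Morse wavelets are out
  of scope; the model-builder interface accepts alternatives.
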