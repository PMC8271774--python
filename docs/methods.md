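# Methods

## The analysis model

The package quantifies whether a cued facial expression is authentic by
comparing facial *micromovements* between matched real and fake
recordings. A recording is a stream of 68 facial landmarks (pixels,
30 fps). Eleven action units (AUs) covering brow, eyelids, cheeks and
lips are each operationalised as the centroid of three landmarks
(0-based indices in the standard 68-point annotation scheme; the
indexing base is a documented convention, since landmark tables are
sometimes printed 1-based). The centroid of A(x1,y1), B(x2,y2),
C(x3,y3) is P((x1+x2+x3)/3, (y1+y2+y3)/3).

Only the trailing 30 s of a recording are analysed — the paradigm cues
the expression late so the earlier material serves as emotional
"sink-in" time. Within the window, each AU yields a scalar movement
signal: Euclidean displacement from a neutral baseline, taken as the
mean AU position over the first second of the window. The onset
threshold is the mid-range of that signal,

    threshold = (max + min) / 2,

and the onset *t* is its first strict crossing. Around *t* four
sections are cut: pre-onset `[window start, t)` and three overlapping
post-onset sections of 0.5 s, 1 s (micromovement) and 4 s
(macromovement), all starting at *t* — 15, 30 and 120 frames at 30 fps.

Per AU and section, three feature variables are computed from the
frame-to-frame delta of the centroid (prev − curr convention):

* `mean_delta` — mean delta magnitude (px/frame), degree of movement;
* `sd_delta` — population SD of the magnitude, variance of movement;
* `dominant_peak_hz` — frequency of the largest bin of the real FFT of
  the mean-removed magnitude series, the vibration level.

Real and fake conditions are compared per emotion with paired two-sided
t-tests (the design is 2 × 4 within-subject): per AU × section ×
feature (99 cells per emotion), collapsed over AUs and sections, and —
for HRV — per band variable. Significance is coded at three levels
(`***` p<0.001, `**` p<0.01, `*` p<0.05; boundaries fall in `ns`),
uncorrected by default to match star-grid reporting; Benjamini–Hochberg
is available. A linear model `mean_delta ~ C(section) +
C(authenticity) + C(side)` (all main effects fitted simultaneously,
type-II ANOVA p-values) summarises which design factors drive average
movement; a stepwise-selection variant was deliberately not implemented
because selection order is not recoverable from star-style reports.

HRV: RR intervals (s) are cleaned to (0.3, 2.0) s, resampled to a 4-Hz
tachogram in ms by cubic spline over beat times, mean-removed, and the
periodogram integrated over VLF 0.003–0.04, LF 0.04–0.15 and HF
0.15–0.4 Hz (half-open bands). Percentages divide by the three-band
sum — the only closed reading of "overall power" — so they always sum
to 100. A 180-s sliding window (default step 10 s, end-timestamped)
tracks the composition over a recording. An optional ECG front-end
(5–15 Hz band-pass, squared energy, adaptive-threshold peaks with a
0.3-s refractory period) produces RR from 500-Hz ECG; the analysed
object is always the RR series.

## Key parameter choices

| parameter | default | why |
|---|---|---|
| analysis window | 30 s | trailing cued-expression segment of a 210-s recording |
| baseline | mean over first 1 s of window | neutral posture before the ramp |
| onset smoothing | 5-frame moving average | suppresses single-frame jitter crossings; centred, so no systematic onset shift |
| onset scope | global (median of per-AU onsets) | one cued expression per recording; robust to barely-moving AUs |
| peak search band | 2 Hz – Nyquist | micromovement vibration periods 0.04–0.5 s ⇔ 2–25 Hz; DC excluded by mean removal; ties break to the lower frequency |
| spectral estimate | no taper | sections are short (8–120 frames) and the statistic is a peak *location* |
| min. frames for a spectrum | 8 | shorter sections yield absent values, not unstable ones |
| SD convention | population (ddof 0) | a fixed definition; switchable |
| tachogram | 4 Hz, cubic spline | standard short-term HRV resampling |
| t-tests | paired | within-subject design |

Features use the Euclidean delta magnitude rather than per-axis deltas
(one rotation-robust number per cell; per-axis available via config).
Coordinates stay in raw pixels — movement is reported in px/frame — with
an optional face-width normalisation for cross-subject pooling.

## The synthetic-data generator

No recordings ship with the package, so a generator provides inputs
with programmable ground truth. A schematic 68-point frontal face
(1280 × 980 frame; a package constant, not a measured face) receives
per-landmark Gaussian jitter (default SD 0.3 px). During the final
30 s, the three landmarks of each AU follow a logistic onset ramp
(default 10–90% rise of 2 s, midpoint mid-window) to the profile
amplitude, superposed with a sinusoidal vibration gated by the same
ramp; a multiplier scales left-side AUs for lateralised effects.

One definitional subtlety: the vibration feature is the spectrum of the
delta *magnitude*, and the magnitude of a symmetric positional
oscillation is full-wave rectified — a positional sinusoid at f makes
the speed magnitude oscillate at 2f. The generator therefore defines
`vibration_hz` as the frequency of the delta-magnitude oscillation (the
measured quantity) and realises it as a positional oscillation at f/2.
This keeps generator → analyzer closure exact across the whole 2–25 Hz
band (a naive positional-f generator would alias any programmed
frequency above 7.5 Hz).

RR series are built beat-by-beat from a 0.8-s base interval modulated
by one sinusoid per band at the band's geometric-centre frequency
(0.011 / 0.077 / 0.245 Hz), amplitudes `mod_sd·sqrt(2·share)` so the
modulation variance splits in the programmed ratio, plus 2-ms white
per-beat noise.

Cohorts default to 40 subjects × 4 emotions × 2 conditions
(320 streams) with a shared lognormal per-subject amplitude multiplier
(σ = 0.2; positive, realistically heterogeneous), all regenerated
lazily from per-recording seeds — a fixed cohort seed gives
bit-identical data. The default condition profiles are *illustrative*
effect structure, not empirical claims: more movement in real
expressions for every emotion; for the relaxation-based emotions
(contentment, sadness) a stronger, higher-frequency vibration in fake
expressions; HRV with an arousal-type composition in real
(VLF-dominated, shares 45/30/25) versus relaxation-type in fake
(25/30/45) plus a slightly larger total modulation in fake, so absolute
LF/HF rise in fake while the LF share stays equal. The generator does
not emulate landmark-detector noise characteristics, head pose, blinks
or ectopic beats — passing tests demonstrate internal consistency of
the pipeline, not performance on real faces.

## Validation strategy and problem sizes

Every elementary operation is checked against an independent
brute-force oracle (loop means/SDs, mid-range by max/min, an O(n²) DFT
for the spectral peak). Generator closure is tested by recovery:
injected 4/8/12-Hz vibrations within one frequency bin on the 4-s
section, programmed onsets within ±0.5 s over 50 streams, HRV shares
within ±5 points. Statistical calibration uses 200 null cohorts
(real ≡ fake, n = 40) at reduced recording length — 24-s streams with a
15-s analysis window at full 30 fps, which leaves every per-frame
computation and section length unchanged while keeping the run in
minutes — requiring a pooled per-cell rejection rate of 0.05 ± 0.02.
Direction recovery uses the default cohort at the same reduced length.

## Numerical and degenerate-input policy

Constant movement signals have no mid-range crossing and raise a
no-onset error; an onset at the window start yields an empty, flagged
pre-section; post-sections running past the stream end are truncated
and flagged, and flagged rows are excluded from statistics by default.
Zero-variance paired differences are reported not-computable rather
than p = 0; cells with n < 3 likewise. Identically-zero spectra (after
mean removal) yield an absent peak. Percentage HRV variables are NaN
when total band power is zero. Spectral-peak ties break toward the
lower frequency for determinism.

## Known limitations

Raw-pixel features are camera-geometry dependent; pooling across
subjects assumes comparable scale (or the normalisation flag). The
onset definition is scale-free but assumes a single expression event
per window. The dominant-peak feature reports one frequency even when
the spectrum is broadband (the generator's programmed case is narrow
band). The HRV band integration uses a plain periodogram; very-low-
frequency power is resolution-limited for windows much shorter than
~300 s. The factor regression treats subjects as exchangeable rows
(no random effects).
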