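# Methods

## The measurement model

Pulse transit time (PTT) is the interval a pressure pulse needs to travel
from the proximal aorta to a peripheral site.  Its proximal fiducial is the
aortic-opening (AO) complex of the seismocardiogram (SCG); the distal
fiducial is the foot (onset) of the fingertip photoplethysmogram (PPG).
Higher arterial pressure stiffens the wall and speeds the pulse, so PTT
falls as BP rises.  With r = PTT₀/PTT and a per-subject operating point
(PTT₀, PP₀, MBP₀, γ), the Bramwell–Hill / Moens–Korteweg relations give

    SBP = DBP + PP₀ · r²
    DBP = MBP₀ + 2γ·ln r − (PP₀/3) · r²

Useful identities: at r = 1 the model returns exactly the calibration BP
(DBP = MBP₀ − PP₀/3, SBP = MBP₀ + 2PP₀/3); pulse pressure PP₀·r² is always
positive, so SBP > DBP for every input; and SBP = MBP₀ + 2γ ln r + (2/3)PP₀r²
is strictly increasing in r (decreasing in PTT) for γ ≥ 0.

Mean blood pressure uses the one-third rule MBP = DBP + (SBP − DBP)/3 — the
standard clinical convention.

## Calibration protocol

Three back-to-back sessions, each pairing a device PTT with a simultaneous
cuff reference SBP/DBP:

1. Sessions 1–2: provisional PTT₀′, PP₀′, MBP₀′ = means over the two sessions.
2. Session 3: closed-form γ from the DBP equation at the provisional point,
   γ = (DBP₃ − MBP₀′ + (PP₀′/3)r²) / (2 ln r) with r = PTT₀′/PTT₃.
   The solve uses the stage-1 parameters because those are the only ones
   available at that point in the protocol sequence.
3. Final model: PTT₀, PP₀, MBP₀ = means over all three sessions, keeping the
   stage-2 γ.

Numerical guards: when |r − 1| < 10⁻³ the logarithm carries no information
about γ, so the age default (0.031 under 40 years, 0.09 at 40 and over —
40 itself assigned to the older band) is used and flagged
(`gamma_fallback`).  γ is clamped to [0, 10]: values outside indicate a
failed or inconsistent calibration, not physiology.  Real cuff readings
rounded to integers can legitimately produce clamped γ; the model still
reproduces its calibration point exactly (γ only matters away from r = 1).

## Signal chain

* **Filtering** — 4th-order Butterworth band-passes applied
  forward-backward (`sosfiltfilt`): 5–45 Hz for the SCG, 0.8–8 Hz for the
  PPG.  Zero phase means fiducials of symmetric features are not displaced;
  the passband gain is the squared one-pass magnitude (≈ 1 mid-band).
* **PPG onsets** — systolic peaks by prominence (peaks under half the
  median prominence are treated as diastolic/ripple artifacts); the foot of
  each beat is the maximum of the Savitzky–Golay second derivative on the
  rising edge before its peak.  Initial feet whose foot-to-peak interval
  deviates > 50 ms from the recording median are discarded as
  mis-detections.  The initial estimates are then refined by template
  alignment: beats are cross-correlated (normalised, ±50 ms) against their
  mean template to remove per-beat jitter, and the foot is re-detected once
  on the high-SNR template to remove the common bias.  Onset noise matters
  twice — directly in the PTT and indirectly because jittered anchors smear
  the SCG ensemble — so this refinement dominates the noise robustness of
  the whole chain.
* **Segmentation and ensemble** — 450-ms SCG windows tied to each onset,
  averaged pointwise.  For PTT extraction the window is anchored so that it
  *ends* at the PPG onset: the anchoring beat's own AO then lies at
  window − PTT from the window start for any heart rate (a forward window
  starting at the onset only contains an AO — the *next* beat's — when
  RR − PTT < 450 ms, i.e. above ≈ 90 bpm; the backward anchoring is the
  reading that works at resting heart rates, and it also makes the ensemble
  alignment independent of RR variability, since AO→onset is rigid within a
  beat).  Forward windows remain available (`anchor="post"`).
* **AO detection** — largest positive peak of the ensemble within the
  search region, refined to sub-sample position by parabolic interpolation.
  40-ms edge guards avoid partial bursts at the window boundaries, and the
  search floor window − RR + guard excludes the previous beat's AO.  A
  window whose maximum is below 3× its median absolute amplitude is
  rejected (no discernible AO).  This deterministic rule replaces the
  neural-network AO detector used by commercial devices: it is
  reproducible and inspectable, and on band-limited signals it is exact;
  no claim is made that it matches any proprietary detector beat-for-beat.
* **PTT** — window_ms + (sub-sample onset remainder) − AO offset, from the
  ensemble.  Per-beat PTTs from single-segment AO detection are attached
  for quality assessment (`low_beats` under 5 usable beats; `rejected` when
  onset or AO detection fails).  Recordings shorter than 10 s are refused.

## Synthetic data generator

The generator emulates the two-channel acquisition with exactly known
ground truth; every downstream stage is tested against it.

* **SCG beat**: a Gabor burst — Gaussian-windowed 20-Hz cosine, σ = 10 ms
  (~60 ms support) — whose maximum positive excursion defines AO.  It lies
  inside the 5–45 Hz band and is even about its centre, so zero-phase
  filtering cannot move the peak.
* **PPG beat**: an asymmetric pulse defined through its curvature: a narrow
  positive Gaussian lobe (width 15 ms) exactly at the foot, a broader
  negative lobe (width 50 ms) at the end of the upstroke 160 ms later, and
  a slow decay velocity lobe (centre 320 ms, width 80 ms) returning to
  baseline.  Foot-to-peak is ≈ 250 ms, within the physiologic range.  The
  construction keeps each curvature lobe symmetric and separated, so the
  0.8–8 Hz zero-phase filter attenuates but does not displace the curvature
  maximum: the detector's foot and the generator's fiducial coincide to
  well under one sample at 500 Hz for heart rates 50–90 bpm (the bias grows
  to a few ms above ~120 bpm as the lobes of adjacent beats begin to
  interact — a known limitation).
* **Timing**: first AO at 0.35 s, RR intervals with multiplicative Gaussian
  jitter (default 2% SD, floored at 0.3 s); the PPG foot of each beat is
  placed exactly `true_ptt_ms` after its AO.  The RR jitter stream is
  seeded separately (`timing_seed`) from the noise stream (`seed`), so two
  recordings differing only in `seed` share identical fiducials.
* **Noise**: additive white Gaussian per channel scaled to a requested SNR
  (`inf` = noiseless) against the clean signal power; optional 0.2-Hz
  baseline wander on the PPG to exercise the high-pass edge.
* **Defaults as study conditions**: 20 s at 500 Hz (a sampling rate
  comfortably above both analysis bands; device rates are not public),
  SCG SNR 10 dB and PPG SNR 20 dB — chest accelerometry is markedly noisier
  than a camera PPG of a stationary finger pressed on the lens.
* **Subjects**: a profile (age, baseline SBP/DBP, PTT₀, γ, drift model)
  defines the BP↔PTT law through the pulse-pressure arm of the model:
  PTT = PTT₀·√(PP₀/PP).  A subject dataset is 3 calibration + n measurement
  sessions; between-session BP can stay fixed, drift linearly, or follow a
  random walk.  Heart rate varies ±3% between sessions.

What the generator does **not** emulate: accelerometer axis geometry,
respiration coupling, motion artifacts, camera colorimetry, skin-tone
effects on PPG amplitude, or beat-morphology variability.  Passing tests
therefore demonstrate correctness of the algorithmic chain under the stated
noise model, not clinical accuracy on real recordings.

## Validation statistics

Differences are test − reference; SDs use n − 1.  Threshold bands count
|d| strictly below 5/10/15 mm Hg; Bland–Altman limits are mean ± 2·SD with
outliers strictly outside; percentages round half-up to one decimal.  These
conventions jointly reproduce all eight published count→percentage pairs of
the validation study this pipeline models (e.g. 150/261 → 57.5%,
15/261 → 5.7%).  The AAMI/ESH/ISO criterion-1 thresholds (|mean| ≤ 5 mm Hg,
SD ≤ 8 mm Hg) come from the standard itself; the per-subject criterion-2
grading is out of scope.  Pearson r/p uses the exact t transform; the
per-participant coefficient of variation is 100·SD/mean over each
participant's repeats (participants with fewer than two repeats are
excluded with a warning), averaged across participants.

## Problem sizes and determinism

The bundled study runs 87 synthetic subjects × (3 calibration + 3
measurement) sessions = 522 recordings of 20 s at 500 Hz (261 measurement
pairs, matching the modelled study design), with a 2-mm-Hg random-walk BP
drift between sessions so the γ solve is exercised.  PTT recovery is
measured on a 4 × 4 noiseless HR × PTT grid and on 100 trials at 10 dB on
both channels.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bitwise-identical
recordings and byte-identical reports.

## Known limitations

* The onset detector's sub-sample accuracy is demonstrated on the
  generator's band-limited morphology; real PPG feet are sharper and
  partially above 8 Hz, where the band-pass introduces a systematic
  (subject-independent) foot delay that calibration largely absorbs but
  noiseless-grid tests cannot see.
* The backward window anchoring is one consistent reading of onset-anchored
  segmentation; commercial devices may implement the ensemble differently.
* γ recovery from a single third session is ill-conditioned near r = 1 and
  sensitive to cuff rounding; the clamp and fallback flags make this
  visible rather than hiding it.
* Heart rates above ~120 bpm push adjacent PPG beats into each other and
  PTTs above ~410 ms leave the AO search region; both are outside the
  supported operating range.
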