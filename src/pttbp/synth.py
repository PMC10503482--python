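"""Synthetic two-channel SCG/PPG recordings with known ground truth.

Each cardiac cycle places (i) a high-frequency burst on the SCG channel whose
dominant positive peak marks aortic valve opening (AO), and (ii) a PPG pulse
whose foot — the point of maximum upward curvature at the start of the
upstroke — occurs exactly ``true_ptt_ms`` after that AO.  Both morphologies
are band-limited so the device filter bands (5–45 Hz SCG, 0.8–8 Hz PPG)
preserve the fiducials:

* SCG beat: Gabor burst, a Gaussian-windowed 20-Hz cosine with ~60 ms
  support.  It is even about its centre, so zero-phase filtering cannot move
  the peak.
* PPG beat: asymmetric pulse built from two Gaussian velocity lobes (fast
  rise ~100 ms, slow decay ~500 ms).  The rise lobe is placed so the
  maximum of the pulse's second derivative — the detector's definition of
  the foot — falls exactly at the fiducial time; the lobe is symmetric, so
  again zero-phase filtering leaves the fiducial fixed.

Noise is additive white Gaussian per channel at a requested SNR; RR
intervals carry multiplicative Gaussian jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.special import ndtr

from .preprocess import RawRecording

SCG_BURST_FREQ_HZ = 20.0
SCG_BURST_SIGMA_S = 0.010  # ~60 ms support at 3 sigma
# PPG pulse morphology: the second derivative of the pulse is a narrow
# positive Gaussian lobe at the foot (width PPG_FOOT_CURV_S) and a broader
# negative lobe at the end of the upstroke (centre PPG_RISE_END_S); a slow
# velocity lobe at PPG_DECAY_CENTER_S returns the pulse to baseline.  The
# lobes are kept separated and band-limited so the 0.8-8 Hz device filter
# leaves the curvature maximum - the foot fiducial - in place.
PPG_FOOT_CURV_S = 0.015
PPG_RISE_END_S = 0.16
PPG_RISE_NEG_W_S = 0.05
PPG_DECAY_CENTER_S = 0.32
PPG_DECAY_LOBE_S = 0.08


def _validate(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class BeatTrainSpec:
    """Parameters of one synthetic 20-s acquisition.

    ``true_ptt_ms`` is the ground-truth AO→PPG-foot delay every beat embeds;
    recovery of this value is what the downstream chain is tested against.
    SNRs are in dB (``inf`` = noiseless).  ``rr_jitter_pct`` is the SD of
    the multiplicative RR-interval jitter in percent.
    """

    duration_s: float = 20.0
    fs_hz: float = 500.0
    heart_rate_bpm: float = 60.0
    true_ptt_ms: float = 200.0
    scg_snr_db: float = 10.0
    ppg_snr_db: float = 20.0
    rr_jitter_pct: float = 2.0
    ppg_baseline_amp: float = 0.0  # 0.2-Hz baseline wander, units of pulse amplitude
    seed: int = 0
    # `seed` controls the noise realisation only; fiducial timing (the RR
    # jitter pattern) is driven by `timing_seed` so that two recordings
    # differing only in `seed` share beat times exactly.
    timing_seed: int = 7

    def __post_init__(self) -> None:
        _validate(self.duration_s > 0, "duration_s", "must be > 0")
        _validate(self.fs_hz >= 100, "fs_hz", "must be >= 100")
        _validate(30 <= self.heart_rate_bpm <= 200, "heart_rate_bpm", "must be in [30, 200]")
        _validate(
            0 < self.true_ptt_ms < 60000.0 / self.heart_rate_bpm,
            "true_ptt_ms",
            "must be positive and shorter than one beat",
        )
        _validate(self.rr_jitter_pct >= 0, "rr_jitter_pct", "must be >= 0")


class DriftKind(str, Enum):
    none = "none"
    linear = "linear"
    random_walk = "random_walk"


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth physiology of one synthetic participant.

    The BP↔PTT law is the pulse-pressure arm of the Bramwell-Hill model:
    PP scales as (PTT0/PTT)^2 around the operating point (ptt0_ms, sbp0-dbp0).
    """

    age_years: float = 35.0
    sbp0: float = 120.0
    dbp0: float = 80.0
    gamma_true: float = 0.031
    ptt0_ms: float = 230.0
    drift: DriftKind = DriftKind.none
    drift_magnitude: float = 0.0  # mm Hg per session (linear) or per-step SD (random walk)

    def __post_init__(self) -> None:
        _validate(self.sbp0 > self.dbp0 > 0, "sbp0/dbp0", "need sbp0 > dbp0 > 0")
        _validate(self.ptt0_ms > 0, "ptt0_ms", "must be > 0")
        _validate(self.gamma_true >= 0, "gamma_true", "must be >= 0")

    @property
    def pp0(self) -> float:
        return self.sbp0 - self.dbp0


def _scg_beat(t: np.ndarray, center: float) -> np.ndarray:
    tau = t - center
    return np.exp(-(tau**2) / (2 * SCG_BURST_SIGMA_S**2)) * np.cos(
        2 * math.pi * SCG_BURST_FREQ_HZ * tau
    )


def _psi(x: np.ndarray) -> np.ndarray:
    # antiderivative of the standard normal CDF: x*Phi(x) + phi(x)
    return x * ndtr(x) + np.exp(-x * x / 2.0) / math.sqrt(2 * math.pi)


def _ppg_beat(t: np.ndarray, foot: float) -> np.ndarray:
    # Displacement whose second derivative is
    #   G(tau/w_a) - (w_a/w_b) * G((tau - t_b)/w_b)
    # (G = unnormalised Gaussian), i.e. maximum upward curvature exactly at
    # tau = 0, plus a slow decay velocity lobe returning to baseline.
    tau = t - foot
    w_a, t_b, w_b = PPG_FOOT_CURV_S, PPG_RISE_END_S, PPG_RISE_NEG_W_S
    t_d, w_d = PPG_DECAY_CENTER_S, PPG_DECAY_LOBE_S
    s2pi = math.sqrt(2 * math.pi)
    p = s2pi * w_a * (w_a * _psi(tau / w_a) - w_b * _psi((tau - t_b) / w_b))
    p -= w_a * t_b * s2pi * ndtr((tau - t_d) / w_d)
    return p


def _add_noise(clean: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(snr_db):
        return clean
    p_signal = float(np.mean(clean**2))
    sigma = math.sqrt(p_signal / 10 ** (snr_db / 10.0))
    return clean + rng.normal(0.0, sigma, size=clean.shape)


def synth_beat_train(spec: BeatTrainSpec) -> RawRecording:
    """Generate one two-channel recording per ``spec``.

    Identical specs give bitwise-identical output.  The noise realisation
    depends on ``seed`` while the fiducial timing depends on
    ``timing_seed`` only.
    """
    rng = np.random.default_rng(spec.seed)
    jitter_rng = np.random.default_rng(spec.timing_seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    rr = 60.0 / spec.heart_rate_bpm
    jit = spec.rr_jitter_pct / 100.0

    ao_times: list[float] = []
    t_beat = 0.35  # first AO; leaves room for the pre-onset analysis window
    while t_beat < spec.duration_s:
        ao_times.append(t_beat)
        step = rr * (1.0 + jit * jitter_rng.standard_normal()) if jit > 0 else rr
        t_beat += max(step, 0.3)

    scg = np.zeros(n)
    ppg = np.zeros(n)
    ptt_s = spec.true_ptt_ms / 1000.0
    for ao in ao_times:
        scg += _scg_beat(t, ao)
        ppg += _ppg_beat(t, ao + ptt_s)
    if spec.ppg_baseline_amp > 0:
        ppg += spec.ppg_baseline_amp * np.sin(2 * math.pi * 0.2 * t)

    scg = _add_noise(scg, spec.scg_snr_db, rng)
    ppg = _add_noise(ppg, spec.ppg_snr_db, rng)
    return RawRecording(t=t, scg=scg, ppg=ppg, fs_hz=spec.fs_hz)


def ground_truth_fiducials(spec: BeatTrainSpec) -> tuple[np.ndarray, np.ndarray]:
    """AO times and PPG foot times (seconds) that ``synth_beat_train`` embeds."""
    jitter_rng = np.random.default_rng(spec.timing_seed)
    rr = 60.0 / spec.heart_rate_bpm
    jit = spec.rr_jitter_pct / 100.0
    ao_times = []
    t_beat = 0.35
    while t_beat < spec.duration_s:
        ao_times.append(t_beat)
        step = rr * (1.0 + jit * jitter_rng.standard_normal()) if jit > 0 else rr
        t_beat += max(step, 0.3)
    ao = np.asarray(ao_times)
    return ao, ao + spec.true_ptt_ms / 1000.0


def bp_to_ptt(profile: SubjectProfile, sbp: float, dbp: float) -> float:
    """PTT (ms) implied by a blood pressure under the subject's PP law.

    Inverts the pulse-pressure relation PP = PP0·(PTT0/PTT)^2:
    PTT = PTT0·sqrt(PP0/(sbp−dbp)).
    """
    if sbp <= dbp:
        raise ValueError(f"need sbp > dbp, got {sbp} <= {dbp}")
    return profile.ptt0_ms * math.sqrt(profile.pp0 / (sbp - dbp))


@dataclass(frozen=True)
class SyntheticSession:
    """One calibration or measurement session of a synthetic subject."""

    recording: RawRecording
    sbp_ref: float
    dbp_ref: float
    true_ptt_ms: float
    is_calibration: bool


def _bp_trajectory(
    profile: SubjectProfile, n_sessions: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    sbp, dbp = profile.sbp0, profile.dbp0
    out = []
    for i in range(n_sessions):
        out.append((sbp, dbp))
        if profile.drift is DriftKind.linear:
            sbp += profile.drift_magnitude
            dbp += 0.5 * profile.drift_magnitude
        elif profile.drift is DriftKind.random_walk:
            sbp += profile.drift_magnitude * rng.standard_normal()
            dbp += 0.6 * profile.drift_magnitude * rng.standard_normal()
            dbp = min(dbp, sbp - 10.0)  # keep a physiologic pulse pressure
    return out


def synth_subject_dataset(
    profile: SubjectProfile,
    n_cal: int = 3,
    n_meas: int = 3,
    seed: int = 0,
    heart_rate_bpm: float = 70.0,
    scg_snr_db: float = 10.0,
    ppg_snr_db: float = 20.0,
    rr_jitter_pct: float = 2.0,
    duration_s: float = 20.0,
    fs_hz: float = 500.0,
) -> list[SyntheticSession]:
    """Emit ``n_cal`` calibration then ``n_meas`` measurement sessions.

    The per-subject design mirrors a calibrate-then-measure protocol:
    three back-to-back calibrations followed by repeated measurements.
    Each session's recording embeds the PTT implied by that session's
    (possibly drifting) true BP through :func:`bp_to_ptt`.
    """
    if n_cal < 3:
        raise ValueError("protocol requires n_cal >= 3")
    if n_meas < 1:
        raise ValueError("n_meas must be >= 1")
    rng = np.random.default_rng((seed, 0x5E55))
    traj = _bp_trajectory(profile, n_cal + n_meas, rng)
    sessions: list[SyntheticSession] = []
    for i, (sbp, dbp) in enumerate(traj):
        ptt = bp_to_ptt(profile, sbp, dbp)
        hr = heart_rate_bpm * (1.0 + 0.03 * rng.standard_normal())
        hr = float(np.clip(hr, 40.0, 180.0))
        spec = BeatTrainSpec(
            duration_s=duration_s,
            fs_hz=fs_hz,
            heart_rate_bpm=hr,
            true_ptt_ms=ptt,
            scg_snr_db=scg_snr_db,
            ppg_snr_db=ppg_snr_db,
            rr_jitter_pct=rr_jitter_pct,
            seed=int(rng.integers(2**31)),
            timing_seed=int(rng.integers(2**31)),
        )
        sessions.append(
            SyntheticSession(
                recording=synth_beat_train(spec),
                sbp_ref=sbp,
                dbp_ref=dbp,
                true_ptt_ms=ptt,
                is_calibration=i < n_cal,
            )
        )
    return sessions
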