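"""Signal chain: band-pass filtering, PPG onset detection, SCG segmentation,
ensemble averaging, aortic-opening (AO) detection and pulse-transit-time (PTT)
computation.

The chain mirrors a smartphone PTT device: the chest-wall seismocardiogram
(SCG) is band-passed 5–45 Hz, the fingertip photoplethysmogram (PPG)
0.8–8 Hz; the SCG is segmented into 450-ms windows tied to the PPG pulse
onsets and ensemble-averaged; the AO fiducial is located on the ensemble;
PTT is the AO-to-PPG-onset interval.

Anchoring convention
--------------------
The AO of a given heartbeat precedes that beat's peripheral PPG onset by
PTT.  ``compute_ptt`` therefore anchors each 450-ms ensemble window so that
it *ends* at a PPG onset: the anchoring beat's own AO then falls inside the
window at offset ``window_ms − PTT`` regardless of heart rate, and the
alignment is insensitive to RR-interval variability (the AO→onset interval
is rigid within a beat).  ``segment_scg`` also supports forward windows
(``anchor="post"``, onset to onset+450 ms), the literal reading of
onset-anchored segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal as sps


class Quality(str, Enum):
    """Quality flag for a PTT extraction."""

    ok = "ok"
    low_beats = "low_beats"
    rejected = "rejected"


class InsufficientBeatsError(ValueError):
    """Raised when no complete analysis segment can be formed."""


@dataclass(frozen=True)
class RawRecording:
    """Two-channel SCG/PPG time series on a uniform grid.

    Attributes
    ----------
    t : np.ndarray
        Sample times in seconds, uniformly spaced.
    scg : np.ndarray
        Chest acceleration, arbitrary units.
    ppg : np.ndarray
        Optical blood-volume signal, arbitrary units.
    fs_hz : float
        Sampling rate; must match the grid spacing.
    """

    t: np.ndarray
    scg: np.ndarray
    ppg: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if len(self.scg) != n or len(self.ppg) != n:
            raise ValueError("scg/ppg must have the same length as t")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-9, atol=1e-12):
                raise ValueError("fs_hz does not match the time grid spacing")

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs_hz


@dataclass(frozen=True)
class EnsembleScg:
    """Ensemble-averaged SCG window anchored to PPG onsets."""

    waveform: np.ndarray
    fs_hz: float
    window_ms: float = 450.0
    n_beats: int = 1

    def __post_init__(self) -> None:
        expected = int(round(self.window_ms / 1000.0 * self.fs_hz))
        if len(self.waveform) != expected:
            raise ValueError(
                f"waveform length {len(self.waveform)} != round(window_ms/1000*fs) = {expected}"
            )
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass(frozen=True)
class PttEstimate:
    """Extracted pulse transit time with per-beat detail.

    ``ptt_ms`` comes from AO detection on the ensemble-averaged SCG (the
    high-SNR path); ``per_beat_ptt_ms`` holds single-segment detections used
    for quality assessment.
    """

    ptt_ms: float
    per_beat_ptt_ms: tuple[float, ...] = ()
    n_beats_used: int = 0
    quality: Quality = Quality.ok


def bandpass_iir(
    x: np.ndarray, fs_hz: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``), so the passband gain is the
    squared magnitude of the one-pass design and the phase is exactly zero.
    """
    if not (0.0 < low_hz < high_hz < fs_hz / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {fs_hz / 2}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling to a common analysis rate."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


ONSET_SG_WIN_S = 0.021   # Savitzky-Golay window for the curvature estimate
PEAK_PROM_FRAC = 0.5     # peaks below this fraction of the median prominence are ripple


def _second_derivative(x: np.ndarray, fs_hz: float) -> np.ndarray:
    # Savitzky-Golay second derivative: smooths broadband residual noise
    # while leaving the band-limited pulse curvature essentially unbiased.
    win = max(7, int(round(ONSET_SG_WIN_S * fs_hz)) | 1)
    return sps.savgol_filter(x, window_length=win, polyorder=3, deriv=2) * fs_hz**2


def _parabolic_refine(y: np.ndarray, k: int) -> float:
    """Sub-sample position of a local maximum by parabolic interpolation."""
    if 0 < k < len(y) - 1:
        a, b, c = y[k - 1], y[k], y[k + 1]
        denom = a - 2.0 * b + c
        if denom < 0:
            return k + 0.5 * (a - c) / denom
    return float(k)


def _refine_onsets(
    x: np.ndarray, fs_hz: float, onsets_s: np.ndarray
) -> np.ndarray:
    """Template-alignment refinement of initial onset estimates.

    Independently detected feet carry per-beat noise that smears any
    downstream ensemble.  Beats are re-aligned by cross-correlation against
    their mean template (removing relative jitter), and the foot is
    re-detected once on the template (removing the common bias), giving
    onsets whose per-beat error is dominated by the template's much smaller
    noise.
    """
    pre = int(round(0.15 * fs_hz))
    post = int(round(0.35 * fs_hz))
    max_lag = int(round(0.05 * fs_hz))
    ks = np.round(onsets_s * fs_hz).astype(int)
    keep = (ks - pre - max_lag >= 0) & (ks + post + max_lag <= len(x))
    ks = ks[keep]
    if len(ks) < 3:
        return onsets_s
    beats = np.stack([x[k - pre : k + post] for k in ks])
    template = beats.mean(axis=0)
    tz = template - template.mean()

    lags = np.arange(-max_lag, max_lag + 1)
    shifts = np.empty(len(ks))
    for i, k in enumerate(ks):
        scores = np.empty(len(lags))
        for m, l in enumerate(lags):
            w = x[k - pre + l : k + post + l]
            wz = w - w.mean()
            denom = float(np.linalg.norm(wz))
            scores[m] = np.dot(wz, tz) / denom if denom > 0 else -np.inf
        j = int(np.argmax(scores))
        shifts[i] = lags[0] + _parabolic_refine(scores, j)

    d2 = _second_derivative(template, fs_hz)
    half = int(round(0.10 * fs_hz))
    lo = max(1, pre - half)
    j = lo + int(np.argmax(d2[lo : pre + half]))
    j_foot = _parabolic_refine(d2, j)
    return (ks + shifts + (j_foot - pre)) / fs_hz


def detect_ppg_onsets(
    ppg_filtered: np.ndarray, fs_hz: float, refine: bool = True
) -> np.ndarray:
    """Locate pulse onsets (feet) on a band-passed PPG.

    Systolic peaks are found by prominence; each onset is the maximum of the
    second derivative on the rising edge preceding its peak (the point of
    sharpest upward inflection, the conventional foot of the pulse).  Ties
    break to the earliest sample.  With ``refine`` the initial estimates are
    re-aligned against the mean beat template (see :func:`_refine_onsets`).

    Returns onset times in seconds, strictly increasing.  Onsets implying
    inter-beat intervals outside 0.3–2.0 s are discarded.
    """
    x = np.asarray(ppg_filtered, dtype=float)
    if len(x) < 2 * fs_hz:
        raise ValueError("need at least 2 s of PPG")
    amp = np.ptp(x)
    if amp <= 0 or not np.isfinite(amp):
        return np.asarray([])
    peaks, props = sps.find_peaks(x, distance=int(0.25 * fs_hz), prominence=0.05 * amp)
    if len(peaks) == 0:
        return np.asarray([])
    # keep only peaks comparable to the median beat (rejects ripple peaks)
    prom = props["prominences"]
    peaks = peaks[prom >= PEAK_PROM_FRAC * np.median(prom)]

    d2 = _second_derivative(x, fs_hz)
    search = int(round(0.45 * fs_hz))  # upstroke may take up to ~350 ms before the peak
    onsets_pos: list[float] = []
    upstrokes: list[float] = []
    prev_peak = None
    for p in peaks:
        lo = max(0, p - search)
        if prev_peak is not None:
            lo = max(lo, prev_peak + 2)
        prev_peak = p
        if p - lo < 3:
            continue
        k = lo + int(np.argmax(d2[lo:p]))  # argmax returns the earliest maximum
        pos = _parabolic_refine(d2, k)
        onsets_pos.append(pos)
        upstrokes.append(p - pos)
    if not onsets_pos:
        return np.asarray([])
    pos = np.asarray(onsets_pos)
    ups = np.asarray(upstrokes)
    if len(pos) >= 5:
        # the foot-to-peak interval is stable within a recording; a deviant
        # one marks a mis-detected foot
        good = np.abs(ups - np.median(ups)) <= 0.05 * fs_hz
        pos = pos[good]
    t = np.unique(pos) / fs_hz
    if refine and len(t) >= 3:
        t = np.sort(_refine_onsets(x, fs_hz, t))
    # enforce physiologic inter-onset intervals
    keep = [0]
    for i in range(1, len(t)):
        gap = t[i] - t[keep[-1]]
        if gap < 0.3:
            continue
        keep.append(i)
    t = t[keep]
    if len(t) >= 2 and np.any(np.diff(t) > 2.0):
        warnings.warn("inter-onset gaps above 2 s; possible missed beats", stacklevel=2)
    return t


def segment_scg(
    scg_filtered: np.ndarray,
    onsets: Sequence[float],
    fs_hz: float,
    window_ms: float = 450.0,
    anchor: str = "post",
) -> list[np.ndarray]:
    """Cut equal-length SCG windows tied to PPG onsets.

    ``anchor="post"`` takes [onset, onset + window) — the forward reading of
    onset-anchored segmentation; ``anchor="pre"`` takes [onset − window,
    onset), which is what PTT extraction uses (see module docstring).
    Windows that do not fit inside the recording are dropped.
    """
    x = np.asarray(scg_filtered, dtype=float)
    nwin = int(round(window_ms / 1000.0 * fs_hz))
    if anchor not in ("post", "pre"):
        raise ValueError("anchor must be 'post' or 'pre'")
    segments: list[np.ndarray] = []
    for onset in onsets:
        i = int(round(onset * fs_hz))
        start = i if anchor == "post" else i - nwin
        stop = start + nwin
        if start < 0 or stop > len(x):
            continue
        segments.append(x[start:stop])
    if not segments:
        raise InsufficientBeatsError("insufficient beats: no complete segment fits")
    return segments


def ensemble_average(
    segments: Sequence[np.ndarray], fs_hz: float, window_ms: float = 450.0
) -> EnsembleScg:
    """Pointwise mean of equal-length segments (raises SNR ∝ sqrt(n))."""
    if len(segments) == 0:
        raise InsufficientBeatsError("insufficient beats: no segments to average")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"ragged segments: lengths {sorted(lengths)}")
    wave = np.mean(np.stack(segments), axis=0)
    return EnsembleScg(waveform=wave, fs_hz=fs_hz, window_ms=window_ms, n_beats=len(segments))


def detect_ao(
    ensemble: EnsembleScg,
    edge_guard_ms: float = 40.0,
    search_ms: tuple[float, float] | None = None,
    min_snr: float = 3.0,
) -> float | None:
    """Offset (ms from window start) of the aortic-opening fiducial.

    The AO is taken as the largest positive peak of the ensemble-averaged
    SCG within the search region.  ``edge_guard_ms`` excludes both window
    edges (the anchoring PPG onset sits at one edge; partial bursts there
    would bias the peak).  Returns ``None`` when no peak rises above
    ``min_snr`` times the median absolute amplitude (rejected quality).
    """
    w = ensemble.waveform
    fs = ensemble.fs_hz
    lo_ms = edge_guard_ms
    hi_ms = ensemble.window_ms - edge_guard_ms
    if search_ms is not None:
        lo_ms = max(lo_ms, search_ms[0])
        hi_ms = min(hi_ms, search_ms[1])
    lo = int(np.ceil(lo_ms / 1000.0 * fs))
    hi = int(np.floor(hi_ms / 1000.0 * fs))
    if hi <= lo:
        return None
    region = w[lo:hi]
    noise_floor = np.median(np.abs(w))
    if not np.isfinite(region).all() or region.max() <= min_snr * noise_floor:
        return None
    k = lo + int(np.argmax(region))
    return _parabolic_refine(w, k) / fs * 1000.0


def compute_ptt(
    recording: RawRecording,
    window_ms: float = 450.0,
    scg_band: tuple[float, float] = (5.0, 45.0),
    ppg_band: tuple[float, float] = (0.8, 8.0),
    filter_order: int = 4,
    edge_guard_ms: float = 40.0,
    ao_min_snr: float = 3.0,
    min_beats: int = 5,
) -> PttEstimate:
    """Run the full filter → onset → segment → ensemble → AO chain.

    With pre-onset windows the AO of each anchoring beat sits at
    ``window_ms − PTT`` from the window start, so ``PTT = window_ms − AO
    offset``.  The search region is narrowed to exclude the previous beat's
    AO (which enters the window when RR + PTT < window).  Per-beat PTTs come
    from single-segment AO detection and feed the quality flag only.
    """
    if recording.duration_s < 10.0:
        raise ValueError(f"recording must be >= 10 s, got {recording.duration_s:.1f} s")
    fs = recording.fs_hz
    scg_f = bandpass_iir(recording.scg, fs, *scg_band, order=filter_order)
    ppg_f = bandpass_iir(recording.ppg, fs, *ppg_band, order=filter_order)
    onsets = detect_ppg_onsets(ppg_f, fs)
    if len(onsets) < 2:
        return PttEstimate(ptt_ms=float("nan"), quality=Quality.rejected)
    rr_ms = float(np.median(np.diff(onsets))) * 1000.0
    try:
        segments = segment_scg(scg_f, onsets, fs, window_ms=window_ms, anchor="pre")
    except InsufficientBeatsError:
        return PttEstimate(ptt_ms=float("nan"), quality=Quality.rejected)
    # sub-sample remainder lost when windows snap to the sample grid; the
    # window nominally ends at the onset but actually at round(onset*fs)
    nwin = int(round(window_ms / 1000.0 * fs))
    fracs_ms = []
    for onset in onsets:
        i = int(round(onset * fs))
        if i - nwin >= 0 and i <= len(scg_f):
            fracs_ms.append((onset * fs - i) / fs * 1000.0)
    # only the anchoring beat's AO may lie in [window - RR + guard, window - guard]
    search = (max(0.0, window_ms - rr_ms + edge_guard_ms), window_ms)
    ens = ensemble_average(segments, fs, window_ms=window_ms)
    offset = detect_ao(ens, edge_guard_ms=edge_guard_ms, search_ms=search, min_snr=ao_min_snr)
    if offset is None:
        return PttEstimate(ptt_ms=float("nan"), quality=Quality.rejected)
    ptt_ms = window_ms + float(np.mean(fracs_ms)) - offset

    per_beat: list[float] = []
    for seg, frac in zip(segments, fracs_ms):
        single = EnsembleScg(waveform=seg, fs_hz=fs, window_ms=window_ms, n_beats=1)
        off_i = detect_ao(single, edge_guard_ms=edge_guard_ms, search_ms=search, min_snr=ao_min_snr)
        if off_i is not None:
            per_beat.append(window_ms + frac - off_i)
    quality = Quality.ok if len(segments) >= min_beats else Quality.low_beats
    return PttEstimate(
        ptt_ms=float(ptt_ms),
        per_beat_ptt_ms=tuple(per_beat),
        n_beats_used=len(segments),
        quality=quality,
    )
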