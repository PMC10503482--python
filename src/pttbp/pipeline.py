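"""End-to-end synthetic study: simulate → PTT → calibrate → estimate → validate.

Emulates a per-participant protocol of three back-to-back calibration
sessions (device PTT measured simultaneously with a cuff reference)
followed by repeated paired test/reference measurements.  The test BP of a
measurement session is the calibrated model evaluated at that session's
extracted PTT; the reference BP is the session's true BP.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .bpmodel import CalibrationRecord, calibrate, estimate_bp
from .config import PipelineConfig
from .preprocess import Quality, compute_ptt
from .synth import DriftKind, SubjectProfile, synth_subject_dataset
from .valstats import MeasurementPair, ValidationReport, validation_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyResult:
    """Outcome of a synthetic validation study."""

    report: ValidationReport
    pairs: tuple[MeasurementPair, ...]
    n_subjects: int
    n_rejected_subjects: int
    config_hash: str
    seed: int


def sample_profile(rng: np.random.Generator, drift: DriftKind, drift_magnitude: float) -> SubjectProfile:
    """Draw one subject from a plausible adult population.

    Ages 19-70 uniform; baseline SBP ~ N(125, 15) within [95, 175]; pulse
    pressure ~ N(45, 8) within [25, 70]; resting PTT0 ~ N(230, 25) ms.
    """
    age = float(rng.uniform(19.0, 70.0))
    sbp0 = float(np.clip(rng.normal(125.0, 15.0), 95.0, 175.0))
    pp = float(np.clip(rng.normal(45.0, 8.0), 25.0, 70.0))
    ptt0 = float(np.clip(rng.normal(230.0, 25.0), 160.0, 310.0))
    gamma = 0.031 if age < 40 else 0.09
    return SubjectProfile(
        age_years=age,
        sbp0=sbp0,
        dbp0=sbp0 - pp,
        gamma_true=gamma,
        ptt0_ms=ptt0,
        drift=drift,
        drift_magnitude=drift_magnitude,
    )


def run_subject(
    profile: SubjectProfile,
    participant_id: str,
    config: PipelineConfig,
    seed: int,
    n_meas: int = 3,
    scg_snr_db: float = 10.0,
    ppg_snr_db: float = 20.0,
    heart_rate_bpm: float = 70.0,
) -> list[MeasurementPair]:
    """One participant through the full chain; [] when any stage rejects."""
    sessions = synth_subject_dataset(
        profile,
        n_cal=3,
        n_meas=n_meas,
        seed=seed,
        heart_rate_bpm=heart_rate_bpm,
        scg_snr_db=scg_snr_db,
        ppg_snr_db=ppg_snr_db,
    )
    kwargs = dict(
        window_ms=config.window_ms,
        scg_band=config.scg_band_hz,
        ppg_band=config.ppg_band_hz,
        filter_order=config.filter_order,
        edge_guard_ms=config.ao_edge_guard_ms,
        ao_min_snr=config.ao_min_snr,
        min_beats=config.min_beats,
    )
    cal_records = []
    for s in sessions[:3]:
        est = compute_ptt(s.recording, **kwargs)
        if est.quality is Quality.rejected:
            logger.warning("%s: calibration session rejected", participant_id)
            return []
        cal_records.append(
            CalibrationRecord(ptt_ms=est.ptt_ms, sbp_ref=s.sbp_ref, dbp_ref=s.dbp_ref)
        )
    model = calibrate(cal_records, age_years=profile.age_years)
    logger.debug("%s: model %s", participant_id, model)

    pairs = []
    for s in sessions[3:]:
        est = compute_ptt(s.recording, **kwargs)
        if est.quality is Quality.rejected:
            logger.warning("%s: measurement session rejected", participant_id)
            continue
        bp = estimate_bp(model, est.ptt_ms)
        # heart rate from beats used over the recording span
        test_hr = est.n_beats_used / s.recording.duration_s * 60.0
        pairs.append(
            MeasurementPair(
                participant_id=participant_id,
                test_sbp=bp.sbp,
                test_dbp=bp.dbp,
                ref_sbp=s.sbp_ref,
                ref_dbp=s.dbp_ref,
                test_hr=test_hr,
                ref_hr=heart_rate_bpm,
            )
        )
    return pairs


def run_end_to_end(
    config: PipelineConfig,
    n_subjects: int = 20,
    n_meas: int = 3,
    drift: DriftKind = DriftKind.none,
    drift_magnitude: float = 0.0,
    scg_snr_db: float = 10.0,
    ppg_snr_db: float = 20.0,
) -> StudyResult:
    """Synthetic validation study over ``n_subjects`` participants.

    Deterministic under a fixed ``config.seed``: subject profiles, per-session
    seeds and noise all derive from it.
    """
    rng = np.random.default_rng(config.seed)
    all_pairs: list[MeasurementPair] = []
    n_rejected = 0
    for i in range(n_subjects):
        profile = sample_profile(rng, drift, drift_magnitude)
        hr = float(rng.uniform(55.0, 90.0))
        subject_seed = int(rng.integers(2**31))
        pairs = run_subject(
            profile,
            participant_id=f"S{i + 1:03d}",
            config=config,
            seed=subject_seed,
            n_meas=n_meas,
            scg_snr_db=scg_snr_db,
            ppg_snr_db=ppg_snr_db,
            heart_rate_bpm=hr,
        )
        if not pairs:
            n_rejected += 1
        all_pairs.extend(pairs)
    report = validation_report(
        all_pairs, thresholds=config.band_thresholds, ba_k=config.bland_altman_k
    )
    return StudyResult(
        report=report,
        pairs=tuple(all_pairs),
        n_subjects=n_subjects,
        n_rejected_subjects=n_rejected,
        config_hash=config.config_hash,
        seed=config.seed,
    )
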