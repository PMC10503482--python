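"""Bramwell-Hill / Moens-Korteweg blood-pressure model and its calibration.

With r = PTT0/PTT:

    SBP = DBP + PP0 * r**2
    DBP = MBP0 + 2*gamma*ln(r) - (PP0/3) * r**2

(PTT0, PP0, MBP0) define the per-subject operating point and gamma the
subject-specific vessel-wall constant.  Calibration is a three-session
protocol: sessions 1-2 set a provisional operating point, session 3 solves
for gamma against it, and the final operating point averages all three
sessions while keeping the session-3 gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

GAMMA_YOUNG = 0.031  # age < 40 years
GAMMA_OLD = 0.09     # age >= 40 years
AGE_CUTOFF_YEARS = 40.0
GAMMA_MAX = 10.0
R_SINGULAR_TOL = 1e-3  # |r - 1| below this gives no gamma information


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration session: device PTT plus simultaneous cuff reference."""

    ptt_ms: float
    sbp_ref: float
    dbp_ref: float

    def __post_init__(self) -> None:
        if not self.sbp_ref > self.dbp_ref > 0:
            raise ValueError(f"need sbp_ref > dbp_ref > 0, got {self.sbp_ref}/{self.dbp_ref}")
        if self.ptt_ms <= 0:
            raise ValueError("ptt_ms must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-subject parameters of the BP equations."""

    ptt0_ms: float
    pp0: float
    mbp0: float
    gamma: float
    age_years: float = 35.0
    gamma_fallback: bool = False  # True when gamma is the age default (singular solve)

    def __post_init__(self) -> None:
        for name in ("ptt0_ms", "pp0", "mbp0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0 (clamped upstream)")


@dataclass(frozen=True)
class BpEstimate:
    sbp: float
    dbp: float
    ptt_ms: float

    @property
    def pp(self) -> float:
        return self.sbp - self.dbp

    @property
    def mbp(self) -> float:
        return mbp_from_sbp_dbp(self.sbp, self.dbp)


def mbp_from_sbp_dbp(sbp: float, dbp: float) -> float:
    """Mean blood pressure by the one-third rule: DBP + (SBP-DBP)/3."""
    if sbp <= dbp:
        raise ValueError(f"need sbp > dbp, got {sbp} <= {dbp}")
    return dbp + (sbp - dbp) / 3.0


def default_gamma(age_years: float) -> float:
    """Age-band initial gamma: 0.031 below 40 years, 0.09 from 40 up."""
    if age_years <= 0:
        raise ValueError("age_years must be > 0")
    return GAMMA_YOUNG if age_years < AGE_CUTOFF_YEARS else GAMMA_OLD


def estimate_bp(model: CalibrationModel, ptt_ms: float) -> BpEstimate:
    """Evaluate the BP equations at a measured PTT."""
    if ptt_ms <= 0:
        raise ValueError("ptt_ms must be > 0")
    r = model.ptt0_ms / ptt_ms
    dbp = model.mbp0 + 2.0 * model.gamma * math.log(r) - (model.pp0 / 3.0) * r * r
    sbp = dbp + model.pp0 * r * r
    return BpEstimate(sbp=sbp, dbp=dbp, ptt_ms=ptt_ms)


def solve_gamma(
    cal3: CalibrationRecord,
    ptt0_ms: float,
    pp0: float,
    mbp0: float,
    age_years: float = 35.0,
    gamma_max: float = GAMMA_MAX,
    r_tol: float = R_SINGULAR_TOL,
) -> tuple[float, bool]:
    """Closed-form gamma from the third calibration session.

    Inverts the DBP equation at (ptt0_ms, pp0, mbp0):

        gamma = (DBP3 - MBP0 + (PP0/3)*r**2) / (2*ln r),   r = PTT0/PTT3

    Near r = 1 the log vanishes and the equation carries no information
    about gamma; the age default is returned with ``fallback=True``.  The
    solution is clamped to [0, gamma_max] — values outside indicate a
    failed calibration, not physiology.

    Returns ``(gamma, fallback)``.
    """
    r = ptt0_ms / cal3.ptt_ms
    if abs(r - 1.0) < r_tol:
        return default_gamma(age_years), True
    gamma = (cal3.dbp_ref - mbp0 + (pp0 / 3.0) * r * r) / (2.0 * math.log(r))
    return float(min(max(gamma, 0.0), gamma_max)), False


def calibrate(
    records: Sequence[CalibrationRecord], age_years: float
) -> CalibrationModel:
    """Three-stage calibration protocol.

    Stage 1: provisional PTT0/PP0/MBP0 from the means of sessions 1-2.
    Stage 2: gamma solved from session 3 against the stage-1 parameters
    (falling back to the age default when the solve is singular).
    Stage 3: final PTT0/PP0/MBP0 from the means of all three sessions,
    keeping the stage-2 gamma.
    """
    if len(records) != 3:
        raise ValueError(f"calibration protocol requires exactly 3 records, got {len(records)}")
    pps = [r.sbp_ref - r.dbp_ref for r in records]
    mbps = [mbp_from_sbp_dbp(r.sbp_ref, r.dbp_ref) for r in records]
    ptts = [r.ptt_ms for r in records]

    ptt0_12 = (ptts[0] + ptts[1]) / 2.0
    pp0_12 = (pps[0] + pps[1]) / 2.0
    mbp0_12 = (mbps[0] + mbps[1]) / 2.0
    gamma, fallback = solve_gamma(records[2], ptt0_12, pp0_12, mbp0_12, age_years=age_years)

    return CalibrationModel(
        ptt0_ms=sum(ptts) / 3.0,
        pp0=sum(pps) / 3.0,
        mbp0=sum(mbps) / 3.0,
        gamma=gamma,
        age_years=age_years,
        gamma_fallback=fallback,
    )
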