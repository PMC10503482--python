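"""Device-validation statistics for paired test/reference BP measurements.

Covers the surface used to grade a cuffless BP device against a cuff
reference: paired difference mean/SD, absolute-difference threshold bands,
Bland-Altman limits of agreement with outlier counts, Pearson correlation,
per-participant coefficient of variation, and the AAMI/ESH/ISO criterion-1
check (|mean difference| <= 5 mm Hg, SD <= 8 mm Hg).

Conventions: differences are test − reference; bands use strict inequality
(|d| < threshold); Bland-Altman limits are mean ± k·SD with k = 2 and
outliers strictly outside; percentages are rounded half-up to one decimal;
SDs use the n−1 denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

QUANTITIES = ("sbp", "dbp", "hr")
DEFAULT_THRESHOLDS = (5.0, 10.0, 15.0)
AAMI_MEAN_LIMIT = 5.0  # mm Hg
AAMI_SD_LIMIT = 8.0    # mm Hg


@dataclass(frozen=True)
class MeasurementPair:
    """One simultaneous test/reference measurement for a participant."""

    participant_id: str
    test_sbp: float
    test_dbp: float
    ref_sbp: float
    ref_dbp: float
    test_hr: float | None = None
    ref_hr: float | None = None

    def __post_init__(self) -> None:
        if not (self.test_sbp > self.test_dbp > 0):
            raise ValueError("test BP must satisfy sbp > dbp > 0")
        if not (self.ref_sbp > self.ref_dbp > 0):
            raise ValueError("reference BP must satisfy sbp > dbp > 0")


def pairs_to_frame(pairs: Sequence[MeasurementPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in pairs],
            "test_sbp": [p.test_sbp for p in pairs],
            "test_dbp": [p.test_dbp for p in pairs],
            "ref_sbp": [p.ref_sbp for p in pairs],
            "ref_dbp": [p.ref_dbp for p in pairs],
            "test_hr": [p.test_hr for p in pairs],
            "ref_hr": [p.ref_hr for p in pairs],
        }
    )


def _columns(pairs: Sequence[MeasurementPair], quantity: str) -> tuple[np.ndarray, np.ndarray]:
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    test = np.asarray([getattr(p, f"test_{quantity}") for p in pairs], dtype=float)
    ref = np.asarray([getattr(p, f"ref_{quantity}") for p in pairs], dtype=float)
    if np.isnan(test).any() or np.isnan(ref).any():
        raise ValueError(f"quantity {quantity!r} missing for some pairs")
    return test, ref


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, n: int, ndigits: int = 1) -> float:
    """count/n as a percentage, rounded half-up."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round_half_up(100.0 * count / n, ndigits)


def diff_stats(pairs: Sequence[MeasurementPair], quantity: str) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of test − reference."""
    test, ref = _columns(pairs, quantity)
    if len(test) < 2:
        raise ValueError("need at least 2 pairs")
    d = test - ref
    return float(np.mean(d)), float(np.std(d, ddof=1))


def band_percentages(
    pairs: Sequence[MeasurementPair],
    quantity: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Counts and percentages of |test − ref| strictly below each threshold."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    th = list(thresholds)
    if any(t <= 0 for t in th) or sorted(th) != th:
        raise ValueError("thresholds must be positive and ascending")
    test, ref = _columns(pairs, quantity)
    absd = np.abs(test - ref)
    counts = tuple(int(np.sum(absd < t)) for t in th)
    pcts = tuple(percentage(c, len(pairs)) for c in counts)
    return counts, pcts


@dataclass(frozen=True)
class BlandAltman:
    """Limits of agreement mean ± k·SD, with strictly-outside outlier count."""

    mean: float
    sd: float
    k: float
    lower: float
    upper: float
    n: int
    n_outside: int
    pct_outside: float
    averages: tuple[float, ...] = field(repr=False, default=())
    differences: tuple[float, ...] = field(repr=False, default=())


def bland_altman(
    pairs: Sequence[MeasurementPair], quantity: str, k: float = 2.0
) -> BlandAltman:
    test, ref = _columns(pairs, quantity)
    if len(test) < 2:
        raise ValueError("need at least 2 pairs")
    d = test - ref
    avg = (test + ref) / 2.0
    m = float(np.mean(d))
    s = float(np.std(d, ddof=1))
    lower, upper = m - k * s, m + k * s
    outside = int(np.sum((d < lower) | (d > upper)))
    return BlandAltman(
        mean=m,
        sd=s,
        k=k,
        lower=lower,
        upper=upper,
        n=len(d),
        n_outside=outside,
        pct_outside=percentage(outside, len(d)),
        averages=tuple(avg),
        differences=tuple(d),
    )


def pearson(pairs: Sequence[MeasurementPair], quantity: str) -> tuple[float, float]:
    """Pearson r between test and reference, with two-sided p."""
    test, ref = _columns(pairs, quantity)
    if len(test) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(test) == 0 or np.std(ref) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sst.pearsonr(test, ref)
    return float(r), float(p)


def paired_ttest(pairs: Sequence[MeasurementPair], quantity: str) -> tuple[float, float]:
    """Two-sided paired t-test of test vs reference; returns (t, p)."""
    test, ref = _columns(pairs, quantity)
    t, p = sst.ttest_rel(test, ref)
    return float(t), float(p)


def cv_per_participant(
    pairs: Sequence[MeasurementPair], quantity: str, source: str = "test"
) -> tuple[float, dict[str, float]]:
    """Within-participant coefficient of variation, averaged over participants.

    CV = 100·SD/mean over each participant's repeated measurements of one
    source ("test" or "ref").  Participants with fewer than two
    measurements are excluded with a warning.
    """
    if source not in ("test", "ref"):
        raise ValueError("source must be 'test' or 'ref'")
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    values: dict[str, list[float]] = {}
    for p in pairs:
        v = getattr(p, f"{source}_{quantity}")
        if v is None:
            raise ValueError(f"{source}_{quantity} missing for participant {p.participant_id}")
        values.setdefault(p.participant_id, []).append(float(v))
    cvs: dict[str, float] = {}
    excluded = []
    for pid, vals in values.items():
        if len(vals) < 2:
            excluded.append(pid)
            continue
        arr = np.asarray(vals)
        cvs[pid] = float(100.0 * np.std(arr, ddof=1) / np.mean(arr))
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} participant(s) with < 2 measurements", stacklevel=2
        )
    if not cvs:
        raise ValueError("no participant has >= 2 measurements")
    return float(np.mean(list(cvs.values()))), cvs


def aami_criterion1(mean_diff: float, sd_diff: float) -> bool:
    """Criterion 1 of the AAMI/ESH/ISO protocol: |mean| <= 5 and SD <= 8 mm Hg."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return abs(mean_diff) <= AAMI_MEAN_LIMIT and sd_diff <= AAMI_SD_LIMIT


@dataclass(frozen=True)
class QuantityStats:
    mean_diff: float
    sd_diff: float
    band_counts: tuple[int, ...]
    band_pcts: tuple[float, ...]
    bland_altman: BlandAltman
    pearson_r: float
    pearson_p: float
    aami_pass: bool
    cv_test_pct: float | None = None
    cv_ref_pct: float | None = None


@dataclass(frozen=True)
class ValidationReport:
    """Full validation surface over a table of measurement pairs."""

    n_pairs: int
    sbp: QuantityStats
    dbp: QuantityStats
    hr: QuantityStats | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    ba_k: float = 2.0

    @property
    def aami_pass(self) -> bool:
        return self.sbp.aami_pass and self.dbp.aami_pass


def _quantity_stats(
    pairs: Sequence[MeasurementPair],
    quantity: str,
    thresholds: Sequence[float],
    k: float,
    with_cv: bool,
) -> QuantityStats:
    mean_d, sd_d = diff_stats(pairs, quantity)
    counts, pcts = band_percentages(pairs, quantity, thresholds)
    ba = bland_altman(pairs, quantity, k=k)
    r, p = pearson(pairs, quantity)
    cv_test = cv_ref = None
    if with_cv:
        counts_per = {}
        for pr in pairs:
            counts_per[pr.participant_id] = counts_per.get(pr.participant_id, 0) + 1
        if any(c >= 2 for c in counts_per.values()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv_test = cv_per_participant(pairs, quantity, "test")[0]
                cv_ref = cv_per_participant(pairs, quantity, "ref")[0]
    return QuantityStats(
        mean_diff=mean_d,
        sd_diff=sd_d,
        band_counts=counts,
        band_pcts=pcts,
        bland_altman=ba,
        pearson_r=r,
        pearson_p=p,
        aami_pass=aami_criterion1(mean_d, sd_d),
        cv_test_pct=cv_test,
        cv_ref_pct=cv_ref,
    )


def validation_report(
    pairs: Sequence[MeasurementPair],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ba_k: float = 2.0,
) -> ValidationReport:
    """Compute every statistic of the validation surface in one pass."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a validation report")
    has_hr = all(p.test_hr is not None and p.ref_hr is not None for p in pairs)
    hr_stats = _quantity_stats(pairs, "hr", thresholds, ba_k, True) if has_hr else None
    return ValidationReport(
        n_pairs=len(pairs),
        sbp=_quantity_stats(pairs, "sbp", thresholds, ba_k, True),
        dbp=_quantity_stats(pairs, "dbp", thresholds, ba_k, True),
        hr=hr_stats,
        thresholds=tuple(thresholds),
        ba_k=ba_k,
    )


def plot_bland_altman(ba: BlandAltman, path: str, title: str = "Bland-Altman") -> None:
    """Scatter of difference vs average with mean and ±k·SD limits."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.averages, ba.differences, s=12, alpha=0.6)
    ax.axhline(ba.mean, color="k", lw=1)
    for y in (ba.lower, ba.upper):
        ax.axhline(y, color="r", ls="--", lw=1)
    ax.set_xlabel("Mean of test and reference (mm Hg)")
    ax.set_ylabel("Test − reference (mm Hg)")
    ax.set_title(f"{title} (n={ba.n}, {ba.n_outside} outside ±{ba.k:g} SD)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
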