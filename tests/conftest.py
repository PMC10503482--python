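import numpy as np
import pytest

from pttbp import BeatTrainSpec, MeasurementPair, synth_beat_train

INF = float("inf")


@pytest.fixture(scope="session")
def noiseless_spec() -> BeatTrainSpec:
    return BeatTrainSpec(
        heart_rate_bpm=60.0,
        true_ptt_ms=200.0,
        scg_snr_db=INF,
        ppg_snr_db=INF,
        rr_jitter_pct=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_spec):
    return synth_beat_train(noiseless_spec)


def pairs_from_diffs(
    sbp_diffs, dbp_diffs=None, ref_sbp=120.0, ref_dbp=80.0, participant="P1"
) -> list[MeasurementPair]:
    """Build a pairs table realizing given test-reference differences."""
    if dbp_diffs is None:
        dbp_diffs = np.zeros_like(np.asarray(sbp_diffs, dtype=float))
    return [
        MeasurementPair(
            participant_id=participant,
            test_sbp=ref_sbp + ds,
            test_dbp=ref_dbp + dd,
            ref_sbp=ref_sbp,
            ref_dbp=ref_dbp,
        )
        for ds, dd in zip(sbp_diffs, dbp_diffs)
    ]
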