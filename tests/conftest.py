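import numpy as np
import pytest

import holterhrv as h


def match_detections(det_t: np.ndarray, true_t: np.ndarray, tol_s: float = 0.05):
    """Greedy one-to-one matching; returns (sensitivity, ppv)."""
    if len(true_t) == 0 or len(det_t) == 0:
        return 0.0, 0.0
    used = set()
    tp = 0
    for t in det_t:
        j = int(np.argmin(np.abs(true_t - t)))
        if abs(true_t[j] - t) <= tol_s and j not in used:
            tp += 1
            used.add(j)
    return tp / len(true_t), tp / len(det_t)


@pytest.fixture(scope="session")
def clean_record():
    """5-min noiseless single-lead record, constant 800 ms RR."""
    cfg = h.EcgSimConfig(
        duration_s=300.0, mean_rr_ms=800.0, rr_jitter_ms=0.0, leads=["II"], seed=11
    )
    return h.generate_ecg(cfg)


@pytest.fixture(scope="session")
def ectopic_record():
    """10-min record with 2% ectopics and physiologic jitter."""
    cfg = h.EcgSimConfig(
        duration_s=600.0, mean_rr_ms=800.0, ectopic_rate=0.02, leads=["II"], seed=12
    )
    return h.generate_ecg(cfg)


@pytest.fixture(scope="session")
def modulated_record():
    """Record with known LF (0.10 Hz, 40 ms) and HF (0.25 Hz, 25 ms) content."""
    cfg = h.EcgSimConfig(
        duration_s=320.0,
        mean_rr_ms=800.0,
        lf_mod=(0.10, 40.0),
        hf_mod=(0.25, 25.0),
        leads=["II"],
        seed=13,
    )
    return h.generate_ecg(cfg)


@pytest.fixture(scope="session")
def classified_ectopic(ectopic_record):
    rec, _ = ectopic_record
    return h.classify_beats(h.detect_beats(rec, "II"))
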