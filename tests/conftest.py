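import numpy as np
import pytest

from burstlet import load_preset, generate_recording
from burstlet.pipeline import AnalysisOptions, analyze_recording


@pytest.fixture(scope="session")
def control_recording():
    """One mixed burstlet/burst recording (raw mode) reused across tests."""
    return generate_recording(load_preset("3_1_control"), 300.0, seed=7)


@pytest.fixture(scope="session")
def control_analysis(control_recording):
    return analyze_recording(control_recording, AnalysisOptions())


def match_events(ground_truth, detected, tol=0.3):
    """Pair ground-truth events with detected events by onset proximity."""
    d_on = np.array([e.onset for e in detected])
    pairs = []
    for gt in ground_truth:
        if len(d_on) == 0:
            pairs.append((gt, None))
            continue
        j = int(np.argmin(np.abs(d_on - gt.onset)))
        pairs.append((gt, detected[j] if abs(d_on[j] - gt.onset) <= tol else None))
    return pairs
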