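"""Photostimulation scoring: per-trial success and stimulation-to-burst latency.

A stimulus is scored successful when a burst-group event begins within the
half-open window (stim, stim + 0.5 s]; its latency is the burst onset minus
the stimulation start, in ms.  Each burst can satisfy only one stimulus, and
burstlets never count.  A session is "entraining" when its success rate
exceeds 80% — the criterion used to define a threshold stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SUCCESS_WINDOW_S = 0.5
ENTRAINMENT_RATE = 0.8


@dataclass
class StimTrial:
    stim_time: float
    burst_onset: float | None
    success: bool
    latency_ms: float | None


@dataclass
class StimSummary:
    success_rate: float
    mean_latency_ms: float        # nan when no successful trials
    n_trials: int
    is_entraining: bool


def score_stim_trials(stim_times, burst_onsets,
                      window: float = SUCCESS_WINDOW_S) -> list[StimTrial]:
    """Score each stimulus against the burst-group onsets.

    Both inputs must be time-ordered.  For each stimulus the earliest
    unconsumed burst onset in (stim, stim + window] marks a success; the
    burst is then consumed so one burst cannot satisfy two stimuli.
    """
    stims = np.asarray(stim_times, dtype=float)
    bursts = np.asarray(burst_onsets, dtype=float)
    if np.any(np.diff(stims) < 0) or np.any(np.diff(bursts) < 0):
        raise ValueError("stimulus and burst times must be time-ordered")

    trials: list[StimTrial] = []
    j = 0
    for s in stims:
        while j < len(bursts) and bursts[j] <= s:
            j += 1
        if j < len(bursts) and bursts[j] <= s + window:
            onset = float(bursts[j])
            trials.append(StimTrial(float(s), onset, True, (onset - s) * 1000.0))
            j += 1
        else:
            trials.append(StimTrial(float(s), None, False, None))
    return trials


def summarize_session(trials: list[StimTrial]) -> StimSummary:
    """Success rate, mean latency over successful trials, entrainment flag."""
    if not trials:
        raise ValueError("cannot summarize an empty session")
    successes = [t for t in trials if t.success]
    rate = len(successes) / len(trials)
    latency = (float(np.mean([t.latency_ms for t in successes]))
               if successes else math.nan)
    return StimSummary(rate, latency, len(trials), rate > ENTRAINMENT_RATE)


def expected_false_success_prob(endogenous_rate: float,
                                window: float = SUCCESS_WINDOW_S) -> float:
    """Chance a spontaneous burst lands in the success window.

    A spontaneous burst inside the window is indistinguishable from a
    triggered one and counts as a success; for a Poisson-like endogenous
    rhythm at ``endogenous_rate`` Hz the per-trial false-success probability
    is ``1 - exp(-rate * window)``.  Entrainment protocols stimulate
    slightly faster than the endogenous rhythm to keep this small.
    """
    if endogenous_rate < 0:
        raise ValueError("endogenous_rate must be >= 0")
    return 1.0 - math.exp(-endogenous_rate * window)
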