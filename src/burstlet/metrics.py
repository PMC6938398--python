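"""Rhythm metrics computed from classified event trains.

The two headline statistics are the mean instantaneous frequency — the mean
of 1/interval over consecutive onsets of ALL rhythmic events (burstlets and
the burst group together) — and the burstlet fraction, the ratio of
burstlets to all rhythmic events, with a doublet counting as one event.
Intervals are anchored onset-to-onset; a doublet's onset is its first
component's onset and intra-doublet intervals never enter the frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .events import EventTrain


class MetricsError(ValueError):
    """Undefined metric (too few events / empty train / bad baseline)."""


@dataclass
class MetricsSummary:
    mean_f: float                 # Hz; nan when < 2 events
    burstlet_fraction: float
    mean_burst_amp: float         # burst group (bursts + doublets); nan if none
    mean_burstlet_amp: float      # nan if no burstlets
    mean_xii_amp: float           # nan if no motor-channel events
    n_events: int
    n_burstlets: int
    n_bursts: int
    n_doublets: int


def mean_frequency(onsets) -> float:
    """Mean of instantaneous frequencies 1/interval over consecutive onsets.

    Raises :class:`MetricsError` with fewer than 2 onsets (undefined, which
    is distinct from a zero frequency) or non-increasing onsets.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 2:
        raise MetricsError("mean frequency needs at least 2 onsets")
    intervals = np.diff(onsets)
    if np.any(intervals <= 0):
        raise MetricsError("onsets must be strictly increasing")
    return float(np.mean(1.0 / intervals))


def burstlet_fraction(train: EventTrain) -> float:
    """Burstlets / (burstlets + bursts + doublets); doublet counts once."""
    if train.n_events == 0:
        raise MetricsError("burstlet fraction undefined for an empty train")
    return train.n_burstlets / train.n_events


def normalized_change(value: float, baseline: float) -> float:
    """Ratio of a metric to its within-experiment baseline value."""
    if baseline <= 0:
        raise MetricsError("baseline must be > 0")
    return value / baseline


def summarize(train: EventTrain, xii_events=None) -> MetricsSummary:
    """Populate the full metrics summary for one classified train.

    ``xii_events`` (detected or classified motor-channel events) only feeds
    the motor-amplitude mean; the burstlet fraction is purely a property of
    the already-classified train, so a recording whose motor channel is
    silent yields fraction 1.0 upstream.
    """
    if train.n_events == 0:
        raise MetricsError("cannot summarize an empty train")
    onsets = train.onsets
    mean_f = mean_frequency(onsets) if len(onsets) >= 2 else math.nan

    def amp_mean(evs):
        return float(np.mean([e.peak_amplitude for e in evs])) if evs else math.nan

    bursts = [e for e in train if e.in_burst_group]
    burstlets = [e for e in train if e.event_class == "burstlet"]
    xii = list(xii_events) if xii_events else []
    return MetricsSummary(
        mean_f=mean_f,
        burstlet_fraction=burstlet_fraction(train),
        mean_burst_amp=amp_mean(bursts),
        mean_burstlet_amp=amp_mean(burstlets),
        mean_xii_amp=amp_mean(xii),
        n_events=train.n_events,
        n_burstlets=train.n_burstlets,
        n_bursts=train.n_bursts,
        n_doublets=train.n_doublets)


@dataclass
class NormalizedMetrics:
    norm_f: float
    norm_burstlet_fraction: float


def normalize_summary(summary: MetricsSummary,
                      baseline: MetricsSummary) -> NormalizedMetrics:
    """Per-experiment normalization of frequency and burstlet fraction."""
    norm_f = normalized_change(summary.mean_f, baseline.mean_f)
    if baseline.burstlet_fraction > 0:
        norm_bf = normalized_change(summary.burstlet_fraction,
                                    baseline.burstlet_fraction)
    else:
        norm_bf = math.nan
    return NormalizedMetrics(norm_f, norm_bf)
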