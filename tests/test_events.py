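import numpy as np
import pytest

from burstlet.events import (ClassifiedEvent, DetectedEvent, DetectionConfig,
                             DetectionError, DoubletThreshold,
                             DoubletThresholdError, classify_events,
                             detect_events, fit_doublet_threshold,
                             fuse_doublets, group_for_analysis)
from burstlet.integration import IntegratedTrace, integrate_trace
from burstlet.synthetic import _event_kernel

FS = 2000.0


def _envelope_trace(onsets, amps, noise_sd=0.0, duration=None, seed=0,
                    dur=0.4):
    rng = np.random.default_rng(seed)
    duration = duration or (max(onsets) + 5.0)
    n = int(duration * FS)
    env = np.zeros(n)
    for onset, amp in zip(onsets, amps):
        i0 = int(onset * FS)
        span = min(n - i0, int(dur * 3 * FS))
        env[i0:i0 + span] += amp * _event_kernel(span, FS, dur / 8, 3 * dur / 8)
    if noise_sd:
        env = np.maximum(env + rng.normal(0, noise_sd, n), 0)
    return IntegratedTrace(env, FS, 50.0)


class TestDetection:
    def test_flat_noise_free_trace_yields_no_events(self):
        assert detect_events(IntegratedTrace(np.zeros(30000), FS, 50.0)) == []

    def test_single_envelope_onset_within_20ms(self):
        """One 10x-noise envelope: exactly one event, onset near truth."""
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noise_sd = 0.03
            raw_env = np.zeros(int(20 * FS))
            i0 = int(9.7 * FS)
            span = int(1.2 * FS)
            raw_env[i0:i0 + span] = 10 * noise_sd * _event_kernel(
                span, FS, 0.05, 0.15)
            sigma = noise_sd + raw_env / np.sqrt(2 / np.pi)
            raw = sigma * rng.standard_normal(len(raw_env))
            events = detect_events(integrate_trace(raw, FS))
            assert len(events) == 1
            errors.append(events[0].onset - 9.7)
        assert abs(np.median(errors)) < 0.02

    def test_two_envelopes_give_two_ordered_events(self):
        trace = _envelope_trace([5.0, 10.0], [0.5, 0.5], noise_sd=0.005)
        events = detect_events(trace)
        assert len(events) == 2
        assert events[0].onset < events[1].onset
        assert events[0].onset == pytest.approx(5.0, abs=0.05)

    def test_short_trace_raises_baseline_error(self):
        with pytest.raises(DetectionError):
            detect_events(IntegratedTrace(np.zeros(100), FS, 50.0))

    def test_merged_doublet_counts_two_peaks(self):
        trace = _envelope_trace([5.0, 5.35], [0.6, 0.6], noise_sd=0.005)
        events = detect_events(trace)
        assert len(events) == 1
        assert events[0].n_peaks >= 2

    def test_time_shift_shifts_onsets_only(self):
        a = detect_events(_envelope_trace([5.0, 11.0], [0.5, 0.4],
                                          noise_sd=0.005, duration=20))
        b = detect_events(_envelope_trace([7.0, 13.0], [0.5, 0.4],
                                          noise_sd=0.005, duration=22))
        assert len(a) == len(b) == 2
        for ea, eb in zip(a, b):
            assert eb.onset - ea.onset == pytest.approx(2.0, abs=0.02)


class TestDoubletThreshold:
    def test_mixture_recovers_sub2s_component(self):
        """Intervals from N(1.2, 0.2) + N(5, 1) give threshold near 1.6 s."""
        thresholds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            iv = np.concatenate([rng.normal(1.2, 0.2, 40),
                                 rng.normal(5.0, 1.0, 160)])
            iv = np.clip(iv, 0.05, None)
            rng.shuffle(iv)
            onsets = np.cumsum(iv)
            res = fit_doublet_threshold(onsets)
            assert res.peak_found
            thresholds.append(res.threshold)
        assert np.mean(thresholds) == pytest.approx(1.6, abs=0.1)

    def test_no_sub2s_mode_reports_not_found(self):
        rng = np.random.default_rng(0)
        onsets = np.cumsum(np.clip(rng.normal(5.0, 1.0, 150), 0.5, None))
        res = fit_doublet_threshold(onsets)
        assert not res.peak_found

    def test_too_few_events_signals_fallback(self):
        with pytest.raises(DoubletThresholdError):
            fit_doublet_threshold(np.arange(5.0))

    def test_threshold_capped_at_two_seconds(self):
        rng = np.random.default_rng(3)
        iv = np.concatenate([rng.normal(1.7, 0.4, 60),
                             rng.normal(6.0, 0.5, 60)])
        res = fit_doublet_threshold(np.cumsum(np.clip(iv, 0.05, None)))
        if res.peak_found:
            assert res.threshold <= 2.0


def _dev(channel, onset, offset, peak=0.5, n_peaks=1):
    return DetectedEvent(channel, onset, offset, (onset + offset) / 2,
                         peak, n_peaks)


class TestClassification:
    def test_overlapping_xii_event_makes_burst(self):
        out = classify_events([_dev("preBotC", 10.0, 10.5)],
                              [_dev("XII", 10.05, 10.4)])
        assert out[0].event_class == "burst"
        assert out[0].xii_partner is not None

    def test_no_overlap_makes_burstlet(self):
        out = classify_events([_dev("preBotC", 20.0, 20.3)],
                              [_dev("XII", 25.0, 25.3)])
        assert out[0].event_class == "burstlet"
        assert out[0].xii_partner is None

    def test_close_burst_pair_fuses_into_one_doublet(self):
        pre = [_dev("preBotC", 30.0, 30.4), _dev("preBotC", 31.2, 31.6)]
        xii = [_dev("XII", 30.0, 30.4), _dev("XII", 31.2, 31.6)]
        out = classify_events(pre, xii,
                              DoubletThreshold(1.6, 1.2, 0.2, True))
        assert len(out) == 1
        assert out[0].event_class == "doublet"
        assert out[0].onset == pytest.approx(30.0)
        assert out[0].offset == pytest.approx(31.6)

    def test_classes_partition_events(self):
        rng = np.random.default_rng(1)
        pre = [_dev("preBotC", t, t + 0.3) for t in np.cumsum(rng.uniform(2, 4, 30))]
        xii = [_dev("XII", e.onset + 0.01, e.offset + 0.01)
               for i, e in enumerate(pre) if i % 2 == 0]
        out = classify_events(pre, xii, DoubletThreshold(1.6, 1.2, 0.2, True))
        assert all(e.event_class in ("burstlet", "burst", "doublet") for e in out)
        train = group_for_analysis(out)
        assert train.n_burstlets + train.n_bursts + train.n_doublets == train.n_events

    def test_unordered_input_rejected(self):
        pre = [_dev("preBotC", 10.0, 10.5), _dev("preBotC", 5.0, 5.5)]
        with pytest.raises(ValueError, match="ordered"):
            classify_events(pre, [])

    def test_multi_peak_long_event_becomes_doublet(self):
        pre = [_dev("preBotC", t, t + 0.5) for t in (10.0, 15.0, 20.0)]
        pre.append(_dev("preBotC", 25.0, 25.9, n_peaks=2))
        xii = [_dev("XII", e.onset + 0.01, e.offset + 0.01) for e in pre]
        out = classify_events(pre, xii)
        assert out[-1].event_class == "doublet"
        assert all(e.event_class == "burst" for e in out[:-1])


class TestGrouping:
    def _train(self, nl, nb, nd):
        evs = ([ClassifiedEvent("preBotC", 10 * i, 10 * i + 1, 10 * i, 0.4, 1,
                                "burstlet") for i in range(nl)]
               + [ClassifiedEvent("preBotC", 100 + 10 * i, 101 + 10 * i,
                                  100 + 10 * i, 0.7, 1, "burst")
                  for i in range(nb)]
               + [ClassifiedEvent("preBotC", 300 + 10 * i, 301 + 10 * i,
                                  300 + 10 * i, 0.7, 2, "doublet")
                  for i in range(nd)])
        return group_for_analysis(evs)

    def test_doublets_join_burst_group_counting_once(self):
        train = self._train(3, 7, 2)
        assert train.n_events == 12
        assert train.n_burstlets == 3
        assert train.n_burst_group == 9

    def test_all_burstlets_unchanged(self):
        train = self._train(4, 0, 0)
        assert train.n_burst_group == 0
        assert train.n_events == 4

    def test_empty_train(self):
        assert self._train(0, 0, 0).n_events == 0


def test_fuse_doublets_is_noop_without_peak():
    evs = [ClassifiedEvent("XII", 1.0, 1.4, 1.2, 0.5, 1, "burst"),
           ClassifiedEvent("XII", 2.0, 2.4, 2.2, 0.5, 1, "burst")]
    out = fuse_doublets(evs, DoubletThreshold(0.0, np.nan, np.nan, False))
    assert len(out) == 2
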