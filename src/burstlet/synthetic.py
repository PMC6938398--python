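"""Ground-truth-labeled synthetic dual-channel recordings.

The generator is phenomenological: it emulates integrated (or raw) population
activity of an inspiratory rhythm recorded simultaneously from the rhythm
generator (preBotC channel) and the motor output (XII channel), so that the
downstream detection/classification/metrics pipeline can be validated against
known event labels.

Model
-----
Event times follow a gamma renewal process.  Because the rhythm statistic the
field reports (*f*) is the mean of instantaneous frequencies 1/T, and for a
gamma interval T with shape ``k`` one has ``E[1/T] = (k/(k-1)) / E[T]``, the
interval mean is calibrated to ``(k/(k-1)) / prebotc_rate`` so the generated
rhythm reproduces the preset rate in the reported statistic.

Each event is a burstlet or a burst.  Class labels are assigned by an
evenly-spread quota scheme (accumulator with random phase) whose long-run
burstlet fraction is exactly ``burstlet_prob``: bursts are regularly
interleaved among burstlets, as in the recordings emulated here, where the
motor output keeps a slow regular rhythm rather than the clustered output
that i.i.d. thinning would produce.  Bursts (never burstlets) are mirrored on
the XII channel with gain ``xii_gain`` and delay ``xii_delay``; a burst
becomes a doublet with probability ``doublet_prob`` by appending a second
component ``intra_doublet_interval`` later.

Events are rendered as difference-of-exponentials envelopes (fast rise,
slower decay; burstlets rise more slowly than bursts).  In ``raw`` mode the
trace is white noise amplitude-modulated by the envelope — a stand-in for
rectifiable multi-unit activity that exercises the integration stage.  In
``envelope`` mode the envelope plus additive Gaussian noise is emitted
directly (already-integrated-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .presets import ConditionPreset, PresetError, StimPreset

# E|N(0,1)| — converts a modulation SD to the mean of the rectified signal.
_RECTIFIED_GAIN = math.sqrt(2.0 / math.pi)

#: minimum rendered component amplitude (a.u.); amplitude draws are clipped
#: here so that every ground-truth event stays detectable above the noise.
MIN_AMPLITUDE = 0.1

#: refractory floor on renewal intervals (s).  Two rhythmic events closer
#: than the doublet threshold would be a doublet by definition, so the
#: renewal law excludes sub-floor intervals; doublets are generated
#: explicitly via ``doublet_prob`` instead.
REFRACTORY_S = 1.5


@dataclass(frozen=True)
class GroundTruthEvent:
    """One labeled rhythmic event (a doublet is ONE event)."""

    onset: float
    offset: float
    event_class: str          # "burstlet" | "burst" | "doublet"
    peak_amplitude: float
    appears_on_xii: bool


@dataclass
class DualChannelRecording:
    """Time-aligned preBotC and XII traces with optional ground truth."""

    sampling_rate: float
    duration: float
    prebotc_raw: np.ndarray
    xii_raw: np.ndarray
    ground_truth: list[GroundTruthEvent] | None = None
    mode: str = "raw"

    def __post_init__(self) -> None:
        n = int(round(self.duration * self.sampling_rate))
        if len(self.prebotc_raw) != n or len(self.xii_raw) != n:
            raise ValueError(
                "both channels must have length round(duration * sampling_rate)")
        if self.ground_truth is not None:
            onsets = [e.onset for e in self.ground_truth]
            if any(b < a for a, b in zip(onsets, onsets[1:])):
                raise ValueError("ground-truth events must be time-ordered")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.prebotc_raw)) / self.sampling_rate


@dataclass
class StimSession:
    """A photostimulation session rendered into a recording."""

    stim_times: np.ndarray
    preset: ConditionPreset
    success_prob: float
    latency_mean_ms: float
    latency_sd_ms: float
    recording: DualChannelRecording
    ground_truth_success: np.ndarray = field(default=None)  # bool per stimulus
    ground_truth_latency_ms: np.ndarray = field(default=None)  # nan on failure


@dataclass
class CellDotCounts:
    """Per-cell integer transcript dot counts with a group label per cell."""

    counts: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size and (np.any(self.counts < 0)
                                 or not np.issubdtype(self.counts.dtype, np.integer)):
            raise ValueError("dot counts must be non-negative integers")
        self.group = np.asarray(self.group)


def _truncated_inv_mean(theta: float, k: float, floor: float = REFRACTORY_S) -> float:
    """E[1/T] for T ~ gamma(k, theta) conditioned on T >= floor."""
    from scipy.special import gammaincc
    x = floor / theta
    # E[1/T | T>=a] = Q(k-1, a/theta) / (theta (k-1) Q(k, a/theta))
    return gammaincc(k - 1.0, x) / (theta * (k - 1.0) * gammaincc(k, x))


def _calibrated_scale(rate: float, k: float) -> float:
    """Gamma scale such that the truncated renewal has E[1/T] = rate."""
    from scipy.optimize import brentq
    if k <= 1.0:
        raise ValueError("rate_cv must be < 1 (gamma shape > 1)")
    theta0 = (k / (k - 1.0)) / rate / k  # untruncated solution
    return brentq(lambda th: _truncated_inv_mean(th, k) - rate,
                  theta0 * 0.2, theta0 * 5.0, xtol=1e-12)


def _quota_burst_mask(n: int, burstlet_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Evenly-spread class assignment: True where the event is a burst.

    An accumulator advances by (1 - burstlet_prob) per event and emits a
    burst on every unit crossing, so the long-run burstlet fraction is exact
    and bursts are maximally regularly interleaved.  The initial phase is
    random so distinct seeds give distinct sequences.
    """
    q = 1.0 - burstlet_prob
    acc = rng.random() + q * np.arange(1, n + 1)
    return np.diff(np.floor(np.concatenate([[acc[0] - q], acc]))) >= 1


def _event_kernel(n: int, fs: float, rise: float, decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials envelope sampled at fs."""
    t = np.arange(n) / fs
    e = np.exp(-t / decay) - np.exp(-t / rise)
    peak = e.max()
    return e / peak if peak > 0 else e


def _render(env: np.ndarray, fs: float, onset: float, amp: float,
            duration: float, is_burstlet: bool) -> None:
    """Add one event envelope in place.

    Bursts use rise/decay = duration/8 and 3*duration/8; burstlets rise and
    decay more slowly (duration/4, duration/2), mirroring their lower-
    frequency population firing.
    """
    if is_burstlet:
        rise, decay = duration / 4.0, duration / 2.0
    else:
        rise, decay = duration / 8.0, 3.0 * duration / 8.0
    i0 = int(round(onset * fs))
    if i0 >= len(env):
        return
    span = min(len(env) - i0, int(round((duration * 3.0) * fs)))
    env[i0:i0 + span] += amp * _event_kernel(span, fs, rise, decay)


def _emit(env: np.ndarray, noise_sd: float, mode: str,
          rng: np.random.Generator) -> np.ndarray:
    if mode == "raw":
        sigma = noise_sd + env / _RECTIFIED_GAIN
        return sigma * rng.standard_normal(len(env))
    # envelope mode: already-integrated-like trace, clipped non-negative
    return np.maximum(env + rng.normal(0.0, noise_sd, len(env)), 0.0)


def generate_recording(preset: ConditionPreset, duration: float, seed: int,
                       mode: str = "raw") -> DualChannelRecording:
    """Generate one dual-channel recording under a condition preset.

    Parameters
    ----------
    preset : ConditionPreset
    duration : float
        Recording length (s); must exceed ``10 / prebotc_rate`` so enough
        events occur for stable statistics.
    seed : int
        Seed for the recording's random stream; identical
        ``(preset, duration, seed, mode)`` gives bit-identical output.
    mode : {"raw", "envelope"}
        ``raw`` emits amplitude-modulated noise (integrate before detecting);
        ``envelope`` emits the integrated-like envelope plus noise.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if duration <= 10.0 / preset.prebotc_rate:
        raise ValueError(
            f"duration must exceed 10/prebotc_rate = {10.0 / preset.prebotc_rate:.1f} s")
    if mode not in ("raw", "envelope"):
        raise ValueError("mode must be 'raw' or 'envelope'")

    fs = preset.sampling_rate
    rng = np.random.default_rng(seed)

    # truncated-gamma renewal calibrated so E[1/interval] = prebotc_rate
    k = 1.0 / preset.rate_cv ** 2
    theta = _calibrated_scale(preset.prebotc_rate, k)
    mean_interval = k * theta
    n_draw = int(duration / mean_interval * 1.5) + 32

    def draw(n):
        iv = rng.gamma(k, theta, n)
        while True:
            short = iv < REFRACTORY_S
            if not short.any():
                return iv
            iv[short] = rng.gamma(k, theta, int(short.sum()))

    intervals = draw(n_draw)
    while intervals.sum() < duration:
        intervals = np.concatenate([intervals, draw(n_draw)])
    onsets = np.cumsum(intervals)
    onsets = onsets[onsets < duration - 3.0]
    n = len(onsets)

    is_burst = _quota_burst_mask(n, preset.burstlet_prob, rng)
    is_doublet = is_burst & (rng.random(n) < preset.doublet_prob)
    durations = np.clip(
        rng.normal(preset.event_duration_mean, preset.event_duration_sd, n),
        0.15, None)
    amp_b = rng.normal(preset.burst_amp_mean, preset.burst_amp_sd, n)
    amp_l = rng.normal(preset.burstlet_amp_mean, preset.burstlet_amp_sd, n)
    amps = np.clip(np.where(is_burst, amp_b, amp_l), MIN_AMPLITUDE, None)
    amps2 = np.clip(rng.normal(preset.burst_amp_mean, preset.burst_amp_sd, n),
                    MIN_AMPLITUDE, None)
    intra = np.clip(
        rng.normal(preset.intra_doublet_interval_mean,
                   preset.intra_doublet_interval_sd, n),
        0.15, 1.9)

    n_samples = int(round(duration * fs))
    env_pre = np.zeros(n_samples)
    env_xii = np.zeros(n_samples)
    truth: list[GroundTruthEvent] = []

    for i in range(n):
        onset, dur, amp = float(onsets[i]), float(durations[i]), float(amps[i])
        if not is_burst[i]:
            _render(env_pre, fs, onset, amp, dur, is_burstlet=True)
            truth.append(GroundTruthEvent(onset, onset + dur, "burstlet", amp, False))
            continue
        _render(env_pre, fs, onset, amp, dur, is_burstlet=False)
        _render(env_xii, fs, onset + preset.xii_delay, amp * preset.xii_gain,
                dur, is_burstlet=False)
        if is_doublet[i]:
            gap, amp2 = float(intra[i]), float(amps2[i])
            _render(env_pre, fs, onset + gap, amp2, dur, is_burstlet=False)
            _render(env_xii, fs, onset + gap + preset.xii_delay,
                    amp2 * preset.xii_gain, dur, is_burstlet=False)
            truth.append(GroundTruthEvent(onset, onset + gap + dur, "doublet",
                                          max(amp, amp2), True))
        else:
            truth.append(GroundTruthEvent(onset, onset + dur, "burst", amp, True))

    pre = _emit(env_pre, preset.noise_sd, mode, rng)
    xii = _emit(env_xii, preset.noise_sd, mode, rng)
    return DualChannelRecording(fs, duration, pre, xii, truth, mode)


def generate_stim_session(preset: ConditionPreset, n_stims: int,
                          success_prob: float, latency_mean_ms: float,
                          latency_sd_ms: float, seed: int,
                          isi_range: tuple[float, float] = (3.0, 6.0),
                          mode: str = "raw") -> StimSession:
    """Generate one photostimulation session.

    Each stimulus independently triggers a burst with probability
    ``success_prob``; triggered bursts occur at the stimulus time plus a
    latency drawn from a normal distribution truncated to (0, 500) ms.
    Non-triggered stimuli have no burst within the 0.5 s success window
    (no endogenous rhythm is rendered — the entrainment protocol emulated
    here stimulates slightly faster than the endogenous rhythm precisely to
    keep the windows clear of spontaneous bursts).
    """
    if not 8 <= n_stims <= 20:
        raise ValueError("n_stims must lie in [8, 20]")
    if not 0.0 <= success_prob <= 1.0:
        raise ValueError("success_prob must lie in [0, 1]")
    if latency_mean_ms >= 500.0:
        raise PresetError("latency_mean_ms must be < 500 ms "
                          "(would violate the 0.5 s success window)")
    if not (3.0 <= isi_range[0] <= isi_range[1] <= 6.0):
        raise ValueError("inter-stimulus intervals must lie within 3-6 s")

    fs = preset.sampling_rate
    rng = np.random.default_rng(seed)
    isi = rng.uniform(isi_range[0], isi_range[1], n_stims - 1)
    stim_times = 5.0 + np.concatenate([[0.0], np.cumsum(isi)])
    success = rng.random(n_stims) < success_prob

    latency_ms = np.full(n_stims, np.nan)
    for i in np.flatnonzero(success):
        while True:
            lat = rng.normal(latency_mean_ms, latency_sd_ms)
            if 0.0 < lat < 500.0:
                latency_ms[i] = lat
                break

    duration = float(stim_times[-1] + 5.0)
    n_samples = int(round(duration * fs))
    env_pre = np.zeros(n_samples)
    env_xii = np.zeros(n_samples)
    truth: list[GroundTruthEvent] = []
    for i in np.flatnonzero(success):
        onset = float(stim_times[i] + latency_ms[i] / 1000.0)
        dur = float(np.clip(rng.normal(preset.event_duration_mean,
                                       preset.event_duration_sd), 0.15, None))
        amp = float(np.clip(rng.normal(preset.burst_amp_mean,
                                       preset.burst_amp_sd), MIN_AMPLITUDE, None))
        _render(env_pre, fs, onset, amp, dur, is_burstlet=False)
        _render(env_xii, fs, onset + preset.xii_delay, amp * preset.xii_gain,
                dur, is_burstlet=False)
        truth.append(GroundTruthEvent(onset, onset + dur, "burst", amp, True))

    rec = DualChannelRecording(
        fs, duration,
        _emit(env_pre, preset.noise_sd, mode, rng),
        _emit(env_xii, preset.noise_sd, mode, rng),
        truth, mode)
    return StimSession(stim_times, preset, success_prob, latency_mean_ms,
                       latency_sd_ms, rec, success, latency_ms)


def generate_stim_session_from_preset(stim: StimPreset, n_stims: int, seed: int,
                                      preset_file=None, mode: str = "raw") -> StimSession:
    """Convenience wrapper resolving a :class:`StimPreset` by its condition."""
    from .presets import load_preset
    cond = load_preset(stim.condition, preset_file)
    return generate_stim_session(cond, n_stims, stim.success_prob,
                                 stim.latency_mean_ms, stim.latency_sd_ms,
                                 seed, mode=mode)


# dot-count ranges of the five transcript-abundance bins (dots/cell)
_BIN_RANGES = ((0, 0), (1, 3), (4, 9), (10, 15), (16, 40))


def generate_dot_counts(n_cells: int, bin_fractions, seed: int,
                        group: str = "preBotC") -> CellDotCounts:
    """Draw per-cell transcript dot counts from a 5-bin mixture.

    Each cell is assigned to one of the five transcript-abundance bins with
    the given probabilities and its dot count is drawn uniformly from that
    bin's range: 0; 1-3; 4-9; 10-15; 16-40.
    """
    fractions = np.asarray(bin_fractions, dtype=float)
    if fractions.shape != (5,):
        raise ValueError("bin_fractions must have exactly 5 entries")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("bin_fractions must sum to 1 (tolerance 1e-9)")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    bins = rng.choice(5, size=n_cells, p=fractions)
    lows = np.array([r[0] for r in _BIN_RANGES])
    highs = np.array([r[1] for r in _BIN_RANGES])
    counts = rng.integers(lows[bins], highs[bins] + 1)
    return CellDotCounts(counts, np.full(n_cells, group))
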