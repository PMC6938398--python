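"""Condition presets for the synthetic recording generator.

A :class:`ConditionPreset` bundles every generator parameter for one
experimental condition (bath solution / drug combination): the rhythm rate,
interval dispersion, burstlet probability, event amplitudes and durations,
cross-channel gain/delay, and noise level.  The packaged ``presets.json``
transcribes the group means reported for each condition of the study this
package emulates (e.g. ``9_1.5_control`` carries a 0.22 Hz rhythm with
burstlet fraction 0.14; ``3_1_control`` a 0.23 Hz rhythm with burstlet
fraction 0.58).

``prebotc_rate`` is defined as the *mean instantaneous frequency* the
condition should exhibit, i.e. the mean of 1/interval — the statistic the
field reports as *f* — not the reciprocal of the mean interval.  The
generator calibrates its gamma interval distribution accordingly (see
:mod:`burstlet.synthetic`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path


class PresetError(ValueError):
    """Unknown preset name or invariant-violating preset configuration."""


@dataclass(frozen=True)
class ConditionPreset:
    """Generator parameters for one experimental condition.

    Parameters
    ----------
    prebotc_rate : float
        Target mean instantaneous event frequency (Hz, events/s).
    rate_cv : float
        Coefficient of variation of inter-event intervals (0 < cv < 1).
    burstlet_prob : float
        Long-run fraction of rhythmic events that are burstlets.
    doublet_prob : float
        Probability that a burst is extended to a doublet.
    burst_amp_mean, burst_amp_sd : float
        Burst peak amplitude distribution (a.u.).
    burstlet_amp_mean, burstlet_amp_sd : float
        Burstlet peak amplitude distribution (a.u.); burstlets are the
        smaller deflections, so the mean must lie below the burst mean.
    event_duration_mean, event_duration_sd : float
        Nominal event duration distribution (s).
    intra_doublet_interval_mean, intra_doublet_interval_sd : float
        Onset-to-onset spacing of the two components of a doublet (s);
        must stay below the 2 s doublet-defining cap.
    xii_gain : float
        XII amplitude per unit of preBotC burst amplitude.
    xii_delay : float
        Conduction delay from preBotC to XII (s, >= 0).
    noise_sd : float
        Baseline noise amplitude (a.u.).
    sampling_rate : float
        Output sampling rate (Hz).
    """

    name: str
    prebotc_rate: float
    rate_cv: float
    burstlet_prob: float
    doublet_prob: float
    burst_amp_mean: float
    burst_amp_sd: float
    burstlet_amp_mean: float
    burstlet_amp_sd: float
    event_duration_mean: float
    event_duration_sd: float
    intra_doublet_interval_mean: float
    intra_doublet_interval_sd: float
    xii_gain: float
    xii_delay: float
    noise_sd: float
    sampling_rate: float

    def __post_init__(self) -> None:
        def bad(field: str, why: str) -> PresetError:
            return PresetError(f"preset {self.name!r}: field {field!r} {why}")

        if not 0.0 <= self.burstlet_prob <= 1.0:
            raise bad("burstlet_prob", "must lie in [0, 1]")
        if not 0.0 <= self.doublet_prob <= 1.0:
            raise bad("doublet_prob", "must lie in [0, 1]")
        if self.prebotc_rate <= 0:
            raise bad("prebotc_rate", "must be > 0")
        if not 0.0 < self.rate_cv < 1.0:
            raise bad("rate_cv", "must lie in (0, 1)")
        for f in ("burst_amp_sd", "burstlet_amp_sd", "event_duration_sd",
                  "intra_doublet_interval_sd", "noise_sd"):
            if getattr(self, f) < 0:
                raise bad(f, "must be >= 0")
        if self.sampling_rate <= 0:
            raise bad("sampling_rate", "must be > 0")
        if self.intra_doublet_interval_mean >= 2.0:
            raise bad("intra_doublet_interval_mean",
                      "must be < 2 s (doublets are defined by the sub-2-s peak)")
        if self.burstlet_amp_mean >= self.burst_amp_mean:
            raise bad("burstlet_amp_mean",
                      "must be < burst_amp_mean (burstlets are the smaller events)")
        if self.xii_delay < 0:
            raise bad("xii_delay", "must be >= 0")


@dataclass(frozen=True)
class StimPreset:
    """Parameters for one photostimulation condition.

    ``success_prob`` is the per-stimulus probability of triggering a burst;
    ``latency_mean_ms``/``latency_sd_ms`` parameterise the stimulation-to-
    burst latency of successful trials.  ``condition`` names the
    :class:`ConditionPreset` used to render the triggered bursts.
    """

    name: str
    success_prob: float
    latency_mean_ms: float
    latency_sd_ms: float
    condition: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_prob <= 1.0:
            raise PresetError(
                f"stim preset {self.name!r}: success_prob must lie in [0, 1]")
        if self.latency_mean_ms >= 500.0:
            raise PresetError(
                f"stim preset {self.name!r}: latency_mean_ms must be < 500 ms "
                "(would violate the 0.5 s success window)")
        if self.latency_sd_ms < 0:
            raise PresetError(
                f"stim preset {self.name!r}: latency_sd_ms must be >= 0")


_CONDITION_FIELDS = {f.name for f in fields(ConditionPreset)}


def _read_preset_file(preset_file: str | Path | None) -> dict:
    if preset_file is None:
        text = resources.files("burstlet").joinpath("presets.json").read_text()
    else:
        text = Path(preset_file).read_text()
    return json.loads(text)


def available_presets(preset_file: str | Path | None = None) -> list[str]:
    """Names of the condition presets in the packaged (or given) file."""
    return sorted(_read_preset_file(preset_file).get("conditions", {}))


def available_stim_presets(preset_file: str | Path | None = None) -> list[str]:
    """Names of the stimulation presets in the packaged (or given) file."""
    return sorted(_read_preset_file(preset_file).get("stim", {}))


def load_preset(name: str, preset_file: str | Path | None = None) -> ConditionPreset:
    """Load one condition preset by name.

    Raises
    ------
    PresetError
        If ``name`` is unknown (the message lists the valid names) or the
        stored values violate a preset invariant.
    """
    data = _read_preset_file(preset_file).get("conditions", {})
    if name not in data:
        raise PresetError(
            f"unknown condition preset {name!r}; available: {sorted(data)}")
    entry = {k: v for k, v in data[name].items() if k in _CONDITION_FIELDS}
    return ConditionPreset(name=name, **{k: v for k, v in entry.items() if k != "name"})


def load_stim_preset(name: str, preset_file: str | Path | None = None) -> StimPreset:
    """Load one photostimulation preset by name."""
    data = _read_preset_file(preset_file).get("stim", {})
    if name not in data:
        raise PresetError(
            f"unknown stim preset {name!r}; available: {sorted(data)}")
    entry = dict(data[name])
    entry.pop("reported", None)
    return StimPreset(name=name, **{k: v for k, v in entry.items() if k != "name"})


def reported_values(name: str, preset_file: str | Path | None = None) -> dict:
    """Published group statistics stored alongside a condition preset.

    Returns the ``reported`` block of the preset entry (means and SDs of
    frequency, burstlet fraction etc. as printed in the source study), or an
    empty dict when none is stored.  Used by the figure-reproduction tables
    to show the synthetic recovery next to the published value.
    """
    data = _read_preset_file(preset_file)
    for section in ("conditions", "stim"):
        if name in data.get(section, {}):
            return dict(data[section][name].get("reported", {}))
    raise PresetError(f"unknown preset {name!r}")
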