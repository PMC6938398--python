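"""Reading and writing recordings, event tables and summaries.

Recordings persist to HDF5 (datasets ``/prebotc`` and ``/xii``, attributes
``sampling_rate`` and ``duration``, ground truth as a ``/ground_truth``
table) with a CSV fallback (columns ``time_s, prebotc, xii``; no ground
truth).  Event and metrics tables are tab-separated.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import ClassifiedEvent, DetectedEvent, EventTrain
from .synthetic import DualChannelRecording, GroundTruthEvent

_GT_DTYPE = np.dtype([("onset", "f8"), ("offset", "f8"), ("event_class", "S16"),
                      ("peak_amplitude", "f8"), ("appears_on_xii", "?")])


def save_recording_hdf5(rec: DualChannelRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("prebotc", data=rec.prebotc_raw)
        f.create_dataset("xii", data=rec.xii_raw)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["duration"] = rec.duration
        f.attrs["mode"] = rec.mode
        if rec.ground_truth is not None:
            table = np.array(
                [(e.onset, e.offset, e.event_class.encode(),
                  e.peak_amplitude, e.appears_on_xii) for e in rec.ground_truth],
                dtype=_GT_DTYPE)
            f.create_dataset("ground_truth", data=table)


def load_recording_hdf5(path) -> DualChannelRecording:
    with h5py.File(path, "r") as f:
        truth = None
        if "ground_truth" in f:
            truth = [GroundTruthEvent(float(r["onset"]), float(r["offset"]),
                                      r["event_class"].decode(),
                                      float(r["peak_amplitude"]),
                                      bool(r["appears_on_xii"]))
                     for r in f["ground_truth"][()]]
        return DualChannelRecording(
            float(f.attrs["sampling_rate"]), float(f.attrs["duration"]),
            f["prebotc"][()], f["xii"][()], truth,
            str(f.attrs.get("mode", "raw")))


def save_recording_csv(rec: DualChannelRecording, path) -> None:
    pd.DataFrame({"time_s": rec.times, "prebotc": rec.prebotc_raw,
                  "xii": rec.xii_raw}).to_csv(path, index=False)


def load_recording_csv(path, mode: str = "raw") -> DualChannelRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    fs = float(round(fs))
    return DualChannelRecording(fs, len(df) / fs, df["prebotc"].to_numpy(),
                                df["xii"].to_numpy(), None, mode)


def load_recording(path) -> DualChannelRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return load_recording_hdf5(path)
    return load_recording_csv(path)


def events_to_frame(events) -> pd.DataFrame:
    """Events table: channel, onset_s, offset_s, peak_time_s, peak_amp, n_peaks, class."""
    if isinstance(events, EventTrain):
        events = events.events
    rows = []
    for e in events:
        rows.append({
            "channel": e.channel, "onset_s": e.onset, "offset_s": e.offset,
            "peak_time_s": e.peak_time, "peak_amp": e.peak_amplitude,
            "n_peaks": e.n_peaks,
            "class": getattr(e, "event_class", "")})
    return pd.DataFrame(rows, columns=["channel", "onset_s", "offset_s",
                                       "peak_time_s", "peak_amp", "n_peaks",
                                       "class"])


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dot_counts_tsv(path) -> pd.DataFrame:
    """Cell table with cell_id, region_label, dot_count columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"region_label", "dot_count"} - set(df.columns)
    if missing:
        raise ValueError(f"dot-count table missing columns: {sorted(missing)}")
    return df
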