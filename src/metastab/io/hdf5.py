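"""Lossless HDF5 container for continuous and epoched EEG.

Layout::

    /data                float64, (channel, sample) or (epoch, channel, sample)
    /events              int64 sample indices (continuous only)
    /channel_names       variable-length UTF-8 strings
    /channel_positions   float64 (channel, 3), optional
    attrs: kind ("continuous"|"epoched"), fs, subject_id, pulse_sample
"""

from __future__ import annotations

import numpy as np
import h5py

from ..containers import ContinuousEEG, EpochedEEG


def write_hdf5(record, path) -> None:
    """Write a :class:`ContinuousEEG` or :class:`EpochedEEG` container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=record.data)
        names = np.array(record.channel_names, dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("channel_names", data=names)
        if record.channel_positions is not None:
            f.create_dataset("channel_positions", data=record.channel_positions)
        f.attrs["fs"] = float(record.fs)
        f.attrs["subject_id"] = record.subject_id
        if isinstance(record, EpochedEEG):
            f.attrs["kind"] = "epoched"
            f.attrs["pulse_sample"] = int(record.pulse_sample)
        elif isinstance(record, ContinuousEEG):
            f.attrs["kind"] = "continuous"
            f.create_dataset("events", data=record.events)
        else:
            raise TypeError(f"cannot serialize {type(record).__name__}")


def read_hdf5(path):
    """Read a container written by :func:`write_hdf5`."""
    with h5py.File(path, "r") as f:
        if "kind" not in f.attrs:
            raise ValueError(f"{path}: missing 'kind' attribute; not a container file")
        kind = f.attrs["kind"]
        data = f["data"][()]
        names = [n.decode() if isinstance(n, bytes) else n for n in f["channel_names"][()]]
        pos = f["channel_positions"][()] if "channel_positions" in f else None
        fs = float(f.attrs["fs"])
        subject = str(f.attrs.get("subject_id", ""))
        if kind == "epoched":
            return EpochedEEG(
                data=data,
                fs=fs,
                channel_names=names,
                pulse_sample=int(f.attrs["pulse_sample"]),
                channel_positions=pos,
                subject_id=subject,
            )
        if kind == "continuous":
            events = f["events"][()] if "events" in f else np.empty(0, np.int64)
            return ContinuousEEG(
                data=data,
                fs=fs,
                channel_names=names,
                events=events,
                channel_positions=pos,
                subject_id=subject,
            )
        raise ValueError(f"{path}: unknown container kind {kind!r}")
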