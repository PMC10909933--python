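"""BrainVision triplet (.vhdr/.vmrk/.eeg) reader and writer.

Supports the common subset: binary IEEE_FLOAT_32 or INT_16 data, either
MULTIPLEXED or VECTORIZED orientation, with Mk-style markers.  Headers
are validated; a marker file whose ``DataFile`` reference disagrees with
the header triplet is rejected.
"""

from __future__ import annotations

import configparser
import re
from pathlib import Path

import numpy as np

from ..containers import ContinuousEEG

_HEADER_MAGIC = "Brain Vision Data Exchange Header File"
_MARKER_MAGIC = "Brain Vision Data Exchange Marker File"


def write_brainvision(record: ContinuousEEG, vhdr_path, marker_type: str = "TMS") -> None:
    """Write a BrainVision triplet (IEEE_FLOAT_32, multiplexed, 1 µV units)."""
    vhdr = Path(vhdr_path)
    eeg = vhdr.with_suffix(".eeg")
    vmrk = vhdr.with_suffix(".vmrk")
    n_ch = record.n_channels
    interval_us = 1e6 / record.fs
    lines = [
        f"{_HEADER_MAGIC} Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:.10g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(record.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        f"{_MARKER_MAGIC} Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for k, onset in enumerate(record.events, start=2):
        # BrainVision marker positions are 1-based sample indices
        mlines.append(f"Mk{k}=Stimulus,{marker_type},{int(onset) + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    record.data.T.astype("<f4").tofile(eeg)


def _parse_ini(path: Path, magic: str) -> configparser.ConfigParser:
    text = path.read_text(encoding="utf-8", errors="replace")
    first, _, rest = text.partition("\n")
    if magic not in first:
        raise ValueError(f"{path}: missing signature {magic!r}")
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    cp.optionxform = str
    cp.read_string(rest)
    return cp


def read_brainvision(vhdr_path) -> ContinuousEEG:
    """Read a BrainVision triplet given its .vhdr path."""
    vhdr = Path(vhdr_path)
    cp = _parse_ini(vhdr, _HEADER_MAGIC)
    try:
        common = cp["Common Infos"]
        data_file = common["DataFile"]
        n_ch = int(common["NumberOfChannels"])
        interval_us = float(common["SamplingInterval"])
        data_format = common.get("DataFormat", "BINARY")
        orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    except KeyError as exc:
        raise ValueError(f"{vhdr}: header missing field {exc.args[0]!r}") from None
    if data_format.upper() != "BINARY":
        raise ValueError(f"{vhdr}: unsupported DataFormat={data_format!r}")
    binary_format = cp.get("Binary Infos", "BinaryFormat", fallback="IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(binary_format.upper())
    if dtype is None:
        raise ValueError(f"{vhdr}: unsupported BinaryFormat={binary_format!r}")

    names, resolutions = [], []
    ch_section = cp["Channel Infos"] if cp.has_section("Channel Infos") else {}
    for i in range(1, n_ch + 1):
        entry = ch_section.get(f"Ch{i}")
        if entry is None:
            names.append(f"Ch{i}")
            resolutions.append(1.0)
            continue
        parts = entry.split(",")
        names.append(parts[0] or f"Ch{i}")
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    eeg_path = vhdr.parent / data_file
    if not eeg_path.exists():
        raise ValueError(f"{vhdr}: DataFile {data_file!r} not found")
    raw = np.fromfile(eeg_path, dtype=dtype).astype(np.float64)
    if raw.size % n_ch:
        raise ValueError(f"{eeg_path}: size not divisible by {n_ch} channels")
    n_samp = raw.size // n_ch
    if orientation == "MULTIPLEXED":
        data = raw.reshape(n_samp, n_ch).T
    elif orientation == "VECTORIZED":
        data = raw.reshape(n_ch, n_samp)
    else:
        raise ValueError(f"{vhdr}: unsupported DataOrientation={orientation!r}")
    data = data * np.asarray(resolutions)[:, None]

    events = _read_markers(vhdr, common.get("MarkerFile"), data_file)
    return ContinuousEEG(
        data=data,
        fs=1e6 / interval_us,
        channel_names=names,
        events=events,
        subject_id=vhdr.stem,
    )


def _read_markers(vhdr: Path, marker_file: str | None, data_file: str) -> np.ndarray:
    if not marker_file:
        return np.empty(0, np.int64)
    vmrk = vhdr.parent / marker_file
    if not vmrk.exists():
        raise ValueError(f"{vhdr}: MarkerFile {marker_file!r} not found")
    cp = _parse_ini(vmrk, _MARKER_MAGIC)
    ref = cp.get("Common Infos", "DataFile", fallback=data_file)
    if ref != data_file:
        raise ValueError(
            f"{vmrk}: DataFile reference {ref!r} does not match header's {data_file!r}"
        )
    onsets = []
    if cp.has_section("Marker Infos"):
        for key, val in cp["Marker Infos"].items():
            if not re.fullmatch(r"Mk\d+", key):
                continue
            parts = val.split(",")
            if len(parts) < 3 or parts[0] == "New Segment":
                continue
            onsets.append(int(parts[2]) - 1)  # back to 0-based
    return np.array(sorted(onsets), dtype=np.int64)
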