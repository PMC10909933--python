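"""Minimal EDF (16-bit) reader/writer.

Implements the core EDF header + data-record layout: fixed-width ASCII
header of 256 bytes plus 256 bytes per signal, followed by little-endian
int16 data records.  Event annotations (EDF+) are not supported; EDF files
round-trip signal data only, up to 16-bit quantization of the per-channel
physical range.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from ..containers import ContinuousEEG

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(record: ContinuousEEG, path) -> None:
    """Write a continuous record as plain EDF (one data record).

    Each channel is scaled to its own physical min/max over the full
    16-bit digital range, the best precision EDF affords.
    """
    data = record.data
    n_ch, n_samp = data.shape
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    duration = n_samp / record.fs
    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),  # version
            _field(record.subject_id or "X", 80),
            _field("recording", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field("1", 8),  # n data records
            _field(f"{duration:.6f}"[:8].rstrip("."), 8),
            _field(str(n_ch), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_field(nm, 16) for nm in record.channel_names),
            b"".join(_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_max),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(n_samp), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        digital.tofile(fh)


def _ascii(buf: bytes) -> str:
    return buf.decode("ascii", errors="strict").strip()


def read_edf(path) -> ContinuousEEG:
    """Read a plain EDF file (all channels must share one sampling rate)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_records = int(_ascii(head[236:244]))
            duration = float(_ascii(head[244:252]))
            n_ch = int(_ascii(head[252:256]))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header numeric field: {exc}")
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                _ascii(sig[base + i * width : base + (i + 1) * width])
                for i in range(n_ch)
            ]

        # per-signal field block offsets, in units already multiplied by n_ch
        labels = [
            _ascii(sig[i * 16 : (i + 1) * 16]) for i in range(n_ch)
        ]
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch  # skip transducer + unit
        phys_min = np.array(
            [float(_ascii(sig[off + i * 8 : off + (i + 1) * 8])) for i in range(n_ch)]
        )
        off += 8 * n_ch
        phys_max = np.array(
            [float(_ascii(sig[off + i * 8 : off + (i + 1) * 8])) for i in range(n_ch)]
        )
        off += 8 * n_ch
        dig_min = np.array(
            [float(_ascii(sig[off + i * 8 : off + (i + 1) * 8])) for i in range(n_ch)]
        )
        off += 8 * n_ch
        dig_max = np.array(
            [float(_ascii(sig[off + i * 8 : off + (i + 1) * 8])) for i in range(n_ch)]
        )
        off += 8 * n_ch + 80 * n_ch
        n_samp = [
            int(_ascii(sig[off + i * 8 : off + (i + 1) * 8])) for i in range(n_ch)
        ]
        if len(set(n_samp)) != 1:
            raise ValueError(f"{path}: heterogeneous per-signal sampling not supported")
        spr = n_samp[0]
        if duration <= 0:
            raise ValueError(f"{path}: non-positive record duration")
        fs = spr / duration

        raw = np.fromfile(fh, dtype="<i2")
    expected = n_records * n_ch * spr
    if raw.size < expected:
        raise ValueError(f"{path}: expected {expected} samples, found {raw.size}")
    raw = raw[:expected].reshape(n_records, n_ch, spr)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(
        np.float64
    )
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return ContinuousEEG(data=data, fs=fs, channel_names=labels)
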