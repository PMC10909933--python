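"""Tabular serialization of time-series traces (CSV + JSON sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_trace(trace, path, band: str | None = None, group: str | None = None,
                config: dict | None = None, seed: int | None = None) -> None:
    """Write a 1-D trace as CSV with a JSON metadata sidecar.

    ``trace`` is either an object exposing ``times_ms`` and ``value``
    1-D arrays (e.g. a MetastabilityTrace) or a ``(times_ms, values)``
    pair.  NaN values (window-edge padding) serialize as empty fields.
    """
    if isinstance(trace, tuple):
        times_ms, values = trace
    else:
        times_ms, values = trace.times_ms, trace.value
        band = band or getattr(trace, "band", None)
    times_ms = np.asarray(times_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("write_trace expects a 1-D trace; average epochs first")
    if times_ms.shape != values.shape:
        raise ValueError("time axis and values must have equal length")

    df = pd.DataFrame({"time_ms": times_ms, "value": values})
    if band is not None:
        df["band"] = band
    if group is not None:
        df["group"] = group
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")

    sidecar = {"config": config or {}, "seed": seed}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def read_trace(path):
    """Read a trace CSV back as ``(times_ms, values, dataframe)``."""
    df = pd.read_csv(path)
    if "time_ms" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: not a trace table (need time_ms, value columns)")
    return df["time_ms"].to_numpy(), df["value"].to_numpy(), df
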