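"""Readers/writers for EEG containers and tabular traces.

The internal canonical container is a single HDF5 layout; BrainVision and
EDF are import/export paths.  All readers return data in microvolts with
sample-accurate event onsets.
"""

from .hdf5 import read_hdf5, write_hdf5
from .edf import read_edf, write_edf
from .brainvision import read_brainvision, write_brainvision
from .tables import write_trace, read_trace

__all__ = [
    "read_eeg",
    "read_hdf5",
    "write_hdf5",
    "read_edf",
    "write_edf",
    "read_brainvision",
    "write_brainvision",
    "write_trace",
    "read_trace",
]


def read_eeg(path, format: str | None = None):
    """Read a continuous EEG record with events.

    Parameters
    ----------
    path : str or Path
        File path (``.vhdr`` for BrainVision, ``.edf``, ``.h5``/``.hdf5``).
    format : {"brainvision", "edf", "hdf5"}, optional
        Explicit format; inferred from the extension when omitted.

    Returns
    -------
    ContinuousEEG
    """
    from pathlib import Path

    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {
            ".vhdr": "brainvision",
            ".edf": "edf",
            ".h5": "hdf5",
            ".hdf5": "hdf5",
        }.get(ext)
        if format is None:
            raise ValueError(f"cannot infer EEG format from extension {ext!r}")
    if format == "brainvision":
        return read_brainvision(path)
    if format == "edf":
        return read_edf(path)
    if format == "hdf5":
        rec = read_hdf5(path)
        from ..containers import ContinuousEEG

        if not isinstance(rec, ContinuousEEG):
            raise ValueError(f"{path} holds epoched data, not a continuous record")
        return rec
    raise ValueError(f"unknown format {format!r}")
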