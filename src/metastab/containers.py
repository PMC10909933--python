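"""Core data containers shared across the analysis pipeline.

Array axis conventions: epoched data is ``(epoch, channel, sample)``,
continuous data is ``(channel, sample)``.  Amplitudes are in microvolts,
time is carried as sample indices internally; milliseconds appear only at
API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with event markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    events : ndarray of int
        Sample indices of event (pulse) onsets.
    channel_positions : ndarray, shape (n_channels, 3), optional
        Sensor coordinates in mm.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    channel_positions: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """Epoched EEG: ``data[epoch, channel, sample]`` in microvolts.

    ``pulse_sample`` is the index of the TMS pulse within every epoch
    (all epochs share the same relative pulse latency).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    pulse_sample: int
    channel_positions: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be (n_epochs, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if not (0 <= self.pulse_sample < self.data.shape[2]):
            raise ValueError(
                f"pulse_sample {self.pulse_sample} outside epoch of "
                f"{self.data.shape[2]} samples"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Epoch time axis in ms, 0 at the first sample."""
        return np.arange(self.n_samples) * 1000.0 / self.fs

    def channel_indices(self, names) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.channel_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown channel {exc.args[0]!r}") from None


@dataclass
class Connectome:
    """Weighted structural network with metric embedding and delays.

    weights ``c_ij`` are symmetric, nonnegative, zero-diagonal; distances
    are Euclidean in mm; delays ``tau_ij = d_ij / conduction_velocity``
    in ms; strengths are weight row sums.
    """

    weights: np.ndarray
    distances: np.ndarray
    delays: np.ndarray
    coordinates: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.delays = np.asarray(self.delays, dtype=np.float64)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.distances.shape != (n, n):
            raise ValueError("weights/distances must be square and consistent")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diag(self.weights).any():
            raise ValueError("weight diagonal must be zero")
        if not self.node_labels:
            self.node_labels = [f"node{i:02d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)
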