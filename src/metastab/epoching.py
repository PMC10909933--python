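"""Cut continuous recordings into pulse-locked epochs."""

from __future__ import annotations

import logging

import numpy as np

from .containers import ContinuousEEG, EpochedEEG

logger = logging.getLogger(__name__)


def epoch(record: ContinuousEEG, events=None, t_pre_ms: float = 500.0,
          t_post_ms: float = 1500.0) -> EpochedEEG:
    """Epoch a continuous record around event onsets.

    Each epoch spans ``[-t_pre_ms, +t_post_ms)`` around its event; the
    pulse lands at sample ``round(t_pre_ms * fs / 1000)``.  Events whose
    window would cross the record edges are dropped with a log message.

    Raises
    ------
    ValueError
        If no usable events remain.
    """
    if events is None:
        events = record.events
    events = np.asarray(events, dtype=np.int64)
    if events.size == 0:
        raise ValueError("no events to epoch around")
    n_pre = int(round(t_pre_ms * record.fs / 1000.0))
    n_post = int(round(t_post_ms * record.fs / 1000.0))
    if n_pre + n_post < 1:
        raise ValueError("epoch window must span at least one sample")

    usable = events[(events - n_pre >= 0) & (events + n_post <= record.n_samples)]
    dropped = events.size - usable.size
    if dropped:
        logger.info("dropped %d events too close to record edges", dropped)
    if usable.size == 0:
        raise ValueError("no usable events: all windows cross the record edges")

    data = np.stack([record.data[:, e - n_pre : e + n_post] for e in usable])
    return EpochedEEG(
        data=data,
        fs=record.fs,
        channel_names=list(record.channel_names),
        pulse_sample=n_pre,
        channel_positions=record.channel_positions,
        subject_id=record.subject_id,
    )
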