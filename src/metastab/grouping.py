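"""Channel grouping from the pulse-evoked potential.

At the post-pulse global-field-power peak, each channel's deviation from
the grand channel mean is ranked; the top and bottom tertiles form two
local channel groups straddling the stimulated region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochedEEG

__all__ = [
    "ChannelGrouping",
    "evoked_response",
    "global_field_power",
    "group_channels",
]


@dataclass
class ChannelGrouping:
    group_top: list[str]
    group_bottom: list[str]
    gfp_peak_sample: int
    mean_differences: np.ndarray  #: per-channel value - grand mean, at the peak

    def to_dict(self) -> dict:
        return {
            "group_top": self.group_top,
            "group_bottom": self.group_bottom,
            "gfp_peak_sample": int(self.gfp_peak_sample),
            "mean_differences": [float(v) for v in self.mean_differences],
        }


def evoked_response(*eegs: EpochedEEG) -> np.ndarray:
    """Grand-average ERP (channel x sample) across epochs and inputs.

    Multiple inputs (subjects) are first epoch-averaged individually,
    then averaged together, weighting subjects equally.
    """
    if not eegs:
        raise ValueError("need at least one epoched input")
    per_subject = []
    for eeg in eegs:
        if eeg.n_epochs < 1:
            raise ValueError("input with zero epochs")
        per_subject.append(eeg.data.mean(axis=0))
    shapes = {a.shape for a in per_subject}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent (channel, sample) shapes: {shapes}")
    return np.mean(per_subject, axis=0)


def global_field_power(maps: np.ndarray) -> np.ndarray:
    """Spatial (population) standard deviation across channels per sample.

    ``maps`` is (channel, sample) or (channel,) for a single map.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return maps.std(axis=0)  # ddof=0


def group_channels(erp: np.ndarray, channel_names: list[str], fs: float,
                   pulse_sample: int = 0,
                   search_window_ms: tuple[float, float] = (10.0, 300.0)
                   ) -> ChannelGrouping:
    """Derive two tertile channel groups from the ERP's GFP peak.

    The GFP peak is searched within ``search_window_ms`` after the pulse
    (excluding any residual pulse-sample discontinuity); ties resolve to
    the earliest sample.  At the peak, channel deviations from the grand
    mean are sorted ascending; the bottom floor(n/3) channels form
    ``group_bottom`` and the top floor(n/3) form ``group_top``; exact
    ties resolve by channel order.
    """
    erp = np.asarray(erp, dtype=float)
    n_ch, n_samp = erp.shape
    if n_ch < 3:
        raise ValueError("grouping requires at least 3 channels")
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")

    lo = pulse_sample + int(round(search_window_ms[0] * fs / 1000.0))
    hi = pulse_sample + int(round(search_window_ms[1] * fs / 1000.0))
    lo = max(lo, 0)
    hi = min(hi, n_samp - 1)
    if hi < lo:
        raise ValueError("GFP search window outside epoch")

    gfp = global_field_power(erp[:, lo : hi + 1])
    peak = lo + int(np.argmax(gfp))  # argmax -> earliest maximal sample

    values = erp[:, peak]
    diffs = values - values.mean()
    if np.allclose(diffs, 0.0):
        raise ValueError(
            "all channels equal at the GFP peak; tertile assignment undefined "
            "(choose a different search window or check the ERP)"
        )
    order = np.argsort(diffs, kind="stable")  # stable: ties by channel order
    size = n_ch // 3
    bottom = [channel_names[i] for i in sorted(order[:size])]
    top = [channel_names[i] for i in sorted(order[-size:])]
    return ChannelGrouping(
        group_top=top,
        group_bottom=bottom,
        gfp_peak_sample=peak,
        mean_differences=diffs,
    )
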