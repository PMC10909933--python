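"""Analysis configuration: frequency bands, window lengths, thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: Default band edges in Hz.  Only the alpha band is fixed by convention
#: upstream of this package; the others follow common usage and are
#: overridable via :class:`AnalysisConfig`.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class AnalysisConfig:
    """Tunable parameters for the metastability pipeline.

    All windows in milliseconds.  ``baseline_interval_ms`` is the interval
    whose mean defines 100% for baseline-normalised traces.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    metastability_window_ms: float = 50.0
    lzc_window_ms: float = 100.0
    prepost_window_ms: float = 250.0
    baseline_interval_ms: tuple[float, float] = (525.0, 1525.0)
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        for w in (
            self.metastability_window_ms,
            self.lzc_window_ms,
            self.prepost_window_ms,
        ):
            if w <= 0:
                raise ValueError("window lengths must be positive")
        lo, hi = self.baseline_interval_ms
        if not lo < hi:
            raise ValueError("baseline interval must be increasing")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        for name, (f_lo, f_hi) in self.bands.items():
            if not 0 < f_lo < f_hi:
                raise ValueError(f"band {name!r} edges must be increasing and > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        if "baseline_interval_ms" in raw:
            raw["baseline_interval_ms"] = tuple(raw["baseline_interval_ms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["baseline_interval_ms"] = list(self.baseline_interval_ms)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
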