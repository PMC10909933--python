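"""Pre/post window statistics: paired one-tailed Wilcoxon signed-rank tests.

The signed-rank test is implemented natively: zero differences are
dropped, tied absolute differences receive mid-ranks, and the one-tailed
p-value is exact (full null distribution of the positive-rank sum, via
generating-function convolution) for n <= 25, with a continuity-corrected
normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "PrePostTable",
    "prepost_means",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "run_stats_battery",
    "EFFECTS",
]

EXACT_N_MAX = 25


@dataclass
class PrePostTable:
    """Per-subject window means of one measure (one band, one channel group)."""

    pre: np.ndarray
    post: np.ndarray
    measure: str = ""
    band: str = ""
    group: str = ""
    window_ms: float = 250.0
    ref: np.ndarray | None = None  #: early-epoch reference window means
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape:
            raise ValueError("pre/post must be paired")
        if np.isnan(self.pre).any() or np.isnan(self.post).any():
            raise ValueError("NaN window means are not allowed in a PrePostTable")


def prepost_means(values: np.ndarray, times_ms: np.ndarray, pulse_ms: float,
                  window_ms: float = 250.0, with_reference: bool = False):
    """Mean of a trace in the 250 ms windows flanking the pulse.

    pre covers ``[pulse - window, pulse)``, post covers
    ``(pulse, pulse + window]``.  NaN samples (window-edge padding) are
    ignored, with contributing counts returned.  With ``with_reference``
    a third mean over the earliest full window ``[t0, t0 + window]`` is
    included (comparator for pre-pulse effects).
    """
    values = np.asarray(values, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if pulse_ms - window_ms < times_ms[0] or pulse_ms + window_ms > times_ms[-1]:
        raise ValueError("pre/post windows exceed trace support")
    pre_mask = (times_ms >= pulse_ms - window_ms) & (times_ms < pulse_ms)
    post_mask = (times_ms > pulse_ms) & (times_ms <= pulse_ms + window_ms)

    def _mean(mask):
        sub = values[..., mask]
        n = int(np.sum(~np.isnan(sub)))
        if n == 0:
            raise ValueError("window contains no finite samples")
        return float(np.nanmean(sub)), n

    pre, n_pre = _mean(pre_mask)
    post, n_post = _mean(post_mask)
    out = {"pre": pre, "post": post, "n_pre": n_pre, "n_post": n_post}
    if with_reference:
        ref_mask = (times_ms >= times_ms[0]) & (times_ms <= times_ms[0] + window_ms)
        out["ref"], out["n_ref"] = _mean(ref_mask)
    return out


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (annotation only; pipeline stays nonparametric)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if values.size > 50:
        raise ValueError("Shapiro-Wilk supported for n <= 50")
    if np.ptp(values) == 0:
        raise ValueError("constant input")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def _exact_sf_cdf(ranks2: np.ndarray):
    """Null distribution of 2*T+ over sign patterns; returns probability array.

    ``ranks2`` are doubled mid-ranks (integers).  Entry ``dist[s]`` is the
    number of sign assignments with 2*T+ == s, normalized at the end.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist / dist.sum()


def wilcoxon_signed_rank(pre, post, direction: str) -> tuple[float, float]:
    """One-tailed paired signed-rank test of post vs pre.

    direction="less" tests the alternative post < pre; "greater" tests
    post > pre.  Returns ``(T, p)`` where T is the positive-rank sum of
    the differences ``post - pre`` after dropping zeros.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must be paired")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks = rankdata(np.abs(d))  # mid-ranks on ties
    t_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        dist = _exact_sf_cdf(ranks2)
        s = int(round(2 * t_plus))
        if direction == "less":
            p = dist[: s + 1].sum()
        else:
            p = dist[s:].sum()
    else:
        mu = n * (n + 1) / 4.0
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        if direction == "less":
            z = (t_plus - mu + 0.5) / sd
            p = sps.norm.cdf(z)
        else:
            z = (t_plus - mu - 0.5) / sd
            p = sps.norm.sf(z)
    return t_plus, float(min(p, 1.0))


#: battery rows: (effect name, which pair is compared, tail for the second
#: member of the pair relative to the first)
EFFECTS = [
    ("decrease_after_pulse", "pre", "post", "less"),
    ("increase_before_pulse", "ref", "pre", "greater"),
    ("increase_after_pulse", "pre", "post", "greater"),
]


def run_stats_battery(tables: list[PrePostTable], alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon battery over measures x bands x groups, one row per effect.

    Emits raw one-tailed p-values (mirroring the primary presentation)
    plus a Holm-corrected column across all cells.
    """
    if not tables:
        raise ValueError("no tables supplied")
    rows = []
    for tbl in tables:
        for effect, a_name, b_name, tail in EFFECTS:
            a = tbl.ref if a_name == "ref" else getattr(tbl, a_name)
            b = getattr(tbl, b_name)
            if a is None:
                rows.append(
                    dict(measure=tbl.measure, band=tbl.band, group=tbl.group,
                         effect=effect, T=np.nan, p=np.nan, n=0, missing=True)
                )
                continue
            try:
                t_stat, p = wilcoxon_signed_rank(a, b, direction=tail)
                n = int(np.sum((np.asarray(b) - np.asarray(a)) != 0))
                rows.append(
                    dict(measure=tbl.measure, band=tbl.band, group=tbl.group,
                         effect=effect, T=t_stat, p=p, n=n, missing=False)
                )
            except ValueError as exc:
                rows.append(
                    dict(measure=tbl.measure, band=tbl.band, group=tbl.group,
                         effect=effect, T=np.nan, p=np.nan, n=0, missing=True,
                         note=str(exc))
                )
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    # Holm correction over the valid cells
    valid = df["p"].notna()
    pvals = df.loc[valid, "p"].to_numpy()
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    df.loc[valid, "p_holm"] = adj
    df["significant_holm"] = df["p_holm"] < alpha
    return df
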