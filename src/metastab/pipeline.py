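"""Cohort-level orchestration: per-subject traces and pre/post tables.

Glue between the measure modules and the statistics battery; used by the
CLI and by the acceptance checks.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .containers import ContinuousEEG, EpochedEEG
from .lzc import sliding_lzc
from .microstates import backfit, fit_microstates
from .phase import (average_over, extract_phase, kop_trace,
                    sliding_metastability)
from .stats import PrePostTable, prepost_means

__all__ = [
    "subject_metastability",
    "cohort_kop_tables",
    "subject_lzc_trace",
    "cohort_lzc_table",
    "cohort_prepost_pvalues",
]


def subject_metastability(eeg: EpochedEEG, band: tuple[float, float],
                          channels=None, window_ms: float = 50.0):
    """Epoch-averaged KOP and metastability traces for one subject.

    Returns ``(times_ms, kop_mean, meta_mean)``; the windowed std is
    computed per epoch and then averaged, margins NaN-masked.
    """
    phase = extract_phase(eeg, band)
    trace = kop_trace(phase, channels=channels)
    meta = sliding_metastability(trace, window_ms=window_ms)
    m = phase.margin
    r = trace.r.astype(float).copy()
    v = meta.value.copy()
    if m > 0:
        r[..., :m] = np.nan
        r[..., -m:] = np.nan
        v[..., :m] = np.nan
        v[..., -m:] = np.nan
    kop_mean = average_over(r)
    meta_mean = average_over(v)
    return trace.times_ms, kop_mean, meta_mean


def cohort_kop_tables(eegs: list[EpochedEEG], band: tuple[float, float],
                      band_name: str = "", channels="cluster",
                      config: AnalysisConfig | None = None
                      ) -> tuple[PrePostTable, PrePostTable]:
    """Per-subject pre/post tables for KOP and KOP-std metastability.

    ``channels`` is "all", "cluster" (the planted cluster, synthetic data
    only), or an explicit label list.
    """
    config = config or AnalysisConfig()
    pre_m, post_m, ref_m = [], [], []
    pre_k, post_k, ref_k = [], [], []
    for eeg in eegs:
        chans = None
        if channels == "cluster":
            chans = eeg.planted["cluster_channels"]
        elif channels != "all" and not isinstance(channels, str):
            chans = channels
        times, kop_mean, meta_mean = subject_metastability(
            eeg, band, channels=chans, window_ms=config.metastability_window_ms
        )
        pulse_ms = eeg.pulse_sample * 1000.0 / eeg.fs
        w = config.prepost_window_ms
        mm = prepost_means(meta_mean, times, pulse_ms, w, with_reference=True)
        kk = prepost_means(kop_mean, times, pulse_ms, w, with_reference=True)
        pre_m.append(mm["pre"]); post_m.append(mm["post"]); ref_m.append(mm["ref"])
        pre_k.append(kk["pre"]); post_k.append(kk["post"]); ref_k.append(kk["ref"])
    meta_tbl = PrePostTable(pre=pre_m, post=post_m, ref=np.asarray(ref_m),
                            measure="metastability", band=band_name,
                            window_ms=config.prepost_window_ms)
    kop_tbl = PrePostTable(pre=pre_k, post=post_k, ref=np.asarray(ref_k),
                           measure="kop", band=band_name,
                           window_ms=config.prepost_window_ms)
    return meta_tbl, kop_tbl


def subject_lzc_trace(rest: ContinuousEEG, tms: EpochedEEG,
                      config: AnalysisConfig | None = None,
                      k_max: int = 10):
    """Microstate-LZC trace for one subject.

    Fits microstates on the resting record (alpha band), backfits every
    stimulated epoch, computes the windowed LZ76 complexity per epoch and
    averages.  Returns ``(times_ms, lzc_mean, model)``.
    """
    from .phase import bandpass

    config = config or AnalysisConfig()
    band = config.bands.get("alpha", (8.0, 12.0))
    model = fit_microstates(rest.data, rest.fs, band=band, k_max=k_max)
    traces = []
    for e in range(tms.n_epochs):
        filtered, _ = bandpass(tms.data[e], band, tms.fs)
        seq = backfit(filtered, model.templates, fs=tms.fs)
        tr = sliding_lzc(seq.labels, window_ms=config.lzc_window_ms,
                         fs=tms.fs, mode="sliding")
        traces.append(tr.value)
        times = tr.times_ms
    return times, average_over(traces), model


def cohort_lzc_table(rests: list[ContinuousEEG], tmss: list[EpochedEEG],
                     config: AnalysisConfig | None = None,
                     k_max: int = 10) -> PrePostTable:
    """Per-subject pre/post windowed-LZC table across a cohort."""
    config = config or AnalysisConfig()
    pre, post, ref = [], [], []
    for rest, tms in zip(rests, tmss):
        times, lzc_mean, _ = subject_lzc_trace(rest, tms, config, k_max=k_max)
        pulse_ms = tms.pulse_sample * 1000.0 / tms.fs
        m = prepost_means(lzc_mean, times, pulse_ms,
                          config.prepost_window_ms, with_reference=True)
        pre.append(m["pre"]); post.append(m["post"]); ref.append(m["ref"])
    return PrePostTable(pre=pre, post=post, ref=np.asarray(ref),
                        measure="lzc", band="alpha",
                        window_ms=config.prepost_window_ms)


def cohort_prepost_pvalues(spec, band: tuple[float, float] = (8.0, 12.0),
                           rest_duration_ms: float = 5000.0,
                           config: AnalysisConfig | None = None,
                           k_max: int = 8) -> dict:
    """One-tailed p-values for the post-pulse drop across a synthetic cohort.

    Generates the cohort described by ``spec`` (one stimulated run and one
    resting record per subject), computes per-subject pre/post window
    means of cluster-channel KOP-std metastability and of windowed
    microstate LZC, and tests post < pre with the signed-rank test.
    Returns the p-values plus the per-subject tables.
    """
    from .stats import wilcoxon_signed_rank
    from .synth import generate_resting_record, generate_tms_epochs

    config = config or AnalysisConfig()
    w = config.prepost_window_ms
    meta_pre, meta_post, lzc_pre, lzc_post = [], [], [], []
    for subject in range(spec.n_subjects):
        tms = generate_tms_epochs(spec, subject=subject)
        pulse_ms = tms.pulse_sample * 1000.0 / tms.fs
        times, _, meta = subject_metastability(
            tms, band, channels=tms.planted["cluster_channels"],
            window_ms=config.metastability_window_ms)
        m = prepost_means(meta, times, pulse_ms, w)
        meta_pre.append(m["pre"])
        meta_post.append(m["post"])

        rest = generate_resting_record(spec, subject=subject,
                                       duration_ms=rest_duration_ms)
        lt, lzc_mean, _ = subject_lzc_trace(rest, tms, config, k_max=k_max)
        lm = prepost_means(lzc_mean, lt, pulse_ms, w)
        lzc_pre.append(lm["pre"])
        lzc_post.append(lm["post"])

    _, p_meta = wilcoxon_signed_rank(meta_pre, meta_post, direction="less")
    _, p_lzc = wilcoxon_signed_rank(lzc_pre, lzc_post, direction="less")
    return {
        "p_meta": p_meta,
        "p_lzc": p_lzc,
        "meta": (np.asarray(meta_pre), np.asarray(meta_post)),
        "lzc": (np.asarray(lzc_pre), np.asarray(lzc_post)),
    }
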