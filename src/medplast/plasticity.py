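"""Baseline normalization, LTP/LTD quantification, PPR, recruitment/silencing.

The central quantity is the fEPSP slope normalized as a percentage of each
channel's own baseline mean; long-term potentiation or depression is
quantified as the mean normalized slope over the final 10 minutes of the
post-induction recording, averaged per channel and then summarized per
cortical layer (mean +/- SEM over channels).

Channel labels use configurable thresholds: *potentiated* when the
last-window mean is at or above 115% of baseline, *depressed* at or below
85%, otherwise *unchanged*.  Both the raw per-channel means and the labels
are emitted, since published per-channel inclusion rules are rarely stated.

Recruitment and silencing are amplitude phenomena: a *recruited* channel is
silent at baseline (median amplitude at or below the 10 uV activation
threshold) and develops a supra-threshold response in the final window after
TBS; a *silenced* channel is baseline-activated but its response collapses
to approximately 0 uV (final-window median at or below a small absolute
threshold, default 4 uV) after LFS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import ACTIVATION_THRESHOLD_UV, QCReport

POTENTIATED_PCT = 115.0
DEPRESSED_PCT = 85.0
SILENT_THRESHOLD_UV = 4.0

LABEL_POTENTIATED = "potentiated"
LABEL_DEPRESSED = "depressed"
LABEL_UNCHANGED = "unchanged"


def normalize_to_baseline(features: pd.DataFrame, qc: QCReport) -> pd.DataFrame:
    """Per-channel normalized slope time course (% of baseline mean).

    Only channels QC'd ``active_stable`` appear; channels whose baseline
    mean slope is non-positive are dropped.  The mean of the baseline
    samples of every returned channel equals 100% (to numerical precision).
    Raises if the slice was excluded by QC.
    """
    if qc.slice_excluded:
        raise ValueError(
            f"slice {qc.slice_id} was excluded by QC ({qc.exclusion_reason}); "
            "refusing to normalize")
    keep = set(qc.active_stable_ids)
    df = features.loc[features.channel_id.isin(keep)].copy()
    base_mean = (df.loc[df.is_baseline]
                 .groupby("channel_id")["slope_uV_per_ms"].mean())
    good = base_mean.loc[base_mean > 0]
    df = df.loc[df.channel_id.isin(good.index)].copy()
    df["normalized_slope_pct"] = (
        df["slope_uV_per_ms"] / df["channel_id"].map(good) * 100.0)
    cols = ["slice_id", "channel_id", "layer", "sweep_index", "time_min",
            "is_baseline", "normalized_slope_pct"]
    return df[[c for c in cols if c in df.columns]].reset_index(drop=True)


def summarize_last_window(normalized: pd.DataFrame,
                          window_min: float = 10.0,
                          potentiated_pct: float = POTENTIATED_PCT,
                          depressed_pct: float = DEPRESSED_PCT
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel plasticity calls and per-layer group summary.

    The last window covers the final ``window_min`` minutes of the
    recording (anchored to its end).  Returns ``(calls, layer_summary)``:
    ``calls`` has one row per channel (``last_window_mean_pct``, ``label``);
    ``layer_summary`` has mean, SEM and n over channels per layer
    (``outside`` channels are not summarized).
    """
    post = normalized.loc[~normalized.is_baseline]
    if post.empty:
        raise ValueError("no post-induction samples to summarize")
    t_end = float(normalized.time_min.max())
    span = t_end - float(post.time_min.min())
    if span + 1e-9 < window_min - normalized.time_min.diff().abs().min():
        raise ValueError(
            f"post-induction span ({span:.1f} min) shorter than the "
            f"required {window_min:.1f}-min window")
    window = normalized.loc[normalized.time_min >= t_end - window_min + 1e-9]

    calls = (window.groupby(["slice_id", "channel_id", "layer"], as_index=False)
             .agg(last_window_mean_pct=("normalized_slope_pct", "mean")))
    calls["label"] = LABEL_UNCHANGED
    calls.loc[calls.last_window_mean_pct >= potentiated_pct, "label"] = LABEL_POTENTIATED
    calls.loc[calls.last_window_mean_pct <= depressed_pct, "label"] = LABEL_DEPRESSED

    grp = calls.loc[calls.layer != "outside"].groupby("layer")["last_window_mean_pct"]
    layer_summary = grp.agg(
        mean_pct="mean",
        sem_pct=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
        n_channels="count").reset_index()
    return calls, layer_summary


def compute_ppr(ppf_features: pd.DataFrame) -> pd.DataFrame:
    """Paired-pulse ratios: slope2 / slope1 per channel and interval.

    ``ppf_features`` comes from :func:`medplast.features.extract_ppf_features`.
    Sweeps where the first slope is zero or unmeasurable are flagged
    (``measurable = False``) rather than dropped.  Ratios are averaged over
    sweeps within each (channel, interval); rows without any measurable
    sweep carry NaN.
    """
    df = ppf_features.copy()
    s1 = df["slope1_uV_per_ms"].to_numpy(dtype=float)
    s2 = df["slope2_uV_per_ms"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((s1 > 0) & np.isfinite(s1) & np.isfinite(s2), s2 / s1, np.nan)
    df["ppr"] = ratio
    df["measurable"] = np.isfinite(ratio)
    out = (df.groupby(["channel_id", "layer", "interval_ms"], as_index=False)
           .agg(ppr=("ppr", "mean"),
                n_sweeps=("ppr", "size"),
                n_measurable=("measurable", "sum")))
    out["measurable"] = out["n_measurable"] > 0
    return out


def _final_window_median(features: pd.DataFrame, window_min: float) -> pd.Series:
    t_end = float(features.time_min.max())
    final = features.loc[features.time_min >= t_end - window_min + 1e-9]
    return final.groupby("channel_id")["amplitude_uV"].median()


def _recruitment_frame(features: pd.DataFrame, base_med: pd.Series,
                       final_med: pd.Series, recruited: pd.Series,
                       silenced: pd.Series) -> pd.DataFrame:
    channels = sorted(base_med.index)
    layer_of = (features.drop_duplicates("channel_id")
                .set_index("channel_id")["layer"])
    return pd.DataFrame({
        "channel_id": channels,
        "layer": [layer_of.get(ch) for ch in channels],
        "baseline_amp_uV": [float(base_med.get(ch, np.nan)) for ch in channels],
        "post_window_amp_uV": [float(final_med.get(ch, np.nan)) for ch in channels],
        "recruited": [bool(recruited.get(ch, False)) for ch in channels],
        "silenced": [bool(silenced.get(ch, False)) for ch in channels],
    })


def detect_recruited(features: pd.DataFrame, qc: QCReport,
                     threshold_uV: float = ACTIVATION_THRESHOLD_UV,
                     silent_threshold_uV: float = SILENT_THRESHOLD_UV,
                     post_window_min: float = 10.0) -> pd.DataFrame:
    """Recruited (unsilenced) channels after LTP induction.

    A channel is recruited iff it was approximately silent at baseline
    (median amplitude at or below ``silent_threshold_uV``; in particular it
    was *not* an activated channel) and its final-window median amplitude
    rises strictly above the activation threshold.  The near-zero baseline
    requirement keeps channels hovering at the activation threshold -- whose
    ordinary potentiation can nudge them across 10 uV -- from being mistaken
    for silent-synapse recruitment.  Returns one row per channel with
    baseline/final amplitudes and flags; only meaningful for retained TBS
    slices.
    """
    if qc.slice_excluded:
        raise ValueError(f"slice {qc.slice_id} was excluded by QC")
    base_med = (features.loc[features.is_baseline]
                .groupby("channel_id")["amplitude_uV"].median())
    final_med = _final_window_median(features, post_window_min)
    eligible = base_med <= silent_threshold_uV
    recruited = eligible & (final_med.reindex(base_med.index) > threshold_uV)
    silenced = pd.Series(False, index=base_med.index)
    out = _recruitment_frame(features, base_med, final_med, recruited, silenced)
    return out


def detect_silenced(features: pd.DataFrame, qc: QCReport,
                    threshold_uV: float = ACTIVATION_THRESHOLD_UV,
                    silent_threshold_uV: float = SILENT_THRESHOLD_UV,
                    post_window_min: float = 10.0) -> pd.DataFrame:
    """Silenced channels after LTD induction.

    A channel is silenced iff it was baseline-activated (median baseline
    amplitude strictly above ``threshold_uV``) and its final-window median
    amplitude collapses to approximately zero (at or below
    ``silent_threshold_uV``).  The small absolute threshold separates
    genuine silencing from ordinary LTD, which reduces but does not abolish
    the response.
    """
    if qc.slice_excluded:
        raise ValueError(f"slice {qc.slice_id} was excluded by QC")
    base_med = (features.loc[features.is_baseline]
                .groupby("channel_id")["amplitude_uV"].median())
    final_med = _final_window_median(features, post_window_min)
    activated = base_med > threshold_uV
    silenced = activated & (final_med.reindex(base_med.index) <= silent_threshold_uV)
    recruited = pd.Series(False, index=base_med.index)
    return _recruitment_frame(features, base_med, final_med, recruited, silenced)
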