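"""Channel activation, baseline stability, slice exclusion, stimulus calibration.

The experiment's quality rules, hardened into testable form:

* a channel is *activated* when its median baseline fEPSP amplitude exceeds
  10 uV (strictly),
* an activated channel is *stable* when the coefficient of variation of its
  baseline slopes over the final 15 min of baseline is below 5% (strictly),
* a slice is *excluded* when more than 10% of its activated channels are
  unstable (strictly), or when it has no activated channels at all,
* the stimulus intensity is the smallest tested one eliciting 40-60% of the
  maximum fEPSP slope on the input-output curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridLayout

ACTIVATION_THRESHOLD_UV = 10.0
CV_LIMIT = 0.05
EXCLUSION_FRACTION = 0.10

STATUS_INACTIVE = "inactive"
STATUS_STABLE = "active_stable"
STATUS_UNSTABLE = "active_unstable"


@dataclass
class QCReport:
    """Per-slice QC outcome: channel statuses and the exclusion decision."""

    slice_id: str
    channels: pd.DataFrame   # channel_id, status, baseline_median_amp_uV,
    #                          baseline_mean_slope, baseline_cv, reason
    n_active: int = 0
    n_unstable: int = 0
    unstable_fraction: float = 0.0
    slice_excluded: bool = False
    exclusion_reason: str = ""

    def status_of(self, channel_id: int) -> str:
        row = self.channels.loc[self.channels.channel_id == channel_id]
        if row.empty:
            raise KeyError(f"channel {channel_id} not in QC report")
        return row.status.iloc[0]

    @property
    def active_stable_ids(self) -> list[int]:
        df = self.channels
        return df.loc[df.status == STATUS_STABLE, "channel_id"].tolist()

    def to_dict(self) -> dict:
        return {
            "slice_id": self.slice_id,
            "n_active": self.n_active,
            "n_unstable": self.n_unstable,
            "unstable_fraction": self.unstable_fraction,
            "slice_excluded": bool(self.slice_excluded),
            "exclusion_reason": self.exclusion_reason,
            "channels": self.channels.to_dict(orient="records"),
        }


def _require_features(features: pd.DataFrame) -> pd.DataFrame:
    if features is None or len(features) == 0:
        raise ValueError("empty feature table")
    baseline = features.loc[features.is_baseline]
    if baseline.empty:
        raise ValueError("feature table holds no baseline sweeps")
    return baseline


def classify_activated(features: pd.DataFrame,
                       threshold_uV: float = ACTIVATION_THRESHOLD_UV
                       ) -> pd.Series:
    """Activation flag per channel: median baseline amplitude strictly above
    ``threshold_uV`` ("above 10 uV"), so exactly 10.0 uV is *not* activated."""
    baseline = _require_features(features)
    med = baseline.groupby("channel_id")["amplitude_uV"].median()
    return med > threshold_uV


def assess_baseline_stability(features: pd.DataFrame,
                              window_min: float = 15.0,
                              cv_limit: float = CV_LIMIT) -> pd.DataFrame:
    """Stability per channel: population CV of baseline slopes in the final
    ``window_min`` of baseline, stable iff CV strictly below ``cv_limit``.

    Channels with non-positive mean baseline slope are flagged unstable with
    reason "degenerate baseline".  Returns a frame indexed by channel_id with
    columns ``baseline_mean_slope``, ``baseline_cv``, ``stable``, ``reason``.
    """
    baseline = _require_features(features)
    t_end = baseline.time_min.max()
    window = baseline.loc[baseline.time_min >= t_end - window_min + 1e-9]
    out = []
    for ch, grp in window.groupby("channel_id"):
        slopes = grp["slope_uV_per_ms"].to_numpy(dtype=float)
        slopes = slopes[np.isfinite(slopes)]
        mean = slopes.mean() if slopes.size else np.nan
        if slopes.size == 0 or not np.isfinite(mean) or mean <= 0:
            out.append((ch, np.nan, np.nan, False, "degenerate baseline"))
            continue
        cv = float(np.std(slopes) / mean)     # population SD
        out.append((ch, float(mean), cv, cv < cv_limit, ""))
    return pd.DataFrame(
        out, columns=["channel_id", "baseline_mean_slope", "baseline_cv",
                      "stable", "reason"]).set_index("channel_id")


def build_qc_report(features: pd.DataFrame,
                    slice_id: str | None = None,
                    threshold_uV: float = ACTIVATION_THRESHOLD_UV,
                    window_min: float = 15.0,
                    cv_limit: float = CV_LIMIT,
                    exclusion_fraction: float = EXCLUSION_FRACTION) -> QCReport:
    """Full QC for one slice's feature table, including the exclusion rule."""
    if slice_id is None:
        slice_id = str(features["slice_id"].iloc[0])
    activated = classify_activated(features, threshold_uV)
    stability = assess_baseline_stability(features, window_min, cv_limit)
    baseline = features.loc[features.is_baseline]
    med_amp = baseline.groupby("channel_id")["amplitude_uV"].median()

    rows = []
    for ch in sorted(activated.index):
        act = bool(activated.loc[ch])
        st = stability.loc[ch] if ch in stability.index else None
        if not act:
            status, reason = STATUS_INACTIVE, ""
        elif st is not None and bool(st.stable):
            status, reason = STATUS_STABLE, ""
        else:
            status = STATUS_UNSTABLE
            reason = st.reason if st is not None else "no baseline slopes"
        rows.append({
            "channel_id": int(ch),
            "status": status,
            "baseline_median_amp_uV": float(med_amp.get(ch, np.nan)),
            "baseline_mean_slope": float(st.baseline_mean_slope) if st is not None else np.nan,
            "baseline_cv": float(st.baseline_cv) if st is not None else np.nan,
            "reason": reason,
        })
    channels = pd.DataFrame(rows)
    report = QCReport(slice_id=slice_id, channels=channels)
    report.n_active = int((channels.status != STATUS_INACTIVE).sum())
    report.n_unstable = int((channels.status == STATUS_UNSTABLE).sum())
    report.unstable_fraction = (
        report.n_unstable / report.n_active if report.n_active else 0.0)
    return apply_slice_exclusion(report, exclusion_fraction)


def apply_slice_exclusion(report: QCReport,
                          exclusion_fraction: float = EXCLUSION_FRACTION
                          ) -> QCReport:
    """Set the slice-exclusion decision: excluded iff the unstable fraction
    strictly exceeds ``exclusion_fraction``, or no channel is activated."""
    if report.n_active == 0:
        report.slice_excluded = True
        report.exclusion_reason = "no active channels"
    elif report.unstable_fraction > exclusion_fraction:
        report.slice_excluded = True
        report.exclusion_reason = (
            f"unstable fraction {report.unstable_fraction:.3f} > "
            f"{exclusion_fraction:.2f}")
    else:
        report.slice_excluded = False
        report.exclusion_reason = ""
    return report


def assign_layers(layout: GridLayout, features: pd.DataFrame) -> pd.DataFrame:
    """(Re)attach the layer label of each channel from the grid layout."""
    out = features.copy()
    out["layer"] = [layout.layer_of_channel(int(ch)) for ch in out["channel_id"]]
    return out


def calibrate_stim_intensity(io_curve: pd.DataFrame,
                             lo: float = 0.4,
                             hi: float = 0.6) -> float:
    """Choose the stimulus intensity eliciting ``lo``-``hi`` of the maximum slope.

    ``io_curve`` needs columns ``intensity_ma`` and ``slope_uV_per_ms``
    (one row per intensity; average replicate sweeps first).  Returns the
    smallest tested intensity whose slope falls inside the band; if none
    does, the intensity whose fraction of maximum is closest to 50% is
    returned with a warning.
    """
    df = io_curve.sort_values("intensity_ma")
    if len(df) < 3:
        raise ValueError("need at least 3 tested intensities")
    slopes = df["slope_uV_per_ms"].to_numpy(dtype=float)
    if np.any(slopes < 0):
        raise ValueError("slopes must be non-negative")
    s_max = slopes.max()
    if s_max <= 0:
        raise ValueError("all-zero input-output curve; cannot calibrate")
    frac = slopes / s_max
    in_band = np.nonzero((frac >= lo) & (frac <= hi))[0]
    if in_band.size:
        return float(df["intensity_ma"].iloc[in_band[0]])
    idx = int(np.argmin(np.abs(frac - 0.5)))
    chosen = float(df["intensity_ma"].iloc[idx])
    warnings.warn(
        f"no tested intensity fell in the {lo:.0%}-{hi:.0%} band; "
        f"using {chosen} mA ({frac[idx]:.0%} of maximum slope)",
        stacklevel=2)
    return chosen
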