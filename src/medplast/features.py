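"""Per-sweep fEPSP feature extraction: artifact blanking, amplitude, slope.

Conventions
-----------
fEPSPs are negative-going; amplitudes and slopes are reported as positive
magnitudes, so "larger" always means a stronger response.  The baseline
reference of a trace is the mean of the few milliseconds immediately before
stimulus onset, which makes both measures invariant to constant voltage
offsets and robust to slow drift.

Amplitude is the excursion from that reference to the response trough.  The
trough is located on a lightly smoothed copy of the trace (1 ms boxcar) and
the amplitude is the baseline-to-mean difference of the raw samples in a
short window centered there; this keeps the estimate nearly unbiased both
for genuine responses and for silent channels, where taking the raw minimum
of ~1000 noisy samples would systematically overestimate.

Slope is the magnitude of a least-squares line fitted to the raw samples of
the initial downstroke between 20% and 80% of peak amplitude (a common field
convention; the window fractions are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


class DegenerateWindowError(ValueError):
    """Raised when a slope window holds too few samples to fit a line."""

    def __init__(self, message: str, window_ms: tuple[float, float] | None = None):
        super().__init__(message)
        self.window_ms = window_ms


@dataclass
class FEPSPTrace:
    """One evoked voltage trace on one channel.

    ``samples`` are in microvolts; ``stim_onset_sample`` indexes the stimulus
    delivery.  For paired-pulse sweeps ``stim2_onset_sample`` marks the
    second pulse.
    """

    samples: np.ndarray
    sampling_khz: float
    stim_onset_sample: int
    stim2_onset_sample: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_khz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not 0 <= self.stim_onset_sample < self.samples.size:
            raise ValueError("stim_onset_sample outside trace")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def ms_to_samples(self, ms: float) -> int:
        return int(round(ms * self.sampling_khz))


@dataclass(frozen=True)
class SlopeMeasure:
    """Fitted fEPSP slope magnitude with its window and goodness of fit."""

    slope_uV_per_ms: float
    window_ms: tuple[float, float]   # relative to stimulus onset
    fit_r2: float


def _smooth(x: np.ndarray, sampling_khz: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms * sampling_khz)))
    if w <= 1:
        return np.asarray(x, dtype=float)
    return uniform_filter1d(np.asarray(x, dtype=float), size=w, mode="nearest", axis=-1)


def _baseline_ref(samples: np.ndarray, onset: int, sampling_khz: float,
                  baseline_ms: float) -> float:
    n = max(1, int(round(baseline_ms * sampling_khz)))
    lo = max(0, onset - n)
    if lo == onset:
        raise ValueError("no pre-stimulus samples available for the baseline reference")
    return float(np.mean(samples[lo:onset]))


def blank_artifact(trace: FEPSPTrace, blank_ms: float = 1.0) -> FEPSPTrace:
    """Replace the stimulus artifact by linear interpolation across the blank.

    The ``blank_ms`` window following each stimulus onset is overwritten by
    a straight line between the samples bracketing it.  ``blank_ms = 0``
    returns the trace unchanged.
    """
    if blank_ms < 0:
        raise ValueError("blank_ms must be >= 0")
    if blank_ms == 0:
        return trace
    samples = trace.samples.copy()
    onsets = [trace.stim_onset_sample]
    if trace.stim2_onset_sample is not None:
        onsets.append(trace.stim2_onset_sample)
    n_blank = trace.ms_to_samples(blank_ms)
    for onset in onsets:
        hi = onset + n_blank
        if hi >= samples.size:
            raise ValueError(
                f"blank window ({blank_ms} ms after sample {onset}) exceeds the trace"
            )
        lo = max(0, onset - 1)
        ramp = np.linspace(samples[lo], samples[hi], hi - lo + 1)
        samples[lo:hi + 1] = ramp
    return FEPSPTrace(samples, trace.sampling_khz, trace.stim_onset_sample,
                      trace.stim2_onset_sample)


def measure_amplitude(trace: FEPSPTrace,
                      search_ms: tuple[float, float] = (2.0, 50.0),
                      baseline_ms: float = 5.0,
                      smooth_ms: float = 1.0,
                      peak_avg_ms: float = 0.25,
                      onset: int | None = None) -> float:
    """fEPSP amplitude (uV): baseline reference minus the response trough.

    The search window is relative to the stimulus onset (default 2-50 ms,
    excluding the artifact).  The returned value is positive for a
    negative-going response; a trace with no negative excursion yields a
    value near (or below) zero.
    """
    onset = trace.stim_onset_sample if onset is None else onset
    s0 = onset + trace.ms_to_samples(search_ms[0])
    s1 = onset + trace.ms_to_samples(search_ms[1])
    s1 = min(s1, trace.n_samples)
    if s1 - s0 < 2:
        raise ValueError(f"empty amplitude search window {search_ms} ms")
    ref = _baseline_ref(trace.samples, onset, trace.sampling_khz, baseline_ms)
    sm = _smooth(trace.samples, trace.sampling_khz, smooth_ms)
    peak_idx = s0 + int(np.argmin(sm[s0:s1]))
    half = max(0, trace.ms_to_samples(peak_avg_ms) // 2)
    lo = max(s0, peak_idx - half)
    hi = min(s1, peak_idx + half + 1)
    return ref - float(np.mean(trace.samples[lo:hi]))


def measure_slope(trace: FEPSPTrace,
                  frac_lo: float = 0.2,
                  frac_hi: float = 0.8,
                  search_ms: tuple[float, float] = (2.0, 50.0),
                  baseline_ms: float = 5.0,
                  smooth_ms: float = 1.0,
                  onset: int | None = None) -> SlopeMeasure:
    """Initial-downstroke slope magnitude (uV/ms) of the fEPSP.

    The downstroke is the segment from stimulus onset to the response
    trough; a line is least-squares fitted to the raw samples between
    ``frac_lo`` and ``frac_hi`` of the peak amplitude (thresholds located on
    the smoothed trace, so the window is invariant to trace scaling).
    """
    if not (0 <= frac_lo < frac_hi <= 1):
        raise ValueError("need 0 <= frac_lo < frac_hi <= 1")
    onset = trace.stim_onset_sample if onset is None else onset
    s0 = onset + trace.ms_to_samples(search_ms[0])
    s1 = min(onset + trace.ms_to_samples(search_ms[1]), trace.n_samples)
    if s1 - s0 < 2:
        raise ValueError(f"empty slope search window {search_ms} ms")
    ref = _baseline_ref(trace.samples, onset, trace.sampling_khz, baseline_ms)
    sm = _smooth(trace.samples, trace.sampling_khz, smooth_ms)
    depth = ref - sm
    peak_idx = s0 + int(np.argmin(sm[s0:s1]))
    depth_peak = depth[peak_idx]
    khz = trace.sampling_khz

    def _window_ms(i_lo: int, i_hi: int) -> tuple[float, float]:
        return ((i_lo - onset) / khz, (i_hi - onset) / khz)

    if depth_peak <= 0:
        raise DegenerateWindowError(
            "no negative-going response; slope window undefined",
            window_ms=_window_ms(s0, peak_idx),
        )
    seg = depth[s0:peak_idx + 1]
    above_lo = np.nonzero(seg >= frac_lo * depth_peak)[0]
    above_hi = np.nonzero(seg >= frac_hi * depth_peak)[0]
    i_lo = s0 + int(above_lo[0])
    i_hi = s0 + int(above_hi[0])
    if i_hi - i_lo + 1 < 3:
        raise DegenerateWindowError(
            f"slope window holds {i_hi - i_lo + 1} samples (< 3)",
            window_ms=_window_ms(i_lo, i_hi),
        )
    y = trace.samples[i_lo:i_hi + 1]
    t = np.arange(y.size) / khz
    t_c = t - t.mean()
    denom = float(t_c @ t_c)
    slope = float(t_c @ (y - y.mean())) / denom
    resid = y - (y.mean() + slope * t_c)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return SlopeMeasure(abs(slope), _window_ms(i_lo, i_hi), r2)


def extract_features(bundle,
                     blank_ms: float = 1.0,
                     search_ms: tuple[float, float] = (2.0, 50.0),
                     frac_lo: float = 0.2,
                     frac_hi: float = 0.8,
                     baseline_ms: float = 5.0) -> pd.DataFrame:
    """Tidy per-(channel, sweep) feature table for a slice bundle.

    Returns one row per channel and sweep with columns ``slice_id``,
    ``condition``, ``channel_id``, ``layer``, ``sweep_index``, ``time_min``,
    ``is_baseline``, ``amplitude_uV``, ``slope_uV_per_ms``.  Sweeps or
    channels whose slope window degenerates (e.g. silent channels) get
    ``NaN`` slope rather than aborting the slice; the amplitude is still
    reported.  Deterministic given the bundle.
    """
    from .protocols import LFS_LTD, TBS_LTP

    layout = bundle.layout
    n_sweeps, n_channels, _ = bundle.traces.shape
    khz = bundle.waveform.sampling_khz
    onset = bundle.stim_onset_sample
    if bundle.protocol.kind in (TBS_LTP, LFS_LTD):
        baseline_end = bundle.protocol.baseline_min
    else:
        baseline_end = np.inf

    layers = [layout.layer_of_channel(ch + 1) for ch in range(n_channels)]
    records: list[dict] = []
    for i in range(n_sweeps):
        time_min = float(bundle.times_min[i])
        for ch in range(n_channels):
            raw = np.asarray(bundle.traces[i, ch], dtype=float)
            row = {
                "slice_id": bundle.slice_id,
                "condition": bundle.condition,
                "channel_id": ch + 1,
                "layer": layers[ch],
                "sweep_index": i,
                "time_min": time_min,
                "is_baseline": time_min < baseline_end,
                "amplitude_uV": np.nan,
                "slope_uV_per_ms": np.nan,
            }
            try:
                trace = FEPSPTrace(raw, khz, onset)
                trace = blank_artifact(trace, blank_ms)
                row["amplitude_uV"] = measure_amplitude(
                    trace, search_ms=search_ms, baseline_ms=baseline_ms)
                row["slope_uV_per_ms"] = measure_slope(
                    trace, frac_lo=frac_lo, frac_hi=frac_hi,
                    search_ms=search_ms, baseline_ms=baseline_ms).slope_uV_per_ms
            except DegenerateWindowError:
                pass           # silent/flat channel: amplitude kept, slope NaN
            except ValueError:
                row["amplitude_uV"] = np.nan     # corrupt sweep: flag everything
            records.append(row)
    return pd.DataFrame.from_records(records)


def extract_ppf_features(bundle,
                         blank_ms: float = 1.0,
                         frac_lo: float = 0.2,
                         frac_hi: float = 0.8,
                         tail_fit_ms: float = 8.0,
                         tail_margin_ms: float = 0.5) -> pd.DataFrame:
    """Paired-pulse feature table: slopes of both responses per sweep.

    The second response rides on the decay tail of the first at short
    intervals; before measuring it, an exponential ``A * exp(-t / tau)`` is
    fitted to the inter-pulse tail and subtracted, and the second response is
    re-referenced to the residual inter-pulse level.  Columns:
    ``channel_id``, ``layer``, ``sweep_index``, ``interval_ms``,
    ``slope1_uV_per_ms``, ``slope2_uV_per_ms``.
    """
    from scipy.optimize import curve_fit

    layout = bundle.layout
    khz = bundle.waveform.sampling_khz
    onset1 = bundle.stim_onset_sample
    n_sweeps, n_channels, n_samples = bundle.traces.shape
    records: list[dict] = []
    for i in range(n_sweeps):
        interval = float(bundle.interval_ms[i])
        onset2 = int(bundle.stim2_onset_sample[i])
        for ch in range(n_channels):
            raw = np.asarray(bundle.traces[i, ch], dtype=float)
            row = {
                "channel_id": ch + 1,
                "layer": layout.layer_of_channel(ch + 1),
                "sweep_index": i,
                "interval_ms": interval,
                "slope1_uV_per_ms": np.nan,
                "slope2_uV_per_ms": np.nan,
            }
            try:
                trace = FEPSPTrace(raw, khz, onset1, stim2_onset_sample=onset2)
                trace = blank_artifact(trace, blank_ms)
                search1 = (2.0, interval - tail_margin_ms)
                row["slope1_uV_per_ms"] = measure_slope(
                    trace, frac_lo=frac_lo, frac_hi=frac_hi,
                    search_ms=search1).slope_uV_per_ms

                # Fit the first response's decay tail and extrapolate it
                # under the second response before measuring.
                samples = trace.samples.copy()
                ref1 = _baseline_ref(samples, onset1, khz, 5.0)
                fit_lo = max(onset1 + trace.ms_to_samples(2.0),
                             onset2 - trace.ms_to_samples(tail_fit_ms))
                fit_hi = onset2 - trace.ms_to_samples(tail_margin_ms)
                if fit_hi - fit_lo >= 10:
                    t_fit = np.arange(fit_lo, fit_hi) / khz
                    y_fit = ref1 - samples[fit_lo:fit_hi]   # positive decaying tail
                    noise_sd = float(np.std(samples[max(0, onset1 - trace.ms_to_samples(5.0)):onset1]))
                    if float(np.mean(y_fit)) > 3.0 * max(noise_sd, 1e-12):
                        t0 = t_fit[0]

                        def _decay(t, a, tau):
                            return a * np.exp(-(t - t0) / tau)

                        try:
                            (a, tau), _ = curve_fit(
                                _decay, t_fit, y_fit,
                                p0=(max(y_fit[0], 1e-6), 8.0 / 1.0),
                                bounds=((0.0, 0.1), (np.inf, 1e3)),
                                maxfev=2000)
                            t_all = np.arange(fit_lo, n_samples) / khz
                            samples[fit_lo:] += _decay(t_all, a, tau)
                        except RuntimeError:
                            pass
                corrected = FEPSPTrace(samples, khz, onset1, stim2_onset_sample=onset2)
                row["slope2_uV_per_ms"] = measure_slope(
                    corrected, frac_lo=frac_lo, frac_hi=frac_hi,
                    search_ms=(2.0, 50.0), onset=onset2).slope_uV_per_ms
            except (DegenerateWindowError, ValueError):
                pass
            records.append(row)
    return pd.DataFrame.from_records(records)
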