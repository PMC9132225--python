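"""Synthetic 8x8 multielectrode-array slice recordings.

The generator produces slice bundles with the statistical structure the
analysis pipeline assumes: a deep-layer stimulation site, negative-going
dual-exponential fEPSPs whose amplitude decays with grid distance from the
stimulus, a biphasic stimulus artifact, evoked sweeps every 0.5 min (15 min
baseline + 60 min follow-up by default), condition-preset plasticity
kinetics after TBS or LFS, paired-pulse protocols, recruited channels
(~0 uV at baseline) at the edge of the activated area, silenced channels
after LFS, and additive Gaussian noise.  Every bundle carries a ground-truth
record so detectors can be scored; readers can strip it for blinded runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEPSPTrace
from .grid import DEEP, OUTSIDE, SUPERFICIAL, GridLayout
from .presets import ConditionPreset, PlasticityKinetics, WaveformParams
from .protocols import IO, LFS_LTD, PPF, TBS_LTP, ProtocolSpec

ACTIVATION_TRUTH_UV = 10.0   # generative "activated channel" amplitude criterion


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


@dataclass
class SliceBundle:
    """One slice's sweeps plus protocol/condition metadata and optional truth.

    ``traces`` has shape ``(n_sweeps, n_channels, n_samples)`` in uV;
    ``times_min`` the sweep timestamps.  For paired-pulse bundles
    ``interval_ms`` and ``stim2_onset_sample`` are per-sweep arrays; for IO
    bundles ``intensity_ma`` is per-sweep.  ``truth`` is a per-channel
    DataFrame present only for synthetic bundles (and absent after a blinded
    read).
    """

    slice_id: str
    mouse_id: str
    condition: str
    layout: GridLayout
    protocol: ProtocolSpec
    waveform: WaveformParams
    times_min: np.ndarray
    traces: np.ndarray
    stim_onset_sample: int
    interval_ms: np.ndarray | None = None
    stim2_onset_sample: np.ndarray | None = None
    intensity_ma: np.ndarray | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float32)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.traces.ndim != 3:
            raise ValueError("traces must be (n_sweeps, n_channels, n_samples)")
        if self.traces.shape[0] != self.times_min.size:
            raise ValueError("times_min length must match sweep count")
        if self.traces.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"expected {self.layout.n_channels} channels, got {self.traces.shape[1]}"
            )
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("sweep times must be strictly increasing")

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    def trace(self, sweep_index: int, channel_id: int) -> FEPSPTrace:
        stim2 = None
        if self.stim2_onset_sample is not None:
            stim2 = int(self.stim2_onset_sample[sweep_index])
        return FEPSPTrace(
            np.asarray(self.traces[sweep_index, channel_id - 1], dtype=float),
            self.waveform.sampling_khz,
            self.stim_onset_sample,
            stim2_onset_sample=stim2,
        )


def waveform_template(params: WaveformParams, total_ms: float | None = None
                      ) -> tuple[np.ndarray, int]:
    """Unit-amplitude fEPSP template and the stimulus-onset sample index.

    The template is 0 before response onset and follows the normalized dual
    exponential afterwards, so ``-amp * template`` has trough ``-amp``.
    """
    if total_ms is None:
        total_ms = params.pre_ms + params.post_ms
    khz = params.sampling_khz
    n = int(round(total_ms * khz))
    onset = int(round(params.pre_ms * khz))
    t_ms = (np.arange(n) - onset) / khz - params.latency_ms
    tr, td = params.tau_rise_ms, params.tau_decay_ms
    f = np.where(t_ms >= 0, np.exp(-np.maximum(t_ms, 0) / td)
                 - np.exp(-np.maximum(t_ms, 0) / tr), 0.0)
    t_peak = params.peak_time_ms
    f_peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return f / f_peak, onset


def artifact_waveform(params: WaveformParams, n_samples: int, onset: int
                      ) -> np.ndarray:
    """Biphasic stimulus artifact: +A then -A over ``artifact_width_ms``."""
    art = np.zeros(n_samples)
    half = max(1, int(round(params.artifact_width_ms * params.sampling_khz / 2)))
    art[onset:onset + half] = params.artifact_amp_uV
    art[onset + half:onset + 2 * half] = -params.artifact_amp_uV
    return art


def simulate_waveform(params: WaveformParams, peak_amp: float, rng_state=None
                      ) -> FEPSPTrace:
    """One evoked sweep on one channel: artifact + fEPSP + Gaussian noise."""
    rng = _as_rng(rng_state)
    template, onset = waveform_template(params)
    samples = -peak_amp * template + artifact_waveform(params, template.size, onset)
    if params.noise_sd_uV > 0:
        samples = samples + rng.normal(0.0, params.noise_sd_uV, template.size)
    return FEPSPTrace(samples, params.sampling_khz, onset)


def simulate_sweep_series(channel_amp: float,
                          kinetics: PlasticityKinetics,
                          protocol: ProtocolSpec,
                          params: WaveformParams | None = None,
                          rng_state=None,
                          plateau: float | None = None
                          ) -> tuple[np.ndarray, np.ndarray, int]:
    """Sweep series for one channel under a TBS or LFS protocol.

    Returns ``(times_min, traces, stim_onset_sample)`` where ``traces`` is
    ``(n_sweeps, n_samples)``.  Pre-induction peak amplitudes are
    ``channel_amp``; post-induction amplitudes are scaled by the kinetics
    multiplier m(t) (with ``plateau`` overriding the group-level value).
    """
    if protocol.kind not in (TBS_LTP, LFS_LTD):
        raise ValueError("sweep series require a TBS_LTP or LFS_LTD protocol")
    params = params or WaveformParams()
    rng = _as_rng(rng_state)
    times = protocol.sweep_times_min()
    m = kinetics.multiplier(times, protocol.induction_time_min, plateau=plateau)
    template, onset = waveform_template(params)
    art = artifact_waveform(params, template.size, onset)
    amps = channel_amp * np.asarray(m)
    traces = -amps[:, None] * template[None, :] + art[None, :]
    if params.noise_sd_uV > 0:
        traces = traces + rng.normal(0.0, params.noise_sd_uV, traces.shape)
    return times, traces, onset


def _base_amplitudes(layout: GridLayout, params: WaveformParams,
                     rng: np.random.Generator) -> np.ndarray:
    """True baseline fEPSP amplitude per channel (distance decay x jitter)."""
    n = layout.n_channels
    amps = np.empty(n)
    for ch in range(1, n + 1):
        d = layout.distance_um(ch)
        amps[ch - 1] = params.amp_at_stim_uV * np.exp(-d / params.decay_length_um)
    if params.amp_jitter_ln_sd > 0:
        amps *= np.exp(rng.normal(0.0, params.amp_jitter_ln_sd, n))
    amps[layout.stim_channel_id - 1] = 0.0    # stimulating electrode records no fEPSP
    return amps


def _pick_recruited(layout: GridLayout, active: np.ndarray, layer: str,
                    mean_n: float, interior_fraction: float,
                    rng: np.random.Generator) -> list[int]:
    """Channels to convert to recruited: silent cells touching the active area."""
    edge_cand, interior_cand = [], []
    for ch in range(1, layout.n_channels + 1):
        if active[ch - 1] or ch == layout.stim_channel_id:
            continue
        if layout.layer_of_channel(ch) != layer:
            continue
        if any(active[nb - 1] for nb in layout.neighbors8(ch)):
            edge_cand.append(ch)
        else:
            interior_cand.append(ch)
    n = min(int(rng.poisson(mean_n)), len(edge_cand) + len(interior_cand))
    chosen: list[int] = []
    for _ in range(n):
        pool = interior_cand if (interior_cand and rng.random() < interior_fraction) \
            else (edge_cand or interior_cand)
        ch = int(rng.choice(pool))
        pool.remove(ch)
        chosen.append(ch)
    return chosen


def _pick_silenced(layout: GridLayout, active: np.ndarray, layer: str,
                   mean_n: float, rng: np.random.Generator) -> list[int]:
    """Active channels at the edge of the activated area to silence after LFS."""
    cand = [
        ch for ch in range(1, layout.n_channels + 1)
        if active[ch - 1]
        and layout.layer_of_channel(ch) == layer
        and (layout.on_border(ch)
             or any(not active[nb - 1] for nb in layout.neighbors8(ch)))
    ]
    n = min(int(rng.poisson(mean_n)), len(cand))
    return [int(c) for c in rng.choice(cand, size=n, replace=False)] if n else []


def simulate_slice(preset: ConditionPreset,
                   protocol: ProtocolSpec | None = None,
                   layout: GridLayout | None = None,
                   rng_state=None,
                   params: WaveformParams | None = None,
                   slice_id: str = "slice-00",
                   mouse_id: str = "mouse-00") -> SliceBundle:
    """Simulate one slice bundle under a condition preset.

    Active channels form a blob around the stimulation site with
    distance-decaying amplitude; per-channel plasticity plateaus scatter
    around the preset's layer value; recruited channels (TBS) sit at the
    edge of the activated area with ~0 uV baseline; silenced channels (LFS)
    are active channels whose response collapses to ~0 uV.  The generative
    ground truth is attached as ``bundle.truth``.
    """
    protocol = protocol or ProtocolSpec()
    layout = layout or GridLayout()
    params = params or WaveformParams()
    rng = _as_rng(rng_state)

    if protocol.kind in (TBS_LTP, LFS_LTD):
        for layer in (SUPERFICIAL, DEEP):
            try:
                preset.kinetics(protocol.kind, layer)
            except KeyError:
                raise ValueError(
                    f"preset {preset.condition!r} lacks a {layer} plateau for "
                    f"{protocol.kind}") from None

    base = _base_amplitudes(layout, params, rng)
    active = base > ACTIVATION_TRUTH_UV
    n_ch = layout.n_channels
    layers = np.array([layout.layer_of_channel(ch) for ch in range(1, n_ch + 1)])

    plateau = np.ones(n_ch)
    recruited = np.zeros(n_ch, dtype=bool)
    recruited_amp = np.zeros(n_ch)
    silenced = np.zeros(n_ch, dtype=bool)

    if protocol.kind in (TBS_LTP, LFS_LTD):
        for layer in (SUPERFICIAL, DEEP):
            kin = preset.kinetics(protocol.kind, layer)
            mask = active & (layers == layer)
            plateau[mask] = np.maximum(
                rng.normal(kin.plateau, kin.channel_sd, int(mask.sum())), 0.0)
    if protocol.kind == TBS_LTP:
        for layer in (SUPERFICIAL, DEEP):
            chans = _pick_recruited(
                layout, active, layer, preset.n_recruited_per_slice.get(layer, 0.0),
                preset.recruited_interior_fraction, rng)
            for ch in chans:
                recruited[ch - 1] = True
                base[ch - 1] = 0.0
                recruited_amp[ch - 1] = max(
                    rng.normal(preset.recruited_amp_uV[layer],
                               preset.recruited_amp_sd_uV), 0.0)
    if protocol.kind == LFS_LTD:
        for layer in (SUPERFICIAL, DEEP):
            for ch in _pick_silenced(
                    layout, active, layer,
                    preset.n_silenced_per_slice.get(layer, 0.0), rng):
                silenced[ch - 1] = True
                plateau[ch - 1] = 0.0

    template, onset = waveform_template(params)
    times = protocol.sweep_times_min()
    interval_ms = stim2_onset = intensity = None

    if protocol.kind in (TBS_LTP, LFS_LTD):
        kin = PlasticityKinetics(1.0, preset.tau_plasticity_min, preset.channel_sd)
        t_ind = protocol.induction_time_min
        # (n_sweeps, n_channels) amplitude matrix.
        amps = np.empty((times.size, n_ch))
        for ch in range(n_ch):
            if recruited[ch]:
                dt = np.maximum(times - t_ind, 0.0)
                rise = np.where(times < t_ind, 0.0,
                                1.0 - np.exp(-dt / preset.tau_plasticity_min))
                amps[:, ch] = recruited_amp[ch] * rise
            elif active[ch]:
                amps[:, ch] = base[ch] * kin.multiplier(times, t_ind, plateau[ch])
            else:
                amps[:, ch] = base[ch]
        art = artifact_waveform(params, template.size, onset)
        traces = -amps[:, :, None] * template[None, None, :] + art[None, None, :]
    elif protocol.kind == PPF:
        total_ms = params.pre_ms + max(protocol.ppf_intervals_ms) + params.post_ms
        template, onset = waveform_template(params, total_ms=total_ms)
        art1 = artifact_waveform(params, template.size, onset)
        n_sweeps = protocol.n_sweeps
        interval_ms = np.repeat(protocol.ppf_intervals_ms,
                                protocol.ppf_sweeps_per_interval).astype(float)
        stim2_onset = onset + np.round(
            interval_ms * params.sampling_khz).astype(int)
        times = np.arange(n_sweeps) * protocol.sample_period_min
        ratios = np.empty((n_sweeps, n_ch))
        for ch in range(n_ch):
            layer = layers[ch]
            curve = preset.ppr_curve.get(layer) or preset.ppr_curve.get(DEEP, {})
            ratios[:, ch] = [curve.get(iv, 1.0) for iv in interval_ms]
        traces = np.empty((n_sweeps, n_ch, template.size))
        for i in range(n_sweeps):
            shift = int(stim2_onset[i] - onset)
            t2 = np.zeros_like(template)
            t2[shift:] = template[:template.size - shift]
            a2 = np.zeros_like(art1)
            a2[shift:] = art1[:art1.size - shift]
            traces[i] = (-base[None, :].T * (template[None, :] + ratios[i][:, None] * t2[None, :])
                         + art1[None, :] + a2[None, :])
    elif protocol.kind == IO:
        intensity = np.repeat(protocol.io_intensities_ma,
                              protocol.io_sweeps_per_intensity).astype(float)
        times = np.arange(intensity.size) * protocol.sample_period_min
        # Saturating recruitment of fibers with intensity; the preset base
        # amplitudes correspond to the top of the tested range.
        i_half = 0.4 * max(protocol.io_intensities_ma)
        gain = intensity ** 2 / (intensity ** 2 + i_half ** 2)
        gain = gain / gain.max()
        art = artifact_waveform(params, template.size, onset)
        traces = -(gain[:, None] * base[None, :])[:, :, None] * template[None, None, :] \
            + art[None, None, :]
    else:
        raise ValueError(f"unsupported protocol kind {protocol.kind!r}")

    if params.noise_sd_uV > 0:
        traces = traces + rng.normal(0.0, params.noise_sd_uV, traces.shape)

    truth = pd.DataFrame({
        "channel_id": np.arange(1, n_ch + 1),
        "row": [layout.rc(ch)[0] for ch in range(1, n_ch + 1)],
        "col": [layout.rc(ch)[1] for ch in range(1, n_ch + 1)],
        "layer": layers,
        "base_amp_uV": base,
        "active": active,
        "plateau": plateau,
        "recruited": recruited,
        "recruited_amp_uV": recruited_amp,
        "silenced": silenced,
    })
    return SliceBundle(
        slice_id=slice_id, mouse_id=mouse_id, condition=preset.condition,
        layout=layout, protocol=protocol, waveform=params,
        times_min=times, traces=traces, stim_onset_sample=onset,
        interval_ms=interval_ms, stim2_onset_sample=stim2_onset,
        intensity_ma=intensity, truth=truth,
    )


def simulate_cohort(preset: ConditionPreset,
                    n_slices: int,
                    protocol: ProtocolSpec | None = None,
                    layout: GridLayout | None = None,
                    seed: int | np.random.SeedSequence = 0,
                    params: WaveformParams | None = None) -> list[SliceBundle]:
    """Independent slices with per-slice sub-seeds derived from ``seed``."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    protocol = protocol or ProtocolSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_slices)
    bundles = []
    for i, child in enumerate(children):
        bundles.append(simulate_slice(
            preset, protocol, layout, np.random.default_rng(child), params,
            slice_id=f"{preset.condition}-{protocol.kind.lower()}-s{i:02d}",
            mouse_id=f"mouse-{i:02d}"))
    return bundles
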