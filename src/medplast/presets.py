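"""Generative parameters: waveform shape, plasticity kinetics, condition presets.

The condition presets hard-code the reported group outcomes of the
observational-fear experiment as generative truth, so the analysis pipeline
can be validated by parameter recovery:

* ``naive``        -- home-cage controls: strong LTP, strong LTD, silent-synapse
                      recruitment after TBS and silencing after LFS.
* ``observer``     -- psychological stress (watched a cage-mate being shocked):
                      reduced LTP, weaker LTD, recruitment with larger
                      superficial-layer amplitudes.
* ``demonstrator`` -- physiological stress (received foot shocks): LTP loss,
                      weak LTD, and no recruitment or silencing at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .grid import DEEP, SUPERFICIAL


@dataclass(frozen=True)
class WaveformParams:
    """Shape and noise parameters of a single evoked sweep.

    The fEPSP is modeled as a negative-going dual exponential
    ``f(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` starting ``latency_ms``
    after the stimulus, scaled so its extremum equals ``-peak_amp``.  The
    stimulus itself leaves a brief biphasic artifact at onset.  Channel
    amplitude falls off with Euclidean grid distance ``d`` from the
    stimulation site as ``exp(-d / decay_length_um)``.
    """

    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 8.0
    latency_ms: float = 2.5          # synaptic + conduction delay
    artifact_amp_uV: float = 200.0
    artifact_width_ms: float = 0.4
    noise_sd_uV: float = 0.25        # additive white Gaussian, per sample
    sampling_khz: float = 20.0
    pre_ms: float = 6.0              # recorded context before stimulus onset
    post_ms: float = 55.0            # recorded window after (last) stimulus
    decay_length_um: float = 300.0
    amp_at_stim_uV: float = 60.0     # evoked amplitude at zero grid distance
    amp_jitter_ln_sd: float = 0.25   # lognormal between-channel amplitude scatter

    def __post_init__(self) -> None:
        if self.sampling_khz <= 0:
            raise ValueError("sampling rate must be positive")
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be >= 0")
        for name in ("latency_ms", "artifact_width_ms", "pre_ms",
                     "decay_length_um", "amp_at_stim_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.post_ms < 50.0:
            raise ValueError("post_ms must cover >= 50 ms after the stimulus")

    @property
    def peak_time_ms(self) -> float:
        """Analytic time of the dual-exponential extremum, after response onset."""
        import math

        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "WaveformParams":
        return cls(**d)


@dataclass(frozen=True)
class PlasticityKinetics:
    """Mono-exponential approach of the response to a per-channel plateau.

    The multiplier applied to a channel's response is 1 before induction and
    ``m(t) = 1 + (plateau - 1) * (1 - exp(-(t - t_ind) / tau))`` afterwards,
    so the mean over a late window approximates ``plateau``.  ``plateau`` is
    a unitless factor (>1 LTP, <1 LTD, 0 silencing); individual channels
    scatter around it with SD ``channel_sd``.
    """

    plateau: float = 1.0
    tau_plasticity_min: float = 5.0
    channel_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.plateau < 0:
            raise ValueError("plateau must be >= 0")
        if self.tau_plasticity_min <= 0:
            raise ValueError("tau_plasticity_min must be positive")
        if self.channel_sd < 0:
            raise ValueError("channel_sd must be >= 0")

    def multiplier(self, t_min, t_induction_min: float, plateau: float | None = None):
        """Vectorized m(t); ``plateau`` overrides the group-level value."""
        import numpy as np

        p = self.plateau if plateau is None else plateau
        t = np.asarray(t_min, dtype=float)
        dt = t - t_induction_min
        m = np.where(dt < 0, 1.0, 1.0 + (p - 1.0) * (1.0 - np.exp(-np.maximum(dt, 0.0) / self.tau_plasticity_min)))
        return m if m.ndim else float(m)


@dataclass(frozen=True)
class ConditionPreset:
    """Per-condition generative truth (plateaus, PPR curves, recruitment)."""

    condition: str
    ltp_plateau: dict[str, float]            # layer -> multiplier after TBS
    ltd_plateau: dict[str, float]            # layer -> multiplier after LFS
    ppr_curve: dict[str, dict[float, float]]  # layer -> interval_ms -> ratio
    n_recruited_per_slice: dict[str, float]  # layer -> expected count (TBS)
    recruited_amp_uV: dict[str, float]       # layer -> asymptotic amplitude
    n_silenced_per_slice: dict[str, float]   # layer -> expected count (LFS)
    recruited_amp_sd_uV: float = 1.0
    recruited_interior_fraction: float = 0.0  # stress knob for the edge classifier
    channel_sd: float = 0.05                 # between-channel plateau scatter
    tau_plasticity_min: float = 5.0

    def kinetics(self, protocol_kind: str, layer: str) -> PlasticityKinetics:
        from .protocols import LFS_LTD, TBS_LTP

        if protocol_kind == TBS_LTP:
            plateau = self.ltp_plateau[layer]
        elif protocol_kind == LFS_LTD:
            plateau = self.ltd_plateau[layer]
        else:
            raise ValueError(f"protocol kind {protocol_kind!r} has no plasticity preset")
        return PlasticityKinetics(
            plateau=plateau,
            tau_plasticity_min=self.tau_plasticity_min,
            channel_sd=self.channel_sd,
        )


def _ppr(sup50: float) -> dict[str, dict[float, float]]:
    base = {25.0: 1.40, 50.0: 1.20, 75.0: 1.10, 100.0: 1.05}
    sup = dict(base)
    sup[50.0] = sup50
    return {SUPERFICIAL: sup, DEEP: dict(base)}


# Plateaus encode the reported last-10-min group means (% of baseline / 100);
# recruited amplitudes are the reported late-window means in uV.  Demonstrator
# animals show neither recruitment nor silencing.
PRESETS: dict[str, ConditionPreset] = {
    "naive": ConditionPreset(
        condition="naive",
        ltp_plateau={SUPERFICIAL: 1.54145, DEEP: 1.48872},
        ltd_plateau={SUPERFICIAL: 0.67375, DEEP: 0.69583},
        ppr_curve=_ppr(1.20),
        n_recruited_per_slice={SUPERFICIAL: 1.333, DEEP: 3.667},
        recruited_amp_uV={SUPERFICIAL: 11.506, DEEP: 13.937},
        n_silenced_per_slice={SUPERFICIAL: 1.400, DEEP: 1.200},
    ),
    "observer": ConditionPreset(
        condition="observer",
        ltp_plateau={SUPERFICIAL: 1.28799, DEEP: 1.32249},
        ltd_plateau={SUPERFICIAL: 0.84644, DEEP: 0.78943},
        ppr_curve=_ppr(1.05),
        n_recruited_per_slice={SUPERFICIAL: 1.800, DEEP: 1.800},
        recruited_amp_uV={SUPERFICIAL: 18.504, DEEP: 13.411},
        n_silenced_per_slice={SUPERFICIAL: 2.333, DEEP: 1.667},
    ),
    "demonstrator": ConditionPreset(
        condition="demonstrator",
        ltp_plateau={SUPERFICIAL: 1.07795, DEEP: 1.07558},
        ltd_plateau={SUPERFICIAL: 0.83772, DEEP: 0.80480},
        ppr_curve=_ppr(1.06),
        n_recruited_per_slice={SUPERFICIAL: 0.0, DEEP: 0.0},
        recruited_amp_uV={SUPERFICIAL: 0.0, DEEP: 0.0},
        n_silenced_per_slice={SUPERFICIAL: 0.0, DEEP: 0.0},
    ),
}


def get_preset(condition: str, **overrides) -> ConditionPreset:
    try:
        preset = PRESETS[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r}; known: {sorted(PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset
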