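"""Stimulation protocol descriptions.

Four protocol kinds cover the experiments the pipeline analyzes:

* ``IO`` -- input-output calibration (single pulses at increasing intensity),
* ``PPF`` -- paired pulses at 25/50/75/100 ms inter-pulse intervals,
* ``TBS_LTP`` -- baseline, theta-burst stimulation (4 pulses at 100 Hz per
  burst), then post-induction follow-up,
* ``LFS_LTD`` -- baseline, low-frequency stimulation (1 Hz, 900 pulses),
  then post-induction follow-up.

Evoked responses are sampled every 0.5 min; the baseline lasts 15 min.  The
post-induction duration is a configurable default (60 min) chosen so that a
"last 10 min" analysis window sits on the plateau of the plasticity time
course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IO = "IO"
PPF = "PPF"
TBS_LTP = "TBS_LTP"
LFS_LTD = "LFS_LTD"
PROTOCOL_KINDS = (IO, PPF, TBS_LTP, LFS_LTD)


@dataclass(frozen=True)
class ProtocolSpec:
    kind: str = TBS_LTP
    pulse_width_ms: float = 0.2          # biphasic constant-current pulse
    baseline_min: float = 15.0
    post_min: float = 60.0
    sample_period_min: float = 0.5
    tbs_pulses_per_burst: int = 4        # at 100 Hz within each burst
    tbs_n_bursts: int = 10               # bursts delivered at 5 Hz
    lfs_freq_hz: float = 1.0
    lfs_n_pulses: int = 900
    ppf_intervals_ms: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)
    ppf_sweeps_per_interval: int = 4
    io_intensities_ma: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    io_sweeps_per_intensity: int = 2

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.sample_period_min <= 0:
            raise ValueError("sample_period_min must be positive")
        for name in ("baseline_min", "post_min"):
            span = getattr(self, name)
            n = span / self.sample_period_min
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"sample_period_min must divide {name} ({span} / "
                    f"{self.sample_period_min} is not integral)"
                )
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.lfs_freq_hz <= 0 or self.lfs_n_pulses <= 0:
            raise ValueError("LFS parameters must be positive")

    @property
    def lfs_delivery_s(self) -> float:
        """Total LFS delivery time in seconds (900 pulses at 1 Hz -> 900 s)."""
        return self.lfs_n_pulses / self.lfs_freq_hz

    @property
    def n_baseline_sweeps(self) -> int:
        return round(self.baseline_min / self.sample_period_min)

    @property
    def n_post_sweeps(self) -> int:
        return round(self.post_min / self.sample_period_min)

    @property
    def n_sweeps(self) -> int:
        if self.kind in (TBS_LTP, LFS_LTD):
            return self.n_baseline_sweeps + self.n_post_sweeps
        if self.kind == PPF:
            return len(self.ppf_intervals_ms) * self.ppf_sweeps_per_interval
        return len(self.io_intensities_ma) * self.io_sweeps_per_intensity

    @property
    def induction_time_min(self) -> float:
        """Time of plasticity induction relative to recording start."""
        if self.kind not in (TBS_LTP, LFS_LTD):
            raise ValueError(f"{self.kind} protocol has no induction")
        return self.baseline_min

    def sweep_times_min(self):
        import numpy as np

        return np.arange(self.n_sweeps) * self.sample_period_min

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "pulse_width_ms": self.pulse_width_ms,
            "baseline_min": self.baseline_min,
            "post_min": self.post_min,
            "sample_period_min": self.sample_period_min,
            "tbs_pulses_per_burst": self.tbs_pulses_per_burst,
            "tbs_n_bursts": self.tbs_n_bursts,
            "lfs_freq_hz": self.lfs_freq_hz,
            "lfs_n_pulses": self.lfs_n_pulses,
            "ppf_intervals_ms": list(self.ppf_intervals_ms),
            "ppf_sweeps_per_interval": self.ppf_sweeps_per_interval,
            "io_intensities_ma": list(self.io_intensities_ma),
            "io_sweeps_per_intensity": self.io_sweeps_per_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        for key in ("ppf_intervals_ms", "io_intensities_ma"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
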