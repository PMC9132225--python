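"""Slice-bundle containers and tidy result tables.

Two dialects share one in-memory model (:class:`~medplast.simulate.SliceBundle`):

* **HDF5** (primary): ``/meta`` group whose ``json`` attribute holds the
  metadata record; ``/sweeps/{i}`` float32 datasets of shape
  ``[n_channels, n_samples]`` with ``time_min`` and ``stim_onset_sample``
  attributes (plus ``interval_ms`` / ``stim2_onset_sample`` /
  ``intensity_ma`` where the protocol has them); the generative ground
  truth, when present, under a clearly separated ``/truth`` group so
  analysis code can be run blinded.
* **CSV directory** (fallback): ``metadata.json``, one ``sweep_%04d.csv``
  per sweep (one column per channel, header ``ch01..``), and ``truth.csv``.

Voltages are stored as float32 microvolts, times as float64 minutes,
sample indices 0-based.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import GridLayout
from .presets import WaveformParams
from .protocols import ProtocolSpec
from .simulate import SliceBundle

_FORMAT = "medplast-bundle"
_VERSION = 1

_META_KEYS = ("slice_id", "mouse_id", "condition", "layout", "protocol",
              "waveform", "stim_onset_sample", "n_sweeps", "n_channels",
              "n_samples")


class BundleFormatError(ValueError):
    """A container violates the documented bundle layout."""


def _meta_record(bundle: SliceBundle) -> dict:
    return {
        "format": _FORMAT,
        "version": _VERSION,
        "slice_id": bundle.slice_id,
        "mouse_id": bundle.mouse_id,
        "condition": bundle.condition,
        "layout": bundle.layout.to_dict(),
        "protocol": bundle.protocol.to_dict(),
        "waveform": bundle.waveform.to_dict(),
        "stim_onset_sample": int(bundle.stim_onset_sample),
        "n_sweeps": int(bundle.n_sweeps),
        "n_channels": int(bundle.traces.shape[1]),
        "n_samples": int(bundle.traces.shape[2]),
    }


def write_bundle(bundle: SliceBundle, path: str | Path,
                 dialect: str | None = None) -> Path:
    """Write a bundle as HDF5 (``*.h5``/``*.hdf5``) or a CSV directory.

    The dialect is inferred from the path suffix unless given explicitly
    (``"hdf5"`` or ``"csv"``).  Returns the path written.
    """
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if dialect == "hdf5":
        return _write_hdf5(bundle, path)
    if dialect == "csv":
        return _write_csvdir(bundle, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_hdf5(bundle: SliceBundle, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        meta = h5.create_group("meta")
        meta.attrs["json"] = json.dumps(_meta_record(bundle), sort_keys=True)
        sweeps = h5.create_group("sweeps")
        for i in range(bundle.n_sweeps):
            ds = sweeps.create_dataset(
                str(i), data=np.asarray(bundle.traces[i], dtype=np.float32))
            ds.attrs["time_min"] = float(bundle.times_min[i])
            ds.attrs["stim_onset_sample"] = int(bundle.stim_onset_sample)
            if bundle.interval_ms is not None:
                ds.attrs["interval_ms"] = float(bundle.interval_ms[i])
                ds.attrs["stim2_onset_sample"] = int(bundle.stim2_onset_sample[i])
            if bundle.intensity_ma is not None:
                ds.attrs["intensity_ma"] = float(bundle.intensity_ma[i])
        if bundle.truth is not None:
            truth = h5.create_group("truth")
            truth.attrs["json"] = bundle.truth.to_json(orient="records")
    return path


def _write_csvdir(bundle: SliceBundle, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    meta = _meta_record(bundle)
    meta["times_min"] = [float(t) for t in bundle.times_min]
    if bundle.interval_ms is not None:
        meta["interval_ms"] = [float(v) for v in bundle.interval_ms]
        meta["stim2_onset_sample"] = [int(v) for v in bundle.stim2_onset_sample]
    if bundle.intensity_ma is not None:
        meta["intensity_ma"] = [float(v) for v in bundle.intensity_ma]
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    n_channels = bundle.traces.shape[1]
    header = ",".join(f"ch{c + 1:02d}" for c in range(n_channels))
    for i in range(bundle.n_sweeps):
        np.savetxt(path / f"sweep_{i:04d}.csv",
                   np.asarray(bundle.traces[i], dtype=np.float32).T,
                   delimiter=",", header=header, comments="", fmt="%.9g")
    if bundle.truth is not None:
        bundle.truth.to_csv(path / "truth.csv", index=False)
    return path


# -- raw part readers (shared by read_bundle and validate_bundle) -----------

def _read_parts(path: Path, blinded: bool) -> dict:
    """Load raw container parts with layout checks but no semantic checks."""
    if not path.exists():
        raise FileNotFoundError(path)
    return _parts_hdf5(path, blinded) if path.is_file() else _parts_csvdir(path, blinded)


def _check_meta(meta: dict, where: str) -> None:
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise BundleFormatError(f"{where}: metadata missing {missing[0]!r}")


def _parts_hdf5(path: Path, blinded: bool) -> dict:
    with h5py.File(path, "r") as h5:
        if "meta" not in h5:
            raise BundleFormatError(f"{path}: missing /meta group")
        meta = json.loads(h5["meta"].attrs["json"])
        _check_meta(meta, str(path))
        if "sweeps" not in h5:
            raise BundleFormatError(f"{path}: missing /sweeps group")
        sweeps = h5["sweeps"]
        traces, times = [], []
        interval, stim2, intensity = [], [], []
        for i in range(meta["n_sweeps"]):
            key = str(i)
            if key not in sweeps:
                raise BundleFormatError(f"{path}: missing dataset /sweeps/{i}")
            ds = sweeps[key]
            if ds.shape != (meta["n_channels"], meta["n_samples"]):
                raise BundleFormatError(
                    f"{path}: /sweeps/{i} has shape {ds.shape}, expected "
                    f"{meta['n_channels']} channels x {meta['n_samples']} samples")
            traces.append(ds[()])
            times.append(float(ds.attrs["time_min"]))
            if "interval_ms" in ds.attrs:
                interval.append(float(ds.attrs["interval_ms"]))
                stim2.append(int(ds.attrs["stim2_onset_sample"]))
            if "intensity_ma" in ds.attrs:
                intensity.append(float(ds.attrs["intensity_ma"]))
        truth = None
        if not blinded and "truth" in h5:
            truth = pd.read_json(_stdio.StringIO(h5["truth"].attrs["json"]),
                                 orient="records")
    return {"meta": meta, "times": times, "traces": np.stack(traces),
            "interval_ms": interval or None, "stim2": stim2 or None,
            "intensity": intensity or None, "truth": truth}


def _parts_csvdir(path: Path, blinded: bool) -> dict:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise BundleFormatError(f"{path}: missing metadata.json")
    meta = json.loads(meta_path.read_text())
    _check_meta(meta, str(path))
    traces = []
    for i in range(meta["n_sweeps"]):
        f = path / f"sweep_{i:04d}.csv"
        if not f.exists():
            raise BundleFormatError(f"{path}: missing {f.name}")
        arr = np.loadtxt(f, delimiter=",", skiprows=1, dtype=np.float32, ndmin=2).T
        if arr.shape != (meta["n_channels"], meta["n_samples"]):
            raise BundleFormatError(
                f"{path}: {f.name} has shape {arr.shape}, expected "
                f"{meta['n_channels']} channels x {meta['n_samples']} samples")
        traces.append(arr)
    truth = None
    truth_path = path / "truth.csv"
    if not blinded and truth_path.exists():
        truth = pd.read_csv(truth_path)
    return {"meta": meta, "times": meta["times_min"], "traces": np.stack(traces),
            "interval_ms": meta.get("interval_ms"),
            "stim2": meta.get("stim2_onset_sample"),
            "intensity": meta.get("intensity_ma"), "truth": truth}


def read_bundle(path: str | Path, blinded: bool = False) -> SliceBundle:
    """Read a bundle from either dialect; ``blinded=True`` strips the truth."""
    parts = _read_parts(Path(path), blinded)
    meta = parts["meta"]
    return SliceBundle(
        slice_id=meta["slice_id"],
        mouse_id=meta["mouse_id"],
        condition=meta["condition"],
        layout=GridLayout.from_dict(meta["layout"]),
        protocol=ProtocolSpec.from_dict(meta["protocol"]),
        waveform=WaveformParams.from_dict(meta["waveform"]),
        times_min=np.asarray(parts["times"], dtype=float),
        traces=np.asarray(parts["traces"], dtype=np.float32),
        stim_onset_sample=int(meta["stim_onset_sample"]),
        interval_ms=None if parts["interval_ms"] is None
        else np.asarray(parts["interval_ms"], float),
        stim2_onset_sample=None if parts["stim2"] is None
        else np.asarray(parts["stim2"], int),
        intensity_ma=None if parts["intensity"] is None
        else np.asarray(parts["intensity"], float),
        truth=parts["truth"],
    )


@dataclass
class ValidationReport:
    """Outcome of content checks on a stored bundle."""

    path: str
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, passed, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    @property
    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]

    def to_dict(self) -> dict:
        return {"path": self.path, "passed": self.passed,
                "checks": [{"name": n, "passed": ok, "detail": d}
                           for n, ok, d in self.checks]}


def validate_bundle(path: str | Path) -> ValidationReport:
    """Content checks on a stored bundle; reports problems, never raises on them.

    Checks: container layout, monotone sweep timestamps at the declared
    sampling period, declared trace geometry, complete layer assignment,
    finite samples.  Truly unreadable paths still raise I/O errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ValidationReport(str(path))
    try:
        parts = _read_parts(path, blinded=False)
    except (BundleFormatError, KeyError) as exc:
        report.add("container layout", False, str(exc))
        return report
    report.add("container layout", True)
    meta = parts["meta"]

    times = np.asarray(parts["times"], dtype=float)
    dt = np.diff(times)
    monotone = bool(np.all(dt > 0)) if dt.size else True
    report.add("monotone time stamps", monotone,
               "" if monotone else "non-monotone time stamps")
    try:
        period = float(meta["protocol"]["sample_period_min"])
        regular = bool(np.allclose(dt, period, atol=1e-9)) if dt.size else True
    except (KeyError, TypeError):
        regular, period = False, float("nan")
    report.add("declared sampling period", regular,
               "" if regular else f"sweep spacing differs from {period} min")

    try:
        layout = GridLayout.from_dict(meta["layout"])
        grid_ok = parts["traces"].shape[1] == layout.n_channels
        detail = "" if grid_ok else (
            f"expected {layout.n_channels} channels, got {parts['traces'].shape[1]}")
        layer_ok, layer_detail = True, ""
    except ValueError as exc:
        grid_ok, detail = True, ""
        layer_ok, layer_detail = False, f"incomplete layer assignment ({exc})"
    else:
        missing = [c for c in range(layout.n_cols)
                   if c not in layout.layer_of_column]
        if missing:
            layer_ok, layer_detail = False, "incomplete layer assignment"
    report.add("grid completeness", grid_ok, detail)
    report.add("layer assignment", layer_ok, layer_detail)
    finite = bool(np.all(np.isfinite(parts["traces"])))
    report.add("finite samples", finite, "" if finite else "non-finite samples")
    return report


def write_feature_table(features: pd.DataFrame, path: str | Path) -> Path:
    """Tidy feature CSV: header row, UTF-8, '.' decimal, stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False, float_format="%.9g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
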