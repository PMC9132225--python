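"""One-command orchestration: simulate/ingest -> features -> QC -> plasticity
-> recruitment -> spatial maps -> group report.

All randomness flows from a single root seed through named sub-streams, so a
given (config, seed) pair reproduces every output byte for byte.  The run
manifest records inputs, seeds, and every slice excluded by QC with its
reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import extract_features, extract_ppf_features
from .grid import GridLayout, OUTSIDE
from .io import read_bundle, write_bundle, write_feature_table
from .plasticity import (SILENT_THRESHOLD_UV, compute_ppr, detect_recruited,
                         detect_silenced, normalize_to_baseline,
                         summarize_last_window)
from .presets import WaveformParams, get_preset
from .protocols import LFS_LTD, PPF, TBS_LTP, ProtocolSpec
from .qc import (ACTIVATION_THRESHOLD_UV, CV_LIMIT, EXCLUSION_FRACTION,
                 QCReport, build_qc_report)
from .simulate import SliceBundle, simulate_cohort
from .spatial import build_spatial_map, count_by_layer, flag_edge_channels


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see the CLI for the YAML mirror."""

    # input: either existing bundle paths, or a simulation request
    bundle_paths: list[str] = field(default_factory=list)
    condition: str = "naive"
    protocol_kind: str = TBS_LTP
    n_slices: int = 1
    seed: int = 0
    # thresholds / windows
    activation_threshold_uV: float = ACTIVATION_THRESHOLD_UV
    cv_limit: float = CV_LIMIT
    exclusion_fraction: float = EXCLUSION_FRACTION
    silent_threshold_uV: float = SILENT_THRESHOLD_UV
    potentiated_pct: float = 115.0
    depressed_pct: float = 85.0
    last_window_min: float = 10.0
    stability_window_min: float = 15.0
    # outputs
    out_dir: str | None = None
    save_bundles: bool = False

    def __post_init__(self) -> None:
        for name in ("activation_threshold_uV", "exclusion_fraction",
                     "silent_threshold_uV", "last_window_min",
                     "stability_window_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class SliceResult:
    """Per-slice analysis products (None where not applicable)."""

    slice_id: str
    qc: QCReport
    features: pd.DataFrame
    calls: pd.DataFrame | None = None
    layer_summary: pd.DataFrame | None = None
    recruitment: pd.DataFrame | None = None
    spatial_map: object | None = None
    layer_counts: pd.DataFrame | None = None
    ppr: pd.DataFrame | None = None


def analyze_bundle(bundle: SliceBundle, config: PipelineConfig | None = None
                   ) -> SliceResult:
    """Run features -> QC -> plasticity/recruitment -> map for one bundle.

    Excluded slices stop after QC (their result carries only features + QC).
    """
    cfg = config or PipelineConfig()
    features = extract_features(bundle)
    qc = build_qc_report(
        features, slice_id=bundle.slice_id,
        threshold_uV=cfg.activation_threshold_uV,
        window_min=cfg.stability_window_min,
        cv_limit=cfg.cv_limit,
        exclusion_fraction=cfg.exclusion_fraction)
    result = SliceResult(bundle.slice_id, qc, features)
    if qc.slice_excluded:
        return result

    kind = bundle.protocol.kind
    if kind == PPF:
        result.ppr = compute_ppr(extract_ppf_features(bundle))
        return result
    if kind not in (TBS_LTP, LFS_LTD):
        return result

    if kind == TBS_LTP:
        recruitment = detect_recruited(
            features, qc, threshold_uV=cfg.activation_threshold_uV,
            silent_threshold_uV=cfg.silent_threshold_uV,
            post_window_min=cfg.last_window_min)
    else:
        recruitment = detect_silenced(
            features, qc, threshold_uV=cfg.activation_threshold_uV,
            silent_threshold_uV=cfg.silent_threshold_uV,
            post_window_min=cfg.last_window_min)
    result.recruitment = recruitment

    normalized = normalize_to_baseline(features, qc)
    # Silenced channels are a separate event (response -> ~0 uV), not an
    # LTD magnitude; keep them out of the plateau estimate.
    silenced_ids = set(recruitment.loc[recruitment.silenced, "channel_id"])
    if silenced_ids:
        normalized = normalized.loc[~normalized.channel_id.isin(silenced_ids)]
    calls, layer_summary = summarize_last_window(
        normalized, window_min=cfg.last_window_min,
        potentiated_pct=cfg.potentiated_pct,
        depressed_pct=cfg.depressed_pct)
    result.calls = calls
    result.layer_summary = layer_summary
    result.spatial_map = build_spatial_map(
        calls, recruitment, qc, bundle.layout, slice_id=bundle.slice_id)
    result.layer_counts = count_by_layer(result.spatial_map)
    return result


@dataclass
class CohortResult:
    """Pooled products over the retained slices of one cohort."""

    condition: str
    protocol_kind: str
    slice_results: list[SliceResult]
    excluded: list[tuple[str, str]]                 # (slice_id, reason)
    calls: pd.DataFrame
    layer_summary: pd.DataFrame                     # channel-pooled mean/SEM/n
    recruitment: pd.DataFrame
    layer_counts: pd.DataFrame
    ppr: pd.DataFrame

    def layer_mean(self, layer: str) -> float:
        row = self.layer_summary.loc[self.layer_summary.layer == layer]
        return float(row.mean_pct.iloc[0]) if len(row) else float("nan")


def analyze_cohort(bundles: list[SliceBundle],
                   config: PipelineConfig | None = None) -> CohortResult:
    """Analyze each slice and pool channel-level results across the cohort.

    The group summary uses the channel as the unit of analysis (mean +/- SEM
    over all retained channels of a layer, pooled across slices).
    """
    cfg = config or PipelineConfig()
    results, excluded = [], []
    for bundle in bundles:
        res = analyze_bundle(bundle, cfg)
        results.append(res)
        if res.qc.slice_excluded:
            excluded.append((res.slice_id, res.qc.exclusion_reason))
    retained = [r for r in results if not r.qc.slice_excluded]
    if not retained:
        raise PipelineError("all slices excluded")

    def _concat(frames: list) -> pd.DataFrame:
        frames = [f for f in frames if f is not None and len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    calls = _concat([r.calls for r in retained])
    recruitment = _concat([
        r.recruitment.assign(slice_id=r.slice_id) for r in retained
        if r.recruitment is not None])
    layer_counts = _concat([r.layer_counts for r in retained])
    ppr = _concat([r.ppr.assign(slice_id=r.slice_id) for r in retained
                   if r.ppr is not None])

    if len(calls):
        grp = calls.loc[calls.layer != OUTSIDE].groupby("layer")["last_window_mean_pct"]
        layer_summary = grp.agg(
            mean_pct="mean",
            sem_pct=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x)))
            if len(x) > 1 else np.nan,
            n_channels="count").reset_index()
    else:
        layer_summary = pd.DataFrame(
            columns=["layer", "mean_pct", "sem_pct", "n_channels"])

    condition = bundles[0].condition if bundles else ""
    kind = bundles[0].protocol.kind if bundles else ""
    return CohortResult(condition, kind, results, excluded, calls,
                        layer_summary, recruitment, layer_counts, ppr)


def recruited_amplitude_summary(cohort: CohortResult) -> pd.DataFrame:
    """Mean final-window amplitude of recruited channels, per layer."""
    rec = cohort.recruitment
    if not len(rec):
        return pd.DataFrame(columns=["layer", "mean_amp_uV", "n_channels"])
    sel = rec.loc[rec.recruited & (rec.layer != OUTSIDE)]
    if not len(sel):
        return pd.DataFrame(columns=["layer", "mean_amp_uV", "n_channels"])
    return (sel.groupby("layer")["post_window_amp_uV"]
            .agg(mean_amp_uV="mean", n_channels="count").reset_index())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a full run and return the manifest.

    With ``bundle_paths`` the slices are read (blinded) from disk; otherwise
    a cohort is simulated under the configured condition preset.  When
    ``out_dir`` is set, tidy CSVs (features, QC, calls, recruitment, layer
    summaries) and the JSON manifest are written there deterministically.
    """
    if config.bundle_paths:
        bundles = [read_bundle(p, blinded=True) for p in config.bundle_paths]
        source = {"kind": "files", "paths": list(config.bundle_paths)}
    else:
        preset = get_preset(config.condition)
        bundles = simulate_cohort(
            preset, config.n_slices, ProtocolSpec(kind=config.protocol_kind),
            GridLayout(), seed=config.seed)
        source = {"kind": "simulation", "condition": config.condition,
                  "protocol": config.protocol_kind,
                  "n_slices": config.n_slices, "seed": config.seed}

    cohort = analyze_cohort(bundles, config)

    manifest = {
        "medplast_version": __version__,
        "seed": config.seed,
        "source": source,
        "n_slices": len(bundles),
        "n_retained": len(bundles) - len(cohort.excluded),
        "excluded": [{"slice_id": s, "reason": r} for s, r in cohort.excluded],
        "condition_groups": sorted({b.condition for b in bundles}),
        "layer_summary": cohort.layer_summary.to_dict(orient="records"),
        "outputs": [],
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        provenance = f"# medplast {__version__} seed={config.seed}\n"

        def _save(df: pd.DataFrame, name: str) -> None:
            p = out / name
            with open(p, "w", encoding="utf-8") as fh:
                fh.write(provenance)
                df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")
            manifest["outputs"].append(name)

        features_all = pd.concat([r.features for r in cohort.slice_results],
                                 ignore_index=True)
        _save(features_all, "features.csv")
        if len(cohort.calls):
            _save(cohort.calls, "calls.csv")
            _save(cohort.layer_summary, "layer_summary.csv")
        if len(cohort.recruitment):
            _save(cohort.recruitment, "recruitment.csv")
        if len(cohort.layer_counts):
            _save(cohort.layer_counts, "layer_counts.csv")
        if len(cohort.ppr):
            _save(cohort.ppr, "ppr.csv")
        qc_blob = {"reports": [r.qc.to_dict() for r in cohort.slice_results]}
        (out / "qc.json").write_text(json.dumps(qc_blob, indent=1, sort_keys=True,
                                                allow_nan=True))
        manifest["outputs"].append("qc.json")
        if config.save_bundles:
            for b in bundles:
                write_bundle(b, out / f"{b.slice_id}.h5")
                manifest["outputs"].append(f"{b.slice_id}.h5")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest
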