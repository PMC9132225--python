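"""Normalization, last-window calls, PPR, recruitment/silencing detectors."""

import numpy as np
import pandas as pd
import pytest

from medplast import (LFS_LTD, PPF, TBS_LTP, PlasticityKinetics, ProtocolSpec,
                      WaveformParams, build_qc_report, compute_ppr,
                      detect_recruited, detect_silenced, extract_features,
                      extract_ppf_features, get_preset, normalize_to_baseline,
                      simulate_slice, summarize_last_window)
from medplast.features import FEPSPTrace, measure_slope
from medplast.simulate import simulate_sweep_series
from tests.conftest import make_feature_table


def _timecourse_table(channel_pct: dict[int, tuple[float, float]],
                      layer: str = "superficial",
                      baseline_min: float = 15.0,
                      post_min: float = 60.0) -> pd.DataFrame:
    """Feature table with constant baseline slope and constant post slope."""
    rows = []
    period = 0.5
    n = int((baseline_min + post_min) / period)
    for ch, (base, post) in channel_pct.items():
        for i in range(n):
            t = i * period
            is_base = t < baseline_min
            rows.append({
                "slice_id": "tc", "condition": "constructed", "channel_id": ch,
                "layer": layer, "sweep_index": i, "time_min": t,
                "is_baseline": is_base,
                "amplitude_uV": 50.0,
                "slope_uV_per_ms": base if is_base else post,
            })
    return pd.DataFrame(rows)


def _qc_for(table: pd.DataFrame):
    return build_qc_report(table, slice_id="tc")


class TestNormalization:
    def test_constant_series_normalizes_to_100(self):
        table = _timecourse_table({1: (30.0, 30.0)})
        norm = normalize_to_baseline(table, _qc_for(table))
        assert np.allclose(norm.normalized_slope_pct, 100.0)
        base = norm.loc[norm.is_baseline, "normalized_slope_pct"]
        assert base.mean() == pytest.approx(100.0, rel=1e-9)

    def test_scale_invariance(self):
        table = _timecourse_table({1: (30.0, 45.0)})
        doubled = table.copy()
        doubled["slope_uV_per_ms"] *= 2.0
        a = normalize_to_baseline(table, _qc_for(table))
        b = normalize_to_baseline(doubled, _qc_for(doubled))
        assert np.allclose(a.normalized_slope_pct, b.normalized_slope_pct)

    def test_idempotence(self):
        """Feeding normalized values back through normalization leaves them
        unchanged (their baseline mean is already 100)."""
        table = _timecourse_table({1: (30.0, 45.0)})
        norm = normalize_to_baseline(table, _qc_for(table))
        renorm_input = table.copy()
        renorm_input["slope_uV_per_ms"] = norm["normalized_slope_pct"].to_numpy()
        renorm = normalize_to_baseline(renorm_input, _qc_for(renorm_input))
        assert np.allclose(renorm.normalized_slope_pct,
                           norm.normalized_slope_pct, rtol=1e-12)

    def test_unstable_channels_are_absent(self):
        stable = _timecourse_table({ch: (30.0, 45.0) for ch in range(1, 11)})
        table = pd.concat([
            stable,
            make_feature_table({11: [95.0, 105.0] * 15}),  # CV = 5% -> unstable
        ], ignore_index=True)
        qc = _qc_for(table)                 # 1/11 unstable: slice retained
        assert not qc.slice_excluded
        norm = normalize_to_baseline(table, qc)
        assert set(norm.channel_id) == set(range(1, 11))

    def test_excluded_slice_is_refused(self):
        table = make_feature_table({1: [95.0, 105.0] * 15})  # only channel unstable
        qc = _qc_for(table)
        assert qc.slice_excluded
        with pytest.raises(ValueError, match="excluded"):
            normalize_to_baseline(table, qc)


class TestLastWindow:
    def test_unchanged_plateau_labels_unchanged(self):
        table = _timecourse_table({1: (30.0, 30.0)})
        calls, summary = summarize_last_window(
            normalize_to_baseline(table, _qc_for(table)))
        assert calls.label.iloc[0] == "unchanged"
        assert calls.last_window_mean_pct.iloc[0] == pytest.approx(100.0)

    def test_closed_form_recovery_through_the_measurement_path(self,
                                                               quiet_params):
        """Plateau 1.5, tau 5 min, 60-min post: the measured last-10-min mean
        of the normalized slope equals the discrete closed form (~150.0%)
        within 1e-6 relative."""
        proto = ProtocolSpec(kind=TBS_LTP)
        kin = PlasticityKinetics(plateau=1.5, tau_plasticity_min=5.0,
                                 channel_sd=0.0)
        times, traces, onset = simulate_sweep_series(
            40.0, kin, proto, params=quiet_params)
        slopes = np.array([
            measure_slope(FEPSPTrace(traces[i], quiet_params.sampling_khz,
                                     onset)).slope_uV_per_ms
            for i in range(len(times))])
        base_mean = slopes[times < proto.baseline_min].mean()
        norm = slopes / base_mean * 100.0
        last = times >= times.max() - 10.0 + 1e-9
        measured = norm[last].mean()
        dt = times[last] - proto.induction_time_min
        expected = (1.0 + 0.5 * (1.0 - np.exp(-dt / 5.0))).mean() * 100.0
        assert measured == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("plateau", [0.67, 0.85, 1.08, 1.29, 1.54])
    def test_parameter_recovery_over_thirty_noisy_channels(self, plateau):
        """30 channels, 2 uV noise, plateau scatter 0.05: the recovered group
        mean lies within 2% of the generative plateau."""
        proto = ProtocolSpec(kind=TBS_LTP)
        params = WaveformParams(noise_sd_uV=2.0, artifact_amp_uV=0.0)
        rng = np.random.default_rng(42)
        kin = PlasticityKinetics(plateau=plateau, channel_sd=0.05)
        means = []
        for _ in range(30):
            ch_plateau = rng.normal(plateau, 0.05)
            times, traces, onset = simulate_sweep_series(
                40.0, kin, proto, params=params, rng_state=rng,
                plateau=ch_plateau)
            slopes = np.array([
                measure_slope(FEPSPTrace(traces[i], params.sampling_khz,
                                         onset)).slope_uV_per_ms
                for i in range(len(times))])
            base = slopes[times < proto.baseline_min].mean()
            last = times >= times.max() - 10.0 + 1e-9
            means.append(slopes[last].mean() / base * 100.0)
        group = float(np.mean(means))
        assert group == pytest.approx(plateau * 100.0, abs=2.0)

    def test_too_short_recording_rejected(self):
        table = _timecourse_table({1: (30.0, 45.0)}, post_min=5.0)
        norm = normalize_to_baseline(table, _qc_for(table))
        with pytest.raises(ValueError, match="window"):
            summarize_last_window(norm, window_min=10.0)


class TestPPR:
    def test_identical_pulses_give_unity_ratio(self):
        df = pd.DataFrame({
            "channel_id": [1] * 4, "layer": ["superficial"] * 4,
            "sweep_index": range(4), "interval_ms": [50.0] * 4,
            "slope1_uV_per_ms": [20.0] * 4, "slope2_uV_per_ms": [20.0] * 4,
        })
        out = compute_ppr(df)
        assert out.ppr.iloc[0] == pytest.approx(1.0)

    def test_zero_first_slope_flags_unmeasurable(self):
        df = pd.DataFrame({
            "channel_id": [1], "layer": ["superficial"], "sweep_index": [0],
            "interval_ms": [50.0], "slope1_uV_per_ms": [0.0],
            "slope2_uV_per_ms": [15.0],
        })
        out = compute_ppr(df)
        assert not bool(out.measurable.iloc[0])
        assert np.isnan(out.ppr.iloc[0])

    def test_generator_facilitation_recovered_noise_free(self, layout):
        """Noise off: measured PPR equals the preset facilitation within 1%,
        including the 25 ms interval where the decay tail of the first
        response must be subtracted (within 2%)."""
        params = WaveformParams(noise_sd_uV=0.0)
        proto = ProtocolSpec(kind=PPF, ppf_sweeps_per_interval=1)
        b = simulate_slice(get_preset("naive"), proto, layout, rng_state=3,
                           params=params)
        ppr = compute_ppr(extract_ppf_features(b))
        active = set(b.truth.loc[b.truth.active, "channel_id"])
        sel = ppr.loc[ppr.channel_id.isin(active) & ppr.measurable]
        curve = get_preset("naive").ppr_curve["deep"]
        for interval, grp in sel.groupby("interval_ms"):
            tol = 0.02 if interval == 25.0 else 0.01
            assert grp.ppr.mean() == pytest.approx(curve[interval], rel=tol), \
                interval


class TestRecruitmentDetectors:
    def test_silent_to_suprathreshold_is_recruited(self):
        table = _timecourse_table({1: (30.0, 30.0)})
        amp = np.where(table.is_baseline, 0.2, 18.0)
        table["amplitude_uV"] = np.where(table.channel_id == 2, amp, 50.0)
        table = pd.concat([table, _timecourse_table({2: (30.0, 30.0)})
                           .assign(amplitude_uV=amp)], ignore_index=True)
        out = detect_recruited(table, _qc_for(table))
        rec = out.set_index("channel_id")
        assert bool(rec.loc[2, "recruited"])
        assert not bool(rec.loc[1, "recruited"])

    def test_activated_baseline_is_ineligible_for_recruitment(self):
        table = _timecourse_table({1: (30.0, 60.0)})
        table["amplitude_uV"] = 15.0          # active at baseline, rises later
        out = detect_recruited(table, _qc_for(table))
        assert not out.recruited.any()

    def test_silencing_requires_collapse_to_near_zero(self):
        base_amp = 20.0
        table = _timecourse_table({1: (30.0, 3.0), 2: (30.0, 22.0)})
        amp1 = np.where(table.loc[table.channel_id == 1, "is_baseline"],
                        base_amp, 1.0)
        amp2 = np.where(table.loc[table.channel_id == 2, "is_baseline"],
                        base_amp, 15.0)
        table.loc[table.channel_id == 1, "amplitude_uV"] = amp1
        table.loc[table.channel_id == 2, "amplitude_uV"] = amp2
        out = detect_silenced(table, _qc_for(table)).set_index("channel_id")
        assert bool(out.loc[1, "silenced"])       # 20 uV -> ~1 uV
        assert not bool(out.loc[2, "silenced"])   # 20 uV -> 15 uV: just LTD

    def test_recruited_and_silenced_are_mutually_exclusive(self, layout):
        params = WaveformParams(noise_sd_uV=0.0)
        for kind, detector in ((TBS_LTP, detect_recruited),
                               (LFS_LTD, detect_silenced)):
            b = simulate_slice(get_preset("observer"), ProtocolSpec(kind=kind),
                               layout, rng_state=8, params=params)
            feats = extract_features(b)
            qc = build_qc_report(feats)
            out = detector(feats, qc)
            assert not (out.recruited & out.silenced).any()

    def test_noise_free_calls_equal_generator_truth(self, layout):
        """Exactness on noise-free input: recruited and silenced calls match
        the generative flags with no false positives or negatives."""
        params = WaveformParams(noise_sd_uV=0.0)
        b = simulate_slice(get_preset("observer"), ProtocolSpec(kind=TBS_LTP),
                           layout, rng_state=8, params=params)
        feats = extract_features(b)
        out = detect_recruited(feats, build_qc_report(feats))
        truth = b.truth.set_index("channel_id")
        for ch in truth.index:
            got = bool(out.set_index("channel_id").loc[ch, "recruited"])
            assert got == bool(truth.loc[ch, "recruited"]), ch

        bl = simulate_slice(get_preset("observer"), ProtocolSpec(kind=LFS_LTD),
                            layout, rng_state=8, params=params)
        feats = extract_features(bl)
        out = detect_silenced(feats, build_qc_report(feats))
        truth = bl.truth.set_index("channel_id")
        for ch in truth.index:
            got = bool(out.set_index("channel_id").loc[ch, "silenced"])
            assert got == bool(truth.loc[ch, "silenced"]), ch
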