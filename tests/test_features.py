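"""The 26-feature vector: hand-derived values, conventions and identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppgaffect as pa
from ppgaffect.errors import InsufficientBeatsError
from ppgaffect.features import (
    frequency_features,
    poincare_features,
    time_geometric,
    time_statistical,
)


def beats_from_nn(nn_ms):
    """BeatSeries with the given NN sequence and valleys 0.3 s pre-peak."""
    peaks = np.concatenate([[1.0], 1.0 + np.cumsum(np.asarray(nn_ms) / 1000.0)])
    return pa.build_beat_series(peaks, peaks - 0.3)


nn_series = st.lists(st.floats(min_value=400.0, max_value=1400.0),
                     min_size=4, max_size=40).map(np.array)


class TestTimeGeometric:
    def test_constant_series(self):
        f = time_geometric(beats_from_nn([800.0] * 5))
        assert f["Mean_HR"] == pytest.approx(75.0)
        assert f["Mean_NNI"] == pytest.approx(800.0)

    def test_hand_example(self, nn_example):
        f = time_geometric(beats_from_nn(nn_example))
        assert f["Mean_NNI"] == pytest.approx(815.0)
        expected_hr = np.mean(60000.0 / nn_example)
        assert f["Mean_HR"] == pytest.approx(expected_hr)
        assert f["Mean_HR"] == pytest.approx(73.677, abs=1e-3)

    def test_instantaneous_mean_convention(self):
        # mean of rates, not rate of the mean interval
        f = time_geometric(beats_from_nn([500.0, 1500.0]))
        assert f["Mean_HR"] == pytest.approx(80.0)
        assert 60000.0 / f["Mean_NNI"] == pytest.approx(60.0)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientBeatsError):
            time_geometric(beats_from_nn([800.0]))


class TestTimeStatistical:
    def test_hand_example(self, nn_example):
        f = time_statistical(nn_example)
        assert f["RMSSD"] == pytest.approx(np.sqrt(7000.0 / 3.0))
        assert f["SDNN"] == pytest.approx(np.sqrt(2100.0 / 3.0))
        assert f["Range_NN"] == 60.0
        # strict inequality: |−60| > 50 counts, |50| does not
        assert f["NN50"] == 1 and f["pNN50"] == pytest.approx(100.0 / 3.0)
        assert f["NN20"] == 3 and f["pNN20"] == 100.0
        assert f["CVSD"] == pytest.approx(np.sqrt(7000.0 / 3.0) / 815.0)
        assert f["CVNNI"] == pytest.approx(np.sqrt(2100.0 / 3.0) / 815.0)

    def test_constant_series_all_zero(self):
        f = time_statistical(np.full(6, 700.0))
        for k in ("RMSSD", "SDNN", "SDSD", "Range_NN", "NN50", "NN20"):
            assert f[k] == 0.0

    @given(nn=nn_series)
    @settings(max_examples=50, deadline=None)
    def test_pnn20_dominates_pnn50(self, nn):
        f = time_statistical(nn)
        assert f["pNN20"] >= f["pNN50"]


class TestFrequency:
    def test_constant_series_zero_power_and_sentinels(self):
        nn = np.full(8, 800.0)
        t = 1.0 + np.cumsum(np.concatenate([[0.0], nn])) / 1000.0
        f = frequency_features(nn, t)
        assert f["LF"] == f["HF"] == f["Total_Power"] == 0.0
        assert np.isnan(f["LF_HF_ratio"])
        assert np.isnan(f["nLFP"]) and np.isnan(f["nHFP"])

    @pytest.mark.parametrize("tone_hz,band", [(0.25, "HF"), (0.10, "LF")])
    def test_single_tone_lands_in_its_band(self, tone_hz, band):
        # 60-s tachogram RR(t) = 800 + 50 sin(2 pi f t)
        beats = [0.0]
        while beats[-1] < 60.0:
            rr = 800.0 + 50.0 * np.sin(2 * np.pi * tone_hz * beats[-1])
            beats.append(beats[-1] + rr / 1000.0)
        beats = np.array(beats)
        nn = np.diff(beats) * 1000.0
        f = frequency_features(nn, beats)
        frac = f[band] / (f["LF"] + f["HF"])
        assert frac > 0.9

    @given(nn=nn_series)
    @settings(max_examples=30, deadline=None)
    def test_band_power_consistency(self, nn):
        t = 1.0 + np.cumsum(np.concatenate([[0.0], nn])) / 1000.0
        f = frequency_features(nn, t)
        assert f["LF"] >= 0 and f["HF"] >= 0
        assert f["LF"] + f["HF"] <= f["Total_Power"] * (1 + 1e-9)
        if f["LF"] + f["HF"] > 0:
            assert f["nLFP"] + f["nHFP"] == pytest.approx(1.0, abs=1e-12)


class TestPoincare:
    @given(seed=st.integers(0, 2 ** 31 - 1), n=st.integers(8, 60),
           sd=st.floats(1.0, 120.0))
    @settings(max_examples=100, deadline=None)
    def test_classic_identities(self, seed, n, sd):
        nn = np.random.default_rng(seed).normal(800.0, sd, n)
        f = poincare_features(nn)
        rmssd_pop = np.sqrt(np.mean(np.diff(nn) ** 2))
        assert f["SD1"] == pytest.approx(rmssd_pop / np.sqrt(2), rel=1e-9)
        lhs = f["SD1"] ** 2 + f["SD2"] ** 2
        rhs = 2.0 * np.var(nn)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_alternating_series_collapses_sd2(self):
        # pure beat-to-beat alternation has no spread along the identity
        # line; the longitudinal axis collapses (clamped at exactly zero)
        f = poincare_features(np.array([800.0, 900.0] * 3))
        assert f["SD2"] == 0.0
        assert f["SD1"] > 0.0

    def test_sd12_and_csi_coincide(self, nn_example):
        f = poincare_features(nn_example)
        assert f["SD12"] == f["CSI"] == f["SD2"] / f["SD1"]

    def test_cvi_is_log_area_product(self):
        nn = np.random.default_rng(44).normal(820.0, 40.0, 20)
        f = poincare_features(nn)
        assert f["SD2"] > 0
        assert f["CVI"] == pytest.approx(np.log10(16 * f["SD1"] * f["SD2"]))

    def test_short_series_can_collapse_sd2(self, nn_example):
        # with only 3 successive differences the longitudinal variance can
        # fall below the transverse one; the axis clamps to zero and the
        # dependent ratios become sentinels
        f = poincare_features(nn_example)
        assert f["SD2"] == 0.0
        assert np.isnan(f["CVI"])

    def test_zero_variability_sentinels(self):
        f = poincare_features(np.full(5, 800.0))
        assert f["SD1"] == 0.0
        assert np.isnan(f["SD12"]) and np.isnan(f["CSI"]) and np.isnan(f["CVI"])


class TestExtract:
    def test_vector_arity_and_order(self, quiet_segment):
        seg, _ = quiet_segment
        vec = pa.extract_features(pa.beat_series_from_segment(seg))
        assert len(vec) == 26
        assert list(vec.index) == list(pa.FEATURE_NAMES)

    def test_deterministic(self, quiet_segment):
        seg, _ = quiet_segment
        bs = pa.beat_series_from_segment(seg)
        v1 = pa.extract_features(bs)
        v2 = pa.extract_features(bs)
        assert (v1.to_numpy() == v2.to_numpy()).all()

    def test_constant_nn_yields_sentinels_where_undefined(self):
        # 0.75 s spacing is exactly representable, so NN is exactly constant
        peaks = 1.0 + 0.75 * np.arange(9)
        bs = pa.build_beat_series(peaks, peaks - 0.25)
        vec = pa.extract_features(bs)
        assert vec["RMSSD"] == 0.0 and vec["SDNN"] == 0.0
        assert np.isnan(vec["LF_HF_ratio"]) and np.isnan(vec["SD12"])

    def test_parameter_recovery_with_exact_beats(self):
        cfg = pa.SimConfig(seed=31, duration_s=60.0, sd_rr_ms=40.0)
        rr_ms, beats = pa.simulate_rr(cfg)
        f = time_statistical(rr_ms)
        bs = pa.build_beat_series(beats, beats - 0.2)
        g = time_statistical(bs.nn_ms)
        for key in ("RMSSD", "SDNN"):
            assert g[key] == pytest.approx(f[key], rel=1e-9)
        assert np.mean(bs.nn_ms) == pytest.approx(np.mean(rr_ms), rel=1e-9)

    def test_matrix_extraction_ledger(self, quiet_segment):
        seg, _ = quiet_segment
        dropped = pa.Segment(seg.samples, seg.fs, rating=1, label=pa.DROPPED)
        flat = pa.Segment(np.zeros_like(seg.samples), seg.fs, rating=0, label=0)
        fm, report = pa.extract_matrix([seg, dropped, flat])
        assert report["n_segments"] == 3
        assert report["dropped_rating"] == 1
        assert report["dropped_beats"] == 1
        assert report["kept"] == fm.n_rows == 1
        assert fm.feature_names == pa.FEATURE_NAMES

    def test_registry_has_26_ordered_ids(self):
        reg = pa.feature_registry()
        assert [r["id"] for r in reg] == list(range(1, 27))
        assert [r["name"] for r in reg] == list(pa.FEATURE_NAMES)
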