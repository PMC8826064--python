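import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairspace.active_space import (
    TransmissionLossBand,
    broadband_noise_level,
    detection_distance,
    distance_surface_summary,
    fit_detection_distance_model,
    match_noise_to_call,
    select_tl_band,
    transmission_loss,
)
from pairspace.io import RunConfig
from pairspace.simulate import synthetic_tl_bands
from pairspace.states import RESTING_MILLING, TRAVELLING


class TestBroadband:
    def test_two_equal_bands(self):
        assert broadband_noise_level({100: 90.0, 200: 90.0}) == pytest.approx(
            93.0103, abs=1e-4
        )

    def test_single_band_identity(self):
        assert broadband_noise_level({500: 97.3}) == pytest.approx(97.3, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(level=st.floats(60, 120), n=st.integers(1, 19))
    def test_n_equal_bands_closed_form(self, level, n):
        centers = np.linspace(40, 2500, n)
        bands = {float(c): level for c in centers}
        expect = level + 10.0 * np.log10(n)
        assert broadband_noise_level(bands) == pytest.approx(expect, abs=1e-9)

    def test_out_of_range_bands_ignored(self):
        # 20 Hz and 5 kHz fall outside the 40 Hz - 2.5 kHz analysis band
        assert broadband_noise_level({20: 120.0, 100: 95.0, 5000: 120.0}) == pytest.approx(
            95.0, abs=1e-12
        )

    def test_empty_in_range_set_raises(self):
        with pytest.raises(ValueError):
            broadband_noise_level({20: 120.0})


class TestNoiseMatching:
    noise = pd.DataFrame({"t_s": [0.0, 600.0, 1200.0], "broadband_db": [95.0, 96.0, 97.0]})

    def test_recent_sample_matched(self):
        s = match_noise_to_call(630.0, self.noise, 600.0)
        assert s["broadband_db"] == 96.0

    def test_stale_sample_excluded(self):
        assert match_noise_to_call(1901.0, self.noise, 600.0) is None

    def test_exact_time_matches(self):
        s = match_noise_to_call(600.0, self.noise, 600.0)
        assert s["broadband_db"] == 96.0

    def test_call_before_first_sample_excluded(self):
        assert match_noise_to_call(-1.0, self.noise, 600.0) is None


class TestBandSelection:
    table = synthetic_tl_bands()

    @pytest.mark.parametrize("f,center", [(500.0, 500.0), (125.0, 125.0),
                                          (360.0, 500.0), (353.0, 250.0)])
    def test_peak_frequency_to_octave_band(self, f, center):
        assert select_tl_band(f, self.table).center_hz == center

    def test_uncovered_frequency_raises_with_coverage(self):
        with pytest.raises(ValueError, match="outside covered"):
            select_tl_band(10.0, self.table)


class TestTransmissionLoss:
    def test_reference_distance_gives_intercept(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 200.0)
        assert transmission_loss(band, 1.0) == pytest.approx(20.0, abs=1e-12)

    def test_near_piece(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 500.0)
        assert transmission_loss(band, 100.0) == pytest.approx(50.0, abs=1e-9)

    def test_far_piece_hand_value(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 200.0)
        # 20 + 15*log10(200) + 20*log10(2000/200) = 74.515...
        assert transmission_loss(band, 2000.0) == pytest.approx(
            20.0 + 15.0 * np.log10(200.0) + 20.0, abs=1e-9
        )

    def test_continuity_at_crossover(self):
        for _, r in synthetic_tl_bands().iterrows():
            band = TransmissionLossBand(r["center_hz"], r["a_db"], r["b_near"],
                                        r["b_far"], r["crossover_m"])
            c = band.crossover_m
            below = transmission_loss(band, c * (1 - 1e-12))
            above = transmission_loss(band, c * (1 + 1e-12))
            assert abs(below - above) < 1e-9

    def test_subreference_distance_clamped(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 200.0)
        assert transmission_loss(band, 0.1) == transmission_loss(band, 1.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(a=st.floats(0, 30), bn=st.floats(5, 25), bf=st.floats(5, 35),
           cross=st.floats(10, 5000),
           d1=st.floats(1, 10000), d2=st.floats(1, 10000))
    def test_monotone_nondecreasing(self, a, bn, bf, cross, d1, d2):
        band = TransmissionLossBand(500, a, bn, bf, cross)
        lo, hi = sorted((d1, d2))
        assert transmission_loss(band, lo) <= transmission_loss(band, hi) + 1e-9


class TestDetectionDistance:
    def test_near_piece_closed_form(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 500.0)
        d, floored = detection_distance(148.0, 98.0, band)
        assert not floored
        assert d == pytest.approx(100.0, abs=1e-9)
        # forward check: SNR at the solution is exactly zero
        assert 148.0 - transmission_loss(band, d) - 98.0 == pytest.approx(0.0, abs=1e-9)

    def test_far_piece_forward_check(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 200.0)
        d, floored = detection_distance(168.0, 98.0, band)
        assert not floored
        assert d > band.crossover_m
        assert 168.0 - transmission_loss(band, d) - 98.0 == pytest.approx(0.0, abs=1e-6)

    def test_no_positive_snr_floored(self):
        band = TransmissionLossBand(500, 20.0, 15.0, 20.0, 200.0)
        d, floored = detection_distance(98.0, 98.0, band)
        assert floored and d == 1.0

    def test_monotone_in_level_and_noise(self):
        band = TransmissionLossBand(500, 5.0, 18.0, 24.0, 800.0)
        rng = np.random.default_rng(0)
        rl = np.sort(rng.uniform(124, 173, 50))
        d = np.array([detection_distance(r, 98.0, band)[0] for r in rl])
        assert (np.diff(d) > 0).all()
        noise = np.sort(rng.uniform(94, 104, 50))
        d2 = np.array([detection_distance(150.0, n, band)[0] for n in noise])
        assert (np.diff(d2) < 0).all()

    def test_infinite_crossover_single_slope(self):
        band = TransmissionLossBand(500, 10.0, 18.0, 24.0, np.inf)
        d, floored = detection_distance(150.0, 96.0, band)
        assert not floored
        assert d == pytest.approx(10 ** ((150 - 96 - 10) / 18), rel=1e-12)


class TestDistanceModel:
    def _detections(self, rng, G=12, n=25, ratio=1.0):
        rows = []
        for g in range(G):
            u = rng.normal(0, 0.3)
            for i in range(n):
                state = RESTING_MILLING if i % 2 else TRAVELLING
                mu = 600.0 * (ratio if state == TRAVELLING else 1.0) * np.exp(u)
                rows.append(
                    {"tag_id": f"t{g}", "distance_m": rng.gamma(2.0, mu / 2.0),
                     "state": state, "floored": False}
                )
        return pd.DataFrame(rows)

    def test_recovers_multiplicative_effect(self):
        rng = np.random.default_rng(44)
        det = self._detections(rng, ratio=1.5)
        res = fit_detection_distance_model(det)
        c = res["contrast"].iloc[0]
        assert abs(c["estimate"] - np.log(1.5)) < 2 * c["se"]

    def test_degenerate_distances_flagged_not_fatal(self):
        det = pd.DataFrame(
            {"tag_id": ["a"] * 4 + ["b"] * 4, "distance_m": 500.0,
             "state": [RESTING_MILLING, TRAVELLING] * 4, "floored": False}
        )
        res = fit_detection_distance_model(det)
        assert any("degenerate" in f for f in res["flags"])


class TestSurfaceSummary:
    def test_single_estimate_single_cell(self):
        det = pd.DataFrame(
            {"received_level_db": [148.0], "noise_db": [98.0], "distance_m": [480.0]}
        )
        out = distance_surface_summary(det)
        assert len(out) == 1
        assert out["median_distance_m"].iloc[0] == 480.0

    def test_refinement_keeps_singleton_values(self):
        det = pd.DataFrame(
            {"received_level_db": [148.0, 150.5], "noise_db": [98.0, 95.2],
             "distance_m": [480.0, 800.0]}
        )
        coarse = distance_surface_summary(det, rl_bin_db=4.0, noise_bin_db=4.0)
        fine = distance_surface_summary(det, rl_bin_db=0.5, noise_bin_db=0.5)
        assert sorted(coarse["median_distance_m"]) == sorted(fine["median_distance_m"])

    def test_monotone_in_level_at_fixed_noise(self):
        band = TransmissionLossBand(500, 5.0, 18.0, 24.0, 800.0)
        rl = np.linspace(130, 168, 20)
        det = pd.DataFrame(
            {
                "received_level_db": rl,
                "noise_db": 98.0,
                "distance_m": [detection_distance(r, 98.0, band)[0] for r in rl],
            }
        )
        out = distance_surface_summary(det, rl_bin_db=2.0).sort_values("rl_bin_db")
        assert (np.diff(out["median_distance_m"]) >= 0).all()
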