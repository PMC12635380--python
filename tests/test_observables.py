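"""Observable tests against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.signal import hilbert

import hopfbif as hb
from hopfbif.observables import BandpassSpec, pool_fcd_values


def _sine_ts(freqs_hz, T=2000, tr=0.72, phases=None):
    t = np.arange(T) * tr
    phases = phases or [0.0] * len(freqs_hz)
    values = np.vstack([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs_hz, phases)])
    return hb.BoldTimeSeries(values, tr)


class TestBandpass:
    def test_passband_sine_preserved(self):
        ts = _sine_ts([0.03])
        out = hb.bandpass_filter(ts)
        rms_in = np.sqrt(np.mean(ts.values**2))
        rms_out = np.sqrt(np.mean(out.values**2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_dc_rejected(self):
        ts = hb.BoldTimeSeries(np.full((1, 2000), 3.0), 0.72)
        out = hb.bandpass_filter(ts)
        assert np.sqrt(np.mean(out.values**2)) < 1e-6 * 3.0

    @pytest.mark.parametrize("freq", [0.004, 0.2])
    def test_stopband_gain_matches_analytic_squared_response(self, freq):
        # forward-backward filtering doubles the attenuation: |H(f)|^2
        from scipy.signal import butter, sosfreqz

        tr = 0.72
        ts = _sine_ts([freq], T=6000, tr=tr)
        out = hb.bandpass_filter(ts)
        sos = butter(2, [0.008, 0.08], btype="bandpass", fs=1 / tr, output="sos")
        _, h = sosfreqz(sos, worN=[2 * np.pi * freq * tr])
        expected_gain = np.abs(h[0]) ** 2
        # use the central section to dodge filtfilt edge transients
        mid = slice(1500, 4500)
        gain = np.sqrt(np.mean(out.values[0, mid] ** 2)) / np.sqrt(np.mean(ts.values[0, mid] ** 2))
        assert gain == pytest.approx(expected_gain, rel=0.10)

    def test_band_above_nyquist_rejected(self):
        ts = _sine_ts([0.03], T=100, tr=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            hb.bandpass_filter(ts, BandpassSpec(low=0.008, high=0.08))


class TestStaticFC:
    def test_identical_rows_correlate_to_one(self, rng):
        row = rng.standard_normal(50)
        fc = hb.static_fc(hb.BoldTimeSeries(np.vstack([row, row]), 0.72))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_negated_row_correlates_to_minus_one(self, rng):
        row = rng.standard_normal(50)
        fc = hb.static_fc(hb.BoldTimeSeries(np.vstack([row, -row]), 0.72))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_pairwise_pearson(self, rng):
        x = rng.standard_normal((3, 5))
        fc = hb.static_fc(hb.BoldTimeSeries(x, 0.72))
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert fc[i, j] == pytest.approx(expected)

    def test_zero_variance_node_named_in_error(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            hb.static_fc(hb.BoldTimeSeries(x, 0.72))

    def test_invariant_under_positive_affine_rescaling(self, rng):
        x = rng.standard_normal((4, 60))
        scaled = x * rng.uniform(0.5, 3.0, size=(4, 1)) + rng.normal(size=(4, 1))
        a = hb.static_fc(hb.BoldTimeSeries(x, 0.72))
        b = hb.static_fc(hb.BoldTimeSeries(scaled, 0.72))
        assert np.allclose(a, b)


class TestPhaseCoherence:
    def test_identical_signals_fully_coherent(self):
        ts = _sine_ts([0.03, 0.03])
        frames = hb.phase_coherence_frames(ts)
        assert np.allclose(frames[:, 0, 1], 1.0)

    def test_quadrature_pair_near_zero_coherence(self):
        # sin vs cos: constant pi/2 phase lag -> cos(pi/2) = 0 away from edges
        ts = _sine_ts([0.03, 0.03], phases=[0.0, np.pi / 2])
        frames = hb.phase_coherence_frames(ts)
        interior = frames[200:-200, 0, 1]
        assert np.all(np.abs(interior) < 0.05)

    def test_matches_bruteforce_from_explicit_phases(self, rng):
        x = rng.standard_normal((4, 30))
        ts = hb.BoldTimeSeries(x, 0.72)
        frames = hb.phase_coherence_frames(ts)
        phi = np.angle(hilbert(x, axis=1))
        for t in range(30):
            for i in range(4):
                for j in range(4):
                    assert frames[t, i, j] == pytest.approx(np.cos(phi[i, t] - phi[j, t]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="Hilbert"):
            hb.phase_coherence_frames(hb.BoldTimeSeries(np.ones((2, 3)), 0.72))


class TestFCD:
    def test_synchronized_network_gives_all_ones(self):
        ts = _sine_ts([0.03, 0.03, 0.03], T=50)
        fcd = hb.fcd_matrix(ts)
        assert np.allclose(fcd.values, 1.0)

    def test_unit_diagonal_and_symmetry(self, rng):
        ts = hb.BoldTimeSeries(rng.standard_normal((4, 40)), 0.72)
        fcd = hb.fcd_matrix(ts)
        assert np.allclose(np.diag(fcd.values), 1.0)
        assert np.allclose(fcd.values, fcd.values.T)
        assert np.all(np.abs(fcd.values) <= 1.0)

    def test_matches_bruteforce_cosine_similarity(self, rng):
        x = rng.standard_normal((3, 5))
        ts = hb.BoldTimeSeries(x, 0.72)
        fcd = hb.fcd_matrix(ts)
        frames = hb.phase_coherence_frames(ts)
        for s in range(5):
            for t in range(5):
                u = [frames[s, i, j] for i in range(3) for j in range(i + 1, 3)]
                v = [frames[t, i, j] for i in range(3) for j in range(i + 1, 3)]
                u, v = np.array(u), np.array(v)
                expected = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
                assert fcd.values[s, t] == pytest.approx(expected)

    def test_time_reversal_reverses_indices(self, rng):
        x = rng.standard_normal((4, 30))
        fwd = hb.fcd_matrix(hb.BoldTimeSeries(x, 0.72)).values
        rev = hb.fcd_matrix(hb.BoldTimeSeries(x[:, ::-1], 0.72)).values
        assert np.allclose(rev, fwd[::-1, ::-1], atol=1e-9)

    def test_trim_frames(self, rng):
        x = rng.standard_normal((4, 30))
        fcd = hb.fcd_matrix(hb.BoldTimeSeries(x, 0.72), trim_frames=5)
        assert fcd.values.shape == (20, 20)
        assert fcd.frame_times[0] == pytest.approx(5 * 0.72)


class TestKSDistance:
    def test_identical_samples_zero(self, rng):
        x = rng.uniform(size=100)
        assert hb.ks_distance(x, x) == 0.0

    def test_three_point_worked_example(self):
        # ECDFs differ by exactly one point mass of 1/3
        assert hb.ks_distance([0.1, 0.2, 0.3], [0.2, 0.3, 0.4]) == pytest.approx(1 / 3)

    def test_disjoint_supports_maximal(self):
        assert hb.ks_distance([0.0, 0.1], [0.9, 1.0]) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self, rng):
        a, b = rng.uniform(size=50), rng.normal(0.3, 1.0, size=70)
        d1, d2 = hb.ks_distance(a, b), hb.ks_distance(b, a)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0

    def test_pools_fcd_upper_triangles(self, rng):
        ts = hb.BoldTimeSeries(rng.standard_normal((4, 20)), 0.72)
        fcd = hb.fcd_matrix(ts)
        pooled = pool_fcd_values([fcd, fcd])
        assert pooled.size == 2 * (20 * 19) // 2
        assert hb.ks_distance(fcd, fcd.upper_values()) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hb.ks_distance(np.array([]), np.array([1.0]))


class TestEstimateFrequencies:
    def test_single_sine_peak(self):
        ts = _sine_ts([0.03])
        omega = hb.estimate_frequencies([ts])
        bin_width = (1 / 0.72) / 256
        assert abs(omega[0] / (2 * np.pi) - 0.03) <= bin_width

    def test_dominant_component_wins(self):
        t = np.arange(2000) * 0.72
        x = np.sin(2 * np.pi * 0.02 * t) + 0.2 * np.sin(2 * np.pi * 0.035 * t)
        omega = hb.estimate_frequencies([hb.BoldTimeSeries(x[None, :], 0.72)])
        bin_width = (1 / 0.72) / 256
        assert abs(omega[0] / (2 * np.pi) - 0.02) <= bin_width

    def test_subject_average_of_node_peaks(self):
        a = _sine_ts([0.02])
        b = _sine_ts([0.04])
        omega = hb.estimate_frequencies([a, b])
        assert omega[0] / (2 * np.pi) == pytest.approx(0.03, abs=2 * (1 / 0.72) / 256)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            hb.estimate_frequencies([])
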