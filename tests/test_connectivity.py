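"""Pairwise connectivity features: closed-form oracles and invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import coherence as scipy_coherence

import tfpf

FS = 160.0
BAND = (8.0, 30.0)


class TestPCC:
    def test_hand_computed_oracle(self):
        # cov/(sx*sy) computed by hand: 0.6
        assert tfpf.compute_pcc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-6)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(100)
        assert tfpf.compute_pcc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_inverse_correlation_is_minus_one(self, rng):
        x = rng.standard_normal(100)
        assert tfpf.compute_pcc(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            tfpf.compute_pcc(np.ones(10), np.arange(10.0))

    def test_matches_numpy_corrcoef(self, rng):
        x, y = rng.standard_normal((2, 500))
        assert tfpf.compute_pcc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 200))
        assert tfpf.compute_pcc(a * x + b, y) == pytest.approx(
            tfpf.compute_pcc(x, y), abs=1e-9)


class TestCoherence:
    def test_linear_noiseless_relation_is_one(self, rng):
        x = rng.standard_normal(320)
        assert tfpf.compute_coherence_band(x, 2 * x, FS, BAND) == pytest.approx(1.0, abs=1e-6)

    def test_pure_delay_keeps_magnitude_coherence(self, rng):
        x = rng.standard_normal(1000)
        assert tfpf.compute_coherence_band(x[3:], x[:-3], FS, BAND) > 0.95

    def test_independent_noise_bias_matches_simulation_oracle(self):
        # null coherence of M-averaged periodograms is biased ~1/M; the
        # exact value (inflated slightly by the 50% frame overlap) is taken
        # from an independent reference implementation
        rng = np.random.default_rng(0)
        ours, reference = [], []
        for _ in range(100):
            x, y = rng.standard_normal((2, 320))
            ours.append(tfpf.compute_coherence_band(x, y, FS, BAND))
            f, cxy = scipy_coherence(x, y, fs=FS, window="hann", nperseg=80,
                                     noverlap=40)
            sel = (f >= BAND[0]) & (f <= BAND[1])
            reference.append(cxy[sel].mean())
        m = (320 - 80) // 40 + 1
        se = np.std(ours) / 10
        assert abs(np.mean(ours) - np.mean(reference)) < 1e-12
        assert 1 / m - 3 * se < np.mean(ours) < 1.5 / m + 3 * se

    def test_empty_band_raises(self, rng):
        x, y = rng.standard_normal((2, 320))
        with pytest.raises(ValueError, match="band"):
            tfpf.compute_coherence_band(x, y, FS, (30.5, 31.5))

    def test_amplitude_scaling_invariance(self, rng):
        x, y = rng.standard_normal((2, 320))
        base = tfpf.compute_coherence_band(x, y, FS, BAND)
        assert tfpf.compute_coherence_band(5 * x, 0.1 * y, FS, BAND) == pytest.approx(
            base, abs=1e-12)


class TestPhaseExtraction:
    def test_sinusoid_phase_advances_at_carrier_rate(self):
        t = np.arange(1600) / FS
        ph = tfpf.extract_phase(np.sin(2 * np.pi * 10.0 * t)[None]).phases[0]
        rate = np.diff(np.unwrap(ph[160:-160])) * FS / (2 * np.pi)
        assert np.allclose(rate, 10.0, rtol=0.01)

    def test_quadrature_pair_constant_half_pi(self):
        t = np.arange(1600) / FS
        seg = np.vstack([np.cos(2 * np.pi * 10 * t), np.sin(2 * np.pi * 10 * t)])
        ph = tfpf.extract_phase(seg).phases
        diff = np.angle(np.exp(1j * (ph[0] - ph[1])))[160:-160]
        assert np.all(np.abs(diff - np.pi / 2) < 0.02)

    def test_phases_wrapped_to_pi(self, rng):
        seg = rng.standard_normal((3, 400))
        ph = tfpf.extract_phase(seg).phases
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)

    def test_all_zero_channel_raises(self):
        with pytest.raises(ValueError, match="zero"):
            tfpf.extract_phase(np.zeros((2, 100)))


class TestPLV:
    def test_constant_difference_is_exactly_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 200)
        assert tfpf.compute_plv(ph, ph - 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_phasors_cancel(self):
        assert tfpf.compute_plv([0.0, np.pi], [0.0, 0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair_gives_sqrt2_over_2(self):
        # |(1 + i)/2| = sqrt(2)/2
        assert tfpf.compute_plv([0.0, np.pi / 2], [0.0, 0.0]) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-6)

    @given(c=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_phase_shift_invariance(self, c):
        rng = np.random.default_rng(3)
        ph = rng.uniform(-np.pi, np.pi, 100)
        assert tfpf.compute_plv(ph, ph + c) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            tfpf.compute_plv([0.0, 1.0], [0.0])


class TestConnectivityMatrix:
    @pytest.mark.parametrize("kind", tfpf.connectivity.FEATURE_KINDS)
    def test_symmetric_unit_diagonal_and_range(self, kind, rng):
        seg = rng.standard_normal((6, 320))
        m = tfpf.connectivity_matrix(seg, FS, BAND, kind).values
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        lo = -1.0 if kind == "PCC" else 0.0
        assert np.all(m >= lo) and np.all(m <= 1.0)

    @pytest.mark.parametrize("kind", tfpf.connectivity.FEATURE_KINDS)
    def test_equals_pairwise_loop(self, kind, rng):
        # the vectorized matrix must equal brute-force iteration of the
        # pairwise operations over all 6 pairs
        seg = rng.standard_normal((4, 320))
        m = tfpf.connectivity_matrix(seg, FS, BAND, kind).values
        phases = tfpf.extract_phase(seg).phases if kind == "PLV" else None
        for i, j in itertools.combinations(range(4), 2):
            if kind == "PCC":
                ref = tfpf.compute_pcc(seg[i], seg[j])
            elif kind == "COH":
                ref = tfpf.compute_coherence_band(seg[i], seg[j], FS, BAND)
            else:
                ref = tfpf.compute_plv(phases[i], phases[j], edge_trim=0.1)
            assert m[i, j] == pytest.approx(ref, abs=1e-10)

    def test_identical_channels_pcc_all_ones(self, rng):
        x = rng.standard_normal(320)
        m = tfpf.connectivity_matrix(np.vstack([x, x]), FS, BAND, "PCC").values
        np.testing.assert_allclose(m, 1.0)

    @pytest.mark.parametrize("kind", tfpf.connectivity.FEATURE_KINDS)
    def test_channel_permutation_equivariance(self, kind, rng):
        seg = rng.standard_normal((5, 320))
        perm = np.array([3, 0, 4, 1, 2])
        m = tfpf.connectivity_matrix(seg, FS, BAND, kind).values
        mp = tfpf.connectivity_matrix(seg[perm], FS, BAND, kind).values
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-10)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="2 channels"):
            tfpf.connectivity_matrix(rng.standard_normal((1, 320)), FS, BAND, "PCC")

    def test_constant_channel_error_names_feature(self):
        seg = np.vstack([np.ones(320), np.random.default_rng(0).standard_normal(320)])
        with pytest.raises(ValueError, match="PCC"):
            tfpf.connectivity_matrix(seg, FS, BAND, "PCC")

    def test_edge_table_lists_all_pairs(self, rng):
        seg = rng.standard_normal((5, 320))
        table = tfpf.connectivity_matrix(seg, FS, BAND, "PLV").to_edge_table()
        assert len(table) == 10
        assert set(table.columns) >= {"channel_i", "channel_j", "feature", "value"}
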