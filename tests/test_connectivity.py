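"""SL, PLV and coherence estimators: analytic limits, baselines, invariants."""

from __future__ import annotations

import numpy as np
import pytest

from distractnet.bands import CANONICAL_BANDS
from distractnet.connectivity import (
    ConnectivityMatrix,
    SLParams,
    SpectralParams,
    coh_matrix,
    mean_strength,
    plv_from_phases,
    plv_matrix,
    sl_matrix,
)
from distractnet.synthetic import coupled_henon, narrowband_noise


def _sine(freq, fs, n, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestSL:
    def test_identical_chaotic_signals_near_one(self):
        x, _ = coupled_henon(2000, 0.0, np.random.default_rng(0))
        mat = sl_matrix(np.vstack([x, x]), SLParams(m=5, lag=2))
        assert mat.values[0, 1] >= 0.95

    def test_independent_noise_baseline_is_p_ref(self):
        """SL floor for independent Gaussian noise sits at p_ref = 0.05."""
        vals = [
            sl_matrix(np.random.default_rng(s).standard_normal((2, 5120))).values[0, 1]
            for s in range(10)
        ]
        assert abs(np.mean(vals) - 0.05) < 0.01

    def test_henon_coupling_monotonic(self):
        params = SLParams(m=5, lag=1)
        means = []
        for c in (0.0, 0.4, 0.8):
            vals = []
            for s in range(5):
                x, y = coupled_henon(1500, c, np.random.default_rng(40 + s))
                vals.append(sl_matrix(np.vstack([x, y]), params).values[0, 1])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_too_short_epoch_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="need more than"):
            sl_matrix(np.random.default_rng(0).standard_normal((2, 200)))

    def test_param_validation(self):
        with pytest.raises(ValueError, match="m must"):
            SLParams(m=1)
        with pytest.raises(ValueError, match="p_ref"):
            SLParams(p_ref=1.5)
        with pytest.raises(ValueError, match="w1 < w2"):
            SLParams(w1=100, w2=50)

    def test_rescale_flag_shifts_floor(self):
        data = np.random.default_rng(1).standard_normal((2, 5120))
        raw = sl_matrix(data).values[0, 1]
        scaled = sl_matrix(data, SLParams(rescale=True)).values[0, 1]
        assert scaled < raw  # floor at ~p_ref maps to ~0


class TestPLV:
    def test_identical_signals(self):
        x = _sine(10, 512.0, 5120)
        mat = plv_matrix(np.vstack([x, x]))
        assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_constant_phase_shift(self):
        x = _sine(10, 512.0, 5120)
        y = _sine(10, 512.0, 5120, phase=np.pi / 3)
        mat = plv_matrix(np.vstack([x, y]))
        assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_rayleigh_baseline_for_independent_phases(self):
        """E[PLV] for iid uniform phases is sqrt(pi)/(2 sqrt(N))."""
        n = 5120
        vals = []
        for s in range(200):
            ph = np.random.default_rng(s).uniform(-np.pi, np.pi, (2, n))
            vals.append(plv_from_phases(ph)[0, 1])
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(2)
        data = np.vstack(
            [narrowband_noise(rng, 2048, 256.0, 8.0, 13.0) for _ in range(3)]
        )
        scaled = data.copy()
        scaled[0] *= 37.5
        a = plv_matrix(data).values
        b = plv_matrix(scaled).values
        assert np.allclose(a, b, atol=1e-12)

    def test_all_zero_channel_zeroed(self):
        data = np.zeros((2, 1024))
        data[1] = _sine(10, 256.0, 1024)
        mat = plv_matrix(data)
        assert mat.values[0, 1] == 0.0


class TestCOH:
    def test_exact_linear_copy(self):
        rng = np.random.default_rng(3)
        x = narrowband_noise(rng, 5120, 512.0, 8.0, 13.0)
        mat = coh_matrix(np.vstack([x, 2.0 * x]), 512.0, CANONICAL_BANDS["alpha"])
        assert mat.values[0, 1] >= 0.99

    def test_symmetry_exact(self):
        data = np.random.default_rng(4).standard_normal((4, 4096))
        v = coh_matrix(data, 512.0, CANONICAL_BANDS["beta"]).values
        assert np.array_equal(v, v.T)

    def test_independent_noise_bias_matches_oracle(self):
        """MSC of independent noise is biased ~1/n_segments; compare the
        estimator's mean against that known baseline within 20%."""
        params = SpectralParams(segment_length=256, overlap=0.0)
        vals = []
        for s in range(100):
            data = np.random.default_rng(s).standard_normal((2, 8 * 256))
            vals.append(
                coh_matrix(data, 256.0, CANONICAL_BANDS["alpha"], params).values[0, 1]
            )
        assert np.mean(vals) == pytest.approx(1.0 / 8.0, rel=0.2)

    def test_single_segment_rejected(self):
        data = np.random.default_rng(0).standard_normal((2, 1024))
        with pytest.raises(ValueError, match="segments"):
            coh_matrix(data, 512.0, CANONICAL_BANDS["alpha"], SpectralParams(segment_length=1024))

    def test_zero_power_channel_zeroed(self):
        data = np.zeros((2, 4096))
        data[1] = np.random.default_rng(1).standard_normal(4096)
        mat = coh_matrix(data, 512.0, CANONICAL_BANDS["theta"])
        assert mat.values[0, 1] == 0.0


class TestMeanStrength:
    @pytest.mark.parametrize(
        "upper,expected",
        [
            ([1.0, 1.0, 1.0], 1.0),
            ([0.0, 0.0, 0.0], 0.0),
            ([0.2, 0.4, 0.0], 0.3),
        ],
    )
    def test_positive_mean(self, upper, expected):
        v = np.zeros((3, 3))
        v[0, 1], v[0, 2], v[1, 2] = upper
        v = v + v.T
        mat = ConnectivityMatrix(v, "PLV", "alpha")
        assert mean_strength(mat) == pytest.approx(expected)


class TestInvariants:
    def test_bounded_and_symmetric_on_random_input(self):
        """All three estimators stay in [0,1] and symmetric on arbitrary data."""
        sl_p = SLParams(m=3, lag=1, n_ref=32)
        for s in range(10):
            rng = np.random.default_rng(s)
            data = rng.standard_normal((3, 700)) * rng.uniform(0.1, 50)
            for mat in (
                sl_matrix(data, sl_p),
                plv_matrix(data),
                coh_matrix(data, 256.0, CANONICAL_BANDS["alpha"], SpectralParams(segment_length=128)),
            ):
                v = mat.values
                assert v.min() >= 0.0 and v.max() <= 1.0
                assert np.allclose(v, v.T, atol=1e-12)
                assert np.all(np.diag(v) == 0)

    def test_matrix_validation(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(bad, "PLV", "alpha")
        with pytest.raises(ValueError, match="estimator"):
            ConnectivityMatrix(np.zeros((2, 2)), "XYZ", "alpha")
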