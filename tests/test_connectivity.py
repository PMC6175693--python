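"""Connectivity metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as st

from oscnet.connectivity import aec, connectivity_matrix, oaec, plv, wpli
from oscnet.spectral import AnalyticBand, BandDefinition, fragment

ALPHA = BandDefinition("alpha", 8, 12)


class TestPlv:
    def test_identical_phases_give_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv(ph, ph) == pytest.approx(1.0)

    def test_constant_lag_gives_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv(ph, ph - 1.234) == pytest.approx(1.0)

    def test_opposite_differences_cancel(self):
        assert plv(np.array([0.0, 0.0]), np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_common_phase_offset(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, 300))
        assert plv(a, b) == pytest.approx(plv(a + 0.7, b + 0.7), abs=1e-12)

    def test_matches_direct_formula(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, 300))
        direct = np.abs(np.mean(np.exp(1j * (a - b))))
        assert plv(a, b) == pytest.approx(direct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(5), np.zeros(6))


class TestAec:
    def test_monotone_scaling_gives_one(self, rng):
        a = rng.random(50)
        assert aec(a, 2 * a) == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, rng):
        a = rng.random(50)
        assert aec(a, a.max() - a) == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4 / (5*24) = 0.8
        assert aec(np.array([1, 2, 3, 4, 5.0]), np.array([2, 1, 4, 3, 5.0])) == pytest.approx(0.8)

    def test_matches_scipy_spearman(self, rng):
        a, b = rng.random((2, 200))
        assert aec(a, b) == pytest.approx(st.spearmanr(a, b).statistic)

    def test_invariant_to_monotone_transform(self, rng):
        a, b = rng.random((2, 100))
        assert aec(np.exp(3 * a), b) == pytest.approx(aec(a, b))

    def test_zero_variance_flagged(self):
        assert np.isnan(aec(np.ones(10), np.arange(10.0)))


class TestWpli:
    def test_constant_quarter_cycle_lag_gives_one(self):
        t = np.arange(1000) / 200
        z = np.exp(1j * 2 * np.pi * 10 * t)
        assert wpli(z, z * np.exp(-1j * np.pi / 2)) == pytest.approx(1.0)

    def test_zero_lag_coupling_gives_zero(self):
        t = np.arange(1000) / 200
        z = np.exp(1j * 2 * np.pi * 10 * t)
        with pytest.warns(UserWarning):
            assert wpli(z, 2 * z) == 0.0

    def test_alternating_imaginary_signs_cancel(self):
        # cross-spectrum imaginary part alternates +a, -a
        x = np.ones(100, dtype=complex)
        y = np.exp(1j * np.pi / 2 * np.tile([1, -1], 50))
        assert wpli(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        z1 = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        z2 = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        im = np.imag(z1 * np.conj(z2))
        assert wpli(z1, z2) == pytest.approx(np.abs(im.mean()) / np.abs(im).mean())


class TestOaec:
    def test_shared_signal_up_to_real_scale_gives_zero(self):
        t = np.arange(2000) / 200
        z = (1 + 0.4 * np.sin(2 * np.pi * 0.3 * t)) * np.exp(1j * 2 * np.pi * 10 * t)
        assert oaec(z, 3.0 * z) == 0.0

    def test_independent_envelopes_near_zero(self, rng):
        n = 5000
        z1 = (1 + 0.5 * rng.random(n)) * np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        z2 = (1 + 0.5 * rng.random(n)) * np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        assert abs(oaec(z1, z2)) < 3 / np.sqrt(n)

    def test_detects_latent_envelope_coupling_monotonically(self, rng):
        # genuinely correlated envelopes with independent phases give a
        # positive (though attenuated) value that grows with the latent
        # envelope correlation; pure zero-lag leakage gives zero instead
        n = 20000
        phases1 = rng.uniform(-np.pi, np.pi, n)
        phases2 = rng.uniform(-np.pi, np.pi, n)
        values = []
        for mix in (0.0, 0.5, 0.9):
            shared = rng.random(n)
            e1 = 1 + mix * shared + (1 - mix) * rng.random(n)
            e2 = 1 + mix * shared + (1 - mix) * rng.random(n)
            values.append(oaec(e1 * np.exp(1j * phases1), e2 * np.exp(1j * phases2)))
        assert values[0] == pytest.approx(0.0, abs=3 / np.sqrt(n))
        assert values[0] < values[1] < values[2]
        assert values[2] > 0.2

    def test_matches_brute_force_oracle(self, rng):
        # independent per-sample reimplementation of the orthogonalization
        n = 400
        z1 = (1 + rng.random(n)) * np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        z2 = (1 + rng.random(n)) * np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        resid_21 = np.array([abs((z2[t] * np.conj(z1[t])).imag) / abs(z1[t]) for t in range(n)])
        resid_12 = np.array([abs((z1[t] * np.conj(z2[t])).imag) / abs(z2[t]) for t in range(n)])
        expect = 0.5 * (
            st.spearmanr(np.abs(z1), resid_21).statistic
            + st.spearmanr(np.abs(z2), resid_12).statistic
        )
        assert oaec(z1, z2) == pytest.approx(expect)

    def test_symmetric_in_arguments(self, rng):
        z1 = (1 + rng.random(500)) * np.exp(1j * rng.uniform(-np.pi, np.pi, 500))
        z2 = (1 + rng.random(500)) * np.exp(1j * rng.uniform(-np.pi, np.pi, 500))
        assert oaec(z1, z2) == pytest.approx(oaec(z2, z1))


class TestConnectivityMatrix:
    def make_ab(self, data_complex, fs=200.0):
        return AnalyticBand(
            phase=np.angle(data_complex),
            amplitude=np.abs(data_complex),
            band=ALPHA,
            fs=fs,
            labels={"subject": "s1", "session": "A", "state": "rest", "block_id": "b1"},
        )

    def test_identical_channels_give_unit_plv(self, rng):
        row = np.exp(1j * rng.uniform(-np.pi, np.pi, 1000))
        ab = self.make_ab(np.vstack([row, row, row]))
        m = connectivity_matrix(ab, "plv", n_frag=10)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    @pytest.mark.parametrize("metric", ["plv", "aec", "wpli", "oaec"])
    def test_fragment_average_equals_mean_of_fragment_values(self, metric, rng):
        z = (1 + rng.random((4, 1000))) * np.exp(1j * rng.uniform(-np.pi, np.pi, (4, 1000)))
        ab = self.make_ab(z)
        m = connectivity_matrix(ab, metric, n_frag=10)
        scalar = {"plv": plv, "aec": aec, "wpli": wpli, "oaec": oaec}[metric]
        for j, k in [(0, 1), (1, 3)]:
            per_frag = []
            for f in fragment(ab, 10):
                zz = f.amplitude * np.exp(1j * f.phase)
                if metric == "plv":
                    per_frag.append(scalar(f.phase[j], f.phase[k]))
                elif metric == "aec":
                    per_frag.append(scalar(f.amplitude[j], f.amplitude[k]))
                else:
                    per_frag.append(scalar(zz[j], zz[k]))
            assert m.values[j, k] == pytest.approx(np.mean(per_frag), abs=1e-10)

    @pytest.mark.parametrize("metric", ["plv", "aec", "wpli", "oaec"])
    def test_matrix_symmetric(self, metric, rng):
        z = (1 + rng.random((5, 600))) * np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 600)))
        m = connectivity_matrix(self.make_ab(z), metric, n_frag=6)
        assert np.allclose(m.values, m.values.T)

    def test_plv_increases_with_planted_coupling(self, rng):
        # coupled phase oscillators: phi_k = phi_j + jitter / coupling
        n = 4000
        base = np.cumsum(rng.normal(0.3, 0.05, n))
        estimates = []
        for coupling in (0.0, 0.5, 2.0):
            jitter_sd = 2.0 / (1.0 + 4 * coupling)
            other = base + rng.normal(0, jitter_sd, n)
            z = np.vstack([np.exp(1j * base), np.exp(1j * other)])
            m = connectivity_matrix(self.make_ab(z), "plv", n_frag=10)
            estimates.append(m.values[0, 1])
        assert estimates[0] < estimates[1] < estimates[2]

    def test_sixty_channel_matrix_shape(self, rng):
        z = (1 + rng.random((60, 500))) * np.exp(1j * rng.uniform(-np.pi, np.pi, (60, 500)))
        m = connectivity_matrix(self.make_ab(z), "plv", n_frag=10)
        assert m.values.shape == (60, 60)
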