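"""Rank statistics, bridge functions and latent correlation estimation."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from ldnet import (
    DataMatrix,
    bridge_F,
    bridge_F_inverse,
    bridge_H,
    bridge_H_inverse,
    estimate_cutoffs,
    kendall_tau,
    kendall_tau_matrix,
    latent_correlation,
    npn_correlation_entry,
    make_differential_pair,
    sample_npn,
)
from ldnet.rank import bvn_cdf


def brute_force_tau(x, y):
    n = len(x)
    s = sum(
        np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    return 2.0 * s / (n * (n - 1))


class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            # 6 pairs: 1 concordant, 1 discordant, 4 tied -> 0
            ((0, 0, 1, 1), (0, 1, 0, 1), 0.0),
        ],
    )
    def test_small_examples_match_pair_enumeration(self, x, y, expected):
        x, y = np.asarray(x, float), np.asarray(y, float)
        assert kendall_tau(x, y) == pytest.approx(brute_force_tau(x, y))
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_ties_contribute_zero_not_tau_b(self, rng):
        # binary data: tau-a is NOT the tie-corrected scipy default
        x = rng.integers(0, 2, size=30).astype(float)
        y = rng.integers(0, 2, size=30).astype(float)
        assert kendall_tau(x, y) == pytest.approx(brute_force_tau(x, y))

    def test_matrix_agrees_with_pairwise(self, rng):
        data = rng.standard_normal((25, 4))
        data[:, 2] = (data[:, 2] > 0.3).astype(float)  # include ties
        tau = kendall_tau_matrix(data)
        assert np.allclose(tau, tau.T)
        assert np.allclose(np.diag(tau), 1.0)
        for j, k in itertools.combinations(range(4), 2):
            assert tau[j, k] == pytest.approx(
                kendall_tau(data[:, j], data[:, k]), abs=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kendall_tau([1.0], [2.0])
        with pytest.raises(ValueError):
            kendall_tau([1.0, 2.0], [1.0, 2.0, 3.0])


class TestNpnEntry:
    @pytest.mark.parametrize("tau, expected", [(0, 0), (1, 1), (1 / 3, 0.5)])
    def test_values(self, tau, expected):
        assert npn_correlation_entry(tau) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            npn_correlation_entry(1.2)


class TestBridges:
    def test_bvn_cdf_matches_scipy(self, rng):
        for _ in range(10):
            h, k = rng.normal(size=2) * 1.5
            r = rng.uniform(-0.95, 0.95)
            ref = multivariate_normal([0, 0], [[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-9)

    def test_F_trivial_and_closed_form(self):
        assert bridge_F(0.0, 0.7, -1.2) == pytest.approx(0.0, abs=1e-15)
        # orthant closed form: Phi2(0,0,t) = 1/4 + arcsin(t)/(2 pi)
        assert bridge_F(0.5, 0.0, 0.0) == pytest.approx(np.arcsin(0.5) / np.pi)

    def test_F_numerical_oracle(self):
        # independent 2-D quadrature via scipy's bivariate normal CDF
        t, lj, lk = 0.3, 0.5, -0.2
        ref = 2 * (
            multivariate_normal([0, 0], [[1, t], [t, 1]]).cdf([lj, lk])
            - norm.cdf(lj) * norm.cdf(lk)
        )
        assert bridge_F(t, lj, lk) == pytest.approx(ref, abs=1e-9)

    def test_H_trivial_and_closed_form(self):
        assert bridge_H(0.0, 0.8) == pytest.approx(0.0, abs=1e-15)
        # t -> 1, cutoff 0: 2 arcsin(1/sqrt(2)) / pi = 1/2
        assert bridge_H(1 - 1e-9, 0.0) == pytest.approx(0.5, abs=1e-4)

    def test_H_numerical_oracle(self):
        t, lj = 0.4, 0.8
        ref = 4 * multivariate_normal(
            [0, 0], [[1, t / np.sqrt(2)], [t / np.sqrt(2), 1]]
        ).cdf([lj, 0.0]) - 2 * norm.cdf(lj)
        assert bridge_H(t, lj) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("lam", [-2.0, -1.0, 0.0, 0.5, 1.0, 2.0])
    def test_bridges_increasing_in_t(self, lam):
        ts = np.linspace(-0.999, 0.999, 41)
        f = bridge_F(ts, lam, -lam / 2)
        h = bridge_H(ts, lam)
        # monotone up to roundoff in the numerically flat tails
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all(np.diff(h) >= -1e-12)
        # strict on the interior where the bridges are numerically resolvable
        mid = (ts > -0.9) & (ts < 0.9)
        if abs(lam) <= 1:
            assert np.all(np.diff(f[mid]) > 0)
            assert np.all(np.diff(h[mid]) > 0)

    def test_rejects_t_outside_open_interval(self):
        with pytest.raises(ValueError):
            bridge_F(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            bridge_H(-1.0, 0.0)


class TestBridgeInverses:
    def test_inverse_trivial(self):
        assert bridge_F_inverse(0.0, 0.4, -0.3) == pytest.approx(0.0, abs=1e-8)
        assert bridge_H_inverse(0.0, 0.9) == pytest.approx(0.0, abs=1e-8)

    def test_inverse_closed_form(self):
        assert bridge_F_inverse(np.arcsin(0.5) / np.pi, 0.0, 0.0) == pytest.approx(
            0.5, abs=1e-7
        )
        # tau = 1/2 is the supremum of H(.; 0): inverse clips to 1 - eps
        assert bridge_H_inverse(0.5, 0.0) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("lams", [(0.0, 0.0), (0.5, -0.2), (1.0, 1.0),
                                      (-1.0, 0.5)])
    def test_F_round_trip(self, lams):
        lj, lk = lams
        for t in np.arange(-0.9, 0.95, 0.15):
            tau = bridge_F(t, lj, lk)
            assert bridge_F_inverse(tau, lj, lk) == pytest.approx(t, abs=1e-6)

    @pytest.mark.parametrize("lam", [-1.5, -0.5, 0.0, 0.5, 1.5])
    def test_H_round_trip(self, lam):
        for t in np.arange(-0.9, 0.95, 0.15):
            tau = bridge_H(t, lam)
            assert bridge_H_inverse(tau, lam) == pytest.approx(t, abs=1e-6)

    def test_out_of_range_tau_clips_to_endpoint(self):
        # the attainable range of F(.; 0, 0) is (-1/2, 1/2)
        assert bridge_F_inverse(0.6, 0.0, 0.0) == pytest.approx(1.0, abs=1e-5)
        assert bridge_F_inverse(-0.6, 0.0, 0.0) == pytest.approx(-1.0, abs=1e-5)


class TestCutoffs:
    def test_half_mean_gives_zero(self):
        data = DataMatrix(
            np.array([[0.0], [1.0], [0.0], [1.0]]), types="binary"
        )
        assert estimate_cutoffs(data)[0] == pytest.approx(0.0)

    def test_normal_quantile(self):
        # mean 1 - Phi(1) -> cutoff 1.0
        n = 10000
        m = 1 - norm.cdf(1.0)
        col = np.zeros(n)
        col[: int(round(m * n))] = 1.0
        data = DataMatrix(col[:, None], types="binary")
        assert estimate_cutoffs(data)[0] == pytest.approx(1.0, abs=1e-3)

    def test_constant_column_clamped(self):
        data = DataMatrix(np.ones((50, 1)), types="binary")
        assert estimate_cutoffs(data)[0] == pytest.approx(norm.ppf(1.0 / 100))

    def test_continuous_columns_nan(self):
        data = DataMatrix(
            np.column_stack([np.arange(4.0), [0, 1, 0, 1]]),
            types=["continuous", "binary"],
        )
        lam = estimate_cutoffs(data)
        assert np.isnan(lam[0]) and np.isfinite(lam[1])


class TestLatentCorrelation:
    def test_continuous_is_sine_of_tau(self, rng):
        data = rng.standard_normal((40, 4))
        est = latent_correlation(DataMatrix(data, types="continuous"))
        tau = kendall_tau_matrix(data)
        expected = np.sin(np.pi * tau / 2.0)
        np.fill_diagonal(expected, 1.0)
        assert est.source == "npn"
        assert np.allclose(est.matrix, expected)

    def test_symmetry_unit_diagonal_clipping(self, rng):
        data = rng.integers(0, 2, size=(30, 5)).astype(float)
        est = latent_correlation(DataMatrix(data, types="binary"), psd=False)
        assert np.array_equal(est.matrix, est.matrix.T)
        assert np.all(np.diag(est.matrix) == 1.0)
        off = est.matrix[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) <= 1 - 1e-6 + 1e-15)

    def test_binary_estimates_projected_psd_by_default(self, rng):
        data = rng.integers(0, 2, size=(25, 6)).astype(float)
        dm = DataMatrix(data, types="binary")
        auto = latent_correlation(dm)
        assert np.linalg.eigvalsh(auto.matrix).min() >= -1e-10
        assert np.allclose(np.diag(auto.matrix), 1.0)
        # continuous data is left as computed under 'auto'
        cdata = DataMatrix(rng.standard_normal((25, 6)), types="continuous")
        assert np.array_equal(
            latent_correlation(cdata).matrix,
            latent_correlation(cdata, psd=False).matrix,
        )

    def test_binary_toy_matches_brute_force(self):
        # n=4, 2 columns: tau by pair enumeration, cutoffs from means,
        # bridge inversion by scipy root finding
        from scipy.optimize import brentq

        b = np.array([[0, 0], [0, 1], [1, 1], [1, 0.0]])
        data = DataMatrix(b, types="binary")
        est = latent_correlation(data, psd=False)
        tau = brute_force_tau(b[:, 0], b[:, 1])
        lam = norm.ppf(1 - b.mean(axis=0))
        root = brentq(
            lambda t: bridge_F(t, lam[0], lam[1]) - tau, -1 + 1e-6, 1 - 1e-6,
            xtol=1e-10,
        )
        assert est.source == "binary"
        assert est.matrix[0, 1] == pytest.approx(root, abs=1e-6)

    def test_mixed_entry_is_H_inverse_composition(self, rng):
        x = rng.standard_normal(60)
        b = (rng.standard_normal(60) + 0.3 * x > 0.4).astype(float)
        data = DataMatrix(np.column_stack([b, x]),
                          types=["binary", "continuous"])
        est = latent_correlation(data, psd=False)
        tau = kendall_tau(b, x)
        lam = estimate_cutoffs(data)[0]
        assert est.source == "mixed"
        assert est.matrix[0, 1] == pytest.approx(
            bridge_H_inverse(tau, lam), abs=1e-12
        )

    @staticmethod
    def _hub_sigma(p, seed):
        from ldnet import generate_hub_precision

        omega, _ = generate_hub_precision(p, seed=seed)
        s = np.linalg.inv(omega)
        d = np.sqrt(np.diag(s))
        s = s / np.outer(d, d)
        np.fill_diagonal(s, 1.0)
        return s

    def test_parameter_recovery_improves_with_n(self):
        sigma = self._hub_sigma(5, seed=3)
        cut = np.array([0.2, 0.8, 0.5, 0.1, 0.9])
        errs = {}
        for n in (200, 2000):
            x, _ = sample_npn(sigma, n, "gaussian_cdf", seed=8)
            obs = x.copy()
            obs[:, 3:] = (x[:, 3:] > cut[3:]).astype(float)
            d = DataMatrix(obs, types=["continuous"] * 3 + ["binary"] * 2)
            errs[n] = np.abs(latent_correlation(d).matrix - sigma).max()
        assert errs[2000] < errs[200]
        assert errs[2000] < 0.1

    def test_gaussian_data_npn_close_to_pearson(self):
        sigma = self._hub_sigma(5, seed=11)
        _, z = sample_npn(sigma, 2000, "id", seed=4)
        est = latent_correlation(DataMatrix(z, types="continuous"))
        pearson = np.corrcoef(z, rowvar=False)
        assert np.abs(est.matrix - pearson).max() < 0.05

    def test_nearest_psd_projection(self, rng):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        from ldnet.rank import LatentCorrelation

        lc = LatentCorrelation(m, "npn").nearest_psd()
        w = np.linalg.eigvalsh(lc.matrix)
        assert w.min() >= -1e-12
        assert np.allclose(np.diag(lc.matrix), 1.0)
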