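"""Latent process operations and the assembled joint density."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

import airedna as a
from airedna.model import LatentProcess, ModelData, joint_log_density
from airedna.qpcr import PLATE_COLUMNS


class TestExpectedCount:
    def test_values_and_linearity(self):
        assert a.expected_count(160.4, 1) == pytest.approx(160.4)
        assert a.expected_count(50.0, 0) == 0.0
        assert a.expected_count(2 * 7.0, 3) == pytest.approx(
            2 * a.expected_count(7.0, 3)
        )


class TestCountLoglik:
    def test_pmf_normalizes(self):
        N = np.arange(0, 100_000)
        ll = a.count_loglik(N, 160.4, 20.0)
        assert abs(np.exp(logsumexp(ll)) - 1.0) < 1e-8

    def test_matches_scipy_nbinom(self):
        # independent route: scipy's (n, p) parameterization with n=phi,
        # p=phi/(phi+lam)
        lam, phi = 37.5, 20.0
        N = np.arange(0, 400)
        ours = a.count_loglik(N, lam, phi)
        ref = stats.nbinom.logpmf(N, phi, phi / (phi + lam))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_poisson_limit(self):
        # checked across the central support (lam +/- 3 sd); the remaining
        # O(((N-lam)^2)/phi) gap vanishes as phi -> infinity
        lam = 160.4
        N = np.arange(120, 200)
        diff = a.count_loglik(N, lam, 1e8) - stats.poisson.logpmf(N, lam)
        assert np.max(np.abs(diff)) < 1e-4

    def test_simulated_variance_matches_relation(self):
        lam, phi, n = 160.4, 20.0, 100_000
        draws = a.simulate_counts([lam] * n, [1] * n, phi, seed=12).astype(float)
        target = lam + lam**2 / phi
        assert draws.var() == pytest.approx(target, rel=0.05)

    def test_degenerate_lambda_rejected(self):
        with pytest.raises(ValueError):
            a.count_loglik(3, 0.0, 20.0)


class TestWaterAndAir:
    def test_water_concentration_reported_value(self):
        W = a.water_concentration(1.0, 9.578)
        assert 12_000 < W < 18_000
        assert a.water_concentration(5.0, 0.0) == pytest.approx(5.0)

    def test_air_log_mean_closed_form(self):
        lnA = a.air_log_mean(14_443.0, -9.53)
        assert lnA == pytest.approx(np.log(14_443.0) - 9.53)
        assert np.exp(lnA) == pytest.approx(1.048, rel=5e-3)
        assert a.air_log_mean(np.e, 0.0) == pytest.approx(1.0)

    def test_sampler_contrasts_do_not_depend_on_water(self):
        for W in (1.0, 1e3, 1e7):
            d = a.air_log_mean(W, -9.5) - a.air_log_mean(W, -10.9)
            assert d == pytest.approx(1.4)


class TestReplicates:
    def test_sum_to_zero_pair(self):
        logs = a.replicate_log_conc(2.0, [0.1, -0.1])
        assert logs.tolist() == pytest.approx([2.1, 1.9])
        assert logs.mean() == pytest.approx(2.0)
        same = a.replicate_log_conc(1.5, [0.0, 0.0])
        assert same.tolist() == [1.5, 1.5]

    def test_constraint_violation_asserts(self):
        with pytest.raises(AssertionError):
            a.replicate_log_conc(1.0, [0.1, 0.05])

    def test_rho_moment_recovery_from_pairs(self):
        rho, n = 0.154, 1000
        rng = np.random.default_rng(31)
        d1, d2 = rng.normal(0, rho, (2, n))
        half = 0.5 * (d1 - d2)
        rho_hat = np.sqrt(2.0) * half.std()
        se = rho / np.sqrt(2 * n)
        assert abs(rho_hat - rho) < 3 * se


class TestReactionConcentrations:
    def test_water_normalization(self):
        assert a.reaction_conc_water(14_443.0, 1.0, 10.0) == pytest.approx(1444.3)
        assert a.reaction_conc_water(55.0, 10.0, 10.0) == pytest.approx(55.0)
        assert a.reaction_conc_water(55.0, 2.0, 10.0) == pytest.approx(
            2 * a.reaction_conc_water(55.0, 1.0, 10.0)
        )

    def test_air_normalization_filter_and_tray_geometry(self):
        assert a.reaction_conc_air(1.0, 16.0, 1.0, 10.0) == pytest.approx(1.6)
        assert a.reaction_conc_air(1.0, 750.0, 1.0, 10.0) == pytest.approx(75.0)
        base = a.reaction_conc_air(2.0, 16.0, 3.0, 10.0)
        assert a.reaction_conc_air(4.0, 16.0, 3.0, 10.0) == pytest.approx(2 * base)
        assert a.reaction_conc_air(2.0, 16.0, 3.0, 20.0) == pytest.approx(base / 2)


def _tiny_instance():
    """2 timepoints, 1 single-replicate sampler, 4 wells."""
    counts = pd.DataFrame({"t": [0, 1], "N": [0, 70], "E": [0, 7]})
    metadata = pd.DataFrame(
        [
            ("w0", "water", 0, "", 1, 1.0, 10.0, np.nan, np.nan),
            ("a0", "air", 0, "mce_air", 1, np.nan, 10.0, 16.0, 1.0),
            ("a1", "air", 1, "mce_air", 1, np.nan, 10.0, 16.0, 1.0),
        ],
        columns=["sample_id", "sample_class", "t", "sampler", "bio_rep",
                 "F_l", "V_ul", "S_cm2", "P_days"],
    )
    plates = pd.DataFrame(
        [
            ("std", "standard", 0, 1, 100.0, 1, 31.2),
            ("w0", "water", 0, 1, np.nan, 1, 22.0),
            ("a0", "air", 0, 1, np.nan, 0, np.nan),
            ("a1", "air", 0, 1, np.nan, 1, 36.0),
        ],
        columns=PLATE_COLUMNS,
    )
    return counts, metadata, plates


class TestJointLogDensity:
    CALIB = a.QpcrCalibration(
        theta=0.7, beta0=39.0, beta1=np.array([-1.5]), gamma0=-1.0,
        gamma1=-0.05,
    )
    LATENT = LatentProcess(
        X=np.array([40.0, 11.0]),
        omega_log=9.0,
        eta=np.array([-10.5]),
        tau=np.array([0.8]),
        rho=np.array([]),
        phi=20.0,
        eps=np.array([[0.3], [-0.2]]),
        delta_half=np.zeros((2, 0)),
    )

    def _oracle(self, latent, calib, priors):
        """Hand-computed sum of the four named density terms."""
        counts, metadata, plates = _tiny_instance()
        W = latent.X * np.exp(latent.omega_log)
        lnA = latent.eta[0] + np.log(W) + latent.eps[:, 0]
        # 1. counts: only t=1 has effort
        lam = latent.X[1] * 7.0
        total = stats.nbinom.logpmf(70, latent.phi, latent.phi / (latent.phi + lam))
        # 2. air transfer noise
        total += stats.norm.logpdf(latent.eps[:, 0], 0.0, latent.tau[0]).sum()
        # 3. wells
        def well(K, Z, Y):
            psi = 1 - np.exp(-K * calib.theta)
            out = stats.bernoulli.logpmf(Z, psi)
            if Z == 1:
                mu = calib.beta0 + calib.beta1[0] * np.log(K)
                sig = np.exp(calib.gamma0 + calib.gamma1 * np.log(K))
                out += stats.norm.logpdf(Y, mu, sig)
            return out

        total += well(100.0, 1, 31.2)
        total += well(W[0] * 1.0 / 10.0, 1, 22.0)
        Q = np.exp(lnA) * 16.0 * 1.0 / 10.0
        total += well(Q[0], 0, None)
        total += well(Q[1], 1, 36.0)
        # 4. priors
        total += stats.norm.logpdf(np.log(latent.X), *priors.log_x).sum()
        total += stats.norm.logpdf(latent.omega_log, *priors.omega_log)
        total += stats.norm.logpdf(latent.eta, *priors.eta).sum()
        total += stats.halfcauchy.logpdf(latent.tau, scale=priors.tau_scale).sum()
        total += stats.expon.logpdf(calib.theta, scale=priors.theta_mean)
        total += stats.norm.logpdf(calib.beta0, *priors.beta0)
        total += stats.norm.logpdf(calib.beta1, *priors.beta1).sum()
        total += stats.norm.logpdf(calib.gamma0, *priors.gamma0)
        total += stats.norm.logpdf(calib.gamma1, *priors.gamma1)
        return float(total)

    def test_matches_term_by_term_oracle(self):
        counts, metadata, plates = _tiny_instance()
        md = ModelData.from_tables(counts, metadata, plates, phi=20.0)
        priors = a.PriorConfig()
        ours = joint_log_density(self.LATENT, self.CALIB, md, priors)
        assert ours == pytest.approx(self._oracle(self.LATENT, self.CALIB, priors),
                                     rel=1e-10)

    def test_empty_plate_leaves_density_unchanged(self):
        counts, metadata, plates = _tiny_instance()
        priors = a.PriorConfig()
        md = ModelData.from_tables(counts, metadata, plates, phi=20.0)
        base = joint_log_density(self.LATENT, self.CALIB, md, priors)
        extra = pd.concat(
            [plates, pd.DataFrame(columns=PLATE_COLUMNS)], ignore_index=True
        )
        md2 = ModelData.from_tables(counts, metadata, extra, phi=20.0)
        assert joint_log_density(self.LATENT, self.CALIB, md2, priors) == base

    def test_displaced_ct_lowers_density(self):
        counts, metadata, plates = _tiny_instance()
        priors = a.PriorConfig()
        base = joint_log_density(
            self.LATENT, self.CALIB,
            ModelData.from_tables(counts, metadata, plates, phi=20.0), priors,
        )
        worse = plates.copy()
        worse.loc[1, "Ct"] += 10.0
        md = ModelData.from_tables(counts, metadata, worse, phi=20.0)
        assert joint_log_density(self.LATENT, self.CALIB, md, priors) < base
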