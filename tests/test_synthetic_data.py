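"""Generator-level checks: moment recovery, closed forms, determinism."""

import numpy as np
import pandas as pd
import pytest

import airedna as a
from airedna.model import LatentProcess, ModelData, joint_log_density
from airedna.synth import DEFAULT_STANDARD_SERIES


class TestSimulateCounts:
    def test_zero_effort_forces_zero_count(self):
        assert a.simulate_counts([100.0], [0], 20.0, seed=1).tolist() == [0]

    def test_negative_binomial_moments(self):
        n = 100_000
        lam = 160.4
        draws = a.simulate_counts([lam] * n, [1] * n, 20.0, seed=2).astype(float)
        target_var = lam + lam**2 / 20.0  # ~1446.8
        se_mean = np.sqrt(target_var / n)
        assert abs(draws.mean() - lam) < 4 * se_mean
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt(max(m4 - target_var**2, 0.0) / n)
        assert abs(draws.var() - target_var) < 4 * se_var

    def test_poisson_limit_variance_ratio(self):
        n = 100_000
        draws = a.simulate_counts([160.4] * n, [1] * n, 1e9, seed=3).astype(float)
        ratio = draws.var() / draws.mean()
        assert abs(ratio - 1.0) < 0.03

    def test_invalid_phi_raises(self):
        with pytest.raises(ValueError):
            a.simulate_counts([10.0], [1], 0.0, seed=1)


class TestSimulateWater:
    def test_reported_conversion_scale(self):
        # 1 fish/day at the fitted integrated eDNA factor lands in the
        # ~15,000 (+/- 3,000) copies/L band
        W = a.simulate_water([1.0], 9.578)
        assert np.isclose(W[0], np.exp(9.578), rtol=1e-12)
        assert 12_000 < W[0] < 18_000

    def test_identity_and_proportionality(self):
        assert a.simulate_water([2.0, 4.0], 0.0).tolist() == [2.0, 4.0]
        W = a.simulate_water([1e-9], 3.0)
        assert W[0] == pytest.approx(1e-9 * np.e**3)

    def test_rejects_nonpositive_x(self):
        with pytest.raises(ValueError):
            a.simulate_water([0.0], 1.0)


class TestSimulateAir:
    ETA = np.array([-10.45, -9.53, -10.91, -9.95])

    def test_noise_free_closed_form(self):
        W = np.array([14_443.0])
        tiny = np.full(4, 1e-12)
        air = a.simulate_air(W, self.ETA, tiny, np.full(2, 1e-12), seed=4)
        per = air.groupby("sampler", sort=False)["A"].mean()
        expected = W[0] * np.exp(self.ETA)
        for j, s in enumerate(a.SAMPLERS):
            assert per[s] == pytest.approx(expected[j], rel=1e-6)
        # matches the published per-sampler deposition at 1 fish/day
        assert np.allclose(
            expected, [0.415, 1.043, 0.261, 0.687], rtol=2e-2
        )

    def test_zero_intercept_returns_water(self):
        W = np.array([123.0, 77.0])
        air = a.simulate_air(
            W, np.zeros(4), np.full(4, 1e-12), np.full(2, 1e-12), seed=5
        )
        single = air[air.sampler == "mce_air"].sort_values("t")
        assert np.allclose(single["A"].to_numpy(), W, rtol=1e-6)

    def test_replicate_deviation_sd_recovery(self):
        rho = 0.386
        n = 10_000
        W = np.full(n, 1000.0)
        air = a.simulate_air(
            W, self.ETA, np.full(4, 1e-12), np.array([rho, 1e-12]), seed=6
        )
        gel = air[air.sampler == "gelatin"].pivot(
            index="t", columns="bio_rep", values="A"
        )
        # log replicate deviations are i.i.d. N(0, rho) in generation, so
        # the half-difference has sd rho/sqrt(2)
        half = 0.5 * (np.log(gel[1]) - np.log(gel[2]))
        rho_hat = half.std() * np.sqrt(2.0)
        se = rho / np.sqrt(2 * n)
        assert abs(rho_hat - rho) < 4 * se

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            a.simulate_air([1.0], np.zeros(3), np.ones(4), np.ones(2), seed=1)


class TestStandardSeries:
    def test_default_replication_scheme(self):
        std = a.make_standard_series()
        assert int(std["n_reps"].sum()) == 16
        assert dict(zip(std["K"], std["n_reps"])) == {
            1e5: 3, 1e4: 3, 1e3: 3, 1e2: 4, 1e1: 3
        }
        assert std.attrs["stock_copies_per_ul"] == 1e6

    def test_override_passthrough(self):
        std = a.make_standard_series({1e2: 2})
        assert int(std.loc[std["K"] == 1e2, "n_reps"].iloc[0]) == 2

    def test_levels_positive_strictly_decreasing_by_decade(self):
        K = a.make_standard_series()["K"].to_numpy()
        assert np.all(K > 0)
        assert np.allclose(K[:-1] / K[1:], 10.0)


class TestSimulateQpcr:
    def test_no_template_never_amplifies(self):
        wells = a.simulate_qpcr([0.0], a.QpcrCalibration(), 50, seed=7)
        assert (wells["Z"] == 0).all()
        assert wells["Ct"].isna().all()

    def test_half_detection_at_log2_rate(self):
        calib = a.QpcrCalibration(theta=np.log(2.0))
        wells = a.simulate_qpcr([1.0], calib, 40_000, seed=8)
        p = wells["Z"].mean()
        assert abs(p - 0.5) < 4 * np.sqrt(0.25 / 40_000)

    def test_high_copy_detection_and_ct_mean(self):
        calib = a.QpcrCalibration(theta=0.1, beta1=np.array([-1.4427]))
        wells = a.simulate_qpcr([1e5], calib, 10_000, seed=9)
        assert wells["Z"].mean() == pytest.approx(1.0)
        mu, sigma = a.ct_moments(1e5, calib, 0)
        assert abs(wells["Ct"].mean() - mu) < 4 * sigma / np.sqrt(len(wells))

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            a.simulate_qpcr([-1.0], a.QpcrCalibration(), 1, seed=1)


class TestDataset:
    def test_identical_seed_gives_byte_identical_dataset(self, tmp_path):
        cfg = a.SimulationConfig(seed=42)
        d1 = a.simulate_dataset(cfg)
        d2 = a.simulate_dataset(a.SimulationConfig(seed=42))
        p1 = d1.write(tmp_path / "one")
        p2 = d2.write(tmp_path / "two")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_plate_rows_join_metadata_and_controls_silent(self, dataset):
        env = dataset.plates[dataset.plates.sample_class.isin(["water", "air"])]
        assert set(env.sample_id) <= set(dataset.metadata.sample_id)
        ctrl = dataset.plates[dataset.plates.sample_class == "control"]
        assert (ctrl.Z == 0).all()
        std = dataset.plates[dataset.plates.sample_class == "standard"]
        # replication scheme per plate: 16 reactions
        per_plate = std.groupby("plate").size()
        assert (per_plate == sum(DEFAULT_STANDARD_SERIES.values())).all()


class TestGenerativeInferenceConsistency:
    def test_joint_density_peaks_at_truth_on_noise_free_data(self):
        cfg = a.SimulationConfig(
            seed=5,
            tau=np.full(4, 1e-9),
            rho=np.full(2, 1e-9),
            calib=a.QpcrCalibration(
                theta=50.0, gamma0=-5.0, gamma1=0.0,
                beta1=np.array([-1.4427]),
            ),
            n_tech_reps=2,
        )
        ds = a.simulate_dataset(cfg)
        md = ModelData.from_tables(ds.counts, ds.metadata, ds.plates, phi=cfg.phi)
        priors = a.PriorConfig()

        def density(omega_shift=0.0, eta_shift=np.zeros(4)):
            latent = LatentProcess(
                X=cfg.true_X,
                omega_log=cfg.omega_log + omega_shift,
                eta=cfg.eta + eta_shift,
                tau=cfg.tau,
                rho=cfg.rho,
                phi=cfg.phi,
                eps=np.zeros((6, 4)),
                delta_half=np.zeros((6, 2)),
            )
            return joint_log_density(latent, cfg.calib, md, priors)

        base = density()
        assert np.isfinite(base)
        for shift in (-0.2, -0.05, 0.05, 0.2):
            assert density(omega_shift=shift) < base
            for j in range(4):
                e = np.zeros(4)
                e[j] = shift
                assert density(eta_shift=e) < base
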