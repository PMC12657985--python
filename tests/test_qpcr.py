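"""qPCR observation model: detection curve, Ct moments, well likelihoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import airedna as a
from airedna.qpcr import validate_plate_table, fit_standards_start
from airedna.model import ModelData


class TestDetectionProbability:
    def test_boundary_and_closed_form(self):
        assert a.detection_probability(0.0, 1.0) == 0.0
        assert a.detection_probability(1.0, np.log(2.0)) == pytest.approx(0.5)

    @given(st.floats(min_value=1e-6, max_value=50.0))
    def test_monotone_in_concentration(self, theta):
        K = 10.0 ** np.arange(1, 7)
        psi = a.detection_probability(K, theta)
        assert np.all(np.diff(psi) >= 0)
        assert np.all((psi >= 0) & (psi < 1.0 + 1e-15))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            a.detection_probability(-1.0, 1.0)
        with pytest.raises(ValueError):
            a.detection_probability(1.0, 0.0)


class TestCtMoments:
    def test_linear_mean(self):
        calib = a.QpcrCalibration(beta0=40.0, beta1=np.array([-1.44]))
        mu, _ = a.ct_moments(np.e**10, calib, 0)
        assert mu == pytest.approx(40.0 - 14.4)

    def test_constant_sd_when_slope_free(self):
        calib = a.QpcrCalibration(gamma0=-1.0, gamma1=0.0)
        for K in (1.0, 1e3, 1e6):
            _, sigma = a.ct_moments(K, calib, 0)
            assert sigma == pytest.approx(np.exp(-1.0))

    def test_perfect_efficiency_slope_gives_3_32_cycles_per_decade(self):
        # standard qPCR identity: Ct drop per decade = |beta1| * ln 10
        calib = a.QpcrCalibration(beta1=np.array([-1.4427]))
        mu10, _ = a.ct_moments(10.0, calib, 0)
        mu100, _ = a.ct_moments(100.0, calib, 0)
        assert mu10 - mu100 == pytest.approx(3.322, abs=1e-3)

    def test_unknown_plate_raises(self):
        calib = a.QpcrCalibration(beta1=np.array([-1.44]))
        with pytest.raises(IndexError):
            a.ct_moments(10.0, calib, plate_id=5)


def _records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "sample_class", "plate",
                                       "tech_rep", "K", "Z", "Ct"])


class TestObservationLoglik:
    def test_empty_set_scores_zero(self):
        calib = a.QpcrCalibration()
        assert a.observation_loglik(_records([]), [], calib) == 0.0

    def test_single_dropout_closed_form(self):
        calib = a.QpcrCalibration(theta=np.log(2.0))
        rec = _records([("s", "standard", 0, 1, 1.0, 0, np.nan)])
        ll = a.observation_loglik(rec, [1.0], calib)
        assert ll == pytest.approx(np.log(0.5))

    def test_additivity_against_per_record_oracle(self):
        calib = a.QpcrCalibration(
            theta=0.8, beta0=39.0, beta1=np.array([-1.5, -1.3]), gamma0=-1.2,
            gamma1=-0.05,
        )
        rows = [
            ("a", "standard", 0, 1, 100.0, 1, 31.0),
            ("b", "standard", 1, 1, 10.0, 0, np.nan),
            ("c", "water", 0, 1, np.nan, 1, 26.5),
        ]
        concs = np.array([100.0, 10.0, 550.0])
        total = a.observation_loglik(_records(rows), concs, calib)
        expected = 0.0
        for (sid, cls, plate, rep, K, Z, Y), conc in zip(rows, concs):
            psi = 1.0 - np.exp(-conc * calib.theta)
            expected += stats.bernoulli.logpmf(Z, psi)
            if Z == 1:
                mu = calib.beta0 + calib.beta1[plate] * np.log(conc)
                sig = np.exp(calib.gamma0 + calib.gamma1 * np.log(conc))
                expected += stats.norm.logpdf(Y, mu, sig)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_amplified_without_ct_is_a_data_error(self):
        rec = _records([("s", "standard", 0, 1, 10.0, 1, np.nan)])
        with pytest.raises(ValueError):
            a.observation_loglik(rec, [10.0], a.QpcrCalibration())


class TestDetectionCurve:
    def test_closed_form_and_monotone(self):
        calib = a.QpcrCalibration(theta=0.1)
        curve = a.detection_curve(calib, [10.0, 100.0])
        assert curve["psi"].tolist() == pytest.approx(
            [1 - np.exp(-1.0), 1 - np.exp(-10.0)]
        )
        # strictly increasing until float saturation at psi == 1
        grid = np.logspace(0, 2.4, 30)
        psi = a.detection_curve(calib, grid)["psi"].to_numpy()
        assert np.all(np.diff(psi) > 0)
        wide = a.detection_curve(calib, np.logspace(0, 6, 30))["psi"].to_numpy()
        assert np.all(np.diff(wide) >= 0) and wide[-1] <= 1.0

    def test_doubling_theta_never_lowers_detection(self):
        grid = np.logspace(-2, 6, 40)
        lo = a.detection_curve(a.QpcrCalibration(theta=0.2), grid)["psi"]
        hi = a.detection_curve(a.QpcrCalibration(theta=0.4), grid)["psi"]
        assert np.all(hi.to_numpy() >= lo.to_numpy())


class TestIngest:
    def test_undetermined_ct_coerced_with_report(self):
        df = _records([
            ("s", "standard", 0, 1, 10.0, 1, "Undetermined"),
            ("t", "standard", 0, 2, 10.0, 1, 33.1),
        ])
        clean, report = validate_plate_table(df)
        assert clean.loc[0, "Z"] == 0 and np.isnan(clean.loc[0, "Ct"])
        assert len(report.coerced_ct) == 1 and not report.clean

    def test_amplified_control_warns_not_fails(self):
        df = _records([("ntc", "control", 0, 1, 0.0, 1, 38.0)])
        with pytest.warns(UserWarning, match="contamination"):
            clean, report = validate_plate_table(df)
        assert report.contaminated_controls == ["ntc"]

    def test_standard_without_concentration_rejected(self):
        df = _records([("s", "standard", 0, 1, np.nan, 0, np.nan)])
        with pytest.raises(ValueError, match="standard"):
            validate_plate_table(df)


class TestCalibrationRecovery:
    def test_standards_only_fit_recovers_truth_within_3_sd(self):
        # 16 reactions x 50 plates pooled onto one shared slope
        truth = a.QpcrCalibration(
            theta=0.6, beta0=38.5, beta1=np.array([-1.45]), gamma0=-1.1,
            gamma1=-0.05,
        )
        rows = []
        std = a.make_standard_series()
        rng_seed = 0
        for p in range(50):
            for _, lv in std.iterrows():
                K, n = float(lv["K"]), int(lv["n_reps"])
                rng_seed += 1
                wells = a.simulate_qpcr([K], truth, n, seed=rng_seed)
                for _, w in wells.iterrows():
                    rows.append(("std", "standard", 0, int(w["tech_rep"]),
                                 K, int(w["Z"]), w["Ct"]))
        plates = _records(rows)
        md = ModelData.from_tables(None, None, plates)
        fit = a.fit(md, mcmc=a.McmcConfig(
            n_chains=4, n_warmup=300, n_sampling=300, seed=3
        ))
        s = fit.summary()
        for name, true_val in [
            ("theta", truth.theta), ("beta0", truth.beta0),
            ("beta1[0]", truth.beta1[0]), ("gamma0", truth.gamma0),
            ("gamma1", truth.gamma1),
        ]:
            row = s.loc[name]
            assert abs(row["mean"] - true_val) < 3 * row["sd"], name

    def test_least_squares_starting_point_is_sane(self, dataset):
        est = fit_standards_start(dataset.plates)
        assert est.beta0 == pytest.approx(38.0, abs=2.0)
        assert np.all(est.beta1 < -1.0)
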