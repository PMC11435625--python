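"""Frequentist calibration, regression and clearance arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from hepatoclear import (
    DepletionDataset,
    Measurement,
    SimulationTruth,
    clint_to_k,
    estimate_clint,
    fit_calibration,
    fit_log_linear,
    quantify,
    simulate_depletion,
    summarize_distribution,
)
from hepatoclear.point import (
    CalibrationError,
    RegressionError,
    RegressionFit,
    assess_abiotic,
    clint_from_fit,
)


def cal_dataset(levels, responses, cid="C"):
    ms = [
        Measurement(cid, 0.0, "calibration", i + 1, r, True, nominal_conc_uM=c)
        for i, (c, r) in enumerate(zip(levels, responses))
    ]
    ms += [Measurement(cid, t, "cells", 1, 1.0) for t in (0.0, 60.0)]
    return DepletionDataset(cid, ms)


class TestCalibration:
    def test_exact_linearity_gives_slope_and_zero_residual(self):
        levels = (0.1, 0.5, 1.0)
        ds = cal_dataset(levels, [2.0 * c for c in levels])
        fit = fit_calibration(ds)
        assert fit.response_factor == pytest.approx(2.0)
        assert fit.fit_residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_zero_intercept_ols_closed_form(self):
        rng = np.random.default_rng(3)
        x = np.array([0.05, 0.1, 0.25, 0.5, 1.0])
        y = 2.0 * x * np.exp(0.05 * rng.standard_normal(x.size))
        ds = cal_dataset(x, y)
        expected = float(np.dot(x, y) / np.dot(x, x))  # independent closed form
        assert fit_calibration(ds).response_factor == pytest.approx(expected)

    def test_single_level_raises(self):
        ds = cal_dataset((0.5, 0.5), (1.0, 1.1))
        with pytest.raises(CalibrationError):
            fit_calibration(ds)


class TestQuantify:
    def test_division_by_response_factor(self, strong_dataset):
        ds, _ = strong_dataset
        cal = fit_calibration(ds)
        df = quantify(ds, cal)
        m = ds.rows("cells")[0]
        row = df[(df.time_min == m.time_min) & (df.replicate == m.replicate)
                 & (df.condition == "cells")]
        assert row["conc_uM"].iloc[0] == pytest.approx(
            m.response / cal.response_factor
        )

    def test_zero_response_is_censored(self):
        ds = cal_dataset((0.1, 1.0), (0.2, 2.0))
        ds.measurements.append(Measurement("C", 120.0, "cells", 1, 0.0))
        df = quantify(ds, fit_calibration(ds))
        zero = df[df["conc_uM"] == 0.0]
        assert zero["censored"].all()

    def test_noiseless_round_trip_recovers_concentration(self, noiseless_dataset):
        ds, truth = noiseless_dataset
        df = quantify(ds, fit_calibration(ds))
        cells = df[df.condition == "cells"]
        expected = np.exp(-truth.k_bio_true * cells["time_min"].to_numpy())
        np.testing.assert_allclose(cells["conc_uM"].to_numpy(), expected, rtol=1e-10)


def quantified(conc_by_time, reps=3):
    rows = []
    for t, c in conc_by_time:
        for r in range(reps):
            rows.append(dict(time_min=t, condition="cells", replicate=r + 1,
                             conc_uM=c, censored=False))
    return pd.DataFrame(rows)


class TestLogLinear:
    def test_flat_series_has_zero_slope_p_one(self):
        fit = fit_log_linear(quantified([(t, 1.0) for t in (0, 30, 60, 120)]))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.p_value == pytest.approx(1.0)

    def test_exact_exponential_recovered_to_ten_digits(self):
        grid = (0, 30, 60, 120, 240)
        fit = fit_log_linear(
            quantified([(t, math.exp(-0.005 * t)) for t in grid])
        )
        assert fit.slope == pytest.approx(-0.005, rel=1e-10)
        assert fit.p_value < 1e-6
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_estimate_unbiased_over_simulations(self):
        # 1000 noisy replicate experiments; mean slope within 2 MC-SE of truth
        k = clint_to_k(5.0)
        slopes = []
        for i in range(1000):
            truth = SimulationTruth(f"S{i}", k_bio_true=k, noise_sd_true=0.1,
                                    seed=9000 + i)
            ds, _ = simulate_depletion(truth, include_controls=False,
                                       include_calibration=False)
            t = np.array([m.time_min for m in ds.rows("cells")])
            y = np.log([m.response for m in ds.rows("cells")])
            df = pd.DataFrame(dict(time_min=t, condition="cells",
                                   replicate=1, conc_uM=np.exp(y),
                                   censored=False))
            slopes.append(fit_log_linear(df).slope)
        slopes = np.array(slopes)
        mc_se = slopes.std(ddof=1) / math.sqrt(slopes.size)
        assert abs(slopes.mean() - (-k)) < 2 * mc_se

    def test_all_censored_raises(self):
        df = quantified([(0, 1.0), (60, 1.0)])
        df["censored"] = True
        with pytest.raises(RegressionError, match="insufficient quantifiable"):
            fit_log_linear(df)


class TestClintFromFit:
    DS = DepletionDataset(
        "C", [Measurement("C", t, "cells", 1, 1.0) for t in (0.0, 60.0)]
    )

    def fit(self, slope, p):
        return RegressionFit(slope=slope, slope_se=1e-4, p_value=p,
                             intercept=0.0, r_squared=0.5, n_obs=18)

    def test_nonsignificant_p_gives_zero_clint(self):
        est = clint_from_fit(self.fit(-0.001, 0.2), self.DS)
        assert est.clint == 0.0 and not est.significant
        assert est.half_life_min is None

    def test_hand_arithmetic_half_life_and_clint(self):
        est = clint_from_fit(self.fit(-0.00347, 1e-4), self.DS)
        assert est.significant
        assert est.half_life_min == pytest.approx(math.log(2) / 0.00347)
        assert est.half_life_min == pytest.approx(199.8, rel=1e-3)
        assert est.clint == pytest.approx(0.00347 * 2000, rel=1e-12)

    def test_positive_slope_is_never_clearance(self):
        est = clint_from_fit(self.fit(+0.002, 1e-6), self.DS)
        assert est.clint == 0.0 and not est.significant

    def test_half_life_slope_product_is_ln2(self):
        for slope in (-0.0005, -0.003, -0.02):
            est = clint_from_fit(self.fit(slope, 1e-9), self.DS)
            assert est.half_life_min * (-slope) == pytest.approx(math.log(2))


class TestAbiotic:
    def test_flat_controls_not_significant(self, flat_dataset):
        ds, _ = flat_dataset
        cal = fit_calibration(ds)
        _, sig, rate, warns = assess_abiotic(ds, cal)
        assert not sig and rate == pytest.approx(0.0, abs=1e-3)
        assert warns == []

    def test_decaying_controls_recovered_exactly(self):
        truth = SimulationTruth("AB", k_bio_true=0.0, k_abio_true=0.002,
                                noise_sd_true=0.0, seed=2)
        ds, _ = simulate_depletion(truth)
        fit, sig, rate, _ = assess_abiotic(ds, fit_calibration(ds))
        assert sig
        assert rate == pytest.approx(0.002, rel=1e-9)

    def test_missing_controls_warn_and_absent(self, flat_dataset):
        ds, _ = flat_dataset
        ds_nc = DepletionDataset(
            ds.chemical_id,
            [m for m in ds.measurements if m.condition in ("cells", "calibration")],
            loq_uM=ds.loq_uM,
        )
        fit, sig, rate, warns = assess_abiotic(ds_nc, fit_calibration(ds_nc))
        assert fit is None and not sig and rate == 0.0
        assert any("no negative-control rows" in w for w in warns)


class TestSummary:
    def make(self, clints):
        from hepatoclear.point import ClintEstimate

        return [
            ClintEstimate(f"c{i}", clint=c, significant=c > 0)
            for i, c in enumerate(clints)
        ]

    def test_single_significant_value(self):
        s = summarize_distribution(self.make([0, 0, 0, 4.52]))
        assert s.n_zero == 3
        assert s.median_significant == pytest.approx(4.52)

    def test_all_zero_median_absent(self):
        s = summarize_distribution(self.make([0, 0]))
        assert s.median_significant is None

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_distribution([])


def test_full_pipeline_noiseless_exact(noiseless_dataset):
    ds, truth = noiseless_dataset
    est = estimate_clint(ds)
    assert est.significant
    assert est.clint == pytest.approx(truth.k_bio_true * 2000, rel=1e-9)
    assert not est.abiotic_significant
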