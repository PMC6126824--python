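"""Maximum-likelihood ensemble checks between two state points."""

import numpy as np
import pytest

from simval.constants import BAR_NM3_TO_KJ_PER_MOL, KB
from simval.data import EnsembleSpec
from simval.ensemble import (
    OverlapError,
    StatePointPair,
    bootstrap_slope_errors,
    deviation_verdict,
    interval_estimates,
    ml_slope_fit,
    suggest_intervals,
    true_slopes,
)
from simval.toymd import gamma_kinetic_sampler, gaussian_dos_sampler

T1, T2 = 300.0, 308.0
B1, B2 = 1 / (KB * T1), 1 / (KB * T2)
SIGMA_E = 2 * KB * T1 * T2 / 8.0  # rule-of-thumb width for an 8 K interval
DOS_A = (B1 + B2) / 2 + 1e-3


def nvt_pair(n, seed, beta2=B2, sigma=SIGMA_E):
    u1 = gaussian_dos_sampler(sigma, DOS_A, B1, n, seed=2 * seed)
    u2 = gaussian_dos_sampler(sigma, DOS_A, beta2, n, seed=2 * seed + 1)
    return StatePointPair(
        EnsembleSpec("NVT", T1), EnsembleSpec("NVT", T2), energy=(u1, u2)
    )


class TestSlopeFit:
    def test_recovers_true_slope_with_coverage(self):
        hits = 0
        for seed in range(40):
            fit = ml_slope_fit(nvt_pair(4000, seed), "T")
            se = fit.slope_se("a_E")
            hits += abs(fit.slopes["a_E"] - (B2 - B1)) <= 3 * se
        assert hits >= 38  # >= 95% nominal coverage

    def test_null_slope_near_zero(self):
        u1 = gaussian_dos_sampler(SIGMA_E, DOS_A, B1, 8000, seed=100)
        u2 = gaussian_dos_sampler(SIGMA_E, DOS_A, B1, 8000, seed=101)
        pair = StatePointPair(
            EnsembleSpec("NVT", T1), EnsembleSpec("NVT", T1), energy=(u1, u2)
        )
        fit = ml_slope_fit(pair, "T")
        assert abs(fit.slopes["a_E"]) <= 3.5 * fit.slope_se("a_E")

    def test_agrees_with_binned_log_ratio_regression(self):
        # direct linear regression on log(h2/h1) over well-populated bins
        n = 200_000
        u1 = gaussian_dos_sampler(SIGMA_E, DOS_A, B1, n, seed=7)
        u2 = gaussian_dos_sampler(SIGMA_E, DOS_A, B2, n, seed=8)
        lo, hi = np.percentile(np.concatenate([u1, u2]), [2, 98])
        bins = np.linspace(lo, hi, 40)
        h1, _ = np.histogram(u1, bins)
        h2, _ = np.histogram(u2, bins)
        ok = (h1 >= 100) & (h2 >= 100)
        centers = 0.5 * (bins[1:] + bins[:-1])
        binned = -np.polyfit(centers[ok], np.log(h2[ok] / h1[ok]), 1)[0]
        pair = StatePointPair(
            EnsembleSpec("NVT", T1), EnsembleSpec("NVT", T2), energy=(u1, u2)
        )
        ml = ml_slope_fit(pair, "T").slopes["a_E"]
        assert ml == pytest.approx(binned, rel=0.02)

    def test_antisymmetric_under_swap(self):
        pair = nvt_pair(5000, 3)
        f = ml_slope_fit(pair, "T")
        g = ml_slope_fit(pair.swapped(), "T")
        assert g.slopes["a_E"] == pytest.approx(-f.slopes["a_E"], rel=1e-6)

    def test_two_parameter_fit_recovers_both_slopes(self):
        # independent E and V channels with known slopes
        e1 = EnsembleSpec("NPT", T1, pressure=1.0)
        e2 = EnsembleSpec("NPT", T2, pressure=301.0)
        truth = true_slopes(e1, e2, "TP")
        sigma_v = 2 * KB * T1 / (300.0 * BAR_NM3_TO_KJ_PER_MOL)  # ~300 bar apart
        a_v_dos = 0.5  # arbitrary reference slope for the volume channel
        rng_v1 = np.random.default_rng(21)
        rng_v2 = np.random.default_rng(22)
        v1 = rng_v1.normal(sigma_v**2 * (a_v_dos - 0.0), sigma_v, 6000)
        v2 = rng_v2.normal(sigma_v**2 * (a_v_dos - truth["a_V"]), sigma_v, 6000)
        u1 = gaussian_dos_sampler(SIGMA_E, DOS_A, B1, 6000, seed=23)
        u2 = gaussian_dos_sampler(SIGMA_E, DOS_A, B2, 6000, seed=24)
        pair = StatePointPair(e1, e2, energy=(u1, u2), volume=(v1, v2))
        fit = ml_slope_fit(pair, "TP")
        for name in ("a_E", "a_V"):
            assert abs(fit.slopes[name] - truth[name]) <= 3 * fit.slope_se(name), name

    def test_potential_vs_total_energy_equivalent(self):
        # adding an independent, exactly canonical kinetic part shifts the
        # energies but not the estimated slope (beyond noise)
        u1 = gaussian_dos_sampler(SIGMA_E, DOS_A, B1, 10_000, seed=31)
        u2 = gaussian_dos_sampler(SIGMA_E, DOS_A, B2, 10_000, seed=32)
        k1 = gamma_kinetic_sampler(900, T1, 10_000, seed=33)
        k2 = gamma_kinetic_sampler(900, T2, 10_000, seed=34)
        spec = (EnsembleSpec("NVT", T1), EnsembleSpec("NVT", T2))
        fit_u = ml_slope_fit(StatePointPair(*spec, energy=(u1, u2)), "T")
        fit_e = ml_slope_fit(StatePointPair(*spec, energy=(u1 + k1, u2 + k2)), "T")
        se = fit_u.slope_se("a_E")
        assert abs(fit_u.slopes["a_E"] - fit_e.slopes["a_E"]) < se

    def test_no_overlap_raises(self):
        u1 = np.random.default_rng(0).normal(0.0, 1.0, 500)
        u2 = np.random.default_rng(1).normal(100.0, 1.0, 500)
        pair = StatePointPair(
            EnsembleSpec("NVT", T1), EnsembleSpec("NVT", T2), energy=(u1, u2)
        )
        with pytest.raises(OverlapError):
            ml_slope_fit(pair, "T")


class TestBootstrapErrors:
    def test_agrees_with_analytic_se(self):
        pair = nvt_pair(4000, 9)
        fit = ml_slope_fit(pair, "T")
        cov = bootstrap_slope_errors(pair, "T", n_resamples=100, seed=5)
        assert np.sqrt(cov[0, 0]) == pytest.approx(
            fit.slope_se("a_E"), rel=0.30
        )

    def test_deterministic_under_seed(self):
        pair = nvt_pair(1000, 10)
        c1 = bootstrap_slope_errors(pair, "T", n_resamples=20, seed=7)
        c2 = bootstrap_slope_errors(pair, "T", n_resamples=20, seed=7)
        np.testing.assert_array_equal(c1, c2)


class TestIntervalEstimates:
    def test_temperature_interval_identity(self):
        # at the true slope the interval is exact: a_E kB T1 T2 = T1 - T2
        est = interval_estimates({"a_E": B2 - B1}, T1, T2, mode="T")
        assert est.delta_T == pytest.approx(T1 - T2, rel=1e-12)

    def test_pressure_interval_1d_identity(self):
        e1 = EnsembleSpec("NPT", 300.0, pressure=1.0)
        e2 = EnsembleSpec("NPT", 300.0, pressure=301.0)
        a_v = true_slopes(e1, e2, "P")["a_V"]
        est = interval_estimates({"a_V": a_v}, 300.0, mode="P")
        assert est.delta_P == pytest.approx(300.0, abs=1e-9)

    def test_pressure_interval_2d_value(self):
        e1 = EnsembleSpec("NPT", 300.0, pressure=1.0)
        e2 = EnsembleSpec("NPT", 308.0, pressure=301.0)
        a_v = true_slopes(e1, e2, "TP")["a_V"]
        est = interval_estimates({"a_V": a_v}, 300.0, 308.0, mode="TP")
        assert round(est.delta_P, 1) == 296.1

    def test_se_propagation_is_linear(self):
        est = interval_estimates(
            {"a_E": B2 - B1}, T1, T2, slope_ses={"a_E": 1e-4}, mode="T"
        )
        assert est.delta_T_se == pytest.approx(1e-4 * KB * T1 * T2)


class TestDeviationVerdict:
    def test_exact_estimate_passes(self):
        rep = deviation_verdict({"delta_T": (8.0, 0.5)}, {"delta_T": 8.0})
        assert rep.deviations["delta_T"] == 0.0
        assert rep.passed

    def test_boundary_fails_just_above_tolerance(self):
        rep = deviation_verdict(
            {"x": (8.0 + 3.01 * 0.5, 0.5)}, {"x": 8.0}, tolerance=3.0
        )
        assert not rep.passed

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            deviation_verdict({"x": (1.0, 0.0)}, {"x": 1.0})


class TestSuggestIntervals:
    def test_temperature_spacing_closed_form(self):
        dT, _ = suggest_intervals(300.0, sigma_E=100.0)
        assert dT == pytest.approx(2 * KB * 300.0**2 / 100.0, rel=1e-12)
        assert dT == pytest.approx(14.97, abs=0.01)

    def test_pressure_spacing_unit_conversion(self):
        _, dP = suggest_intervals(300.0, sigma_V=1.0)
        expected = 2 * KB * 300.0 / BAR_NM3_TO_KJ_PER_MOL
        assert dP == pytest.approx(expected, rel=1e-12)

    def test_width_from_heat_capacity_factor_convention(self):
        dT2, _ = suggest_intervals(300.0, heat_capacity=0.075, factor_two=True)
        dT1, _ = suggest_intervals(300.0, heat_capacity=0.075, factor_two=False)
        assert dT1 == pytest.approx(np.sqrt(2) * dT2, rel=1e-12)

    def test_infinite_width_limit(self):
        dT, _ = suggest_intervals(300.0, sigma_E=1e12)
        assert dT < 1e-8

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            suggest_intervals(300.0, sigma_E=-1.0)
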