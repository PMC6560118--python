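"""nTAC construction, mono-exponential fitting, TIAC integration,
rest-of-body bookkeeping, cross-isotope extrapolation, and band fits."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import mousedosim as md
from mousedosim import kinetics as kin
from mousedosim.errors import (
    DataInconsistencyError,
    DegenerateFitError,
    InvalidArgumentError,
)


def make_ntac(times, values, sds=None, compartment="liver", nuclide=None):
    sds = sds if sds is not None else [0.0] * len(times)
    samples = tuple(
        kin.TimeActivitySample(t, v, s) for t, v, s in zip(times, values, sds)
    )
    return kin.NTAC(compartment=compartment, samples=samples, nuclide=nuclide)


class TestBuildNtac:
    def test_normalization(self):
        ntac = kin.build_ntac([4.0], [1.0], injected_mbq=10.0, compartment="liver")
        assert ntac.na[0] == pytest.approx(0.1)

    def test_cohort_identical_values_zero_sd(self):
        table = pd.DataFrame(
            {
                "animal_id": [f"m{i}" for i in range(5)],
                "compartment": ["liver"] * 5,
                "time_h": [4.0] * 5,
                "nA": [0.2] * 5,
            }
        )
        ntac = kin.cohort_ntac(table, "liver")
        assert ntac.sd[0] == 0.0
        assert ntac.samples[0].n_animals == 5

    def test_cohort_means_track_generator_truth(self, scenario, tb):
        spec = replace(scenario.cohort, nuclide=tb, seed=7)
        table, _ = md.simulate_biodistribution(scenario.kinetics, spec)
        liver = next(k for k in scenario.kinetics if k.name == "liver")
        ntac = kin.cohort_ntac(table, "liver", tb)
        for s in ntac.samples:
            expected = liver.na(s.t, tb)
            margin = 2.0 * s.sd / np.sqrt(s.n_animals) + 1e-12
            assert abs(s.na - expected) <= max(margin, 0.15 * expected)

    def test_implausible_na_warns(self):
        with pytest.warns(UserWarning, match="implausible"):
            kin.TimeActivitySample(1.0, 2.0)

    def test_missing_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kin.build_ntac([4.0, 24.0], [1.0, np.nan], 10.0, "liver")

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_ntac([4.0, 4.0], [0.1, 0.2])


class TestFitMonoexp:
    def test_exact_recovery(self):
        t = np.array([4.0, 24.0, 48.0])
        ntac = make_ntac(t, 0.5 * np.exp(-0.1 * t))
        fit = kin.fit_monoexp(ntac)
        assert fit.a0 == pytest.approx(0.5, abs=1e-8)
        assert fit.lam == pytest.approx(0.1, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_two_points_interpolated_exactly(self):
        ntac = make_ntac([2.0, 10.0], [0.4, 0.1])
        fit = kin.fit_monoexp(ntac)
        assert fit(2.0) == pytest.approx(0.4, rel=1e-7)
        assert fit(10.0) == pytest.approx(0.1, rel=1e-7)

    def test_all_zero_curve_degenerate(self):
        with pytest.raises(DegenerateFitError):
            kin.fit_monoexp(make_ntac([4.0, 24.0], [0.0, 0.0]))

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kin.fit_monoexp(make_ntac([4.0], [0.1]))

    def test_noisy_rate_recovery_median_bias(self):
        """Median bias of the fitted rate < 2% at 10% lognormal noise."""
        rng = np.random.default_rng(11)
        t = np.array([4.0, 24.0, 48.0, 96.0])
        lam_true, a0_true = 0.05, 0.4
        sigma = np.sqrt(np.log(1.0 + 0.10**2))  # cv = 10%
        lams = []
        for _ in range(200):
            noise = rng.lognormal(-0.5 * sigma**2, sigma, len(t))
            ntac = make_ntac(t, a0_true * np.exp(-lam_true * t) * noise)
            lams.append(kin.fit_monoexp(ntac).lam)
        bias = abs(np.median(lams) - lam_true) / lam_true
        assert bias < 0.02


class TestTiac:
    @pytest.mark.parametrize(
        "a0, lam, expected",
        [(1.0, np.log(2) / 17.5, 25.2466), (0.1, 0.05, 2.0)],
    )
    def test_closed_form(self, a0, lam, expected):
        assert kin.tiac(kin.MonoExpFit(a0, lam)) == pytest.approx(expected, rel=1e-4)

    def test_zero_amplitude(self):
        assert kin.tiac(kin.MonoExpFit(0.0, 0.3)) == 0.0

    def test_matches_numeric_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a0 = rng.uniform(0.01, 1.0)
            lam = rng.uniform(0.005, 0.5)
            fit = kin.MonoExpFit(a0, lam)
            numeric, _ = quad(lambda t: a0 * np.exp(-lam * t), 0, np.inf)
            assert kin.tiac(fit) == pytest.approx(numeric, rel=1e-6)

    def test_trapezoid_tail_close_to_analytic_for_dense_sampling(self):
        t = np.linspace(0.0, 96.0, 200)
        fit = kin.MonoExpFit(0.5, 0.05)
        ntac = make_ntac(t, fit(t))
        assert kin.tiac_trapezoid_tail(ntac, fit) == pytest.approx(
            kin.tiac(fit), rel=1e-3
        )


class TestRestOfBody:
    def test_simple_subtraction(self):
        ts = kin.TIACSet(organs={"a": 3.0, "b": 2.0, "c": 1.0}, whole_body=10.0)
        assert kin.rest_of_body(ts).rest_of_body == pytest.approx(4.0)

    def test_exact_conservation(self):
        ts = kin.rest_of_body(
            kin.TIACSet(organs={"a": 3.3, "b": 2.2}, whole_body=9.9)
        )
        assert ts.rest_of_body + sum(ts.organs.values()) == pytest.approx(
            ts.whole_body, rel=1e-12
        )

    def test_organs_summing_to_whole_body(self):
        ts = kin.TIACSet(organs={"a": 5.0, "b": 5.0}, whole_body=10.0)
        assert kin.rest_of_body(ts).rest_of_body == 0.0

    def test_small_deficit_clamped_with_warning(self):
        ts = kin.TIACSet(organs={"a": 10.1}, whole_body=10.0)
        with pytest.warns(UserWarning, match="clamped"):
            out = kin.rest_of_body(ts)
        assert out.rest_of_body == 0.0

    def test_large_deficit_rejected(self):
        ts = kin.TIACSet(organs={"a": 11.0}, whole_body=10.0)
        with pytest.raises(DataInconsistencyError):
            kin.rest_of_body(ts)


class TestExtrapolateNuclide:
    def test_t_zero_point_unchanged(self, tb, indium):
        ntac = make_ntac([0.0, 17.5], [0.2, 0.1], nuclide=indium)
        out = kin.extrapolate_nuclide(ntac, tb)
        assert out.na[0] == pytest.approx(0.2)

    def test_known_value_at_one_half_life(self, tb, indium):
        ntac = make_ntac([17.5], [0.1], nuclide=indium)
        out = kin.extrapolate_nuclide(ntac, tb)
        assert out.na[0] == pytest.approx(0.05987, abs=5e-6)

    def test_same_nuclide_warns_noop(self, tb):
        ntac = make_ntac([4.0], [0.1], nuclide=tb)
        with pytest.warns(UserWarning, match="no-op"):
            out = kin.extrapolate_nuclide(ntac, tb)
        assert np.allclose(out.na, ntac.na)

    def test_decay_corrected_biology_invariant(self, tb, indium):
        t = np.array([4.0, 24.0, 48.0, 96.0])
        na_in = 0.3 * np.exp(-0.02 * t) * np.exp(-indium.decay_constant * t)
        ntac = make_ntac(t, na_in, nuclide=indium)
        out = kin.extrapolate_nuclide(ntac, tb)
        bio_in = ntac.na / np.exp(-indium.decay_constant * t)
        bio_out = out.na / np.exp(-tb.decay_constant * t)
        assert np.allclose(bio_in, bio_out, rtol=1e-12)

    def test_sd_scales_identically(self, tb, indium):
        ntac = make_ntac([24.0], [0.2], sds=[0.04], nuclide=indium)
        out = kin.extrapolate_nuclide(ntac, tb)
        assert out.sd[0] / ntac.sd[0] == pytest.approx(out.na[0] / ntac.na[0])

    def test_refit_tiac_matches_analytic_half_life_substitution(self, tb, indium):
        """Extrapolate-then-fit commutes with fitting then swapping the
        physical rate, for noiseless curves."""
        t = np.array([4.0, 24.0, 48.0, 96.0])
        lam_bio, a0 = 0.015, 0.25
        na_in = a0 * np.exp(-(lam_bio + indium.decay_constant) * t)
        out = kin.extrapolate_nuclide(make_ntac(t, na_in, nuclide=indium), tb)
        refit_tiac = kin.tiac(kin.fit_monoexp(out))
        analytic = a0 / (lam_bio + tb.decay_constant)
        assert refit_tiac == pytest.approx(analytic, rel=1e-3)


class TestFitBands:
    def test_zero_sd_gives_identical_fits(self):
        t = np.array([4.0, 24.0, 48.0])
        ntac = make_ntac(t, 0.5 * np.exp(-0.06 * t))
        bands = kin.fit_bands(ntac)
        assert bands.upper.a0 == pytest.approx(bands.mean.a0)
        assert bands.lower.lam == pytest.approx(bands.mean.lam)

    def test_symmetric_bands_mean_recovers_truth(self):
        t = np.array([4.0, 24.0, 48.0, 96.0])
        ntac = make_ntac(t, 0.4 * np.exp(-0.05 * t), sds=[0.01] * 4)
        bands = kin.fit_bands(ntac)
        assert bands.mean.a0 == pytest.approx(0.4, abs=1e-6)
        assert bands.mean.lam == pytest.approx(0.05, abs=1e-6)

    def test_band_tiac_ordering(self, scenario, tb):
        spec = replace(scenario.cohort, nuclide=tb, seed=5)
        table, _ = md.simulate_biodistribution(scenario.kinetics, spec)
        for comp in ("liver", "kidneys", "tumor"):
            bands = kin.fit_bands(kin.cohort_ntac(table, comp, tb))
            lower = 0.0 if bands.lower is None else kin.tiac(bands.lower)
            assert lower <= kin.tiac(bands.mean) <= kin.tiac(bands.upper)

    def test_degenerate_lower_band_only(self):
        t = np.array([4.0, 24.0, 48.0])
        na = 0.1 * np.exp(-0.05 * t)
        ntac = make_ntac(t, na, sds=na)  # mean - 1SD == 0 everywhere
        with pytest.warns(UserWarning, match="lower"):
            bands = kin.fit_bands(ntac)
        assert bands.lower is None
        assert bands.mean is not None


class TestSensitivityDropLast:
    def test_exact_exponential_unchanged(self):
        t = np.array([4.0, 24.0, 48.0, 96.0])
        ntac = make_ntac(t, 0.3 * np.exp(-0.05 * t))
        assert kin.sensitivity_drop_last(ntac) == pytest.approx(0.0, abs=1e-6)

    def test_perturbed_last_point_changes_tiac(self):
        t = np.array([4.0, 24.0, 48.0, 96.0])
        na = 0.3 * np.exp(-0.05 * t)
        na[-1] *= 1.10
        assert kin.sensitivity_drop_last(make_ntac(t, na)) > 0.0

    def test_requires_three_points(self):
        with pytest.raises(InvalidArgumentError):
            kin.sensitivity_drop_last(make_ntac([4.0, 24.0], [0.2, 0.1]))


class TestParameterRecoveryCoverage:
    def test_lambda_interval_covers_truth(self, tb):
        """Across seeded synthetic cohorts the central 95% interval of the
        fitted rate covers the true effective rate (cv <= 20%)."""
        rng = np.random.default_rng(2024)
        t = np.array([4.0, 24.0, 48.0, 96.0])
        lam_true = 0.02 + tb.decay_constant
        cv = 0.20
        sigma = np.sqrt(np.log(1 + cv**2))
        lams = []
        for _ in range(500):
            noise = rng.lognormal(-0.5 * sigma**2, sigma, len(t))
            ntac = make_ntac(t, 0.3 * np.exp(-lam_true * t) * noise)
            lams.append(kin.fit_monoexp(ntac).lam)
        lo, hi = np.quantile(lams, [0.025, 0.975])
        assert lo <= lam_true <= hi
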