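import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntk.errors import (
    DomainError,
    FloatingIndenterError,
    NonPositiveDenominatorError,
    NoRootInValidityDomainError,
)
from ntk.mechanics import (
    INDENTER_CATALOG,
    ElasticityConfig,
    GelMeasurement,
    IndenterSpec,
    MediumSpec,
    ModulusResult,
    buoyant_load,
    check_validity,
    film_coefficients,
    hertz_modulus,
    invert_indentation,
    modified_hertz_modulus,
    modulus_from_measurement,
    omega,
    summarize_replicates,
)


def modulus_oracle(F, R, d, h, nu=0.5, grouping="printed"):
    """Independent single-expression evaluation of the full model."""
    w = math.sqrt(R * d) / h
    hr = h / R
    if grouping == "printed":
        a = 10.05 - 0.63 * hr * (3.1 + hr**2)
    else:
        a = (10.05 - 0.63 * hr) / (3.1 + hr**2)
    b = 4.8 - 4.23 * hr**2
    den = 1 + 1.15 * w ** (1 / 3) + a * w + b * w**2
    return (
        3 * (1 - nu**2) * F / (4 * math.sqrt(R) * d**1.5) * (1 + 2.3 * w) / den,
        den,
    )


class TestBuoyantLoad:
    def test_si3n4_example(self, si3n4, water):
        # (4/3) pi R^3 drho g with R=3.96875e-4, drho=2184, g=9.81
        assert buoyant_load(si3n4, water) == pytest.approx(5.610111e-6, rel=1e-5)

    def test_wc_example(self, wc, water):
        assert buoyant_load(wc, water) == pytest.approx(2.405155e-3, rel=1e-5)

    def test_neutral_buoyancy_raises(self, water):
        ind = IndenterSpec("neutral", 1e-3, water.density)
        with pytest.raises(FloatingIndenterError):
            buoyant_load(ind, water)

    def test_floating_raises(self, water):
        with pytest.raises(FloatingIndenterError):
            buoyant_load(IndenterSpec("cork", 1e-3, 240.0), water)


class TestHertzModulus:
    def test_worked_example(self):
        E = hertz_modulus(5.61e-6, 3.96875e-4, 1.0e-4, nu=0.5)
        assert E == pytest.approx(158.4, abs=0.1)

    def test_linearity_in_force(self):
        E1 = hertz_modulus(1e-6, 1e-3, 1e-4)
        E2 = hertz_modulus(2e-6, 1e-3, 1e-4)
        assert E2 == pytest.approx(2 * E1, rel=1e-14)

    def test_poisson_factor(self):
        E0 = hertz_modulus(1e-6, 1e-3, 1e-4, nu=0.0)
        E05 = hertz_modulus(1e-6, 1e-3, 1e-4, nu=0.5)
        assert E0 / E05 == pytest.approx(1 / 0.75, rel=1e-14)

    @pytest.mark.parametrize("bad", [dict(force=0), dict(radius=-1), dict(delta=0)])
    def test_domain_errors(self, bad):
        kwargs = dict(force=1e-6, radius=1e-3, delta=1e-4)
        kwargs.update(bad)
        with pytest.raises(DomainError):
            hertz_modulus(**kwargs)


class TestOmega:
    def test_zero_indentation(self):
        assert omega(1e-3, 0.0, 1e-3) == 0.0

    def test_identity_point(self):
        assert omega(2e-3, 2e-3, 2e-3) == pytest.approx(1.0, rel=1e-14)

    def test_derived_value(self):
        assert omega(3.96875e-4, 1.0e-4, 1.3e-3) == pytest.approx(0.153244, rel=1e-5)

    def test_bad_h(self):
        with pytest.raises(DomainError):
            omega(1e-3, 1e-4, 0.0)


class TestFilmCoefficients:
    def test_printed_at_h_equals_r(self):
        alpha, beta = film_coefficients(1e-3, 1e-3, "printed")
        assert alpha == pytest.approx(10.05 - 0.63 * 4.1, rel=1e-12)  # 7.467
        assert beta == pytest.approx(0.57, rel=1e-10)

    def test_fraction_at_h_equals_r(self):
        alpha, beta = film_coefficients(1e-3, 1e-3, "fraction")
        assert alpha == pytest.approx(9.42 / 4.1, rel=1e-12)
        assert beta == pytest.approx(0.57, rel=1e-10)

    @given(
        st.floats(1e-6, 1e-1), st.floats(1e-6, 1e-1),
        st.sampled_from(["printed", "fraction"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_finite(self, r, h, grouping):
        alpha, beta = film_coefficients(r, h, grouping)
        assert math.isfinite(alpha) and math.isfinite(beta)


class TestModifiedHertz:
    def test_omega_zero_is_identity(self):
        assert modified_hertz_modulus(123.4, 0.0, 7.0, 0.5) == 123.4

    def test_worked_example(self):
        # R = h = 3.96875e-4 m, delta = 1e-4 m -> omega = sqrt(delta/R)
        w = math.sqrt(1e-4 / 3.96875e-4)
        assert w == pytest.approx(0.501964, rel=1e-5)
        E = modified_hertz_modulus(158.4, w, 7.467, 0.57)
        assert E / 158.4 == pytest.approx(0.3711, abs=2e-4)
        assert E == pytest.approx(58.8, abs=0.1)

    def test_nonpositive_denominator_raises(self):
        # printed grouping, h/R ~ 3.3, delta/h ~ 0.08
        R, h = 1e-4, 3.3e-4
        d = 0.08 * h
        alpha, beta = film_coefficients(R, h, "printed")
        w = omega(R, d, h)
        _, den = modulus_oracle(1e-6, R, d, h)
        assert den <= 0  # independent sign check
        with pytest.raises(NonPositiveDenominatorError):
            modified_hertz_modulus(100.0, w, alpha, beta)

    def test_never_negative(self):
        # denominator just above floor would give a huge positive value;
        # at or below floor it must raise, never return a negative modulus
        with pytest.raises(NonPositiveDenominatorError):
            modified_hertz_modulus(100.0, 1.0, -2.15, 0.0)


class TestCheckValidity:
    def test_boundary_rh_inclusive(self):
        report = check_validity(radius=0.3, delta=0.01, thickness_h=1.0)
        assert report.valid

    def test_below_rh_bound(self):
        report = check_validity(radius=0.29, delta=0.01, thickness_h=1.0)
        assert not report.valid
        assert "R/h >= 0.3" in report.violations

    def test_delta_over_h_bound(self):
        report = check_validity(radius=1.0, delta=0.61, thickness_h=1.0)
        assert not report.valid
        assert "delta/h <= min(0.6, R/h)" in report.violations

    def test_upper_rh_bound(self):
        assert check_validity(12.7, 0.1, 1.0).valid
        assert not check_validity(12.71, 0.1, 1.0).valid

    @given(
        st.floats(1e-6, 1e3), st.floats(0, 1e3), st.floats(1e-6, 1e3)
    )
    @settings(max_examples=100, deadline=None)
    def test_pure_total_and_matches_inequalities(self, r, d, h):
        report = check_validity(r, d, h)
        rh, dh = r / h, d / h
        assert report.checks["R/h >= 0.3"] == (rh >= 0.3)
        assert report.checks["R/h <= 12.7"] == (rh <= 12.7)
        assert report.checks["delta/h <= min(0.6, R/h)"] == (dh <= min(0.6, rh))
        assert report.valid == all(report.checks.values())

    def test_total_on_degenerate_inputs(self):
        for args in [(0.0, 0.0, 0.0), (-1.0, 1.0, 1.0), (1.0, -1.0, 1.0)]:
            assert not check_validity(*args).valid  # never raises


class TestModulusFromMeasurement:
    def test_composed_worked_example(self, si3n4, water):
        meas = GelMeasurement(thickness_h=si3n4.radius, indentation_delta=1.0e-4)
        res = modulus_from_measurement(si3n4, water, meas)
        assert res.E_hertz == pytest.approx(158.4, abs=0.1)
        assert res.E_modified == pytest.approx(58.8, abs=0.1)
        assert res.valid

    def test_zero_delta_rejected(self, si3n4, water):
        with pytest.raises(DomainError):
            hertz_modulus(buoyant_load(si3n4, water), si3n4.radius, 0.0)

    def test_invalid_geometry_flagged_not_fatal(self, si3n4, water):
        h = si3n4.radius / 0.29  # R/h = 0.29 < 0.3
        meas = GelMeasurement(thickness_h=h, indentation_delta=1e-5)
        res = modulus_from_measurement(si3n4, water, meas)
        assert not res.valid
        assert "R/h >= 0.3" in res.violations
        assert res.E_modified > 0

    def test_agrees_with_oracle(self, si3n4, water):
        rng = np.random.default_rng(42)
        F = buoyant_load(si3n4, water)
        for _ in range(50):
            h = rng.uniform(0.5, 2.0) * si3n4.radius
            d = rng.uniform(0.05, 0.5) * h
            expected, den = modulus_oracle(F, si3n4.radius, d, h)
            if den <= 1e-9:
                with pytest.raises(NonPositiveDenominatorError):
                    modulus_from_measurement(si3n4, water, GelMeasurement(h, d))
                continue
            res = modulus_from_measurement(si3n4, water, GelMeasurement(h, d))
            assert res.E_modified == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_covariance_in_force(self, k):
        R, h, d, nu = 1e-3, 1.2e-3, 2e-4, 0.5
        w = omega(R, d, h)
        a, b = film_coefficients(R, h)
        E1h = hertz_modulus(1e-6, R, d, nu)
        E2h = hertz_modulus(k * 1e-6, R, d, nu)
        assert E2h == pytest.approx(k * E1h, rel=1e-12)
        E1m = modified_hertz_modulus(E1h, w, a, b)
        E2m = modified_hertz_modulus(E2h, w, a, b)
        assert E2m == pytest.approx(k * E1m, rel=1e-12)


class TestThickSampleLimit:
    # convergence is O(omega^(1/3)) via the 1.15 w^(1/3) term: the ratio at
    # omega = w is ~ 1 - 1.15 w^(1/3), so 1e-3 closeness needs w <~ 6e-10
    def test_correction_vanishes(self, si3n4, water):
        R = si3n4.radius
        h = R
        d = (1e-10 * h) ** 2 / R  # omega = 1e-10
        res = modulus_from_measurement(si3n4, water, GelMeasurement(h, d))
        assert res.omega == pytest.approx(1e-10, rel=1e-9)
        assert res.E_modified / res.E_hertz == pytest.approx(1.0, abs=1e-3)

    def test_cube_root_convergence_rate(self, si3n4, water):
        R = si3n4.radius
        h = R
        ratios = []
        for w in (1e-3, 1e-6, 1e-9, 1e-12):
            d = (w * h) ** 2 / R
            res = modulus_from_measurement(si3n4, water, GelMeasurement(h, d))
            ratios.append(res.E_modified / res.E_hertz)
            assert res.E_modified / res.E_hertz == pytest.approx(
                1.0 - 1.15 * w ** (1 / 3), abs=1.5 * w ** (2 / 3) + 1e-12
            )
        assert all(a < b < 1.0 for a, b in zip(ratios, ratios[1:]))


class TestInvertIndentation:
    def test_round_trip(self, si3n4, water):
        h = si3n4.radius
        meas = GelMeasurement(h, 1e-4)
        E_true = modulus_from_measurement(si3n4, water, meas).E_modified
        d = invert_indentation(E_true, si3n4, water, h)
        E_back = modulus_from_measurement(
            si3n4, water, GelMeasurement(h, d)
        ).E_modified
        assert E_back == pytest.approx(E_true, rel=1e-9)

    def test_monotone_larger_E_smaller_delta(self, si3n4, water):
        h = si3n4.radius
        d1 = invert_indentation(100.0, si3n4, water, h)
        d2 = invert_indentation(200.0, si3n4, water, h)
        assert d2 < d1

    def test_forward_model_monotone_on_bracket(self, si3n4, water):
        # grid pre-scan oracle: forward model strictly decreasing in delta
        h = si3n4.radius
        deltas = np.geomspace(1e-9, 0.59 * h, 200)
        values = [
            modulus_from_measurement(
                si3n4, water, GelMeasurement(h, float(d))
            ).E_modified
            for d in deltas
        ]
        assert np.all(np.diff(values) < 0)

    def test_unreachable_stiffness_raises(self, si3n4, water):
        with pytest.raises(NoRootInValidityDomainError):
            invert_indentation(1e30, si3n4, water, si3n4.radius)

    def test_too_soft_raises(self, si3n4, water):
        with pytest.raises(NoRootInValidityDomainError):
            invert_indentation(1e-6, si3n4, water, si3n4.radius)


class TestSummarizeReplicates:
    def _result(self, e):
        return ModulusResult(
            E_hertz=e, E_modified=e, force=1e-6, omega=0.1, alpha=7.0, beta=0.5,
            R_over_h=1.0, delta_over_h=0.1, valid=True, violations=(),
            grouping="printed", poisson_ratio=0.5,
        )

    def test_identical_triplicate(self):
        summary = summarize_replicates([self._result(100.0)] * 3)
        assert summary.mean_E_modified == 100.0
        assert summary.sd_E_modified == 0.0

    def test_textbook_sd(self):
        summary = summarize_replicates([self._result(e) for e in (100, 110, 120)])
        assert summary.mean_E_modified == pytest.approx(110.0)
        assert summary.sd_E_modified == pytest.approx(10.0)
        assert summary.sem_E_modified == pytest.approx(10.0 / math.sqrt(3))

    def test_single_replicate_warns_nan(self):
        with pytest.warns(UserWarning):
            summary = summarize_replicates([self._result(100.0)])
        assert math.isnan(summary.sd_E_modified)

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            summarize_replicates([])


class TestTypes:
    def test_gel_measurement_invariants(self):
        with pytest.raises(DomainError):
            GelMeasurement(thickness_h=0.0, indentation_delta=0.0)
        with pytest.raises(DomainError):
            GelMeasurement(thickness_h=1e-3, indentation_delta=1e-3)

    def test_indenter_invariants(self):
        with pytest.raises(DomainError):
            IndenterSpec("bad", -1e-3, 1000.0)
        with pytest.raises(DomainError):
            IndenterSpec("bad", 1e-3, 0.0)

    def test_catalog(self):
        assert INDENTER_CATALOG["si3n4_1_32"].radius == pytest.approx(3.96875e-4)
        assert INDENTER_CATALOG["zro2_1_32"].density == 5680.0
        assert INDENTER_CATALOG["wc_1_8"].radius == pytest.approx(1.5875e-3)

    def test_config_invariants(self):
        with pytest.raises(DomainError):
            ElasticityConfig(poisson_ratio=0.7)
        with pytest.raises(DomainError):
            ElasticityConfig(coefficient_grouping="other")
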