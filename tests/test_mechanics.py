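import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselwall.data_io import GeometryError, PressureSweep, RingGeometry, ValidationError
from vesselwall.mechanics import (
    AdmissibilityError,
    cauchy_stresses,
    circumferential_stretch,
    deformed_inner_diameter,
    estimate_in_vivo_stretch,
    process_sweep,
    tangent_modulus_theta,
)
from vesselwall.synth import VesselModel, simulate_sweep


class TestDeformedInnerDiameter:
    def test_undeformed_identity(self):
        assert deformed_inner_diameter(1000.0, 1000.0, 800.0, 1.0) == pytest.approx(800.0)

    def test_hand_evaluated_value(self):
        # sqrt(1000² − (1000² − 800²)/2) = sqrt(820000)
        d_i = deformed_inner_diameter(1000.0, 1000.0, 800.0, 2.0)
        assert d_i == pytest.approx(math.sqrt(820000.0), rel=1e-12)
        assert d_i == pytest.approx(905.54, abs=0.01)

    def test_boundary_gives_zero(self):
        d_o = math.sqrt((1000.0**2 - 800.0**2) / 2.0)
        assert deformed_inner_diameter(d_o, 1000.0, 800.0, 2.0) == 0.0

    def test_inadmissible_point_raises(self):
        with pytest.raises(AdmissibilityError, match="inadmissible"):
            deformed_inner_diameter(100.0, 1000.0, 800.0, 1.0)


class TestCauchyStresses:
    def test_unloaded_state_is_stress_free(self):
        s = cauchy_stresses(0.0, 0.0, 400.0, 100.0)
        assert s.sigma_theta == 0.0
        assert s.sigma_z == 0.0

    def test_hand_evaluated_values(self):
        # P = 100 mmHg = 13.3322 kPa, r_i = 400 µm, h = 100 µm, f = 0:
        # σθ = 13.3322·400/100 = 53.3288 kPa
        # σz = 13.3322·π·400² / (π·100·900) = 23.7017 kPa
        s = cauchy_stresses(13.3322, 0.0, 400.0, 100.0)
        assert s.sigma_theta == pytest.approx(53.3288, rel=1e-6)
        assert s.sigma_z == pytest.approx(23.7017, abs=1e-4)

    def test_capped_tube_force_balance(self):
        # closed-end cap pushes with −P·π·r_i² → σz = 0
        P, r_i, h = 13.3322, 400.0, 100.0
        f = -P * math.pi * r_i**2 * 1e-6  # kPa·µm² -> mN
        s = cauchy_stresses(P, f, r_i, h)
        assert s.sigma_z == pytest.approx(0.0, abs=1e-12)

    def test_bad_geometry(self):
        with pytest.raises(GeometryError):
            cauchy_stresses(10.0, 0.0, 400.0, 0.0)

    @given(
        p=st.floats(0.1, 40.0),
        r_i=st.floats(100.0, 900.0),
        h=st.floats(20.0, 300.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_laplace_consistency(self, p, r_i, h):
        """σθ equals P·r_i/h to round-off for any admissible geometry."""
        s = cauchy_stresses(p, 0.0, r_i, h)
        assert s.sigma_theta == pytest.approx(p * r_i / h, rel=1e-12)


class TestCircumferentialStretch:
    def test_undeformed(self):
        assert circumferential_stretch(800.0, 1000.0, 800.0, 1000.0) == pytest.approx(1.0)

    def test_derived_value(self):
        lam = circumferential_stretch(905.54, 1000.0, 800.0, 1000.0)
        assert lam == pytest.approx(1.0586, abs=1e-4)

    def test_uniform_scaling(self):
        c = 1.3
        assert circumferential_stretch(800 * c, 1000 * c, 800.0, 1000.0) == pytest.approx(c)

    def test_inner_wall_convention(self):
        assert circumferential_stretch(880.0, 1000.0, 800.0, 1000.0, convention="inner") == pytest.approx(1.1)


def _sweep(lam_z, slope, intercept=10.0):
    p = np.arange(0.0, 121.0, 10.0)
    return PressureSweep(lam_z, p, np.full_like(p, 900.0) + p, intercept + slope * p)


class TestInVivoStretch:
    def test_exact_zero_at_tested_stretch(self):
        sweeps = [_sweep(1.64, -0.02), _sweep(1.72, 0.0), _sweep(1.80, 0.02)]
        res = estimate_in_vivo_stretch(sweeps)
        assert res.lambda_iv == pytest.approx(1.72)
        assert not res.no_sign_change

    def test_linear_interpolation_between_brackets(self):
        sweeps = [_sweep(1.6, -0.01), _sweep(1.7, 0.01), _sweep(1.8, 0.03)]
        res = estimate_in_vivo_stretch(sweeps)
        assert res.lambda_iv == pytest.approx(1.65, abs=1e-9)

    def test_all_positive_slopes_flagged(self):
        sweeps = [_sweep(1.6, 0.01), _sweep(1.7, 0.02), _sweep(1.8, 0.03)]
        res = estimate_in_vivo_stretch(sweeps)
        assert res.no_sign_change
        assert res.lambda_iv == 1.6  # smallest |slope|

    def test_quadratic_used_with_four_sweeps(self):
        # slopes lie exactly on s(λ) = (λ−1.7)·(λ+1) → root at 1.7
        lams = [1.55, 1.65, 1.75, 1.85]
        sweeps = [_sweep(l, (l - 1.7) * (l + 1)) for l in lams]
        res = estimate_in_vivo_stretch(sweeps)
        assert res.lambda_iv == pytest.approx(1.7, abs=1e-6)

    def test_too_few_sweeps(self):
        with pytest.raises(ValidationError):
            estimate_in_vivo_stretch([_sweep(1.6, 0.0), _sweep(1.7, 0.01)])


class TestTangentModulus:
    def test_linear_curve_returns_slope(self):
        lam = np.linspace(1.0, 1.5, 13)
        k = 750.0  # kPa
        sig = k * (lam - 1.0)
        p = np.linspace(0, 120, 13)
        mod = tangent_modulus_theta(lam, sig, p, 60.0)
        assert mod == pytest.approx(k / 1000.0, rel=1e-9)

    def test_quadratic_curve_matches_derivative(self):
        a = 400.0
        lam = np.arange(1.0, 1.5, 0.005)
        sig = a * lam**2
        p = np.linspace(0, 120, len(lam))
        ref_p = 60.0
        k = np.argmin(np.abs(p - ref_p))
        mod = tangent_modulus_theta(lam, sig, p, ref_p)
        assert mod == pytest.approx(2 * a * lam[k] / 1000.0, rel=0.01)

    def test_constant_curve_zero_modulus(self):
        lam = np.linspace(1.0, 1.5, 13)
        p = np.linspace(0, 120, 13)
        assert tangent_modulus_theta(lam, np.full(13, 50.0), p, 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_points(self):
        with pytest.raises(ValidationError):
            tangent_modulus_theta([1.0, 1.1], [0.0, 10.0], [0.0, 10.0], 5.0)

    def test_window_truncated_at_curve_ends(self):
        lam = np.linspace(1.0, 1.5, 6)
        sig = 500.0 * (lam - 1.0)
        p = np.linspace(0, 120, 6)
        mod = tangent_modulus_theta(lam, sig, p, 0.0)  # reference at the first point
        assert mod == pytest.approx(0.5, rel=1e-9)


class TestProcessSweep:
    def test_series_length_matches_sweep(self, default_model, default_ring, lam_star):
        sweep, _ = simulate_sweep(default_model, lam_star)
        res = process_sweep(sweep, default_ring, reference_pressure=100.0)
        assert len(res.states) == len(sweep) == 13
        assert len(res.stresses) == 13

    def test_single_point_sweep_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            PressureSweep(1.7, [0.0], [900.0], [0.0])

    def test_incompressibility_closure(self, default_model, default_ring, lam_star):
        """Deformed wall cross-section area × λz equals the unloaded area."""
        sweep, _ = simulate_sweep(default_model, lam_star)
        res = process_sweep(sweep, default_ring, reference_pressure=100.0)
        A0 = default_ring.D_o**2 - default_ring.D_i**2
        for st_ in res.states:
            A = st_.d_o**2 - st_.d_i**2
            assert A * st_.lambda_z == pytest.approx(A0, rel=1e-9)
            assert st_.lambda_theta * st_.lambda_z * st_.lambda_r == pytest.approx(1.0, abs=1e-12)

    def test_stress_monotone_in_pressure(self, default_model, default_ring, lam_star):
        sweep, _ = simulate_sweep(default_model, lam_star)
        res = process_sweep(sweep, default_ring, reference_pressure=100.0)
        assert np.all(np.diff(res.sigma_theta) > 0)

    def test_reference_outside_range_flagged(self, default_model, default_ring, lam_star):
        sweep, _ = simulate_sweep(default_model, lam_star)
        with pytest.warns(UserWarning, match="outside sweep range"):
            res = process_sweep(sweep, default_ring, reference_pressure=200.0)
        assert any("outside sweep range" in fl for fl in res.flags)
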