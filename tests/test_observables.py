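"""Fields, continuity diagnostics, far fields, cross sections, probabilities."""

import numpy as np
import pytest

import tmatsphere as tms
from tests.conftest import make_linear
from tmatsphere.observables import FarFieldPattern


class TestEvaluateField:
    def test_unit_index_reproduces_incident_wave(self, beam200):
        arr = make_linear(beam200, 2, 30.0, 2.0, 1.0)
        full = tms.solve_full(arr)
        k = beam200.k
        rng = np.random.default_rng(11)
        pts = rng.normal(scale=5.0 / k, size=(12, 3))
        vals = tms.evaluate_field(arr, full, pts)
        expect = np.exp(1j * k * pts[:, 2])
        assert np.max(np.abs(vals - expect)) < 1e-10

    def test_far_zone_matches_far_field_amplitude(self, beam200):
        arr = make_linear(beam200, 1, 0.0, 2.0, 1.001)
        full = tms.solve_full(arr)
        k = beam200.k
        theta = 0.05
        r = 1e4 * 2.0 / k  # kr = 1e4 * ka
        pt = r * np.array([np.sin(theta), 0.0, np.cos(theta)])
        scattered = tms.evaluate_field(arr, full, pt)[0] - np.exp(1j * k * pt[2])
        pat = tms.far_field_amplitude(arr, full, theta=np.array([theta]))
        asymptotic = np.exp(1j * k * r) / r * pat.f[0]
        assert abs(scattered - asymptotic) / abs(asymptotic) < 1e-2

    def test_interior_exterior_limits_agree_at_boundary(self, beam200):
        # the jump across the surface is a truncation artefact: it shrinks as
        # l_max grows and is negligible at convergence
        geom = tms.generate_linear_array(2, 30.0, 2.0, 1.001, beam200)
        nhat = np.array([0.6, 0.0, 0.8])
        jumps = []
        for l_max in (8, 12, 16):
            arr = tms.build_array(geom, beam200, l_max=l_max)
            full = tms.solve_full(arr)
            s = arr.scatterers[0]
            eps = 1e-12 * s.radius
            inner = tms.evaluate_field(arr, full, s.centre + (s.radius - eps) * nhat)[0]
            outer = tms.evaluate_field(arr, full, s.centre + (s.radius + eps) * nhat)[0]
            jumps.append(abs(inner - outer) / abs(outer))
        assert jumps[0] > jumps[1] > jumps[2]
        assert jumps[-1] < 1e-9

    def test_centre_point_rejected(self, two_sphere):
        full = tms.solve_full(two_sphere)
        with pytest.raises(ValueError, match="centre"):
            tms.evaluate_field(two_sphere, full, two_sphere.scatterers[0].centre)


class TestContinuity:
    def test_zero_potential_is_continuous(self, beam200):
        arr = make_linear(beam200, 2, 30.0, 2.0, 1.0)
        full = tms.solve_full(arr)
        ce = tms.boundary_continuity_error(arr, full, 0)
        assert ce.value < 1e-12

    def test_error_decreases_with_l_max_to_machine_floor(self, beam200):
        geom = tms.generate_linear_array(2, 30.0, 2.0, 1.001, beam200)
        vals = []
        for l_max in (6, 8, 10, 12, 14):
            arr = tms.build_array(geom, beam200, l_max=l_max)
            full = tms.solve_full(arr)
            vals.append(tms.boundary_continuity_error(arr, full, 0).value)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-10

    def test_truncating_coefficients_raises_error(self, beam200):
        geom = tms.generate_linear_array(2, 30.0, 2.0, 1.001, beam200)
        arr = tms.build_array(geom, beam200, l_max=14)
        full = tms.solve_full(arr)
        base = tms.boundary_continuity_error(arr, full, 0).value
        cut = 7
        trunc = tms.CoefficientSet(
            b=np.where(np.arange(full.b.shape[1]) <= cut, full.b, 0.0),
            c=np.where(np.arange(full.c.shape[1]) <= cut, full.c, 0.0),
            mode="truncated",
            l_max=full.l_max,
            axisymmetric=True,
            a_in=np.where(np.arange(full.b.shape[1]) <= cut, full.a_in, 0.0),
        )
        assert tms.boundary_continuity_error(arr, trunc, 0).value > 10 * base


class TestFarField:
    def test_single_sphere_at_origin_matches_mie_pattern(self, beam200):
        arr = make_linear(beam200, 1, 0.0, 2.0, 1.001)
        full = tms.solve_full(arr)
        theta = np.linspace(0, np.pi, 33)
        pat = tms.far_field_amplitude(arr, full, theta=theta)
        ref = tms.single_sphere_far_field(arr.scatterers[0].tmat, theta)
        assert np.max(np.abs(pat.f - ref)) < 1e-12 * np.max(np.abs(ref))

    def test_rigid_translation_changes_only_phase(self, beam200):
        k = beam200.k
        tm = tms.soft_sphere_tmatrix(2.0, 1.001, 10, k=k)
        theta = np.linspace(0, np.pi, 17)
        mags = []
        for z0 in (0.0, 37.0 / k):
            arr = tms.ScattererArray([tms.Scatterer(np.array([0, 0, z0]), tm)], beam200, 10)
            pat = tms.far_field_amplitude(arr, tms.solve_full(arr), theta=theta)
            mags.append(np.abs(pat.f))
        assert np.max(np.abs(mags[0] - mags[1])) < 1e-13 * np.max(mags[0])

    def test_kinematic_fringes_at_phase_matching_angles(self, two_sphere):
        # maxima where kd (1 - cos theta) is a multiple of 2 pi
        kin = tms.solve_kinematic(two_sphere)
        theta = np.linspace(1e-4, 1.2, 6001)
        pat = tms.far_field_amplitude(two_sphere, kin, theta=theta)
        intensity = np.abs(pat.f) ** 2
        kd = 30.0
        predicted = [np.arccos(1 - 2 * np.pi * n / kd) for n in (1, 2, 3)]
        from scipy.signal import argrelmax

        found = theta[argrelmax(intensity)[0]]
        for pred in predicted:
            assert np.min(np.abs(found - pred)) < 0.01

    def test_full_pattern_close_to_kinematic_for_weak_wells(self, two_sphere_solutions, two_sphere):
        theta = np.linspace(0, 0.8, 801)
        f_full = np.abs(tms.far_field_amplitude(two_sphere, two_sphere_solutions["full"], theta=theta).f)
        f_kin = np.abs(tms.far_field_amplitude(two_sphere, two_sphere_solutions["kinematic"], theta=theta).f)
        scale = np.max(f_full)
        assert np.max(np.abs(f_full - f_kin)) / scale < 0.05


class TestCrossSections:
    def test_zero_and_isotropic_closed_forms(self, beam200):
        theta, w = tms.angular_grid(8)
        zero = FarFieldPattern(theta=theta, f=np.zeros_like(theta, dtype=complex),
                               weights=w, k=beam200.k)
        assert tms.cross_sections(zero)[1] == 0.0
        iso = FarFieldPattern(theta=theta, f=np.ones_like(theta, dtype=complex),
                              weights=w, k=beam200.k)
        assert tms.cross_sections(iso)[1] == pytest.approx(4 * np.pi, rel=1e-12)

    def test_sigma_converges_on_node_doubling(self, two_sphere, two_sphere_solutions):
        from tmatsphere.observables import _array_phase_bandwidth, angular_grid

        extra = _array_phase_bandwidth(two_sphere)
        full = two_sphere_solutions["full"]
        sigmas = []
        for factor in (1, 2):
            n_extra = factor * (2 * full.l_max + extra + 16) - 2 * full.l_max
            theta, w = angular_grid(full.l_max, True, n_extra - 16)
            pat = tms.far_field_amplitude(two_sphere, full, theta=theta)
            pat.weights = w
            sigmas.append(tms.cross_sections(pat)[1])
        assert abs(sigmas[1] - sigmas[0]) / sigmas[0] < 1e-6

    def test_weak_sphere_sigma_matches_born_integral(self, beam200):
        k = beam200.k
        arr = make_linear(beam200, 1, 0.0, 2.0, 1.001)
        full = tms.solve_full(arr)
        _, sigma = tms.cross_sections(tms.far_field_amplitude(arr, full))
        theta, w = tms.angular_grid(arr.l_max)
        sh = tms.ShellModel(radii=(2.0 / k,), refr_indices=(1.001,), k=k)
        fb = tms.born_form_factor_multishell(sh, beam200, theta)
        sigma_born = np.sum(w * fb**2)
        assert abs(sigma - sigma_born) / sigma_born < 1e-2


class TestOpticalTheorem:
    def test_full_solution_conserves_flux(self, two_sphere, two_sphere_solutions):
        pat = tms.far_field_amplitude(two_sphere, two_sphere_solutions["full"])
        assert tms.optical_theorem_residual(pat, two_sphere.beam) < 1e-6

    def test_born_violates_flux_conservation(self, beam200):
        arr = make_linear(beam200, 2, 8.0, 2.0, 1.01)
        sys_ = tms.assemble_system(arr)
        r_full = tms.optical_theorem_residual(
            tms.far_field_amplitude(arr, tms.solve_full(arr, sys_)), beam200
        )
        r_kin = tms.optical_theorem_residual(
            tms.far_field_amplitude(arr, tms.solve_kinematic(arr, sys_)), beam200
        )
        assert r_kin > 10 * r_full

    def test_zero_potential_residual_is_zero(self, beam200):
        arr = make_linear(beam200, 1, 0.0, 2.0, 1.0)
        pat = tms.far_field_amplitude(arr, tms.solve_full(arr))
        assert tms.optical_theorem_residual(pat, beam200) == 0.0


class TestProbabilities:
    def _per_order_patterns(self, beam, N=2, n_orders=2, n_ref=1.01):
        arr = make_linear(beam, N, 30.0, 2.0, n_ref)
        succ = tms.solve_successive(arr, n_orders)
        return arr, [tms.far_field_amplitude(arr, t) for t in succ.terms]

    def test_single_order_is_kinematic_ratio(self, beam200):
        arr, pats = self._per_order_patterns(beam200, n_orders=1)
        S = 1e-3
        bud = tms.scattering_probabilities(pats[:1], S)
        _, sigma = tms.cross_sections(pats[0])
        assert bud.P_n[0] == pytest.approx(sigma / S, rel=1e-12)

    def test_telescoping_is_exact(self, beam200):
        arr, pats = self._per_order_patterns(beam200, N=4, n_orders=4)
        bud = tms.scattering_probabilities(pats, S=1e-3)
        assert np.sum(bud.sigma_by_order) == pytest.approx(bud.sigma_total, rel=1e-12)
        assert bud.P_total < 1
        assert bud.P_unscattered == pytest.approx(1 - bud.P_total)

    def test_pure_variant_discards_cross_terms(self, beam200):
        arr, pats = self._per_order_patterns(beam200, N=4, n_orders=3)
        bud = tms.scattering_probabilities(pats, S=1e-3, cross_terms="pure")
        assert np.all(bud.sigma_by_order >= 0)
        sig_each = [tms.cross_sections(p)[1] for p in pats]
        assert np.allclose(bud.sigma_by_order, sig_each, rtol=1e-12)

    def test_area_precondition_surfaced_not_clamped(self, beam200):
        arr, pats = self._per_order_patterns(beam200)
        _, sigma = tms.cross_sections(pats[0])
        with pytest.raises(ValueError, match="less than 1"):
            tms.scattering_probabilities(pats, S=sigma / 2)

    def test_multiple_scattering_grows_with_n_spheres(self, beam200):
        P2 = []
        for N in (2, 4, 8, 16):
            arr, pats = self._per_order_patterns(beam200, N=N, n_orders=3)
            bud = tms.scattering_probabilities(pats, S=1e-4)
            P2.append(bud.P_n[1])
        assert all(a <= b for a, b in zip(P2, P2[1:]))


class TestPoisson:
    def test_closed_forms_and_normalization(self):
        p = tms.poisson_probabilities(0.0, 1.0, 5)
        assert p[0] == 1.0 and np.all(p[1:] == 0.0)
        p = tms.poisson_probabilities(1.0, 1.0, 50)
        assert p[1] == pytest.approx(np.exp(-1), rel=1e-12)
        for ratio in (0.5, 1.0, 3.0):
            p = tms.poisson_probabilities(ratio, 1.0, 50)
            assert np.sum(p) == pytest.approx(1.0, abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            tms.poisson_probabilities(1.0, 0.0, 5)
        with pytest.raises(ValueError):
            tms.mean_free_path(0.0, 1.0, 1.0)

    def test_mean_free_path_definition(self):
        # Lambda = 1 / (rho sigma) with rho = 1 / (S dz)
        assert tms.mean_free_path(2.0, 100.0, 3.0) == pytest.approx(150.0)
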