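"""Equation-of-state internals: limits, identities and independent oracles."""

import math

import numpy as np
import pytest

from carbotherm.phsc import (
    PhscComponent,
    PhscEos,
    attraction_parameter,
    covolume_parameter,
    f_attraction,
    f_covolume,
)

from reference_eos import RefEos, f_a as ref_fa

T_ROOM = 298.15


class TestUniversalFunctions:
    def test_covolume_bounded_unit_interval(self, water):
        # d(T) <= sigma over the whole fitted water range
        t = np.linspace(250.0, 650.0, 200) / water.eps_over_k
        fb = f_covolume(t)
        assert np.all(fb > 0.0) and np.all(fb <= 1.0)

    def test_both_decrease_with_temperature(self):
        t = np.linspace(0.3, 5.0, 50)
        assert np.all(np.diff(f_attraction(t)) < 0)
        assert np.all(np.diff(f_covolume(t)) < 0)

    def test_nonpositive_reduced_temperature_rejected(self):
        with pytest.raises(ValueError):
            f_attraction(0.0)


class TestPairParameters:
    def test_zero_diameter_zeroes_both(self):
        a = PhscComponent("pt", r=1.0, sigma=1e-300, eps_over_k=100.0)
        assert attraction_parameter(a, a, T_ROOM) == pytest.approx(0.0, abs=1e-280)
        assert covolume_parameter(a, a, T_ROOM) == pytest.approx(0.0, abs=1e-280)

    def test_symmetry(self, glucose, water):
        assert attraction_parameter(glucose, water, T_ROOM) == attraction_parameter(
            water, glucose, T_ROOM
        )
        assert covolume_parameter(glucose, water, T_ROOM) == covolume_parameter(
            water, glucose, T_ROOM
        )

    def test_water_attraction_against_arithmetic_oracle(self, water):
        tr = T_ROOM / water.eps_over_k
        expected = (
            2.0 * math.pi / 3.0 * water.sigma**3 * water.eps_over_k * ref_fa(tr)
        )
        assert attraction_parameter(water, water, T_ROOM) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_temperature_rejected(self, water):
        with pytest.raises(ValueError):
            attraction_parameter(water, water, -1.0)


class TestContactRdf:
    def test_ideal_gas_limit(self, water_eos):
        g = water_eos.contact_rdf(T_ROOM, 1e-14, np.array([1.0]))
        assert g[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_carnahan_starling_pure_limit(self, water_eos):
        eta = 0.3
        rho = water_eos.eta_to_rho(T_ROOM, eta, np.array([1.0]))
        g = water_eos.contact_rdf(T_ROOM, rho, np.array([1.0]))[0, 0]
        assert g == pytest.approx((1 - eta / 2) / (1 - eta) ** 3, abs=1e-12)

    def test_strictly_increasing_in_packing(self, water_eos):
        etas = np.linspace(0.01, 0.6, 30)
        vals = [
            water_eos.contact_rdf(
                T_ROOM, water_eos.eta_to_rho(T_ROOM, e, np.array([1.0])), np.array([1.0])
            )[0, 0]
            for e in etas
        ]
        assert np.all(np.diff(vals) > 0)

    def test_overpacked_state_rejected(self, water_eos):
        rho = water_eos.eta_to_rho(T_ROOM, 1.05, np.array([1.0]))
        with pytest.raises(ValueError, match="packing"):
            water_eos.contact_rdf(T_ROOM, rho, np.array([1.0]))


class TestAssociation:
    def test_no_kappa_means_no_delta(self):
        a = PhscComponent("hs", r=2.0, sigma=3.0, eps_over_k=250.0, n_sites=0)
        eos = PhscEos([a])
        d = eos.association_strength(T_ROOM, 0.01, np.array([1.0]))
        assert d[0, 0] == 0.0

    def test_zero_association_energy_means_no_delta(self):
        a = PhscComponent(
            "weak", r=2.0, sigma=3.0, eps_over_k=250.0,
            eps_assoc_over_k=0.0, kappa_assoc=0.05, n_sites=2,
        )
        d = PhscEos([a]).association_strength(T_ROOM, 0.01, np.array([1.0]))
        assert d[0, 0] == 0.0

    def test_water_delta_against_arithmetic_oracle(self, water, water_eos):
        eta = 0.4
        rho = water_eos.eta_to_rho(T_ROOM, eta, np.array([1.0]))
        g = water_eos.contact_rdf(T_ROOM, rho, np.array([1.0]))[0, 0]
        expected = (
            g
            * (math.exp(water.eps_assoc_over_k / T_ROOM) - 1.0)
            * water.sigma**3
            * water.kappa_assoc
        )
        d = water_eos.association_strength(T_ROOM, rho, np.array([1.0]))
        assert d[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_all_delta_zero_gives_unbonded_sites(self):
        a = PhscComponent("hs", r=2.0, sigma=3.0, eps_over_k=250.0, n_sites=0)
        st = PhscEos([a]).solve_site_fractions(T_ROOM, 0.01, np.array([1.0]))
        assert st.site_fractions.size == 0  # nothing to bond

    def test_two_site_closed_form(self, water, water_eos):
        """Symmetric donor/acceptor water: X = (-1 + sqrt(1+4 rho D))/(2 rho D)."""
        rho = water_eos.eta_to_rho(T_ROOM, 0.4, np.array([1.0]))
        st = water_eos.solve_site_fractions(T_ROOM, rho, np.array([1.0]))
        D = st.delta[0, 0]
        closed = (-1.0 + math.sqrt(1.0 + 4.0 * rho * D)) / (2.0 * rho * D)
        assert st.site_fractions == pytest.approx(closed, abs=1e-10)

    def test_weak_association_first_order_expansion(self, glucose, water):
        """X ~ 1 - rho sum x s Delta for small Delta."""
        weak_g = glucose.with_parameters(eps_assoc_over_k=50.0, kappa_assoc=1e-4)
        weak_w = water.with_parameters(eps_assoc_over_k=50.0, kappa_assoc=1e-4)
        eos = PhscEos([weak_g, weak_w])
        x = np.array([0.1, 0.9])
        rho = eos.eta_to_rho(T_ROOM, 0.3, x)
        st = eos.solve_site_fractions(T_ROOM, rho, x)
        y = np.array([x[0] * weak_g.n_sites / 2, x[1] * weak_w.n_sites / 2])
        for c, (name, _) in enumerate(st.labels):
            i = 0 if name == weak_g.name else 1
            first_order = 1.0 - rho * sum(
                y[j] * st.delta[i, j] for j in range(2)
            )
            assert st.site_fractions[c] == pytest.approx(first_order, abs=5e-5)

    def test_site_fractions_in_unit_interval_and_decreasing_with_density(
        self, glucose_water_eos, x05
    ):
        xs = []
        for eta in np.linspace(0.05, 0.55, 11):
            rho = glucose_water_eos.eta_to_rho(T_ROOM, eta, x05)
            st = glucose_water_eos.solve_site_fractions(T_ROOM, rho, x05)
            assert np.all(st.site_fractions > 0) and np.all(st.site_fractions <= 1)
            xs.append(st.site_fractions.copy())
        assert np.all(np.diff(np.array(xs), axis=0) < 0)

    def test_against_individual_site_fsolve_oracle(self, glucose, water, x05):
        eos = PhscEos([glucose, water])
        rho = eos.eta_to_rho(T_ROOM, 0.45, x05)
        st = eos.solve_site_fractions(T_ROOM, rho, x05)
        ref = RefEos([glucose, water])
        X_ref, sites = ref.site_fractions(T_ROOM, rho, x05)
        by_class = {}
        for val, (ci, ty) in zip(X_ref, sites):
            by_class.setdefault((ci, ty), []).append(val)
        for c, (name, role) in enumerate(st.labels):
            ci = 0 if name == glucose.name else 1
            ty = "D" if role == "donor" else "A"
            ref_vals = by_class[(ci, ty)]
            assert np.allclose(ref_vals, st.site_fractions[c], atol=1e-9)


class TestCompressibility:
    def test_ideal_gas_limit(self, glucose_water_eos, x05):
        rho = glucose_water_eos.eta_to_rho(T_ROOM, 1e-8, x05)
        z = glucose_water_eos.compressibility(T_ROOM, rho, x05)
        assert abs(z.z_total - 1.0) < 1e-6

    def test_no_association_term_without_sites(self):
        a = PhscComponent("chain", r=3.0, sigma=3.5, eps_over_k=300.0)
        eos = PhscEos([a])
        rho = eos.eta_to_rho(T_ROOM, 0.3, np.array([1.0]))
        z = eos.compressibility(T_ROOM, rho, np.array([1.0]))
        assert z.z_assoc == 0.0

    def test_association_dual_route_identity(self, glucose_water_eos, x05):
        """Mass-action-derivative route equals the variational route."""
        rho = glucose_water_eos.eta_to_rho(T_ROOM, 0.45, x05)
        za = glucose_water_eos.compressibility(T_ROOM, rho, x05).z_assoc
        zh = glucose_water_eos.z_assoc_from_helmholtz(T_ROOM, rho, x05)
        assert za == pytest.approx(zh, abs=1e-11)

    def test_pure_water_against_independent_implementation(self, water, water_eos):
        rho = water_eos.eta_to_rho(T_ROOM, 0.4, np.array([1.0]))
        z = water_eos.compressibility(T_ROOM, rho, np.array([1.0])).z_total
        z_ref = RefEos([water]).z_total(T_ROOM, rho, np.array([1.0]))
        assert z == pytest.approx(z_ref, abs=1e-8)

    def test_pressure_route_vs_helmholtz_derivative(self, glucose_water_eos, x05):
        rho = glucose_water_eos.eta_to_rho(T_ROOM, 0.45, x05)
        z = glucose_water_eos.compressibility(T_ROOM, rho, x05).z_total
        h = 1e-6 * rho
        a = lambda r: glucose_water_eos.residual_helmholtz(T_ROOM, r, x05)
        dadr = (a(rho - 2 * h) - 8 * a(rho - h) + 8 * a(rho + h) - a(rho + 2 * h)) / (
            12 * h
        )
        assert z == pytest.approx(1.0 + rho * dadr, abs=1e-8)

    def test_helmholtz_against_quadrature_oracle(self, water, water_eos):
        rho = water_eos.eta_to_rho(T_ROOM, 0.35, np.array([1.0]))
        a_pkg = water_eos.residual_helmholtz(T_ROOM, rho, np.array([1.0]))
        a_ref = RefEos([water]).a_res(T_ROOM, rho, np.array([1.0]))
        assert a_pkg == pytest.approx(a_ref, abs=5e-7)


class TestDensitySolver:
    def test_pressure_residual_contract(self, water_eos):
        st = water_eos.solve_density(T_ROOM, 1e5, np.array([1.0]), phase="liquid")
        p = water_eos.pressure(T_ROOM, st.number_density, np.array([1.0]))
        assert abs(p - 1e5) / 1e5 < 1e-10

    def test_liquid_matches_independent_bisection(self, water_eos):
        st = water_eos.solve_density(T_ROOM, 1e5, np.array([1.0]), phase="liquid")
        f = lambda e: water_eos.pressure(
            T_ROOM, water_eos.eta_to_rho(T_ROOM, e, np.array([1.0])), np.array([1.0])
        ) - 1e5
        lo, hi = st.eta - 0.05, st.eta + 0.05
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert st.eta == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    def test_vapor_root_is_near_ideal(self, water_eos):
        st = water_eos.solve_density(T_ROOM, 100.0, np.array([1.0]), phase="vapor")
        assert st.z_total == pytest.approx(1.0, abs=1e-3)

    def test_reasonable_liquid_water_density(self, water, water_eos):
        st = water_eos.solve_density(T_ROOM, 1e5, np.array([1.0]), phase="liquid")
        g_per_cm3 = st.number_density * water.molar_mass / 6.02214076e23 * 1e24
        assert 0.9 < g_per_cm3 < 1.1

    def test_bad_phase_rejected(self, water_eos):
        with pytest.raises(ValueError):
            water_eos.solve_density(T_ROOM, 1e5, np.array([1.0]), phase="plasma")


class TestFugacity:
    def test_ideal_gas_limit(self, glucose_water_eos, x05):
        st = glucose_water_eos.solve_density(400.0, 1.0, x05, phase="vapor")
        lnphi = glucose_water_eos.ln_fugacity_coefficients(st)
        assert np.all(np.abs(lnphi) < 1e-4)

    def test_sum_matches_residual_gibbs_identity(self, glucose_water_eos, x05):
        """sum x_i ln phi_i = a_res + (Z-1) - ln Z at the solved state."""
        st = glucose_water_eos.solve_density(T_ROOM, 1e5, x05, phase="liquid")
        lnphi = glucose_water_eos.ln_fugacity_coefficients(st)
        a = glucose_water_eos.residual_helmholtz(T_ROOM, st.number_density, x05)
        z = st.pressure / (
            st.number_density * T_ROOM * 1.380649e-23 * 1e30
        )
        g_res = a + (z - 1.0) - math.log(z)
        assert float(x05 @ lnphi) == pytest.approx(g_res, abs=1e-8)

    def test_gibbs_duhem_on_composition_grid(self, glucose_water_eos):
        h = 1e-3
        worst = 0.0
        for xs in (0.02, 0.06, 0.10):
            vals = []
            for k in (-2, -1, 1, 2):
                x = np.array([xs + k * h, 1.0 - xs - k * h])
                st = glucose_water_eos.solve_density(T_ROOM, 1e5, x, phase="liquid")
                vals.append(glucose_water_eos.ln_fugacity_coefficients(st))
            d = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
            worst = max(worst, abs(xs * d[0] + (1 - xs) * d[1]))
        assert worst < 1e-6

    def test_against_independent_implementation(self, glucose, water):
        x = np.array([0.04, 0.96])
        eos = PhscEos([glucose, water])
        st = eos.solve_density(T_ROOM, 1e5, x, phase="liquid")
        lnphi = eos.ln_fugacity_coefficients(st)
        lnphi_ref = RefEos([glucose, water]).ln_phi(T_ROOM, st.number_density, x)
        assert np.allclose(lnphi, lnphi_ref, atol=5e-5)
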