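"""PHSC equation of state: compressibility, Helmholtz energy, density roots,
site fractions and fugacity coefficients.

Model summary
-------------
The compressibility factor decomposes as ``Z = Z_ref + Z_pert + Z_assoc``:

* ``Z_ref`` is the hard-sphere-chain reference,
  ``1 + rho sum_ij x_i x_j r_i r_j b_ij g_ij(d+) - sum_i x_i (r_i-1)(g_ii-1)``,
  with the Boublik-Mansoori-Carnahan-Starling (BMCS) contact value for the
  hard-sphere radial distribution function g_ij.
* ``Z_pert`` is the van der Waals perturbation
  ``-(rho/kT) sum_ij x_i x_j r_i r_j a_ij``.
* ``Z_assoc`` is the Wertheim/SAFT association term built from the unbonded
  site fractions X^A.

Internal units: temperatures in K, energies divided by k_B (so they carry K),
lengths in angstrom, number density in molecules/A^3.  Pressures cross the
boundary in Pa.

The residual Helmholtz energy is obtained in closed form by integrating
``(Z - 1)/rho`` for the reference and perturbation terms and from the
variational (Michelsen-Hendriks) functional for association, which allows all
association derivatives to be taken at fixed site fractions.  Composition and
density derivatives (fugacity coefficients, the density Newton) use
complex-step differentiation of the dtype-generic Helmholtz/pressure path,
which is exact to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from carbotherm.phsc.components import PhscComponent
from carbotherm.phsc.universal import f_attraction, f_covolume

K_BOLTZMANN = 1.380649e-23  # J/K
_TWO_PI_3 = 2.0 * math.pi / 3.0
_PI_6 = math.pi / 6.0

#: Pa per (K * molecules/A^3): P[Pa] = Z rho k_B T / 1e-30
_PRESSURE_UNIT = K_BOLTZMANN * 1.0e30

ETA_MAX = 0.74  # close-packing-ish cap for root searches


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


@dataclass(frozen=True)
class EosBreakdown:
    """Compressibility-factor decomposition (all dimensionless)."""

    z_ref: float
    z_pert: float
    z_assoc: float

    @property
    def z_total(self) -> float:
        return self.z_ref + self.z_pert + self.z_assoc


@dataclass(frozen=True)
class AssociationState:
    """Converged unbonded site fractions.

    ``site_fractions[c]`` is X for site class ``c``; classes are enumerated in
    ``labels`` as ``(component name, 'donor'|'acceptor')`` with per-molecule
    multiplicity ``multiplicities[c] = n_sites/2``.  ``delta`` is the
    donor-acceptor association strength matrix over components (A^3).
    """

    site_fractions: np.ndarray
    labels: tuple[tuple[str, str], ...]
    multiplicities: np.ndarray
    delta: np.ndarray
    residual: float


@dataclass(frozen=True)
class SolutionState:
    """A solved (T, P, x, rho) point of the mixture."""

    temperature: float
    pressure: float
    mole_fractions: np.ndarray
    number_density: float  # molecules / A^3
    eta: float
    z: EosBreakdown
    association: AssociationState | None = None

    @property
    def z_total(self) -> float:
        return self.z.z_total


def _sigma_cross(si: float, sj: float) -> float:
    return 0.5 * (si + sj)


def _eps_cross(ei: float, ej: float) -> float:
    return math.sqrt(ei * ej)


def attraction_parameter(i: PhscComponent, j: PhscComponent, temperature: float) -> float:
    """Cross attraction a_ij(T) in K*A^3 (energy scaled by k_B)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    sig = _sigma_cross(i.sigma, j.sigma)
    eps = _eps_cross(i.eps_over_k, j.eps_over_k)
    if sig == 0.0:
        return 0.0
    return _TWO_PI_3 * sig**3 * eps * float(f_attraction(temperature / eps))


def covolume_parameter(i: PhscComponent, j: PhscComponent, temperature: float) -> float:
    """Cross covolume b_ij(T) in A^3; b_ij = (2 pi/3) d_ij^3."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    sig = _sigma_cross(i.sigma, j.sigma)
    eps = _eps_cross(i.eps_over_k, j.eps_over_k)
    if sig == 0.0:
        return 0.0
    return _TWO_PI_3 * sig**3 * float(f_covolume(temperature / eps))


class PhscEos:
    """PHSC EoS for a fixed set of components.

    Parameters
    ----------
    components :
        Pure-component parameter sets; order defines the composition vector.
    cross_association :
        If True (default) donor sites of one component bond to acceptor sites
        of every associating component, with CR-1 combining rules
        ``eps^AiBj = (eps^Ai + eps^Bj)/2`` and ``kappa^AiBj =
        sqrt(kappa^Ai kappa^Bj)``.  If False only self-association is kept.
    """

    def __init__(self, components: Sequence[PhscComponent], cross_association: bool = True):
        if not components:
            raise ValueError("need at least one component")
        self.components = tuple(components)
        self.cross_association = bool(cross_association)
        n = len(self.components)
        self._r = np.array([c.r for c in self.components])
        self._sigma = np.array([c.sigma for c in self.components])
        self._eps = np.array([c.eps_over_k for c in self.components])
        self._sig_ij = 0.5 * (self._sigma[:, None] + self._sigma[None, :])
        self._eps_ij = np.sqrt(self._eps[:, None] * self._eps[None, :])
        # association-site classes: (component, donor) and (component, acceptor)
        comp_idx, types, mult = [], [], []
        for k, c in enumerate(self.components):
            if c.associating:
                for t in (0, 1):  # 0 = donor, 1 = acceptor
                    comp_idx.append(k)
                    types.append(t)
                    mult.append(c.n_sites // 2)
        self._site_comp = np.array(comp_idx, dtype=int)
        self._site_type = np.array(types, dtype=int)
        self._site_mult = np.array(mult, dtype=float)
        self._n_sites_classes = len(comp_idx)
        self._site_labels = tuple(
            (self.components[c].name, "donor" if t == 0 else "acceptor")
            for c, t in zip(comp_idx, types)
        )
        # donor-acceptor pairing mask and component lookup over site classes
        if comp_idx:
            st = self._site_type
            self._pair_mask = st[:, None] != st[None, :]
            self._pair_comp = np.ix_(self._site_comp, self._site_comp)
        else:
            self._pair_mask = np.zeros((0, 0), dtype=bool)
            self._pair_comp = None
        # donor-acceptor energetic prefactor per component pair (temperature
        # independent part kappa_ij sigma_ij^3 and energy eps_ij^AB)
        kap = np.array([c.kappa_assoc for c in self.components])
        epsab = np.array([c.eps_assoc_over_k for c in self.components])
        assoc = np.array([c.associating for c in self.components])
        self._kappa_ij = np.sqrt(np.outer(kap, kap))
        self._epsab_ij = 0.5 * (epsab[:, None] + epsab[None, :])
        pair_ok = np.outer(assoc, assoc)
        if not self.cross_association:
            pair_ok &= np.eye(n, dtype=bool)
        self._assoc_pair = pair_ok
        self._tcache: dict[float, dict[str, np.ndarray]] = {}
        self._x_warm: np.ndarray | None = None

    # ------------------------------------------------------------------ T cache
    def _at_T(self, T: float) -> dict[str, np.ndarray]:
        if T <= 0:
            raise ValueError("temperature must be positive")
        cached = self._tcache.get(T)
        if cached is not None:
            return cached
        tr = T / self._eps_ij
        fa = f_attraction(tr)
        fb = f_covolume(tr)
        a_ij = _TWO_PI_3 * self._sig_ij**3 * self._eps_ij * fa
        b_ij = _TWO_PI_3 * self._sig_ij**3 * fb
        d_i = self._sigma * np.diag(fb) ** (1.0 / 3.0)
        # donor-acceptor bond volume term K_ij = [exp(epsAB/T)-1] sigma_ij^3 kappa_ij
        K_ij = np.where(
            self._assoc_pair,
            np.expm1(self._epsab_ij / T) * self._sig_ij**3 * self._kappa_ij,
            0.0,
        )
        cached = {"a_ij": a_ij, "b_ij": b_ij, "d_i": d_i, "K_ij": K_ij}
        if len(self._tcache) > 256:
            self._tcache.clear()
        self._tcache[T] = cached
        return cached

    # --------------------------------------------------------------- geometry
    # evaluation helpers are dtype-generic: complex rho/x support complex-step
    # differentiation of the Helmholtz energy to machine precision
    def _packing(self, T: float, rho, x):
        d = self._at_T(T)["d_i"]
        c2 = _PI_6 * np.dot(x, self._r * d**2)
        c3 = _PI_6 * np.dot(x, self._r * d**3)
        return c2 * rho, c3 * rho, c2, c3  # zeta2, eta, and their rho-slopes

    def packing_fraction(self, T: float, rho: float, x: np.ndarray) -> float:
        return float(self._packing(T, rho, np.asarray(x, dtype=float))[1])

    def eta_to_rho(self, T: float, eta: float, x: np.ndarray) -> float:
        c3 = self._packing(T, 1.0, np.asarray(x, dtype=float))[3]
        return float(eta / c3)

    def contact_rdf(self, T: float, rho: float, x: np.ndarray) -> np.ndarray:
        """BMCS contact values g_ij^hs as a matrix."""
        x = np.asarray(x, dtype=float)
        zeta2, eta, _, _ = self._packing(T, rho, x)
        return self._rdf_from_packing(T, eta, zeta2)

    def _zeta_ij(self, T: float, zeta2: float) -> np.ndarray:
        d = self._at_T(T)["d_i"]
        dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
        return 2.0 * dd * zeta2

    def _rdf_from_packing(self, T: float, eta, zeta2) -> np.ndarray:
        if np.real(eta) >= 1.0:
            raise ValueError(f"packing fraction eta={eta} must be < 1")
        z = self._zeta_ij(T, zeta2)
        om = 1.0 - eta
        # third term carries zeta^2: required for the Carnahan-Starling pure limit
        return 1.0 / om + 1.5 * z / om**2 + 0.5 * z**2 / om**3

    def _rdf_drho(self, T: float, rho: float, x: np.ndarray):
        """g_ij and dg_ij/drho (analytic), composition fixed."""
        zeta2, eta, c2, c3 = self._packing(T, rho, x)
        z = self._zeta_ij(T, zeta2)
        zslope = self._zeta_ij(T, c2)  # dz/drho
        om = 1.0 - eta
        g = 1.0 / om + 1.5 * z / om**2 + 0.5 * z**2 / om**3
        dg_deta = 1.0 / om**2 + 3.0 * z / om**3 + 1.5 * z**2 / om**4
        dg_dz = 1.5 / om**2 + z / om**3
        return g, dg_deta * c3 + dg_dz * zslope

    # ------------------------------------------------------------- association
    def association_strength(self, T: float, rho, x) -> np.ndarray:
        """Donor-acceptor association strengths Delta_ij (A^3) over components."""
        zeta2, eta, _, _ = self._packing(T, rho, np.asarray(x))
        g = self._rdf_from_packing(T, eta, zeta2)
        return g * self._at_T(T)["K_ij"]

    def _solve_X(self, T: float, rho, x, tol: float = 1e-15):
        """Unbonded site fractions; dtype-generic (complex-step capable)."""
        nc = self._n_sites_classes
        delta = self.association_strength(T, rho, x)
        if nc == 0:
            return np.empty(0), delta
        D = self._site_delta_matrix(delta)
        y = np.asarray(x)[self._site_comp] * self._site_mult
        is_complex = np.iscomplexobj(x) or np.iscomplexobj(np.asarray(rho))
        if is_complex:
            # warm-start from the real solution; the imaginary part is linear
            # in the perturbation, so a few unconditional Newton steps pin it
            # (a residual-size test would pass before the imaginary part moves)
            X0, _ = self._solve_X(T, np.real(rho), np.real(np.asarray(x)), tol)
            X = X0.astype(complex)
            best = np.inf
            for it in range(40):
                B = D @ (y * X)
                F = X * (1.0 + rho * B) - 1.0
                resid = np.max(np.abs(F))
                # at least two steps so the imaginary part settles, then run
                # to the residual noise floor
                if it >= 2 and (resid < tol or resid >= best):
                    break
                best = min(best, resid)
                J = np.diag(1.0 + rho * B) + rho * X[:, None] * D * y[None, :]
                X = X - np.linalg.solve(J, F)
            if np.max(np.abs(X * (1.0 + rho * (D @ (y * X))) - 1.0)) > 1e-12:
                raise ConvergenceError("complex-step association solve did not converge")
            return X, delta
        X = self._x_warm
        if X is None or X.shape != (nc,):
            X = np.full(nc, 0.5)
        else:
            X = X.copy()
        # a few successive substitutions to enter the Newton basin, then
        # Newton on F(X) = X (1 + rho D(yX)) - 1 (quadratic convergence);
        # damped successive substitution remains as the robust fallback
        converged = False
        for _ in range(4):
            X = 1.0 / (1.0 + rho * (D @ (y * X)))
        best_resid = np.inf
        for _ in range(30):
            B = D @ (y * X)
            F = X * (1.0 + rho * B) - 1.0
            resid = np.max(np.abs(F))
            if resid < tol or resid >= best_resid:  # converged or at noise floor
                converged = resid < 10 * tol
                break
            best_resid = resid
            J = np.diag(1.0 + rho * B) + rho * X[:, None] * D * y[None, :]
            try:
                step = np.linalg.solve(J, F)
            except np.linalg.LinAlgError:
                break
            Xn = X - step
            if np.any(Xn <= 0.0) or np.any(Xn > 1.0 + 1e-12):
                break
            X = Xn
        if not converged:
            for _ in range(10_000):
                Xnew = 1.0 / (1.0 + rho * (D @ (y * X)))
                if np.max(np.abs(Xnew - X)) < tol:
                    X = Xnew
                    break
                X = 0.5 * Xnew + 0.5 * X
        self._x_warm = X.copy()
        return X, delta

    def solve_site_fractions(
        self,
        T: float,
        rho: float,
        x: np.ndarray,
        tol: float = 1e-15,
        max_iter: int = 10_000,
        damping: float = 0.5,
    ) -> AssociationState:
        """Solve the Wertheim mass-action equations for the unbonded fractions.

        Hybrid solver (successive substitution to enter the Newton basin, then
        Newton, with damped successive substitution as fallback), warm-started
        from the previous call.
        """
        x = np.asarray(x, dtype=float)
        X, delta = self._solve_X(T, rho, x, tol)
        if self._n_sites_classes == 0:
            return AssociationState(np.empty(0), (), np.empty(0), delta, 0.0)
        y = x[self._site_comp] * self._site_mult  # site-class number weights
        D = self._site_delta_matrix(delta)
        resid = float(np.max(np.abs(X * (1.0 + rho * (D @ (y * X))) - 1.0)))
        if resid > 1e-12:
            raise ConvergenceError(
                f"association solver residual {resid:.2e} exceeds tolerance"
            )
        return AssociationState(X, self._site_labels, self._site_mult.copy(), delta, resid)

    def _site_delta_matrix(self, delta: np.ndarray) -> np.ndarray:
        """Delta between site classes: donor<->acceptor pairs only."""
        if self._n_sites_classes == 0:
            return np.zeros((0, 0))
        return np.where(self._pair_mask, delta[self._pair_comp], 0.0)

    def _site_fraction_derivative_from(self, T: float, rho, x, X, delta):
        """dX/drho at fixed T, x by implicit differentiation of mass action."""
        _, dg = self._rdf_drho(T, rho, x)
        ddelta = dg * self._at_T(T)["K_ij"]
        D = self._site_delta_matrix(delta)
        Dp = self._site_delta_matrix(ddelta)
        y = np.asarray(x)[self._site_comp] * self._site_mult
        B = D @ (y * X)
        C = Dp @ (y * X)
        M = np.diag(1.0 + rho * B) + rho * X[:, None] * D * y[None, :]
        rhs = -X * (B + rho * C)
        return np.linalg.solve(M, rhs)

    def _site_fraction_derivative(
        self, T: float, rho: float, x: np.ndarray, assoc: AssociationState
    ) -> np.ndarray:
        if self._n_sites_classes == 0:
            return np.empty(0)
        return self._site_fraction_derivative_from(
            T, rho, x, assoc.site_fractions, assoc.delta
        )

    # ---------------------------------------------------------- compressibility
    def _z_terms(self, T: float, rho, x):
        """(z_ref, z_pert, z_assoc); dtype-generic for complex-step use."""
        at = self._at_T(T)
        zeta2, eta, _, _ = self._packing(T, rho, x)
        g = self._rdf_from_packing(T, eta, zeta2)
        rr = np.outer(x * self._r, x * self._r)
        z_ref = 1.0 + rho * np.sum(rr * at["b_ij"] * g) - np.dot(
            x * (self._r - 1.0), np.diag(g) - 1.0
        )
        z_pert = -(rho / T) * np.sum(rr * at["a_ij"])
        z_assoc = 0.0
        if self._n_sites_classes:
            X, delta = self._solve_X(T, rho, x)
            dX = self._site_fraction_derivative_from(T, rho, x, X, delta)
            y = np.asarray(x)[self._site_comp] * self._site_mult
            z_assoc = rho * np.dot(y * (1.0 / X - 0.5), dX)
        return z_ref, z_pert, z_assoc

    def compressibility(self, T: float, rho: float, x: np.ndarray) -> EosBreakdown:
        """Z = Z_ref + Z_pert + Z_assoc at (T, rho, x)."""
        x = np.asarray(x, dtype=float)
        self._check_composition(x)
        if rho < 0:
            raise ValueError("density must be non-negative")
        if rho == 0.0:
            return EosBreakdown(1.0, 0.0, 0.0)
        z_ref, z_pert, z_assoc = self._z_terms(T, rho, x)
        return EosBreakdown(float(z_ref), float(z_pert), float(z_assoc))

    # ------------------------------------------------------------- Helmholtz
    def residual_helmholtz(self, T: float, rho, x):
        """A_res/(N k_B T) at (T, rho, x); exact integral of (Z-1)/rho.

        Dtype-generic: complex rho/x evaluate the analytic continuation, which
        the fugacity-coefficient routines use for complex-step derivatives.
        """
        x = np.asarray(x)
        if rho == 0.0:
            return 0.0
        at = self._at_T(T)
        zeta2, eta, c2, c3 = self._packing(T, rho, x)
        om = 1.0 - eta
        if np.real(eta) >= 1.0:
            raise ValueError("packing fraction must be < 1")
        ln_om = np.log(om)
        # kappa_ij = zeta_ij/eta, constant along the density path
        kap = self._zeta_ij(T, c2) / c3
        i1 = -ln_om
        i2 = 1.0 / om - 1.0 + ln_om
        i3 = 0.5 / om**2 - 0.5 - 2.0 * (1.0 / om - 1.0) - ln_om
        G = (i1 + 1.5 * kap * i2 + 0.5 * kap**2 * i3) / c3  # int_0^rho g_ij drho'
        rr = np.outer(x * self._r, x * self._r)
        a_ref_chain = i1 + 1.5 * np.diag(kap) * (1.0 / om - 1.0) + 0.5 * np.diag(kap) ** 2 * (
            0.5 / om**2 - 0.5 - (1.0 / om - 1.0)
        )
        a_ref = np.sum(rr * at["b_ij"] * G) - np.dot(x * (self._r - 1.0), a_ref_chain)
        a_pert = -(rho / T) * np.sum(rr * at["a_ij"])
        a_assoc = 0.0
        if self._n_sites_classes:
            X, _ = self._solve_X(T, rho, x)
            y = x[self._site_comp] * self._site_mult
            a_assoc = np.dot(y, np.log(X) - 0.5 * X + 0.5)
        out = a_ref + a_pert + a_assoc
        return out if np.iscomplexobj(out) else float(out)

    def z_assoc_from_helmholtz(self, T: float, rho: float, x: np.ndarray) -> float:
        """Association Z via the variational route (fixed site fractions).

        Cross-check for the mass-action-derivative route used by
        :meth:`compressibility`; the two agree to solver precision.
        """
        x = np.asarray(x, dtype=float)
        if self._n_sites_classes == 0 or rho == 0.0:
            return 0.0
        assoc = self.solve_site_fractions(T, rho, x)
        _, dg = self._rdf_drho(T, rho, x)
        D = self._site_delta_matrix(assoc.delta)
        Dp = self._site_delta_matrix(dg * self._at_T(T)["K_ij"])
        y = x[self._site_comp] * self._site_mult
        X = assoc.site_fractions
        h = float((y * X) @ D @ (y * X))
        dh = float((y * X) @ Dp @ (y * X))
        return -0.5 * rho * (h + rho * dh)

    # ---------------------------------------------------------------- pressure
    def pressure(self, T: float, rho: float, x: np.ndarray) -> float:
        """Pressure in Pa at molecular density rho (1/A^3)."""
        z = self.compressibility(T, rho, x).z_total
        return z * rho * T * _PRESSURE_UNIT

    def _pressure_generic(self, T: float, rho, x):
        if rho == 0.0:
            return 0.0 * rho
        return sum(self._z_terms(T, rho, x)) * rho * T * _PRESSURE_UNIT

    def solve_density(
        self,
        T: float,
        P: float,
        x: np.ndarray,
        phase: str = "liquid",
        eta_guess: float | None = None,
        rtol: float = 1e-10,
    ) -> SolutionState:
        """Invert P(rho) = P for the requested phase branch.

        The liquid branch is the highest-density root with positive
        compressibility (dP/drho > 0), the vapor branch the lowest.  A warm
        ``eta_guess`` triggers a safeguarded local Newton search before the
        full bracket scan.
        """
        if T <= 0 or P <= 0:
            raise ValueError("temperature and pressure must be positive")
        if phase not in ("liquid", "vapor"):
            raise ValueError(f"phase must be 'liquid' or 'vapor', got {phase!r}")
        x = np.asarray(x, dtype=float)
        self._check_composition(x)
        c3 = self._packing(T, 1.0, x)[3]

        def f(eta: float) -> float:
            return self.pressure(T, eta / c3, x) - P

        def fdf(eta: float) -> tuple[float, float]:
            # value and exact derivative by one complex-step evaluation
            hc = 1e-150
            pc = self._pressure_generic(T, (eta + 1j * hc) / c3, x)
            return float(pc.real) - P, float(pc.imag) / hc

        eta_root = None
        if eta_guess is not None and 0.0 < eta_guess < ETA_MAX:
            eta_root = self._newton_eta(fdf, eta_guess)
        if eta_root is None and phase == "liquid":
            # dense-liquid cold start; safeguarded, falls back to the scan
            eta_root = self._newton_eta(fdf, 0.55, basin=0.6)
            if eta_root is not None and eta_root < 0.25:
                eta_root = None  # likely drifted to a dilute root: rescan
        if eta_root is None:
            eta_root = self._newton_eta(fdf, self._bracket_scan(f, phase), basin=1e-3)
        if eta_root is None:
            raise ConvergenceError("density polish failed after bracketing")
        rho = eta_root / c3
        if abs(f(eta_root)) > max(rtol * P, 1e-9):
            raise ConvergenceError(
                f"density solve left relative pressure residual "
                f"{abs(f(eta_root)) / P:.2e} at eta={eta_root:.4f}"
            )
        z = self.compressibility(T, rho, x)
        assoc = self.solve_site_fractions(T, rho, x) if self._n_sites_classes else None
        return SolutionState(T, P, x.copy(), rho, eta_root, z, assoc)

    def _newton_eta(self, fdf, eta0: float, basin: float = 0.15):
        """Safeguarded Newton on P(eta) - P with exact (complex-step)
        derivatives; converges the root to machine precision, which keeps
        derived properties smooth in model parameters."""
        eta = eta0
        polished = 0
        for _ in range(60):
            fe, d = fdf(eta)
            if d <= 0.0:  # wandered onto an unstable branch
                return None
            step = fe / d
            new = eta - step
            if not (0.0 < new < ETA_MAX):
                return None
            if abs(new - eta0) > basin + 1e-6:  # left the starting basin
                return None
            eta = new
            if abs(step) < 4e-16 * max(eta, 1e-3):  # about one ulp of eta
                polished += 1  # one extra step past convergence
                if polished >= 2:
                    return eta
        return None

    def _bracket_scan(self, f, phase: str) -> float:
        etas = np.concatenate(
            [np.geomspace(1e-10, 2e-3, 10), np.linspace(4e-3, ETA_MAX, 150)]
        )
        vals = np.array([f(e) for e in etas])
        roots = []
        for k in range(len(etas) - 1):
            if vals[k] == 0.0:
                roots.append(etas[k])
            elif vals[k] * vals[k + 1] < 0.0:
                roots.append(brentq(f, etas[k], etas[k + 1], xtol=1e-15, rtol=8.9e-16))
        stable = []
        for root in roots:
            h = min(1e-7, 0.5 * root)
            if (f(root + h) - f(root - h)) > 0.0:
                stable.append(root)
        if not stable:
            raise ConvergenceError(
                f"no {phase} density root bracketed in eta in (0, {ETA_MAX})"
            )
        return max(stable) if phase == "liquid" else min(stable)

    # ---------------------------------------------------------------- fugacity
    def ln_fugacity_coefficients(self, state: SolutionState) -> np.ndarray:
        """ln(phi_i) from mole-number derivatives of n*a_res at fixed T, V.

        Complex-step differentiation: machine-precision derivatives with no
        subtractive cancellation; the association subproblem is re-solved at
        the complex-perturbed composition.
        """
        n = len(self.components)
        return np.array([self.ln_fugacity_coefficient(state, i) for i in range(n)])

    def ln_fugacity_coefficient(self, state: SolutionState, index: int) -> float:
        """ln(phi_i) for a single component."""
        T, rho, x = state.temperature, state.number_density, state.mole_fractions
        # Z from the solved (P, rho) pair: identical to the EoS value at the
        # converged root but smooth in model parameters (the EoS route would
        # amplify root jitter through dZ/deta when Z is small in the liquid)
        z = state.pressure / (rho * T * _PRESSURE_UNIT)
        if z <= 0:
            raise ValueError("non-positive compressibility factor")
        if len(self.components) == 1:
            return self.residual_helmholtz(T, rho, x[:1]) + z - 1.0 - math.log(z)
        V = 1.0 / rho  # volume per mole-number unit (n_tot = 1)
        h = 1e-150
        nvec = x.astype(complex)
        nvec[index] += 1j * h
        ntot = nvec.sum()
        F = ntot * self.residual_helmholtz(T, ntot / V, nvec / ntot)
        # dF/dn_i (with the (Z-1) density contribution included) - ln Z
        return float(F.imag) / h - math.log(z)

    @staticmethod
    def _check_composition(x: np.ndarray) -> None:
        if np.any(x < -1e-15):
            raise ValueError("mole fractions must be non-negative")
        if abs(float(x.sum()) - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {float(x.sum())!r}")
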