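"""Independent reference implementation of the equation of state.

Deliberately different numerics from the package: individual association
sites solved with ``scipy.optimize.fsolve`` (no site-class reduction), the
residual Helmholtz energy by adaptive quadrature of (Z-1)/rho (no closed
forms), the association compressibility by centered finite differences of the
site fractions, and fugacity coefficients by real finite differences of the
quadrature-based Helmholtz energy.  Slow, but an honest cross-check on tiny
fixtures.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import fsolve

TWO_PI_3 = 2.0 * math.pi / 3.0
PI_6 = math.pi / 6.0


def f_a(t):
    return 1.8681 * math.exp(-0.0619 * t) + 0.6715 * math.exp(-1.7317 * t**1.5)


def f_b(t):
    return 0.7303 * math.exp(-0.1649 * math.sqrt(t)) + 0.2697 * math.exp(-2.3973 * t**1.5)


class RefEos:
    def __init__(self, comps):
        self.comps = comps

    def _pair(self, i, j, T):
        ci, cj = self.comps[i], self.comps[j]
        sig = 0.5 * (ci.sigma + cj.sigma)
        eps = math.sqrt(ci.eps_over_k * cj.eps_over_k)
        a = TWO_PI_3 * sig**3 * eps * f_a(T / eps)
        b = TWO_PI_3 * sig**3 * f_b(T / eps)
        return sig, eps, a, b

    def _diams(self, T):
        return [c.sigma * f_b(T / c.eps_over_k) ** (1 / 3) for c in self.comps]

    def g_contact(self, T, rho, x, i, j):
        d = self._diams(T)
        z2 = PI_6 * rho * sum(xk * ck.r * dk**2 for xk, ck, dk in zip(x, self.comps, d))
        eta = PI_6 * rho * sum(xk * ck.r * dk**3 for xk, ck, dk in zip(x, self.comps, d))
        zij = 2.0 * d[i] * d[j] / (d[i] + d[j]) * z2
        om = 1.0 - eta
        return 1.0 / om + 1.5 * zij / om**2 + 0.5 * zij**2 / om**3

    # individual sites: for each component, n_sites/2 donors + n_sites/2
    # acceptors, every site its own unknown (the package reduces by class)
    def _sites(self):
        sites = []
        for ci, c in enumerate(self.comps):
            half = c.n_sites // 2 if (c.n_sites and c.kappa_assoc > 0) else 0
            for _ in range(half):
                sites.append((ci, "D"))
            for _ in range(half):
                sites.append((ci, "A"))
        return sites

    def _delta(self, T, rho, x, ci, cj):
        a, b = self.comps[ci], self.comps[cj]
        if not (a.kappa_assoc > 0 and b.kappa_assoc > 0):
            return 0.0
        sig = 0.5 * (a.sigma + b.sigma)
        epsab = 0.5 * (a.eps_assoc_over_k + b.eps_assoc_over_k)
        kap = math.sqrt(a.kappa_assoc * b.kappa_assoc)
        g = self.g_contact(T, rho, x, ci, cj)
        return g * (math.exp(epsab / T) - 1.0) * sig**3 * kap

    def site_fractions(self, T, rho, x):
        sites = self._sites()
        if not sites:
            return np.empty(0), sites

        def eqs(X):
            out = np.empty(len(sites))
            for s, (ci, ty) in enumerate(sites):
                acc = 0.0
                for t, (cj, tz) in enumerate(sites):
                    if ty != tz:
                        acc += x[cj] * X[t] * self._delta(T, rho, x, ci, cj)
                out[s] = X[s] * (1.0 + rho * acc) - 1.0
            return out

        X0 = np.full(len(sites), 0.5)
        for _ in range(60):  # successive substitution: X <- X/(F(X)+1)
            X0 = X0 / (eqs(X0) + 1.0)
        X = fsolve(eqs, X0, full_output=False, xtol=1e-13)
        return np.asarray(X), sites

    def z_total(self, T, rho, x):
        if rho == 0.0:
            return 1.0
        z_hs = 0.0
        z_pert = 0.0
        for i, ci in enumerate(self.comps):
            for j, cj in enumerate(self.comps):
                _, _, a, b = self._pair(i, j, T)
                g = self.g_contact(T, rho, x, i, j)
                z_hs += x[i] * x[j] * ci.r * cj.r * b * g
                z_pert += x[i] * x[j] * ci.r * cj.r * a
        z_ref = 1.0 + rho * z_hs - sum(
            x[i] * (c.r - 1.0) * (self.g_contact(T, rho, x, i, i) - 1.0)
            for i, c in enumerate(self.comps)
        )
        return z_ref - rho / T * z_pert + self.z_assoc(T, rho, x)

    def z_assoc(self, T, rho, x):
        sites = self._sites()
        if not sites:
            return 0.0
        h = 1e-6 * rho
        Xp, _ = self.site_fractions(T, rho + h, x)
        Xm, _ = self.site_fractions(T, rho - h, x)
        X, _ = self.site_fractions(T, rho, x)
        dX = (Xp - Xm) / (2.0 * h)
        return rho * sum(
            x[ci] * (1.0 / X[s] - 0.5) * dX[s] for s, (ci, _) in enumerate(sites)
        )

    def a_res(self, T, rho, x):
        val, _ = quad(
            lambda r: (self.z_total(T, r, x) - 1.0) / r, 1e-12, rho,
            limit=200, epsabs=1e-12, epsrel=1e-11,
        )
        return val

    def ln_phi(self, T, rho, x):
        """Fugacity coefficients by finite differences of n*a_res at fixed V."""
        x = np.asarray(x, dtype=float)
        z = self.z_total(T, rho, x)
        V = 1.0 / rho
        out = np.empty(len(x))
        h = 1e-5
        for i in range(len(x)):
            vals = []
            for s in (-2, -1, 1, 2):
                n = x.copy()
                n[i] += s * h
                nt = n.sum()
                vals.append(nt * self.a_res(T, nt / V, n / nt))
            dmu = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
            out[i] = dmu - math.log(z)
        return out
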