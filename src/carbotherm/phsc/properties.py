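"""Solution properties derived from the PHSC EoS: water activity, osmotic
coefficient and symmetric activity coefficients of binary sugar-water systems.

Conventions
-----------
* water activity includes the mole-fraction factor,
  ``a_w = x_w gamma_w = x_w phi_w / phi_0w``, so that a_w(m -> 0) = 1;
* the osmotic coefficient carries the conventional minus sign,
  ``phi = -1000 ln(a_w) / (M_w sum nu_i m_i)``, so phi(m -> 0) = 1;
* molality converts to mole fraction as ``x_s = m / (m + 1000/M_w)``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from carbotherm.phsc.components import PhscComponent
from carbotherm.phsc.eos import PhscEos, SolutionState

ATM_PRESSURE = 101_325.0  # Pa
BAR = 100_000.0  # Pa


def molality_to_mole_fraction(molality: float, molar_mass_water: float = 18.015) -> float:
    """Solute mole fraction of a binary solution at molality mol/kg."""
    if molality < 0:
        raise ValueError("molality must be non-negative")
    return molality / (molality + 1000.0 / molar_mass_water)


def mole_fraction_to_molality(x_solute: float, molar_mass_water: float = 18.015) -> float:
    if not 0 <= x_solute < 1:
        raise ValueError("solute mole fraction must be in [0, 1)")
    return 1000.0 * x_solute / ((1.0 - x_solute) * molar_mass_water)


def osmotic_coefficient(
    a_w: float,
    molalities: Sequence[float] | float,
    stoichiometries: Sequence[float] | float = 1.0,
    molar_mass_water: float = 18.015,
) -> float:
    """phi = -1000 ln(a_w) / (M_w sum nu_i m_i)."""
    m = np.atleast_1d(np.asarray(molalities, dtype=float))
    nu = np.broadcast_to(np.asarray(stoichiometries, dtype=float), m.shape)
    total = float(np.dot(nu, m))
    if total <= 0:
        raise ValueError("total solute molality must be positive")
    if a_w <= 0:
        raise ValueError("water activity must be positive")
    return -1000.0 * math.log(a_w) / (molar_mass_water * total)


class _PureReferenceCache:
    """Memoized pure-component ln(phi_0) at (T, P) for reference states."""

    def __init__(self) -> None:
        self._data: dict[tuple, float] = {}

    def ln_phi0(self, component: PhscComponent, T: float, P: float) -> float:
        key = (component, T, P)
        if key not in self._data:
            eos = PhscEos([component])
            try:
                state = eos.solve_density(T, P, np.array([1.0]), phase="liquid")
            except Exception as exc:  # re-raise naming the reference state
                raise RuntimeError(
                    f"pure-{component.name} reference state failed at "
                    f"T={T} K, P={P} Pa: {exc}"
                ) from exc
            self._data[key] = float(eos.ln_fugacity_coefficients(state)[0])
        return self._data[key]


_REFERENCE_CACHE = _PureReferenceCache()


class BinarySolution:
    """A binary sugar-water mixture at fixed pressure.

    Component order is fixed to (sugar, water).  Successive calls warm-start
    the liquid-density search from the previous packing fraction, which makes
    molality sweeps and fitting loops cheap.
    """

    def __init__(self, sugar: PhscComponent, water: PhscComponent, pressure: float = BAR):
        self.sugar = sugar
        self.water = water
        self.pressure = float(pressure)
        self.eos = PhscEos([sugar, water])
        self._eta_warm: float | None = None

    def state_at(self, T: float, molality: float) -> SolutionState:
        x_s = molality_to_mole_fraction(molality, self.water.molar_mass)
        x = np.array([x_s, 1.0 - x_s])
        state = self.eos.solve_density(
            T, self.pressure, x, phase="liquid", eta_guess=self._eta_warm
        )
        self._eta_warm = state.eta
        return state

    def ln_gamma(self, T: float, molality: float) -> tuple[float, float]:
        """(ln gamma_sugar, ln gamma_water), symmetric convention."""
        state = self.state_at(T, molality)
        lnphi = self.eos.ln_fugacity_coefficients(state)
        ln_phi0_s = _REFERENCE_CACHE.ln_phi0(self.sugar, T, self.pressure)
        ln_phi0_w = _REFERENCE_CACHE.ln_phi0(self.water, T, self.pressure)
        return float(lnphi[0] - ln_phi0_s), float(lnphi[1] - ln_phi0_w)

    def water_activity(self, T: float, molality: float) -> float:
        if molality < 0:
            raise ValueError("molality must be non-negative")
        if molality == 0.0:
            return 1.0
        x_s = molality_to_mole_fraction(molality, self.water.molar_mass)
        state = self.state_at(T, molality)
        ln_phi_w = self.eos.ln_fugacity_coefficient(state, 1)
        ln_phi0_w = _REFERENCE_CACHE.ln_phi0(self.water, T, self.pressure)
        return (1.0 - x_s) * math.exp(ln_phi_w - ln_phi0_w)

    def osmotic_coefficient(self, T: float, molality: float) -> float:
        a_w = self.water_activity(T, molality)
        return osmotic_coefficient(a_w, molality, 1.0, self.water.molar_mass)

    def activity_coefficient_sugar(self, T: float, molality: float) -> float:
        return math.exp(self.ln_gamma(T, molality)[0])

    def properties_at(self, T: float, molality: float) -> tuple[float, float, float]:
        """(a_w, phi, gamma_sugar) from a single density solve."""
        if molality < 0:
            raise ValueError("molality must be non-negative")
        x_s = molality_to_mole_fraction(molality, self.water.molar_mass)
        state = self.state_at(T, max(molality, 1e-12))
        ln_phi_s = self.eos.ln_fugacity_coefficient(state, 0)
        ln_phi_w = self.eos.ln_fugacity_coefficient(state, 1)
        ln_phi0_s = _REFERENCE_CACHE.ln_phi0(self.sugar, T, self.pressure)
        ln_phi0_w = _REFERENCE_CACHE.ln_phi0(self.water, T, self.pressure)
        a_w = (1.0 - x_s) * math.exp(ln_phi_w - ln_phi0_w) if molality > 0 else 1.0
        phi = (
            osmotic_coefficient(a_w, molality, 1.0, self.water.molar_mass)
            if molality > 0
            else 1.0
        )
        gamma = math.exp(ln_phi_s - ln_phi0_s)
        return a_w, phi, gamma


def water_activity(
    T: float,
    P: float,
    molality: float,
    sugar: PhscComponent,
    water: PhscComponent,
) -> float:
    """a_w = x_w phi_w / phi_0w for a binary sugar-water solution."""
    return BinarySolution(sugar, water, P).water_activity(T, molality)


def symmetric_activity_coefficient(
    T: float,
    P: float,
    x: Sequence[float],
    components: Sequence[PhscComponent],
    index: int,
) -> float:
    """gamma_i = phi_i(T,P,x) / phi_0i(T,P); gamma_i -> 1 as x_i -> 1."""
    x = np.asarray(x, dtype=float)
    eos = PhscEos(list(components))
    state = eos.solve_density(T, P, x, phase="liquid")
    lnphi = eos.ln_fugacity_coefficients(state)
    ln_phi0 = _REFERENCE_CACHE.ln_phi0(components[index], T, P)
    return math.exp(float(lnphi[index]) - ln_phi0)


def predict_solution_properties(
    sugar: PhscComponent,
    water: PhscComponent,
    temperature: float,
    molalities: Sequence[float],
    pressure: float = BAR,
) -> pd.DataFrame:
    """Osmotic coefficient, water activity and sugar activity coefficient on a
    molality grid (the shape of the published property figures).

    Returns a DataFrame with columns ``T_K, molality, a_w, phi, gamma_sugar``;
    ``phi`` at m = 0 is reported as the ideal-dilute limit 1.
    """
    sol = BinarySolution(sugar, water, pressure)
    rows = []
    for m in molalities:
        a_w, phi, gamma = sol.properties_at(temperature, float(m))
        rows.append((temperature, m, a_w, phi, gamma))
    return pd.DataFrame(rows, columns=["T_K", "molality", "a_w", "phi", "gamma_sugar"])
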