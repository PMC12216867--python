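"""Solid-liquid-equilibrium solubility of sugars in water.

Equating solid and dissolved-solute fugacities via the melting properties
gives, with a temperature-independent heat-capacity difference dCp,

    -ln(x gamma) = (dH_m/R)(1/T - 1/T_m) + (dCp/R) ln(T_m/T)
                   - (dCp/R)(T_m/T - 1)

The right-hand side vanishes at T = T_m (so x gamma = 1 there) and reduces to
the van 't Hoff form for dCp = 0.  Solubility follows by closing the equation
with an activity-coefficient provider: the ideal case gamma = 1 gives
``x = exp(-RHS)`` directly; a concentration-dependent gamma(x) is solved by a
damped fixed point with a bracketed-bisection fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

from carbotherm import resources
from carbotherm.phsc.properties import mole_fraction_to_molality

R_GAS = 8.314  # J/(mol K)


@dataclass(frozen=True)
class MeltingProperties:
    """Melting temperature (K), melting enthalpy (J/mol) and liquid-solid
    heat-capacity difference at the melting point (J/mol/K)."""

    name: str
    t_m: float
    dh_m: float
    dcp: float = 0.0

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError(f"{self.name}: melting temperature must be positive")
        if self.dh_m <= 0:
            raise ValueError(f"{self.name}: melting enthalpy must be positive")
        if self.dcp < 0:
            raise ValueError(f"{self.name}: heat-capacity difference must be >= 0")


@dataclass(frozen=True)
class SolubilityResult:
    """Converged saturation composition at one temperature."""

    x_solute: float
    molality: float
    gamma_at_solution: float
    iterations: int
    converged: bool
    boundary: bool = False  # x pinned at the T >= T_m boundary


@lru_cache(maxsize=1)
def packaged_melting_properties() -> dict[str, MeltingProperties]:
    """Published melting properties for the six sugars with solubility data."""
    df = resources.load_csv("melting_properties.csv")
    return {
        row.name: MeltingProperties(
            name=row.name,
            t_m=float(row.t_m_K),
            dh_m=float(row.dh_m_J_mol),
            dcp=float(row.dcp_J_mol_K),
        )
        for row in df.itertuples(index=False)
    }


def melting_properties(name: str) -> MeltingProperties:
    """Case-insensitive lookup into :func:`packaged_melting_properties`."""
    table = packaged_melting_properties()
    if name in table:
        return table[name]
    lowered = {k.lower(): v for k, v in table.items()}
    if name.lower() in lowered:
        return lowered[name.lower()]
    raise KeyError(f"no packaged melting properties for {name!r}; have {sorted(table)}")


def sle_rhs(T: float, props: MeltingProperties) -> float:
    """Value of -ln(x gamma) at temperature T (dimensionless)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    tm = props.t_m
    return (
        props.dh_m / R_GAS * (1.0 / T - 1.0 / tm)
        + props.dcp / R_GAS * math.log(tm / T)
        - props.dcp / R_GAS * (tm / T - 1.0)
    )


def ideal_solubility(T: float, props: MeltingProperties) -> float:
    """Saturation mole fraction for gamma = 1: exp(-RHS), capped at 1."""
    return min(1.0, math.exp(-sle_rhs(T, props)))


def solve_solubility(
    T: float,
    props: MeltingProperties,
    activity_provider: Callable[[float], float] | None = None,
    molar_mass_water: float = 18.015,
    tol: float = 1e-10,
    max_iter: int = 500,
    damping: float = 0.5,
    method: str = "fixed-point",
    x_init: float | None = None,
) -> SolubilityResult:
    """Solve ``ln x + ln gamma(x) = -RHS`` for the saturation mole fraction.

    ``activity_provider`` maps solute mole fraction to the symmetric activity
    coefficient; ``None`` means ideal (gamma = 1).  ``method`` selects the
    damped fixed point (default) or a bracketed bisection on
    ``f(x) = ln x + ln gamma(x) + RHS``; both must agree for a healthy
    provider.
    """
    rhs = sle_rhs(T, props)
    if activity_provider is None:
        x = min(1.0, math.exp(-rhs))
        boundary = rhs <= 0.0
        molal = mole_fraction_to_molality(min(x, 1.0 - 1e-15), molar_mass_water)
        return SolubilityResult(x, molal, 1.0, 0, True, boundary)

    if method == "fixed-point":
        x = min(math.exp(-rhs), 0.999) if x_init is None else x_init
        for it in range(1, max_iter + 1):
            gamma = activity_provider(x)
            if gamma <= 0:
                raise ValueError(f"activity provider returned gamma={gamma} at x={x}")
            x_new = min(math.exp(-rhs) / gamma, 0.999)
            if abs(x_new - x) < tol * max(x, 1e-30):
                x = x_new
                break
            x = damping * x + (1.0 - damping) * x_new
        else:
            raise RuntimeError(
                f"solubility fixed point did not converge in {max_iter} iterations "
                f"(last x={x:.6g})"
            )
        gamma = activity_provider(x)
        return SolubilityResult(
            x, mole_fraction_to_molality(x, molar_mass_water), gamma, it, True
        )

    if method == "bisection":
        def f(x: float) -> float:
            return math.log(x) + math.log(activity_provider(x)) + rhs

        lo, hi = 1e-8, 0.999
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise RuntimeError(
                f"no sign change for solubility bracket [{lo}, {hi}]: "
                f"f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
            )
        it = 0
        while hi - lo > tol * max(lo, 1e-30) and it < 200:
            mid = 0.5 * (lo + hi)
            if f(mid) * flo <= 0:
                hi = mid
            else:
                lo, flo = mid, f(mid)
            it += 1
        x = 0.5 * (lo + hi)
        return SolubilityResult(
            x, mole_fraction_to_molality(x, molar_mass_water), activity_provider(x), it, True
        )

    raise ValueError(f"unknown method {method!r}")


def ann_activity_provider(
    weights,
    sugar_name: str,
    T: float,
    molality_grid=None,
    molar_mass_water: float = 18.015,
):
    """gamma_solute(x) provider backed by a trained network.

    The network predicts at discrete molalities, so predictions are made on a
    grid and interpolated (cubic) before root-finding.  ``weights`` must carry
    input/output scaling (i.e. come from :func:`carbotherm.ann.train`, not the
    printed table).
    """
    import warnings

    import numpy as np
    from scipy.interpolate import CubicSpline

    from carbotherm.ann import forward
    from carbotherm.joback import sugar_descriptor
    from carbotherm.phsc.properties import mole_fraction_to_molality

    if weights.input_scaling is None or weights.output_scaling is None:
        raise ValueError(
            "network carries no input/output scaling; the printed weight "
            "table cannot be used for quantitative prediction"
        )
    if molality_grid is None:
        molality_grid = np.linspace(0.05, 6.0, 60)
    grid = np.asarray(molality_grid, dtype=float)
    t_c, v_c, t_m = sugar_descriptor(sugar_name)
    dh_m = melting_properties(sugar_name).dh_m
    X = np.column_stack([
        np.full_like(grid, t_c), np.full_like(grid, v_c),
        np.full_like(grid, t_m), np.full_like(grid, dh_m),
        grid, np.full_like(grid, T),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grid edges may extrapolate slightly
        gamma_grid = forward(weights, X)[:, 1]
    spline = CubicSpline(grid, gamma_grid)

    def gamma(x_solute: float) -> float:
        m = mole_fraction_to_molality(x_solute, molar_mass_water)
        return float(spline(min(max(m, grid[0]), grid[-1])))

    return gamma


def phsc_activity_provider(sugar_name: str, T: float, pressure: float = 1e5):
    """gamma_solute(x) provider backed by the PHSC EoS at (T, P)."""
    import numpy as np

    from carbotherm.phsc.components import load_components
    from carbotherm.phsc.properties import symmetric_activity_coefficient

    sugar, water = load_components(sugar_name, "Water")

    def gamma(x_solute: float) -> float:
        x = np.array([x_solute, 1.0 - x_solute])
        return symmetric_activity_coefficient(T, pressure, x, [sugar, water], 0)

    return gamma
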