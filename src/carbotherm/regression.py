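"""Fitting PHSC pure-sugar parameters to binary osmotic-coefficient data.

The fitted quantities are the five pure-component parameters
(r, sigma, eps/k_B, eps^AB/k_B, kappa^AB); the association-site count is fixed
by molecular structure (two sites per hydroxyl group) and the water parameters
are the packaged reference set, not refit.

The reported objective is the sum of relative absolute deviations

    OF = sum_i |phi_exp_i - phi_calc_i| / phi_exp_i

The optimizer minimizes the smooth least-squares surrogate (sum of squared
relative residuals, i.e. soft-abs smoothing of OF) with bounded trust-region
least squares from seeded Latin-hypercube multi-starts, then reports OF at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from carbotherm.phsc.components import PhscComponent, site_count_from_hydroxyls
from carbotherm.phsc.properties import BAR, BinarySolution

__all__ = [
    "OsmoticDataset",
    "FitResult",
    "DEFAULT_BOUNDS",
    "objective",
    "fit_solute",
    "site_count_from_hydroxyls",
]

_PARAM_NAMES = ("r", "sigma", "eps_over_k", "eps_assoc_over_k", "kappa_assoc")

#: Bounds spanning the packaged fitted-parameter table with headroom.
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "r": (1.0, 15.0),
    "sigma": (2.0, 5.0),
    "eps_over_k": (150.0, 600.0),
    "eps_assoc_over_k": (800.0, 3200.0),
    "kappa_assoc": (0.005, 0.15),
}


@dataclass(frozen=True)
class OsmoticDataset:
    """Experimental or synthetic (T, molality, osmotic coefficient) records."""

    sugar: str
    temperature: np.ndarray  # K
    molality: np.ndarray  # mol/kg
    phi_exp: np.ndarray
    provenance: str = "experimental"
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        m = np.asarray(self.molality, dtype=float)
        p = np.asarray(self.phi_exp, dtype=float)
        if not (t.shape == m.shape == p.shape) or t.ndim != 1:
            raise ValueError("temperature, molality, phi_exp must be equal-length 1-D")
        if np.any(m <= 0):
            raise ValueError("molalities must be positive")
        if np.any(p <= 0):
            raise ValueError("osmotic coefficients must be positive")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "molality", m)
        object.__setattr__(self, "phi_exp", p)

    def __len__(self) -> int:
        return len(self.molality)


@dataclass
class FitResult:
    """Best-of-starts fit with recovery diagnostics."""

    component: PhscComponent
    objective: float  # Eq-18-style sum of relative absolute deviations
    residuals: np.ndarray  # per-point relative residuals (exp - calc)/exp
    n_starts: int
    seed: int | None
    start_objectives: list = field(default_factory=list)
    n_evaluations: int = 0


def _predict_phi(
    dataset: OsmoticDataset, candidate: PhscComponent, water: PhscComponent
) -> np.ndarray:
    sol = BinarySolution(candidate, water, BAR)
    out = np.empty(len(dataset))
    for k, (t, m) in enumerate(zip(dataset.temperature, dataset.molality)):
        try:
            out[k] = sol.osmotic_coefficient(float(t), float(m))
        except Exception as exc:
            raise RuntimeError(
                f"EoS evaluation failed at T={t} K, m={m} mol/kg for "
                f"candidate {candidate.name!r}: {exc}"
            ) from exc
    return out


def objective(
    dataset: OsmoticDataset, candidate: PhscComponent, water: PhscComponent
) -> float:
    """Sum over records of |phi_exp - phi_calc| / phi_exp."""
    phi_calc = _predict_phi(dataset, candidate, water)
    return float(np.sum(np.abs(dataset.phi_exp - phi_calc) / dataset.phi_exp))


def fit_solute(
    dataset: OsmoticDataset,
    water: PhscComponent,
    n_sites: int,
    bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS,
    starts: int = 8,
    seed: int | None = 0,
    molar_mass: float = float("nan"),
    name: str | None = None,
    xtol: float = 1e-10,
    max_nfev: int = 150,
    polish_nfev: int = 120,
) -> FitResult:
    """Fit (r, sigma, eps/k, eps^AB/k, kappa^AB) to osmotic-coefficient data.

    ``n_sites`` is held fixed (use :func:`site_count_from_hydroxyls`).
    Deterministic for a given ``seed``: multi-start points come from a seeded
    Latin hypercube over the bounds and each local search is deterministic.
    """
    if len(dataset) < len(_PARAM_NAMES):
        raise ValueError(
            f"need at least {len(_PARAM_NAMES)} records to fit, got {len(dataset)}"
        )
    lo = np.array([bounds[k][0] for k in _PARAM_NAMES])
    hi = np.array([bounds[k][1] for k in _PARAM_NAMES])
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lower < upper")
    fit_name = name or f"{dataset.sugar} (fitted)"

    def make_component(p: np.ndarray) -> PhscComponent:
        return PhscComponent(
            name=fit_name,
            r=float(p[0]),
            sigma=float(p[1]),
            eps_over_k=float(p[2]),
            eps_assoc_over_k=float(p[3]),
            kappa_assoc=float(p[4]),
            n_sites=int(n_sites),
            molar_mass=molar_mass,
        )

    n_eval = 0

    def residual_vec(p: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        try:
            phi_calc = _predict_phi(dataset, make_component(p), water)
        except RuntimeError:
            # infeasible corner of parameter space: steer the optimizer away
            return np.full(len(dataset), 10.0)
        return (dataset.phi_exp - phi_calc) / dataset.phi_exp

    # screen a seeded Latin-hypercube pool on the raw objective, then run the
    # bounded local searches from the most promising candidates (the objective
    # surface is multimodal; unscreened starts rarely find the global valley)
    sampler = qmc.LatinHypercube(d=len(_PARAM_NAMES), seed=seed)
    pool = lo + sampler.random(max(8 * starts, 64)) * (hi - lo)
    pool_of = np.array([float(np.sum(np.abs(residual_vec(p)))) for p in pool])
    start_points = pool[np.argsort(pool_of)[:starts]]

    best = None
    start_objectives: list[float] = []
    failures: list[str] = []
    for p0 in start_points:
        try:
            res = least_squares(
                residual_vec,
                p0,
                bounds=(lo, hi),
                method="trf",
                x_scale=(hi - lo),
                xtol=xtol,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
        except Exception as exc:
            failures.append(str(exc))
            continue
        of = float(np.sum(np.abs(res.fun)))
        start_objectives.append(of)
        if best is None or of < best[0]:
            best = (of, res)
    if best is None:
        raise RuntimeError(
            f"all {starts} fit starts failed: {'; '.join(failures[:3])}"
        )
    # polish the winner
    res = least_squares(
        residual_vec, best[1].x, bounds=(lo, hi), method="trf",
        x_scale=(hi - lo), xtol=3e-16, ftol=3e-16, gtol=1e-15, max_nfev=polish_nfev,
    )
    of = float(np.sum(np.abs(res.fun)))
    if of > best[0]:
        of, res = best
    return FitResult(
        component=make_component(res.x),
        objective=of,
        residuals=res.fun.copy(),
        n_starts=starts,
        seed=seed,
        start_objectives=start_objectives,
        n_evaluations=n_eval,
    )
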