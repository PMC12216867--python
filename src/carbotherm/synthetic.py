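"""Seeded synthetic pseudo-experiments generated from the PHSC model.

The published property compilations behind the fitted parameter table are not
printed, so testing the regression and network stages requires stand-in data.
The generator evaluates the PHSC model on a molality grid and perturbs the
osmotic coefficient with multiplicative Gaussian noise,

    phi_obs = phi_phsc * (1 + e),   e ~ N(0, sd^2) i.i.d.

mirroring the relative-error structure of the average-relative-deviation
metric the fits minimize.  Defaults follow the binary-data conditions of the
packaged parameter table: temperatures 298-308 K and molalities up to a few
mol/kg.  Noiseless truth columns are always retained for oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from carbotherm.joback import sugar_descriptor
from carbotherm.phsc.components import PhscComponent, load_components
from carbotherm.phsc.properties import BAR, BinarySolution
from carbotherm.regression import OsmoticDataset
from carbotherm.sle import melting_properties


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one binary sugar-water pseudo-dataset."""

    sugar: PhscComponent
    temperature: float = 298.15
    molality_min: float = 0.1
    molality_max: float = 4.0
    n_points: int = 20
    noise_sd: float = 0.01  # relative standard deviation on phi
    noise_mode: str = "multiplicative"  # or "additive"
    seed: int = 0
    pressure: float = BAR

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("need at least 3 grid points")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.molality_min <= self.molality_max:
            raise ValueError("molality grid must be positive and ordered")
        if self.noise_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")


def generate_pseudo_dataset(
    spec: SyntheticSpec, water: PhscComponent | None = None
) -> tuple[OsmoticDataset, pd.DataFrame]:
    """PHSC curve plus seeded noise.

    Returns the noisy :class:`OsmoticDataset` and a companion DataFrame with
    noiseless truth columns (``phi_true, a_w_true, gamma_true``).
    """
    water = water or load_components("Water")[0]
    sol = BinarySolution(spec.sugar, water, spec.pressure)
    m_grid = np.linspace(spec.molality_min, spec.molality_max, spec.n_points)
    phi_true = np.empty_like(m_grid)
    a_w = np.empty_like(m_grid)
    gamma = np.empty_like(m_grid)
    failures = []
    for k, m in enumerate(m_grid):
        try:
            a_w[k], phi_true[k], gamma[k] = sol.properties_at(spec.temperature, float(m))
        except Exception as exc:
            failures.append((float(m), str(exc)))
    if failures:
        raise RuntimeError(f"EoS evaluation failed on grid points: {failures}")
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=m_grid.shape) if spec.noise_sd else 0.0
    if spec.noise_mode == "multiplicative":
        phi_obs = phi_true * (1.0 + eps)
    else:
        phi_obs = phi_true + eps
    dataset = OsmoticDataset(
        sugar=spec.sugar.name,
        temperature=np.full_like(m_grid, spec.temperature),
        molality=m_grid,
        phi_exp=phi_obs,
        provenance="synthetic",
        seed=spec.seed,
    )
    companion = pd.DataFrame(
        {
            "T_K": dataset.temperature,
            "molality": m_grid,
            "phi_exp": phi_obs,
            "phi_true": phi_true,
            "a_w_true": a_w,
            "gamma_true": gamma,
        }
    )
    return dataset, companion


def make_ann_training_table(
    sugar_names: tuple[str, ...] = ("D-Glucose", "Sucrose"),
    descriptor_names: tuple[str, ...] = ("Glucose", "Sucrose"),
    temperatures: tuple[float, ...] = (298.15, 303.15, 308.15),
    n_points: int = 600,
    molality_max: float = 3.9,
    seed: int = 0,
) -> pd.DataFrame:
    """PHSC-generated network training table.

    Each row pairs the six network inputs (T_c, V_c, T_m, dH_m, molality, T)
    with the three PHSC-computed targets (phi, gamma, a_w).  Descriptors come
    from the packaged group-contribution table, melting enthalpies from the
    packaged melting-property table.  Molalities are sampled uniformly per
    sugar up to ``molality_max`` (seeded), emulating the size and coverage of
    the compiled experimental set.
    """
    water = load_components("Water")[0]
    rng = np.random.default_rng(seed)
    rows = []
    per = int(np.ceil(n_points / (len(sugar_names) * len(temperatures))))
    for s_name, d_name in zip(sugar_names, descriptor_names):
        sugar = load_components(s_name)[0]
        t_c, v_c, t_m = sugar_descriptor(d_name)
        dh_m = melting_properties(s_name).dh_m
        for T in temperatures:
            sol = BinarySolution(sugar, water)
            m_vals = np.sort(rng.uniform(0.05, molality_max, size=per))
            for m in m_vals:
                a_w, phi, gam = sol.properties_at(T, float(m))
                rows.append((s_name, t_c, v_c, t_m, dh_m, m, T, phi, gam, a_w))
    df = pd.DataFrame(
        rows,
        columns=["sugar", "T_c", "V_c", "T_m", "dH_m", "molality", "T_K",
                 "phi", "gamma", "a_w"],
    )
    return df.iloc[:n_points].reset_index(drop=True)
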