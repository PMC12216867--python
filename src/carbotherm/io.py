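"""CSV/JSON readers and writers for the package's data schemas.

Schemas
-------
* osmotic-coefficient CSV: columns ``sugar, T_K, molality, phi_exp``
  (extra columns are preserved); UTF-8, comma-delimited, header mandatory.
* PHSC parameter JSON: mirrors the packaged parameter table
  (``name, r, sigma_A, eps_over_k_K, eps_assoc_over_k_K, kappa_assoc,
  n_sites, molar_mass_g_mol``).
* network-weights JSON: ``w_ih, b_h, w_ho, b_o, input_scaling,
  output_scaling, metadata``.

Malformed rows are reported with their 1-based data row number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from carbotherm.ann import AffineScaling, NetworkWeights
from carbotherm.phsc.components import PhscComponent
from carbotherm.regression import FitResult, OsmoticDataset


class ParseError(ValueError):
    """A data file violates its schema."""


# ------------------------------------------------------------- osmotic CSV
def read_osmotic_csv(path, sugar: str | None = None) -> OsmoticDataset:
    """Read experimental (T, molality, phi) records.

    ``sugar`` filters a multi-sugar file; with one sugar present it may be
    omitted.
    """
    df = pd.read_csv(path)
    required = {"sugar", "T_K", "molality", "phi_exp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if sugar is not None:
        df = df[df["sugar"] == sugar]
        if df.empty:
            raise ParseError(f"{path}: no rows for sugar {sugar!r}")
    else:
        sugars = df["sugar"].unique()
        if len(sugars) != 1:
            raise ParseError(
                f"{path}: multiple sugars {list(sugars)}; pass sugar= to select one"
            )
        sugar = str(sugars[0])
    for col in ("T_K", "molality", "phi_exp"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col} value {df.loc[bad[0], col]!r} "
                f"in data row {int(bad[0]) + 1}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 1
            raise ParseError(f"{path}: missing {col} in data row {row}")
        df[col] = coerced
    return OsmoticDataset(
        sugar=sugar,
        temperature=df["T_K"].to_numpy(),
        molality=df["molality"].to_numpy(),
        phi_exp=df["phi_exp"].to_numpy(),
    )


def write_osmotic_csv(path, dataset: OsmoticDataset) -> None:
    pd.DataFrame(
        {
            "sugar": dataset.sugar,
            "T_K": dataset.temperature,
            "molality": dataset.molality,
            "phi_exp": dataset.phi_exp,
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------- component JSON
def component_to_dict(c: PhscComponent) -> dict:
    return {
        "name": c.name,
        "r": c.r,
        "sigma_A": c.sigma,
        "eps_over_k_K": c.eps_over_k,
        "eps_assoc_over_k_K": c.eps_assoc_over_k,
        "kappa_assoc": c.kappa_assoc,
        "n_sites": c.n_sites,
        "molar_mass_g_mol": c.molar_mass,
    }


def component_from_dict(d: dict) -> PhscComponent:
    try:
        return PhscComponent(
            name=d["name"],
            r=float(d["r"]),
            sigma=float(d["sigma_A"]),
            eps_over_k=float(d["eps_over_k_K"]),
            eps_assoc_over_k=float(d.get("eps_assoc_over_k_K", 0.0)),
            kappa_assoc=float(d.get("kappa_assoc", 0.0)),
            n_sites=int(d.get("n_sites", 0)),
            molar_mass=float(d.get("molar_mass_g_mol", float("nan"))),
        )
    except KeyError as exc:
        raise ParseError(f"component record missing field {exc}") from exc


def write_fit_result(path, fit: FitResult) -> None:
    doc = {
        "component": component_to_dict(fit.component),
        "objective": fit.objective,
        "residuals": np.asarray(fit.residuals).tolist(),
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "start_objectives": list(fit.start_objectives),
        "n_evaluations": fit.n_evaluations,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit_result(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    return FitResult(
        component=component_from_dict(doc["component"]),
        objective=float(doc["objective"]),
        residuals=np.asarray(doc["residuals"], dtype=float),
        n_starts=int(doc["n_starts"]),
        seed=doc.get("seed"),
        start_objectives=[float(v) for v in doc.get("start_objectives", [])],
        n_evaluations=int(doc.get("n_evaluations", 0)),
    )


# ----------------------------------------------------------- network JSON
def _scaling_to_dict(sc: AffineScaling | None):
    if sc is None:
        return None
    return {"lo": sc.lo.tolist(), "hi": sc.hi.tolist()}


def _scaling_from_dict(d) -> AffineScaling | None:
    if d is None:
        return None
    return AffineScaling(np.asarray(d["lo"]), np.asarray(d["hi"]))


def write_network(path, weights: NetworkWeights) -> None:
    doc = {
        "w_ih": weights.w_ih.tolist(),
        "b_h": weights.b_h.tolist(),
        "w_ho": weights.w_ho.tolist(),
        "b_o": weights.b_o.tolist(),
        "input_scaling": _scaling_to_dict(weights.input_scaling),
        "output_scaling": _scaling_to_dict(weights.output_scaling),
        "metadata": {k: _jsonable(v) for k, v in weights.metadata.items()},
    }
    Path(path).write_text(json.dumps(doc))


def read_network(path) -> NetworkWeights:
    doc = json.loads(Path(path).read_text())
    try:
        return NetworkWeights(
            w_ih=np.asarray(doc["w_ih"], dtype=float),
            b_h=np.asarray(doc["b_h"], dtype=float),
            w_ho=np.asarray(doc["w_ho"], dtype=float),
            b_o=np.asarray(doc["b_o"], dtype=float),
            input_scaling=_scaling_from_dict(doc.get("input_scaling")),
            output_scaling=_scaling_from_dict(doc.get("output_scaling")),
            metadata=doc.get("metadata", {}),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: network file missing field {exc}") from exc


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(u) for u in v]
    return v
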