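"""Pure-component parameter sets for the PHSC equation of state."""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

from carbotherm import resources


def site_count_from_hydroxyls(n_oh: int) -> int:
    """Association sites from hydroxyl count: one donor and one acceptor per
    OH group, hence ``2 * n_oh`` sites."""
    if n_oh < 0:
        raise ValueError("hydroxyl count must be non-negative")
    return 2 * int(n_oh)


@dataclass(frozen=True)
class PhscComponent:
    """PHSC parameters of one pure component.

    Parameters
    ----------
    r : segment number (dimensionless)
    sigma : segment diameter (angstrom)
    eps_over_k : segment dispersion energy eps/k_B (K)
    eps_assoc_over_k : association (hydrogen-bond) energy eps^AB/k_B (K)
    kappa_assoc : association volume kappa^AB (dimensionless)
    n_sites : total association sites, split half donor / half acceptor
    molar_mass : g/mol
    """

    name: str
    r: float
    sigma: float
    eps_over_k: float
    eps_assoc_over_k: float = 0.0
    kappa_assoc: float = 0.0
    n_sites: int = 0
    molar_mass: float = float("nan")

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"{self.name}: segment number r must be positive")
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: segment diameter must be positive")
        if self.eps_over_k <= 0:
            raise ValueError(f"{self.name}: segment energy must be positive")
        if self.kappa_assoc < 0:
            raise ValueError(f"{self.name}: association volume must be >= 0")
        if self.n_sites < 0 or self.n_sites % 2 != 0:
            raise ValueError(
                f"{self.name}: n_sites must be an even non-negative integer "
                "(half donors, half acceptors)"
            )

    @property
    def associating(self) -> bool:
        return self.n_sites > 0 and self.kappa_assoc > 0 and self.eps_assoc_over_k != 0

    def with_parameters(self, **kwargs) -> "PhscComponent":
        """Copy with selected fields replaced (used by the fitter)."""
        return replace(self, **kwargs)


@lru_cache(maxsize=1)
def _component_table() -> dict[str, PhscComponent]:
    df = resources.load_csv("phsc_parameters.csv")
    out: dict[str, PhscComponent] = {}
    for row in df.itertuples(index=False):
        out[row.name] = PhscComponent(
            name=row.name,
            r=float(row.r),
            sigma=float(row.sigma_A),
            eps_over_k=float(row.eps_over_k_K),
            eps_assoc_over_k=float(row.eps_assoc_over_k_K),
            kappa_assoc=float(row.kappa_assoc),
            n_sites=int(row.n_sites),
            molar_mass=float(row.molar_mass_g_mol),
        )
    return out


def load_components(*names: str) -> list[PhscComponent]:
    """Load packaged fitted parameter sets by name (case-insensitive).

    ``load_components()`` with no arguments returns all fourteen packaged
    components (thirteen sugars plus water).
    """
    table = _component_table()
    if not names:
        return list(table.values())
    lowered = {k.lower(): v for k, v in table.items()}
    out = []
    for name in names:
        if name in table:
            out.append(table[name])
        elif name.lower() in lowered:
            out.append(lowered[name.lower()])
        else:
            raise KeyError(f"no packaged PHSC parameters for {name!r}")
    return out


def load_component(name: str) -> PhscComponent:
    return load_components(name)[0]
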