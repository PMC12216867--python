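"""Joback-Reid group-contribution estimates of carbohydrate critical properties.

The normal boiling point, critical temperature and critical volume of a
molecule are estimated by summing empirical increments over its functional
groups:

    T_b = 198 + sum_k N_k tb_k                                  (K)
    T_c = T_b / (0.584 + 0.965 S - S^2),   S = sum_k N_k tc_k   (K)
    V_c = 17.5 + sum_k N_k vc_k                                 (cm^3/mol)

These feed the neural-network property predictor as molecular descriptors.

Two dialects of the group table are packaged.  The default uses the standard
Joback value tb(-CH2-) = 22.88 K, which reproduces the published polyol
critical temperatures (sorbitol 1092.90 K, xylitol 947.5 K); the alternative
``verbatim=True`` table keeps the transcribed 22.288 K.  Likewise the
denominator of the T_c expression squares the *critical-temperature* group sum
S (the standard Joback form) - squaring the boiling-point sum instead produces
meaningless values for polyols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from carbotherm import resources

GroupKey = tuple[str, bool]  # (group name, in_ring)

#: Standard Joback boiling-point increment for the acyclic methylene group;
#: the transcribed table prints 22.288.
_CH2_STANDARD_TB = 22.88


class UnknownGroupError(KeyError):
    """A group assignment references a group absent from the table."""


@dataclass(frozen=True)
class GroupContribution:
    """One functional group's increments (boiling point K, critical
    temperature (dimensionless), critical volume cm^3/mol)."""

    name: str
    in_ring: bool
    tb_k: float
    tc_k: float
    vc_k: float

    def __post_init__(self) -> None:
        if not (self.tb_k == self.tb_k):  # NaN guard
            raise ValueError(f"tb_k must be finite for group {self.name!r}")
        if self.vc_k < 0:
            raise ValueError(f"vc_k must be >= 0 for group {self.name!r}")


@dataclass(frozen=True)
class GroupAssignment:
    """Multiset of functional groups describing one molecule."""

    molecule: str
    counts: Mapping[GroupKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"group count for {key} must be a non-negative integer")

    @classmethod
    def from_records(cls, molecule: str, groups: Iterable[Mapping]) -> "GroupAssignment":
        """Build from JSON-style records ``{"name", "ring", "count"}``."""
        counts: dict[GroupKey, int] = {}
        for rec in groups:
            key = (str(rec["name"]), bool(rec.get("ring", False)))
            counts[key] = counts.get(key, 0) + int(rec["count"])
        return cls(molecule=molecule, counts=counts)

    def total_groups(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CriticalEstimate:
    """Joback estimates for one molecule (t_b, t_c in K; v_c in cm^3/mol)."""

    molecule: str
    t_b: float
    t_c: float
    v_c: float


@lru_cache(maxsize=4)
def load_group_table(verbatim: bool = False) -> dict[GroupKey, GroupContribution]:
    """The packaged group-increment table.

    With ``verbatim=False`` (default) the acyclic -CH2- boiling increment is
    the standard Joback 22.88; ``verbatim=True`` keeps the transcribed 22.288.
    """
    df = resources.load_csv("joback_groups.csv")
    table: dict[GroupKey, GroupContribution] = {}
    for row in df.itertuples(index=False):
        key = (row.name, bool(row.in_ring))
        if key in table:
            raise ValueError(f"duplicate group in packaged table: {key}")
        tb = float(row.tb_k)
        if not verbatim and key == ("-CH2-", False):
            tb = _CH2_STANDARD_TB
        table[key] = GroupContribution(key[0], key[1], tb, float(row.tc_k), float(row.vc_k))
    return table


def _resolve(assignment: GroupAssignment, table: Mapping[GroupKey, GroupContribution]):
    for key, n in assignment.counts.items():
        if key not in table:
            name, ring = key
            raise UnknownGroupError(
                f"unknown group {name!r} (ring={ring}) in assignment for "
                f"{assignment.molecule!r}"
            )
        yield table[key], n


def estimate_boiling_temperature(
    assignment: GroupAssignment,
    table: Mapping[GroupKey, GroupContribution] | None = None,
) -> float:
    """Normal boiling temperature in K: ``198 + sum N_k tb_k``."""
    table = load_group_table() if table is None else table
    return 198.0 + sum(g.tb_k * n for g, n in _resolve(assignment, table))


def estimate_critical_temperature(
    assignment: GroupAssignment,
    table: Mapping[GroupKey, GroupContribution] | None = None,
) -> float:
    """Critical temperature in K: ``T_b / (0.584 + 0.965 S - S^2)``."""
    table = load_group_table() if table is None else table
    t_b = estimate_boiling_temperature(assignment, table)
    s = sum(g.tc_k * n for g, n in _resolve(assignment, table))
    denom = 0.584 + 0.965 * s - s * s
    if denom <= 0.0:
        raise ValueError(
            f"group-contribution denominator non-positive ({denom:.4g}) for "
            f"{assignment.molecule!r}: assignment outside the method's validity"
        )
    return t_b / denom


def estimate_critical_volume(
    assignment: GroupAssignment,
    table: Mapping[GroupKey, GroupContribution] | None = None,
) -> float:
    """Critical volume in cm^3/mol: ``17.5 + sum N_k vc_k``."""
    table = load_group_table() if table is None else table
    return 17.5 + sum(g.vc_k * n for g, n in _resolve(assignment, table))


def estimate_critical_properties(
    assignment: GroupAssignment,
    table: Mapping[GroupKey, GroupContribution] | None = None,
) -> CriticalEstimate:
    table = load_group_table() if table is None else table
    return CriticalEstimate(
        molecule=assignment.molecule,
        t_b=estimate_boiling_temperature(assignment, table),
        t_c=estimate_critical_temperature(assignment, table),
        v_c=estimate_critical_volume(assignment, table),
    )


@lru_cache(maxsize=1)
def packaged_sugar_descriptors() -> dict[str, tuple[float, float, float]]:
    """Published (T_c K, V_c cm^3/mol, T_m K) for the fifteen sugars.

    These are the descriptor values used as neural-network inputs when a group
    assignment is not supplied.  Lookup is case-insensitive on the sugar name.
    """
    df = resources.load_csv("sugar_descriptors.csv")
    return {
        row.name: (float(row.t_c_K), float(row.v_c_cm3_mol), float(row.t_m_K))
        for row in df.itertuples(index=False)
    }


def sugar_descriptor(name: str) -> tuple[float, float, float]:
    """Lookup into :func:`packaged_sugar_descriptors`.

    Case-insensitive and tolerant of stereo-prefixes ("D-Glucose" finds
    "Glucose"), since the packaged tables differ in naming dialect.
    """
    table = packaged_sugar_descriptors()
    if name in table:
        return table[name]
    lowered = {k.lower(): v for k, v in table.items()}
    for candidate in (name.lower(), name.lower().removeprefix("d-").removeprefix("l-")):
        if candidate in lowered:
            return lowered[candidate]
    raise KeyError(f"unknown sugar {name!r}; packaged: {sorted(table)}")


@lru_cache(maxsize=1)
def packaged_group_assignments() -> dict[str, tuple[GroupAssignment, bool]]:
    """Best-effort packaged assignments: ``{molecule: (assignment, verified)}``.

    Ring-sugar assignments are flagged unverified (no assignment built from the
    packaged table reproduces the published ring-sugar critical volumes).
    """
    doc = resources.load_json("group_assignments.json")
    out: dict[str, tuple[GroupAssignment, bool]] = {}
    for rec in doc["molecules"]:
        out[rec["molecule"]] = (
            GroupAssignment.from_records(rec["molecule"], rec["groups"]),
            bool(rec["verified"]),
        )
    return out
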