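"""Nernst pH adjustment of midpoint potentials and mediator feasibility.

Indigo reduction requires an electron donor/mediator whose midpoint
potential at the vat's (alkaline) pH is at or below the potential indigo
itself needs, about -600 mV vs SHE. A couple transferring m protons and
n electrons shifts its midpoint with pH as

    E°'(pH2) = E°'(pH1) - 2.303 m R T / (n F) * (pH2 - pH1)

with -2.303 RT/F ≈ 59 mV per pH unit at 25 °C. This module evaluates
that shift and classifies candidate mediators (flavins, NADH, ...)
against the indigo threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError, InvariantError

#: Gas constant, J K^-1 mol^-1.
R = 8.315
#: Faraday constant, J mol^-1 V^-1.
F = 96486.0
#: Default absolute temperature, K (25 °C).
T_DEFAULT = 298.0
#: Midpoint potential indigo requires for reduction, mV vs SHE.
E_REQUIRED_MV = -600.0


@dataclass(frozen=True)
class RedoxCouple:
    """A half-reaction with its reference midpoint potential.

    Parameters
    ----------
    name : str
    e_ref_mV : float
        Midpoint potential at ``pH_ref``, mV vs SHE.
    pH_ref : float
    m : int
        Protons transferred (>= 0).
    n : int
        Electrons transferred (>= 1).
    """

    name: str
    e_ref_mV: float
    pH_ref: float
    m: int
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InvariantError(f"couple {self.name!r}: n must be >= 1")
        if self.m < 0:
            raise InvariantError(f"couple {self.name!r}: m must be >= 0")
        if not (abs(self.e_ref_mV) < float("inf")):
            raise InvariantError(f"couple {self.name!r}: e_ref_mV must be finite")


def nernst_slope_mV(T: float = T_DEFAULT) -> float:
    """2.303 R T / F in mV per pH unit (the m/n = 1 slope), ~59 at 298 K."""
    if T <= 0:
        raise InputError("temperature must be positive (kelvin)")
    return 2.303 * R * T / F * 1000.0


def adjust_midpoint(couple: RedoxCouple, pH_target: float,
                    T: float = T_DEFAULT) -> float:
    """Midpoint potential of ``couple`` at ``pH_target``, in mV."""
    slope = nernst_slope_mV(T)
    return couple.e_ref_mV - slope * (couple.m / couple.n) * (pH_target - couple.pH_ref)


def classify_mediator(e_adjusted_mV: float,
                      e_required_mV: float = E_REQUIRED_MV,
                      inclusive: bool = True) -> bool:
    """True when the adjusted potential can drive indigo reduction.

    A couple is feasible when its midpoint potential is at or below the
    required potential; the boundary (equal potentials) counts as
    feasible by default.
    """
    if inclusive:
        return bool(e_adjusted_mV <= e_required_mV)
    return bool(e_adjusted_mV < e_required_mV)


def read_couples(path) -> list[RedoxCouple]:
    """Read a couples TSV (name, e_ref_mV, pH_ref, m, n).

    Rows with any empty field are skipped (the shipped template leaves
    reference potentials to the user); at least one complete row is
    required.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("name", "e_ref_mV", "pH_ref", "m", "n"):
        if col not in table.columns:
            raise InputError(f"couples file missing column {col!r}")
    couples = []
    for _, row in table.iterrows():
        if row[["e_ref_mV", "pH_ref", "m", "n"]].isna().any():
            continue
        couples.append(
            RedoxCouple(str(row["name"]), float(row["e_ref_mV"]),
                        float(row["pH_ref"]), int(row["m"]), int(row["n"]))
        )
    if not couples:
        raise InputError(
            "no complete couples found; fill in e_ref_mV/pH_ref/m/n "
            "(reference potentials are not shipped with the package)"
        )
    return couples


def feasibility_table(couples: list[RedoxCouple], pH_target: float,
                      T: float = T_DEFAULT,
                      e_required_mV: float = E_REQUIRED_MV) -> pd.DataFrame:
    """Adjusted potentials and feasibility flags for a set of couples."""
    rows = []
    for c in couples:
        adj = adjust_midpoint(c, pH_target, T)
        rows.append(
            {
                "name": c.name,
                "e_ref_mV": c.e_ref_mV,
                "pH_ref": c.pH_ref,
                "m": c.m,
                "n": c.n,
                "pH_target": pH_target,
                "e_adjusted_mV": adj,
                "feasible": classify_mediator(adj, e_required_mV),
            }
        )
    return pd.DataFrame(rows).sort_values("name").reset_index(drop=True)
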