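"""MM/PBSA free-energy bookkeeping.

The binding free energy is decomposed additively:

    dG_total = dE_MM + dG_sol - T dS
    dE_MM    = dE_ele + dE_vdw
    dG_sol   = dG_polar + dG_np

with the nonpolar solvation term modelled linearly in solvent-accessible
surface area, dG_np = gamma * SASA + beta (defaults gamma = 0.0054
kcal/mol/A^2, beta = 0.92 kcal/mol). The entropy term T dS is an input
constant, 0 by default (entropy estimation is noisy and commonly omitted
for comparisons within one receptor-ligand series). This module only does
the arithmetic over per-residue component tables exported from an MD
package; it computes no energies from structures. All energies are
kcal/mol; SASA is Angstrom^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

DEFAULT_GAMMA = 0.0054  # kcal/mol/A^2
DEFAULT_BETA = 0.92     # kcal/mol


def nonpolar(
    sasa: Union[float, np.ndarray],
    gamma: float = DEFAULT_GAMMA,
    beta: float = DEFAULT_BETA,
) -> Union[float, np.ndarray]:
    """Nonpolar solvation free energy: G_np = gamma * SASA + beta."""
    arr = np.asarray(sasa, dtype=float)
    if np.any(arr < 0):
        raise ValueError("SASA must be non-negative")
    out = gamma * arr + beta
    return float(out) if np.isscalar(sasa) or arr.ndim == 0 else out


@dataclass(frozen=True)
class EnergyComponents:
    """Per-residue MM/PBSA components plus global constants.

    ``table`` needs columns residue, E_ele, E_vdw, G_polar and exactly one
    of G_np or SASA (the other is derived).
    """

    table: pd.DataFrame
    gamma: float = DEFAULT_GAMMA
    beta: float = DEFAULT_BETA
    tds: float = 0.0

    def __post_init__(self) -> None:
        required = {"residue", "E_ele", "E_vdw", "G_polar"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing component columns: {sorted(missing)}")
        has_np = "G_np" in self.table.columns
        has_sasa = "SASA" in self.table.columns
        if has_np == has_sasa:
            raise ValueError("provide exactly one of G_np or SASA")
        if has_sasa and (self.table["SASA"] < 0).any():
            raise ValueError("SASA must be non-negative")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "EnergyComponents":
        return cls(table=pd.read_csv(path, sep="\t"), **kwargs)


def combine(components: EnergyComponents) -> pd.DataFrame:
    """Per-residue decomposition rows plus a TOTAL row.

    E_MM = E_ele + E_vdw; G_sol = G_polar + G_np;
    G_total = E_MM + G_sol - TdS. The TdS constant is applied to each row
    (and hence once to the TOTAL row via summation of the components).
    """
    t = components.table
    g_np = (
        t["G_np"].to_numpy(dtype=float)
        if "G_np" in t.columns
        else nonpolar(t["SASA"].to_numpy(dtype=float), components.gamma, components.beta)
    )
    e_mm = t["E_ele"].to_numpy(dtype=float) + t["E_vdw"].to_numpy(dtype=float)
    g_polar = t["G_polar"].to_numpy(dtype=float)
    g_total = e_mm + g_polar + g_np - components.tds
    out = pd.DataFrame(
        {
            "residue": t["residue"],
            "E_MM": e_mm,
            "G_polar": g_polar,
            "G_np": g_np,
            "G_total": g_total,
        }
    )
    total = pd.DataFrame(
        {
            "residue": ["TOTAL"],
            "E_MM": [e_mm.sum()],
            "G_polar": [g_polar.sum()],
            "G_np": [g_np.sum()],
            "G_total": [e_mm.sum() + g_polar.sum() + g_np.sum() - components.tds],
        }
    )
    return pd.concat([out, total], ignore_index=True)


def favorability(rows: pd.DataFrame) -> pd.DataFrame:
    """Flag each residue row: favorable iff G_total < 0 (ties unfavorable)."""
    out = rows.copy()
    out["favorable"] = out["G_total"] < 0
    return out
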