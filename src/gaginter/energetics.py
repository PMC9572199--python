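"""Binding-energy accounting for receptor-ligand complexes.

The decomposition balances the potential and solvation energies of the
separated solutes against those of the complex:

    Ebind = Epr + Epl + Esr + Esl - Epc - Esc

where ``Ep*`` are potential energies and ``Es*`` solvation energies of the
receptor (r), ligand (l) and complex (c). The reported quantity is the
energy of binding EoB = -Ebind (negative = favorable; more negative =
stronger). Solvation energies follow the exposed-surface convention:
SASA x 0.65 kJ/(mol Å²) by default. Because the solvation cost shifts EoB
by a receptor-dependent constant, EoB is meaningful only comparatively;
reports always carry the cost parameter used.

Component potential energies are ingested from per-frame tables (they come
from whatever engine produced the trajectory); this module's contribution is
the accounting, windowed averaging (mean ± doubled population STD over the
equilibration window) and the ranking of complexes by mean EoB.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnalysisParams, FormatError, MolecularSystem
from .interactions import window_stats

__all__ = [
    "EnergyTerms",
    "BindingEnergySeries",
    "binding_energy",
    "read_energy_table",
    "series_from_table",
    "window_average",
    "sasa",
    "solvation_energy",
    "rank_complexes",
    "isomer_contrast",
    "ELEMENT_RADII",
    "REFERENCE_RANKING_CS6",
    "REFERENCE_RANKING_CS4",
]

#: Van der Waals radii (Å) for SASA; config-overridable.
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "Na": 2.27, "Mg": 1.73, "Ca": 2.31, "Cl": 1.75,
}

ENERGY_COLUMNS = ("time_ps", "Epr", "Epl", "Esr", "Esl", "Epc", "Esc")


@dataclass(frozen=True)
class EnergyTerms:
    """The six components of the binding-energy decomposition (kJ/mol)."""

    Epr: float  # potential energy, separated receptor
    Epl: float  # potential energy, separated ligand
    Esr: float  # solvation energy, separated receptor
    Esl: float  # solvation energy, separated ligand
    Epc: float  # potential energy, complex
    Esc: float  # solvation energy, complex

    def __post_init__(self):
        for name in ("Epr", "Epl", "Esr", "Esl", "Epc", "Esc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def binding_energy(terms: EnergyTerms) -> tuple[float, float]:
    """(Ebind, EoB) from one set of components.

    Ebind = Epr + Epl + Esr + Esl - Epc - Esc; EoB = -Ebind. A lower
    (more negative) EoB means stronger binding.
    """
    ebind = (terms.Epr + terms.Epl + terms.Esr + terms.Esl
             - terms.Epc - terms.Esc)
    return ebind, -ebind


def read_energy_table(path) -> pd.DataFrame:
    """Read a per-frame component-energy TSV (time_ps + the six components)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(ENERGY_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"energy table missing columns {sorted(missing)}")
    return table


@dataclass
class BindingEnergySeries:
    """Per-frame EoB (kJ/mol) with its time axis, plus window statistics."""

    times: np.ndarray
    eob: np.ndarray
    solvation_cost: float = 0.65

    def window_stats(self, params: AnalysisParams) -> dict:
        return window_stats(self.eob, self.times, params)


def series_from_table(table: pd.DataFrame,
                      solvation_cost: float = 0.65) -> BindingEnergySeries:
    """Frame-wise EoB series from a component table."""
    missing = set(ENERGY_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"energy table missing columns {sorted(missing)}")
    ebind = (table["Epr"] + table["Epl"] + table["Esr"] + table["Esl"]
             - table["Epc"] - table["Esc"]).to_numpy(float)
    return BindingEnergySeries(
        times=table["time_ps"].to_numpy(float), eob=-ebind,
        solvation_cost=solvation_cost,
    )


def window_average(series: BindingEnergySeries,
                   params: AnalysisParams | None = None) -> dict:
    """Windowed mean ± doubled population STD of the EoB series."""
    params = params or AnalysisParams()
    return series.window_stats(params)


# ---------------------------------------------------------------------------
# SASA and solvation
# ---------------------------------------------------------------------------

def sasa(
    system: MolecularSystem,
    coords: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    atom_indices=None,
) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area (Å²), Shrake-Rupley.

    Radii come from :data:`ELEMENT_RADII` unless overridden. Restricting to
    ``atom_indices`` computes the SASA of that sub-structure in isolation
    (e.g. the separated receptor for the solvation terms).
    """
    import biotite.structure as struc

    radii = dict(ELEMENT_RADII if radii is None else radii)
    coords = system.coords if coords is None else np.asarray(coords, float)
    if atom_indices is None:
        atom_indices = np.arange(system.n_atoms)
    atom_indices = np.asarray(atom_indices, int)
    try:
        radius_arr = np.asarray(
            [radii[str(system.elements[i])] for i in atom_indices], float
        )
    except KeyError as exc:
        raise LookupError(f"no SASA radius for element {exc}") from exc

    n = len(atom_indices)
    array = struc.AtomArray(n)
    array.coord = coords[atom_indices].astype(np.float32)
    array.element = np.asarray(
        [str(system.elements[i]).upper() for i in atom_indices], dtype="U2"
    )
    array.atom_name = np.asarray(
        [str(system.names[i]) for i in atom_indices], dtype="U6"
    )
    array.res_name = np.asarray(
        [str(system.residue_names[i]) for i in atom_indices], dtype="U5"
    )
    array.res_id = system.residue_indices[atom_indices]
    array.chain_id = np.asarray(
        [str(system.chain_ids[i]) for i in atom_indices], dtype="U4"
    )
    per_atom = struc.sasa(
        array,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii=radius_arr,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(np.asarray(per_atom, float))
    return per_atom, float(per_atom.sum())


def solvation_energy(sasa_total: float, cost: float = 0.65) -> float:
    """Solvation energy (kJ/mol) = exposed area x cost per Å² (default 0.65)."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return sasa_total * cost


# ---------------------------------------------------------------------------
# Ranking and the isomer contrast
# ---------------------------------------------------------------------------

def rank_complexes(
    solution_means: pd.DataFrame | dict,
    docking_ranks: dict | None = None,
    stds: dict | None = None,
    binding_sites: dict | None = None,
) -> pd.DataFrame:
    """Rank complexes by cross-solution mean EoB (most negative first).

    ``solution_means`` maps complex id -> one mean EoB per ionic solution
    (list/array, or a DataFrame with complexes as columns); the per-complex
    value is the mean over its solutions. Ties keep the input order (stable
    sort by id). Missing docking ranks are reported as <NA> and do not
    affect the ordering.
    """
    if isinstance(solution_means, pd.DataFrame):
        solution_means = {c: solution_means[c].dropna().to_numpy()
                          for c in solution_means.columns}
    rows = []
    for cid, values in solution_means.items():
        values = np.atleast_1d(np.asarray(values, float))
        if values.size == 0:
            raise ValueError(f"complex {cid!r} has no solution means")
        rows.append({
            "complex_id": cid,
            "mean_eob": float(values.mean()),
            "doubled_std": (
                np.nan if stds is None else float(stds.get(cid, np.nan))
            ),
            "docking_rank": (
                None if docking_ranks is None else docking_ranks.get(cid)
            ),
            "binding_sites": (
                "" if binding_sites is None else binding_sites.get(cid, "")
            ),
        })
    table = pd.DataFrame(rows)
    table = table.sort_values(
        "mean_eob", kind="stable", ascending=True
    ).reset_index(drop=True)
    table.insert(0, "md_rank", np.arange(1, len(table) + 1))
    table["docking_rank"] = table["docking_rank"].astype("Int64")
    return table


def isomer_contrast(rank_table_cs4: pd.DataFrame,
                    rank_table_cs6: pd.DataFrame) -> float:
    """Percent binding-strength difference between the CS-4 and CS-6 isomers.

    100 x (|grand mean CS4| - |grand mean CS6|) / |grand mean CS4|, where
    each grand mean averages the per-complex mean EoB column of the rank
    table. Positive = CS-4 bound stronger.
    """
    if len(rank_table_cs4) == 0 or len(rank_table_cs6) == 0:
        raise ValueError("rank tables must be non-empty")
    m4 = abs(float(rank_table_cs4["mean_eob"].mean()))
    m6 = abs(float(rank_table_cs6["mean_eob"].mean()))
    if m4 == 0:
        raise ZeroDivisionError("CS-4 grand mean is zero; contrast undefined")
    return 100.0 * (m4 - m6) / m4


# ---------------------------------------------------------------------------
# Reference ranking tables (HSA:CS complexes, EoB averaged over the
# equilibrated window and over the three ionic solutions)
# ---------------------------------------------------------------------------

def _reference(rows) -> pd.DataFrame:
    table = pd.DataFrame(
        rows, columns=["complex_id", "mean_eob", "std", "docking_rank",
                       "binding_sites", "strongest_site"]
    )
    table.insert(0, "md_rank", np.arange(1, len(table) + 1))
    table["doubled_std"] = 2.0 * table.pop("std")
    return table


#: Ten HSA:CS-6 complexes: per-complex mean EoB (kJ/mol) ± STD, the rank the
#: same complex had after docking, and the receptor subdomains it contacts
#: (strongest site listed separately).
REFERENCE_RANKING_CS6 = _reference([
    ("cs6_c1", -2522.0, 339.0, 2, "IA-IB-IIA-IIIA-IIIB", "IIIA"),
    ("cs6_c2", -2133.0, 301.0, 6, "IB-IIIA-IIIB", "IIIB"),
    ("cs6_c3", -1694.0, 665.0, 9, "IB-IIIA-IIIB", "IIIB"),
    ("cs6_c4", -1670.0, 388.0, 7, "IA-IIA-IIB-IIIA", "IA"),
    ("cs6_c5", -1628.0, 792.0, 1, "IA-IIA-IIIA-IIIB", "IIIB"),
    ("cs6_c6", -1542.0, 665.0, 5, "IA-IIA-IIIA-IIIB", "IIIB"),
    ("cs6_c7", -1498.0, 399.0, 4, "IA-IIA-IIIA-IIIB", "IIIB"),
    ("cs6_c8", -1472.0, 675.0, 3, "IA-IIA", "IIA"),
    ("cs6_c9", -1363.0, 550.0, 10, "IIA-IIB", "IIB"),
    ("cs6_c10", -1033.0, 453.0, 8, "IA-IB", "IA"),
])

REFERENCE_RANKING_CS4 = _reference([
    ("cs4_c1", -2755.0, 624.0, 3, "IB-IIIA-IIIB", "IIIB"),
    ("cs4_c2", -2737.0, 386.0, 9, "IB-IIA-IIIA-IIIB", "IIIA"),
    ("cs4_c3", -2194.0, 702.0, 8, "IA-IB-IIA", "IIA"),
    ("cs4_c4", -1906.0, 556.0, 10, "IA-IB-IIA-IIIA", "IA"),
    ("cs4_c5", -1904.0, 441.0, 4, "IA-IB-IIA-IIB", "IIA"),
    ("cs4_c6", -1641.0, 659.0, 5, "IB-IIA-IIB-IIIA-IIIB", "IIIA"),
    ("cs4_c7", -1639.0, 374.0, 7, "IA-IB-IIA-IIIA-IIIB", "IA"),
    ("cs4_c8", -1637.0, 674.0, 2, "IA-IB-IIIA-IIIB", "IB"),
    ("cs4_c9", -1613.0, 531.0, 1, "IB-IIA-IIIA-IIIB", "IIIB"),
    ("cs4_c10", -1516.0, 493.0, 6, "IB-IIIA-IIIB", "IIIB"),
])
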