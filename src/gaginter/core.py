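"""Core domain model for protein-glycosaminoglycan trajectory analysis.

This module defines the in-memory containers every analysis stage consumes
(:class:`MolecularSystem`, :class:`Trajectory`), the annotation schemes of the
human serum albumin (HSA) / chondroitin sulfate (CS) system — receptor
subdomain ranges, ligand mer grouping, oxygen-class labels, formal charge
groups, hydrophobicity flags — and multi-model PDB input/output.

Conventions
-----------
* Residue numbering is 1-based, PDB style; domain ranges are inclusive on
  both ends.
* Every atom belongs to exactly one of five partitions: ``receptor``,
  ``ligand``, ``water``, ``cation``, ``anion``.
* Coordinates are in Å, times in ps, energies in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PARTITIONS",
    "GagInterError",
    "StructureParseError",
    "ClassificationError",
    "GenerationError",
    "WindowError",
    "GeometryError",
    "ConfigError",
    "FormatError",
    "Atom",
    "ChargeGroup",
    "MolecularSystem",
    "Trajectory",
    "DomainScheme",
    "MerGroupScheme",
    "AnalysisParams",
    "DEFAULT_PARTITION_RULES",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "assign_domain",
    "assign_mer_group",
]

PARTITIONS = ("receptor", "ligand", "water", "cation", "anion")

#: Elements accepted in the cation / anion partitions.
CATION_ELEMENTS = ("Na", "Ca", "Mg")
ANION_ELEMENTS = ("Cl",)

#: Covalent radii (Å) used for distance-based bond perception on input files.
COVALENT_RADII = {"H": 0.31, "C": 0.77, "N": 0.71, "O": 0.66, "S": 1.04}
BOND_TOLERANCE = 0.45  # slack added to the covalent-radius sum

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS = tuple(THREE_TO_ONE)

#: Sugar residue codes used by the fixture ligand: glucuronic acid and
#: N-acetylgalactosamine.
SUGAR_RESIDUES = ("GCU", "NGA")

WATER_RESIDUES = ("HOH", "WAT", "TIP", "SOL")

DEFAULT_PARTITION_RULES: dict[str, str] = {
    **{name: "receptor" for name in AMINO_ACIDS},
    **{name: "ligand" for name in SUGAR_RESIDUES},
    **{name: "water" for name in WATER_RESIDUES},
    "NA": "cation", "CA": "cation", "MG": "cation",
    "CL": "anion",
}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GagInterError(Exception):
    """Base class for all package errors."""


class StructureParseError(GagInterError):
    """A structure file could not be parsed (carries the offending line)."""


class ClassificationError(GagInterError):
    """An atom could not be assigned to a partition or annotation."""


class GenerationError(GagInterError):
    """Synthetic-fixture generation failed (e.g. infeasible placement)."""


class WindowError(GagInterError):
    """An analysis window selects no frames."""


class GeometryError(GagInterError):
    """A geometric operation received degenerate input."""


class ConfigError(GagInterError):
    """Invalid pipeline or parameter configuration."""


class FormatError(GagInterError):
    """A tabular input file is missing required columns."""


# ---------------------------------------------------------------------------
# Atom / charge group / system / trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom view into a :class:`MolecularSystem`."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: np.ndarray
    partial_charge: float | None = None
    is_hydrophobic: bool = False
    charge_group_id: int | None = None
    oxygen_class: str | None = None

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


@dataclass(frozen=True)
class ChargeGroup:
    """A formal-charge group (guanidinium, carboxylate, sulfate, ion, ...).

    ``representative`` is the heavy atom whose element names the group in
    bridge class labels (carboxylate -> its carbon, sulfate -> its sulfur,
    hydroxyl/ring oxygen -> the oxygen, monatomic ion -> itself).
    """

    gid: int
    label: str
    formal_charge: int
    members: tuple[int, ...]
    representative: int

    def center(self, coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
        """Mean position of the heavy (non-H) member atoms."""
        heavy = [i for i in self.members if elements[i] != "H"]
        return coords[np.asarray(heavy)].mean(axis=0)


class MolecularSystem:
    """Annotated collection of atoms: one receptor, one ligand, solvent, ions.

    Internally array-of-columns for speed; :meth:`atom` reconstructs the
    per-atom :class:`Atom` view.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        partitions: Sequence[str],
        bonds: Iterable[tuple[int, int]] = (),
        partial_charges: Sequence[float] | None = None,
        metadata: dict | None = None,
    ):
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.partitions = np.asarray(partitions, dtype=object)
        self.bonds = sorted({tuple(sorted(map(int, b))) for b in bonds})
        self.partial_charges = (
            None if partial_charges is None else np.asarray(partial_charges, float)
        )
        self.metadata = dict(metadata or {})
        self.is_hydrophobic = np.zeros(n, dtype=bool)
        self.oxygen_class = np.full(n, None, dtype=object)
        self.charge_groups: list[ChargeGroup] = []
        self.charge_group_of = np.full(n, -1, dtype=int)
        self._validate()

    # -- construction / validation ------------------------------------------------

    def _validate(self) -> None:
        n = self.n_atoms
        for arr in (self.names, self.elements, self.residue_names,
                    self.residue_indices, self.chain_ids, self.partitions):
            if len(arr) != n:
                raise ValueError("inconsistent column lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.residue_indices < 1):
            raise ValueError("residue indices must be >= 1")
        bad = set(self.partitions) - set(PARTITIONS)
        if bad:
            raise ClassificationError(f"unknown partitions: {sorted(bad)}")
        for part, allowed in (("cation", CATION_ELEMENTS), ("anion", ANION_ELEMENTS)):
            elems = set(self.elements[self.partitions == part])
            extra = elems - set(allowed)
            if extra:
                raise ClassificationError(
                    f"{part} partition contains disallowed elements {sorted(extra)}"
                )
        self._check_water_triplets()

    def _check_water_triplets(self) -> None:
        mask = self.partitions == "water"
        if not mask.any():
            return
        for (chain, resid), idx in self._group_residues(np.where(mask)[0]).items():
            elems = sorted(self.elements[i] for i in idx)
            if elems != ["H", "H", "O"]:
                raise ClassificationError(
                    f"water residue {chain}:{resid} is not an O-H-H triplet ({elems})"
                )

    def _group_residues(self, indices: np.ndarray) -> dict:
        groups: dict[tuple[str, int], list[int]] = {}
        for i in indices:
            groups.setdefault(
                (self.chain_ids[i], int(self.residue_indices[i])), []
            ).append(int(i))
        return groups

    # -- basic accessors ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> Atom:
        gid = int(self.charge_group_of[i])
        return Atom(
            index=int(i),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_index=int(self.residue_indices[i]),
            chain_id=str(self.chain_ids[i]),
            coords=self.coords[i].copy(),
            partial_charge=(
                None if self.partial_charges is None else float(self.partial_charges[i])
            ),
            is_hydrophobic=bool(self.is_hydrophobic[i]),
            charge_group_id=None if gid < 0 else gid,
            oxygen_class=self.oxygen_class[i],
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def partition_indices(self, *parts: str) -> np.ndarray:
        """Atom indices belonging to any of the named partitions."""
        mask = np.isin(self.partitions, list(parts))
        return np.where(mask)[0]

    @property
    def adjacency(self) -> dict[int, list[int]]:
        cached = getattr(self, "_adjacency_cache", None)
        if cached is None:
            adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
            for a, b in self.bonds:
                adj[a].append(b)
                adj[b].append(a)
            cached = self._adjacency_cache = adj
        return cached

    def heavy_neighbors(self, i: int) -> list[int]:
        return [j for j in self.adjacency[i] if self.elements[j] != "H"]

    def water_residues(self) -> list[tuple[int, list[int]]]:
        """(oxygen index, [member indices]) per water molecule."""
        cached = getattr(self, "_water_cache", None)
        if cached is None:
            cached = []
            mask = self.partitions == "water"
            for _, idx in self._group_residues(np.where(mask)[0]).items():
                oxy = [i for i in idx if self.elements[i] == "O"][0]
                cached.append((oxy, idx))
            self._water_cache = cached
        return cached

    # -- annotations --------------------------------------------------------------

    def annotate(self, protonated_his: bool = False) -> "MolecularSystem":
        """Assign hydrophobic flags, oxygen classes and charge groups in place."""
        self._assign_hydrophobic()
        self._assign_oxygen_classes()
        self._assign_charge_groups(protonated_his)
        return self

    def _assign_hydrophobic(self) -> None:
        # An atom is hydrophobic when it is C or S and every bonded heavy
        # neighbor is C or S. A neighborless carbon satisfies this vacuously.
        adj = self.adjacency
        for i in range(self.n_atoms):
            if self.elements[i] not in ("C", "S"):
                continue
            if self.partitions[i] not in ("receptor", "ligand"):
                continue
            heavies = [j for j in adj[i] if self.elements[j] != "H"]
            self.is_hydrophobic[i] = all(
                self.elements[j] in ("C", "S") for j in heavies
            )

    def _assign_oxygen_classes(self) -> None:
        """Ligand oxygen classes derived from atom names (PDB-roundtrippable)."""
        for i in self.partition_indices("ligand"):
            if self.elements[i] != "O":
                continue
            self.oxygen_class[i] = _oxygen_class_from_name(str(self.names[i]))

    def _assign_charge_groups(self, protonated_his: bool) -> None:
        self.charge_groups = []
        self.charge_group_of[:] = -1
        gid = 0

        def add(label: str, charge: int, members: list[int], rep: int) -> None:
            nonlocal gid
            group = ChargeGroup(gid, label, charge, tuple(members), rep)
            self.charge_groups.append(group)
            for m in members:
                self.charge_group_of[m] = gid
            gid += 1

        # receptor side-chain and terminal groups
        rec = self.partition_indices("receptor")
        residues = self._group_residues(rec)
        keys = sorted(residues, key=lambda k: (k[0], k[1]))
        for pos, key in enumerate(keys):
            idx = residues[key]
            resname = str(self.residue_names[idx[0]])
            by_name = {str(self.names[i]): i for i in idx}
            if resname == "ARG" and "CZ" in by_name:
                members = [by_name[n] for n in ("CZ", "NH1", "NH2", "NE") if n in by_name]
                add("guanidinium", +1, members, by_name["CZ"])
            elif resname == "LYS" and "NZ" in by_name:
                add("ammonium", +1, [by_name["NZ"]], by_name["NZ"])
            elif resname == "HIS" and protonated_his and "NE2" in by_name:
                add("imidazolium", +1, [by_name["NE2"]], by_name["NE2"])
            elif resname == "ASP" and "CG" in by_name:
                members = [by_name[n] for n in ("CG", "OD1", "OD2") if n in by_name]
                add("carboxylate", -1, members, by_name["CG"])
            elif resname == "GLU" and "CD" in by_name:
                members = [by_name[n] for n in ("CD", "OE1", "OE2") if n in by_name]
                add("carboxylate", -1, members, by_name["CD"])
            if pos == 0 and "N" in by_name:
                add("n_terminus", +1, [by_name["N"]], by_name["N"])
            if pos == len(keys) - 1 and "C" in by_name and "O" in by_name:
                add("c_terminus", -1, [by_name["C"], by_name["O"]], by_name["C"])

        # ligand sulfates and carboxylates
        lig = self.partition_indices("ligand")
        for _, idx in self._group_residues(lig).items():
            by_name = {str(self.names[i]): i for i in idx}
            if "S" in by_name:
                members = [by_name["S"]] + [
                    by_name[n] for n in ("OS1", "OS2", "OS3") if n in by_name
                ]
                add("SO4-", -1, members, by_name["S"])
            if "C6" in by_name and "O61" in by_name:
                members = [by_name[n] for n in ("C6", "O61", "O62") if n in by_name]
                add("COO-", -1, members, by_name["C6"])

        # monatomic ions
        for i in self.partition_indices("cation"):
            charge = +1 if self.elements[i] == "Na" else +2
            add(f"{self.elements[i]}+", charge, [int(i)], int(i))
        for i in self.partition_indices("anion"):
            add(f"{self.elements[i]}-", -1, [int(i)], int(i))

    def charge_groups_in(self, *parts: str) -> list[ChargeGroup]:
        out = []
        for g in self.charge_groups:
            if self.partitions[g.members[0]] in parts:
                out.append(g)
        return out

    # -- donors / acceptors -------------------------------------------------------

    def donors(self, indices: np.ndarray) -> list[tuple[int, int]]:
        """(heavy donor, hydrogen) pairs among ``indices``: N/O bonded to H."""
        sel = set(int(i) for i in indices)
        adj = self.adjacency
        pairs = []
        for i in sorted(sel):
            if self.elements[i] not in ("N", "O"):
                continue
            for j in adj[i]:
                if self.elements[j] == "H":
                    pairs.append((i, j))
        return pairs

    def acceptors(self, indices: np.ndarray) -> list[int]:
        """N and O atoms among ``indices`` (treated as lone-pair carriers)."""
        return [int(i) for i in indices if self.elements[i] in ("N", "O")]


def _oxygen_class_from_name(name: str) -> str:
    if name.startswith("OS"):
        return "SO4-"
    if name in ("O61", "O62"):
        return "COO-"
    if name in ("O4S", "O6S", "O3", "O13", "O14", "O7"):
        return name
    if name == "O5":
        return "O"
    return "other"


@dataclass
class Trajectory:
    """Ordered frames of coordinates over one :class:`MolecularSystem`.

    ``times`` are in ps and strictly increasing; each frame is an
    ``(n_atoms, 3)`` array in Å.
    """

    system: MolecularSystem
    times: np.ndarray
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != len(self.times):
            raise ValueError("times and frames disagree in length")
        if self.frames.shape[1] != self.system.n_atoms:
            raise ValueError("frame atom count differs from system")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def window_mask(self, t_min: float, t_max: float) -> np.ndarray:
        """Frames with t_min < time <= t_max (strict lower bound)."""
        return (self.times > t_min) & (self.times <= t_max)


# ---------------------------------------------------------------------------
# Annotation schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainScheme:
    """Receptor subdomain partition: named inclusive 1-based residue ranges.

    The HSA defaults split the 585-residue chain into subdomains
    IA 5-107, IB 108-197, IIA 198-296, IIB 297-382, IIIA 383-494,
    IIIB 495-569; residues outside 5-569 are "unassigned".
    """

    subdomains: tuple[tuple[str, int, int], ...] = (
        ("IA", 5, 107), ("IB", 108, 197),
        ("IIA", 198, 296), ("IIB", 297, 382),
        ("IIIA", 383, 494), ("IIIB", 495, 569),
    )

    def __post_init__(self) -> None:
        ranges = [(lo, hi) for _, lo, hi in self.subdomains]
        for (lo, hi) in ranges:
            if lo > hi:
                raise ValueError("empty subdomain range")
        flat = sorted(ranges)
        for (a, b), (c, d) in zip(flat, flat[1:]):
            if c <= b:
                raise ValueError("overlapping subdomain ranges")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.subdomains)

    @property
    def domains(self) -> dict[str, tuple[int, int]]:
        """Parent domains: union of the A/B subdomain pairs."""
        out: dict[str, tuple[int, int]] = {}
        for name, lo, hi in self.subdomains:
            parent = name[:-1]
            if parent in out:
                plo, phi = out[parent]
                out[parent] = (min(plo, lo), max(phi, hi))
            else:
                out[parent] = (lo, hi)
        return out

    def scaled(self, n_residues: int, reference_length: int = 585) -> "DomainScheme":
        """Proportionally rescale the ranges to a chain of ``n_residues``."""
        if n_residues == reference_length:
            return self
        f = n_residues / reference_length
        breaks = [lo for _, lo, _ in self.subdomains] + [self.subdomains[-1][2] + 1]
        scaled = [max(1, round(b * f)) for b in breaks]
        for k in range(1, len(scaled)):  # keep strictly increasing
            scaled[k] = max(scaled[k], scaled[k - 1] + 1)
        subs = tuple(
            (name, scaled[k], scaled[k + 1] - 1)
            for k, (name, _, _) in enumerate(self.subdomains)
        )
        return DomainScheme(subs)


def assign_domain(residue_index: int, scheme: DomainScheme | None = None) -> str:
    """Subdomain label containing ``residue_index``, else ``"unassigned"``."""
    if residue_index < 1:
        raise ValueError("residue_index must be >= 1")
    scheme = scheme or DomainScheme()
    for name, lo, hi in scheme.subdomains:
        if lo <= residue_index <= hi:
            return name
    return "unassigned"


@dataclass(frozen=True)
class MerGroupScheme:
    """Grouping of ligand mers into consecutive triples (24 mers -> 8 groups)."""

    n_mers: int = 24
    group_size: int = 3

    def __post_init__(self) -> None:
        if self.n_mers % self.group_size != 0:
            raise ValueError("group_size must divide n_mers")

    @property
    def n_groups(self) -> int:
        return self.n_mers // self.group_size

    def groups(self) -> dict[int, list[int]]:
        return {
            g: list(range((g - 1) * self.group_size + 1, g * self.group_size + 1))
            for g in range(1, self.n_groups + 1)
        }


def assign_mer_group(mer_index: int, scheme: MerGroupScheme | None = None) -> int:
    """Group index (1-based) of a ligand mer: ceil(mer / group_size)."""
    scheme = scheme or MerGroupScheme()
    if not 1 <= mer_index <= scheme.n_mers:
        raise ValueError(
            f"mer index {mer_index} outside 1..{scheme.n_mers}"
        )
    return math.ceil(mer_index / scheme.group_size)


# ---------------------------------------------------------------------------
# Analysis parameters
# ---------------------------------------------------------------------------

@dataclass
class AnalysisParams:
    """Tunable thresholds shared by all analysis stages.

    The hydrogen-bond (HBo) energy model peaks at ``hbond_optimum_energy``
    (25 kJ/mol) and a bond is counted when its energy reaches
    ``hbond_threshold_fraction`` (25%) of that optimum, i.e. 6.25 kJ/mol by
    default. Distance cutoffs for hydrophobic (HP) and ionic contacts, the
    SASA probe and solvation cost, and the equilibration window bounds are
    all config-exposed here.
    """

    hbond_optimum_energy: float = 25.0        # kJ/mol
    hbond_threshold_fraction: float = 0.25
    hbond_threshold: float | None = None      # kJ/mol; derived if None
    hbond_ramp_inner: float = 2.1             # Å, plateau end of the H...A ramp
    hbond_ramp_outer: float = 2.6             # Å, energy reaches zero here
    hbond_angle_min: float = 100.0            # deg, angular gate
    hp_cutoff: float = 4.5                    # Å, heavy-atom centers
    ionic_cutoff: float = 5.0                 # Å, charge-group centers
    sasa_probe_radius: float = 1.4            # Å
    sasa_n_points: int = 960
    sasa_cost: float = 0.65                   # kJ/(mol Å^2)
    equilibration_time: float = 40000.0       # ps
    window_end: float = 140000.0              # ps
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hbond_threshold is None:
            self.hbond_threshold = (
                self.hbond_threshold_fraction * self.hbond_optimum_energy
            )
        if self.hbond_threshold > self.hbond_optimum_energy:
            raise ValueError("hbond_threshold must not exceed the optimum")
        if min(self.hp_cutoff, self.ionic_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if not self.equilibration_time < self.window_end:
            raise ValueError("equilibration_time must precede window_end")
        if not 0 < self.hbond_ramp_inner < self.hbond_ramp_outer:
            raise ValueError("invalid HBo ramp bounds")

    def replace(self, **kw) -> "AnalysisParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Structure / trajectory I/O (PDB via biotite)
# ---------------------------------------------------------------------------

def _load_pdb(path):
    from biotite.structure.io.pdb import PDBFile

    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite read rarely fails
        raise StructureParseError(f"{path}: {exc}") from exc


def _stack_from_pdb(pdb_file, path):
    try:
        return pdb_file.get_structure()
    except Exception as exc:
        raise StructureParseError(
            f"{path}: {_locate_bad_line(path)}"
        ) from exc


def _locate_bad_line(path) -> str:
    """Best-effort pinpointing of a malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                return f"malformed coordinate record at line {lineno}"
    return "unparseable PDB content"


def _classify(residue_names, rules, fallback):
    parts = []
    for name in residue_names:
        part = rules.get(str(name).strip().upper())
        if part is None:
            part = fallback
        if part is None:
            raise ClassificationError(
                f"residue name {name!r} has no partition rule and no fallback"
            )
        parts.append(part)
    return parts


def _system_from_array(array, rules, fallback, infer_bonds=True) -> MolecularSystem:
    names = [str(n) for n in array.atom_name]
    elements = [str(e).capitalize() for e in array.element]
    res_names = [str(r) for r in array.res_name]
    res_ids = array.res_id.astype(int)
    chains = [str(c) for c in array.chain_id]
    coords = np.asarray(array.coord, dtype=float)
    parts = _classify(res_names, rules, fallback)
    bonds = (
        _infer_bonds(elements, res_ids, chains, coords, parts) if infer_bonds else ()
    )
    system = MolecularSystem(
        names, elements, res_names, res_ids, chains, coords, parts, bonds
    )
    return system.annotate()


def _infer_bonds(elements, res_ids, chains, coords, parts):
    """Distance-based bond perception restricted to same/adjacent residues.

    Ions are never bonded. The residue restriction keeps atoms that a
    synthetic fixture placed next to a foreign molecule from acquiring
    spurious covalent bonds on re-read.
    """
    n = len(elements)
    bondable = [
        i for i in range(n)
        if parts[i] in ("receptor", "ligand", "water") and elements[i] in COVALENT_RADII
    ]
    if not bondable:
        return []
    sub = np.asarray(bondable)
    tree = cKDTree(coords[sub])
    max_r = 2 * max(COVALENT_RADII.values()) + BOND_TOLERANCE
    bonds = []
    for ii, jj in tree.query_pairs(max_r):
        i, j = int(sub[ii]), int(sub[jj])
        if chains[i] != chains[j]:
            continue
        if abs(int(res_ids[i]) - int(res_ids[j])) > 1:
            continue
        if elements[i] == "H" and elements[j] == "H":
            continue
        limit = COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]] + BOND_TOLERANCE
        if np.linalg.norm(coords[i] - coords[j]) <= limit:
            bonds.append((i, j))
    # each H keeps only its nearest heavy partner
    by_h: dict[int, tuple[float, tuple[int, int]]] = {}
    out = []
    for i, j in bonds:
        h = i if elements[i] == "H" else (j if elements[j] == "H" else None)
        if h is None:
            out.append((i, j))
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if h not in by_h or d < by_h[h][0]:
            by_h[h] = (d, (i, j))
    out.extend(b for _, b in by_h.values())
    return out


def read_structure(
    path,
    partition_rules: Mapping[str, str] | None = None,
    fallback: str | None = None,
) -> MolecularSystem:
    """Read a (single- or multi-model) PDB file into an annotated system.

    ``partition_rules`` maps upper-case residue names to partition labels;
    the defaults cover amino acids, the fixture sugar codes, waters and the
    Na/Ca/Mg/Cl ions. Unknown residue names raise
    :class:`ClassificationError` unless ``fallback`` names a partition.
    For multi-model files the first model supplies the coordinates.
    """
    rules = dict(DEFAULT_PARTITION_RULES if partition_rules is None else partition_rules)
    pdb_file = _load_pdb(path)
    stack = _stack_from_pdb(pdb_file, path)
    array = stack[0] if stack.stack_depth() >= 1 else stack
    return _system_from_array(array, rules, fallback)


def read_trajectory(
    path,
    partition_rules: Mapping[str, str] | None = None,
    fallback: str | None = None,
    frame_interval_ps: float = 100.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    PDB carries no time axis, so times default to ``frame_interval_ps``
    spacing starting at ``frame_interval_ps`` (the save-point convention of a
    stored-state schedule: frame k holds the state at (k+1)*interval).
    """
    rules = dict(DEFAULT_PARTITION_RULES if partition_rules is None else partition_rules)
    pdb_file = _load_pdb(path)
    stack = _stack_from_pdb(pdb_file, path)
    system = _system_from_array(stack[0], rules, fallback)
    frames = np.asarray(stack.coord, dtype=float)
    if times is None:
        times = frame_interval_ps * np.arange(1, len(frames) + 1)
    return Trajectory(system=system, times=np.asarray(times, float), frames=frames)


def _array_from_system(system: MolecularSystem, coords: np.ndarray):
    import biotite.structure as struc

    n = system.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.atom_name = np.asarray([str(s) for s in system.names], dtype="U6")
    array.element = np.asarray([str(e).upper() for e in system.elements], dtype="U2")
    array.res_name = np.asarray([str(r) for r in system.residue_names], dtype="U5")
    array.res_id = system.residue_indices.astype(int)
    array.chain_id = np.asarray([str(c) for c in system.chain_ids], dtype="U4")
    array.hetero = ~np.isin(system.partitions, ["receptor"])
    return array


def write_structure(system: MolecularSystem, path) -> None:
    """Write the system's reference coordinates as a single-model PDB."""
    from biotite.structure.io.pdb import PDBFile

    pdb_file = PDBFile()
    pdb_file.set_structure(_array_from_system(system, system.coords))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames as a multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = _array_from_system(traj.system, traj.system.coords)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pdb_file.write(str(path))
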