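"""Synthetic ground-truth fixtures for the HSA/chondroitin-sulfate analyses.

The generator emits *kinematic* trajectories: a multi-domain receptor built
from a reduced per-residue atom set, a sulfated 24-mer (default) polysaccharide
ligand with labeled oxygen classes, explicit waters and Na+/Ca2+/Mg2+/Cl-
ions. Frames are rigid-body receptor/ligand motion plus per-atom Gaussian
jitter; intermolecular events (hydrogen bonds, hydrophobic and ionic
contacts, water and ionic bridges) are *planted* at known frames and places
with geometric margin, and recorded in a machine-readable ledger. No force
field and no integrator are involved: the fixtures exist to test the
analysis code, not dynamics.

Geometry is idealized. Molecules are laid out on serpentine grids in
separated slabs of the box (receptor and ligand near z~10-30, waters above,
ions below), so that outside planted frame ranges no intermolecular contact
satisfies any detector criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisParams,
    DomainScheme,
    FormatError,
    GenerationError,
    MerGroupScheme,
    MolecularSystem,
    Trajectory,
)

__all__ = [
    "FixtureSpec",
    "EventSpec",
    "GroundTruthLedger",
    "build_receptor",
    "build_ligand",
    "build_system",
    "generate_trajectory",
    "schedule_events",
    "generate_energy_table",
    "read_ledger",
]

EVENT_TYPES = ("HBo", "HBo_water", "HP", "ionic", "water_bridge", "ionic_bridge")

#: Default residue pattern for the fixture receptor. Hydrophobic (ALA, LEU,
#: VAL) and charged (GLU, LYS, ASP, ARG) residues are kept non-adjacent so
#: planted contacts cannot graze a neighboring interaction site.
SEQUENCE_PATTERN = (
    "ALA", "GLU", "SER", "LYS", "LEU", "ASP",
    "THR", "ARG", "VAL", "GLN", "GLY", "ASN",
)

HYDROPHOBIC_RESIDUES = ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO")
#: Residues whose reduced side chain is a polar oxygen pseudo-atom "OG".
POLAR_OG_RESIDUES = ("SER", "THR", "ASN", "GLN", "TYR", "TRP", "CYS", "HIS")

WATER_ANGLE = math.radians(104.5)
OH_BOND = 0.96

# planted-contact distances: comfortably inside each detector's criterion
HB_PLANT_DIST = 2.0     # H...acceptor, Å (energy = full 25 kJ/mol optimum)
HP_PLANT_FRACTION = 0.8  # of hp_cutoff
IONIC_PLANT_FRACTION = 0.8  # of ionic_cutoff


# ---------------------------------------------------------------------------
# Specs and ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """One planted event: type, inclusive frame range, optional explicit atoms."""

    event_type: str
    start_frame: int
    stop_frame: int
    receptor_atom: int | None = None
    ligand_atom: int | None = None
    mediator: int | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.stop_frame < self.start_frame:
            raise ValueError("stop_frame before start_frame")

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.stop_frame + 1)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic system + trajectory.

    Full-scale defaults mirror the study system: a 585-residue receptor, a
    24-mer ligand, a 120x110x110 Å box and 100 ps save spacing (so 140 ns
    yields 1400 stored frames). :meth:`desk_scale` gives the small
    configuration used for fast testing.
    """

    n_receptor_residues: int = 585
    ligand_isomer: str = "CS4"
    n_mers: int = 24
    n_waters: int = 2000
    n_cations: int = 60
    n_anions: int = 120
    cation_species: str = "Na"
    box: tuple[float, float, float] = (120.0, 110.0, 110.0)
    n_frames: int | None = 1400
    duration_ps: float | None = None
    frame_interval_ps: float = 100.0
    jitter_sigma: float = 0.0
    planted_events: tuple[EventSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.ligand_isomer not in ("CS4", "CS6"):
            raise ValueError("ligand_isomer must be CS4 or CS6")
        if self.cation_species not in ("Na", "Ca", "Mg"):
            raise ValueError("cation_species must be Na, Ca or Mg")
        if min(self.box) <= 0:
            raise ValueError("box must be positive")
        if self.resolved_n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def resolved_n_frames(self) -> int:
        """Frame count; from floor(duration/interval) when a duration is given."""
        if self.duration_ps is not None:
            return int(math.floor(self.duration_ps / self.frame_interval_ps))
        return int(self.n_frames)

    @classmethod
    def desk_scale(cls, **overrides) -> "FixtureSpec":
        """Small fixture: 60 residues, 12-mer ligand, 500 waters, 200 frames."""
        base = dict(
            n_receptor_residues=60, n_mers=12, n_waters=500,
            n_cations=20, n_anions=40, n_frames=200, duration_ps=None,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "FixtureSpec":
        return replace(self, **kw)


class GroundTruthLedger:
    """Per-frame record of every planted event.

    One row per (frame, event): columns ``frame``, ``time_ps``, ``type``,
    ``receptor_atom``, ``ligand_atom``, ``mediator`` (-1 for direct
    contacts). Endpoints are heavy-atom indices; for ionic contacts they are
    the charge-group representative atoms. For solute-water hydration bonds
    (``HBo_water``) the ``ligand_atom`` column holds the water oxygen.
    """

    COLUMNS = ("frame", "time_ps", "type", "receptor_atom", "ligand_atom", "mediator")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise FormatError(f"ledger missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def events_at(self, frame: int, event_type: str | None = None) -> set[tuple]:
        """Set of (type, receptor_atom, ligand_atom, mediator) keys at a frame."""
        sub = self.table[self.table["frame"] == frame]
        if event_type is not None:
            sub = sub[sub["type"] == event_type]
        return {
            (r.type, int(r.receptor_atom), int(r.ligand_atom), int(r.mediator))
            for r in sub.itertuples()
        }

    def counts(self) -> pd.Series:
        return self.table.groupby("type").size()

    def write_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, sep="\t", index=False)


def read_ledger(path) -> GroundTruthLedger:
    return GroundTruthLedger(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates atom columns and bonds while building a system."""

    def __init__(self):
        self.names, self.elements, self.res_names = [], [], []
        self.res_ids, self.chain_ids, self.coords = [], [], []
        self.partitions, self.bonds = [], []

    def add(self, name, element, res_name, res_id, chain, xyz, partition) -> int:
        idx = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.res_names.append(res_name)
        self.res_ids.append(res_id)
        self.chain_ids.append(chain)
        self.coords.append(tuple(xyz))
        self.partitions.append(partition)
        return idx

    def bond(self, i, j):
        self.bonds.append((i, j))

    def system(self, metadata=None) -> MolecularSystem:
        return MolecularSystem(
            self.names, self.elements, self.res_names, self.res_ids,
            self.chain_ids, np.asarray(self.coords, float), self.partitions,
            self.bonds, metadata=metadata,
        ).annotate()


def _serpentine(n_items: int, origin, spacing, per_row, per_layer_rows,
                row_gap, layer_gap):
    """3D serpentine grid positions for chain-like placement."""
    out = []
    for i in range(n_items):
        layer, rem = divmod(i, per_row * per_layer_rows)
        row, col = divmod(rem, per_row)
        if row % 2 == 1:
            col = per_row - 1 - col
        out.append((
            origin[0] + col * spacing,
            origin[1] + row * row_gap,
            origin[2] + layer * layer_gap,
        ))
    return np.asarray(out, float)


def _receptor_layout(n_residues, box):
    # roughly square footprint: disperses each residue type in 2D
    target = math.ceil(math.sqrt(n_residues * 5.5 / 3.8))
    per_row = max(3, min(int((box[0] - 20.0) // 3.8) + 1, target))
    rows = max(1, int((45.0) // 5.5))
    centers = _serpentine(
        n_residues, (10.0, 10.0, 14.0), 3.8, per_row, rows, 5.5, 5.5
    )
    if centers[:, 0].max() > box[0] - 5 or centers[:, 1].max() > 62.0 \
            or centers[:, 2].max() > 32.0:
        raise GenerationError(
            f"box {box} too small for a {n_residues}-residue receptor"
        )
    return centers


def build_receptor(
    n_residues: int = 585,
    box: tuple[float, float, float] = (120.0, 110.0, 110.0),
    sequence: Sequence[str] | None = None,
    chain: str = "A",
) -> MolecularSystem:
    """Reduced-representation receptor: N/H/CA/C/O plus one side-chain pseudo-atom.

    The backbone amide hydrogen and the polar side-chain oxygen point along
    +z (out of the packing plane), which is where planted partners are
    placed. Charged residues carry their charge-group pseudo-atom (Arg CZ,
    Lys NZ, Asp CG, Glu CD).
    """
    if sequence is None:
        sequence = [
            SEQUENCE_PATTERN[i % len(SEQUENCE_PATTERN)] for i in range(n_residues)
        ]
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")
    centers = _receptor_layout(n_residues, box)
    b = _Builder()
    side_name = {
        "ARG": ("CZ", "C"), "LYS": ("NZ", "N"), "ASP": ("CG", "C"),
        "GLU": ("CD", "C"), "HIS": ("NE2", "N"),
    }
    for ridx, (resname, c) in enumerate(zip(sequence, centers), start=1):
        def at(dx, dy, dz):
            return (c[0] + dx, c[1] + dy, c[2] + dz)

        n = b.add("N", "N", resname, ridx, chain, at(-1.2, 0.8, 0.0), "receptor")
        h = b.add("H", "H", resname, ridx, chain, at(-1.2, 0.8, 1.0), "receptor")
        ca = b.add("CA", "C", resname, ridx, chain, at(0.0, 0.0, 0.0), "receptor")
        cc = b.add("C", "C", resname, ridx, chain, at(1.2, 0.8, 0.0), "receptor")
        o = b.add("O", "O", resname, ridx, chain, at(1.8, 1.85, 0.0), "receptor")
        b.bond(n, h); b.bond(n, ca); b.bond(ca, cc); b.bond(cc, o)
        if resname == "GLY":
            continue
        if resname in side_name:
            name, elem = side_name[resname]
            sc = b.add(name, elem, resname, ridx, chain, at(0.0, -1.5, 0.0), "receptor")
        elif resname in POLAR_OG_RESIDUES:
            sc = b.add("OG", "O", resname, ridx, chain, at(0.0, 0.0, 1.45), "receptor")
        else:
            sc = b.add("CB", "C", resname, ridx, chain, at(0.0, -1.5, 0.0), "receptor")
        b.bond(ca, sc)
    return b.system(metadata={"kind": "receptor", "n_residues": n_residues})


# local atom templates: (name, element, dx, dy, dz); bonds by name pairs
_GCU_ATOMS = [
    ("C1", "C", -2.0, 0.0, 0.0), ("O5", "O", -1.2, 1.15, 0.0),
    ("C5", "C", 0.2, 1.15, 0.0), ("C6", "C", 1.0, 2.3, 0.0),
    ("O61", "O", 2.3, 2.3, 0.0), ("O62", "O", 0.4, 3.4, 0.0),
    ("C3", "C", -1.2, -1.15, 0.0), ("O3", "O", -1.2, -2.5, 0.0),
    ("HO3", "H", -0.3, -3.0, 0.0), ("O13", "O", -3.4, 0.2, 0.0),
]
_GCU_BONDS = [
    ("C1", "O5"), ("O5", "C5"), ("C5", "C6"), ("C6", "O61"), ("C6", "O62"),
    ("C1", "C3"), ("C3", "O3"), ("O3", "HO3"), ("C1", "O13"),
]

_NGA_BASE_ATOMS = [
    ("C1", "C", -2.0, 0.0, 0.0), ("O5", "O", -1.2, 1.15, 0.0),
    ("C5", "C", 0.2, 1.15, 0.0), ("C6", "C", 1.0, 2.3, 0.0),
    ("C4", "C", -0.6, -1.2, 0.0), ("N2", "N", -2.6, -1.2, 0.2),
    ("HN2", "H", -1.8, -1.8, 0.2), ("C7", "C", -4.0, -1.8, 0.3),
    ("O7", "O", -4.4, -3.1, 0.3), ("C8", "C", -5.2, -0.9, 0.3),
    ("O14", "O", -3.4, 0.2, 0.0),
]
_NGA_BASE_BONDS = [
    ("C1", "O5"), ("O5", "C5"), ("C5", "C6"), ("C1", "C4"), ("C1", "N2"),
    ("N2", "HN2"), ("N2", "C7"), ("C7", "O7"), ("C7", "C8"), ("C1", "O14"),
]
# 4-sulfation (CS-4): ester oxygen O4S on C4, hydroxyl on C6
_NGA_CS4_EXTRA = [
    ("O4S", "O", -0.6, -2.55, 0.0), ("S", "S", -0.6, -4.15, 0.0),
    ("OS1", "O", 0.75, -4.75, 0.0), ("OS2", "O", -1.95, -4.75, 0.0),
    ("OS3", "O", -0.6, -5.15, 1.2),
    ("O6", "O", 2.3, 2.3, 0.0), ("HO6", "H", 3.0, 2.95, 0.0),
]
_NGA_CS4_EXTRA_BONDS = [
    ("C4", "O4S"), ("O4S", "S"), ("S", "OS1"), ("S", "OS2"), ("S", "OS3"),
    ("C6", "O6"), ("O6", "HO6"),
]
# 6-sulfation (CS-6): ester oxygen O6S on C6, hydroxyl on C4
_NGA_CS6_EXTRA = [
    ("O6S", "O", 2.3, 2.3, 0.0), ("S", "S", 2.9, 3.8, 0.0),
    ("OS1", "O", 4.3, 4.2, 0.0), ("OS2", "O", 1.7, 4.6, 0.0),
    ("OS3", "O", 3.1, 4.0, 1.5),
    ("O4", "O", -0.6, -2.55, 0.0), ("HO4", "H", 0.3, -3.05, 0.0),
]
_NGA_CS6_EXTRA_BONDS = [
    ("C6", "O6S"), ("O6S", "S"), ("S", "OS1"), ("S", "OS2"), ("S", "OS3"),
    ("C4", "O4"), ("O4", "HO4"),
]

_MER_SPACING = 6.5


def build_ligand(
    isomer: str = "CS4",
    n_mers: int = 24,
    box: tuple[float, float, float] = (120.0, 110.0, 110.0),
    chain: str = "B",
) -> MolecularSystem:
    """Idealized chondroitin-sulfate chain of alternating GlcA/GalNAc mers.

    Odd mers are glucuronic acid (``GCU``, one COO- each), even mers are
    N-acetylgalactosamine (``NGA``, one SO4- each). The sulfate ester oxygen
    is O4S for the CS-4 isomer and O6S for CS-6, which is the only label
    difference between the two outputs. Oxygen classes (SO4-, COO-, O, O3,
    O13, O14, O7, ...) are derived from the atom names.
    """
    if isomer not in ("CS4", "CS6"):
        raise ValueError("isomer must be CS4 or CS6")
    if n_mers % 2 != 0:
        raise ValueError("n_mers must be even (alternating disaccharide units)")
    per_row = max(2, int((box[0] - 16.0) // _MER_SPACING) + 1)
    centers = _serpentine(n_mers, (10.0, 74.0, 20.0), _MER_SPACING, per_row, 50, 13.0, 13.0)
    if centers[:, 0].max() > box[0] - 5 or centers[:, 1].max() > box[1] - 8:
        raise GenerationError(f"box {box} too small for a {n_mers}-mer ligand")
    b = _Builder()
    for mer, c in enumerate(centers, start=1):
        if mer % 2 == 1:
            atoms, bonds, resname = _GCU_ATOMS, _GCU_BONDS, "GCU"
        else:
            extra = _NGA_CS4_EXTRA if isomer == "CS4" else _NGA_CS6_EXTRA
            extra_bonds = (
                _NGA_CS4_EXTRA_BONDS if isomer == "CS4" else _NGA_CS6_EXTRA_BONDS
            )
            atoms = _NGA_BASE_ATOMS + extra
            bonds = _NGA_BASE_BONDS + extra_bonds
            resname = "NGA"
        index_of = {}
        for name, elem, dx, dy, dz in atoms:
            index_of[name] = b.add(
                name, elem, resname, mer, chain,
                (c[0] + dx, c[1] + dy, c[2] + dz), "ligand",
            )
        for u, v in bonds:
            b.bond(index_of[u], index_of[v])
    return b.system(metadata={"kind": "ligand", "isomer": isomer, "n_mers": n_mers})


def _build_solvent(b: _Builder, spec: FixtureSpec) -> None:
    box = spec.box
    # waters in an upper slab, ions in a top sliver; both far from the solutes
    per_row = max(2, int((box[0] - 12.0) // 3.1))
    rows = max(1, int((box[1] - 12.0) // 3.1))
    if spec.n_waters > per_row * rows * max(1, int((box[2] - 60.0) // 3.1)):
        raise GenerationError("box too small for requested water count")
    positions = _serpentine(
        spec.n_waters, (6.0, 6.0, 52.0), 3.1, per_row, rows, 3.1, 3.1
    )
    h1 = np.array([OH_BOND, 0.0, 0.0])
    h2 = np.array([OH_BOND * math.cos(WATER_ANGLE), OH_BOND * math.sin(WATER_ANGLE), 0.0])
    resid = 1
    for p in positions:
        o = b.add("O", "O", "HOH", resid, "W", p, "water")
        i1 = b.add("H1", "H", "HOH", resid, "W", p + h1, "water")
        i2 = b.add("H2", "H", "HOH", resid, "W", p + h2, "water")
        b.bond(o, i1); b.bond(o, i2)
        resid += 1
    n_ions = spec.n_cations + spec.n_anions
    per_row_i = max(2, int((box[0] - 12.0) // 4.0))
    ion_pos = _serpentine(
        n_ions, (6.0, 6.0, box[2] - 8.0), 4.0, per_row_i, 200, 4.0, 4.0
    )
    if ion_pos[:, 1].max() > box[1] - 4:
        raise GenerationError("box too small for requested ion count")
    cat = spec.cation_species
    resid = 1
    for k, p in enumerate(ion_pos):
        if k < spec.n_cations:
            b.add(cat.upper(), cat, cat.upper(), resid, "I", p, "cation")
        else:
            b.add("CL", "Cl", "CL", resid, "I", p, "anion")
        resid += 1


def build_system(spec: FixtureSpec) -> MolecularSystem:
    """Assemble receptor + ligand + waters + ions into one annotated system."""
    rec = build_receptor(spec.n_receptor_residues, spec.box)
    lig = build_ligand(spec.ligand_isomer, spec.n_mers, spec.box)
    b = _Builder()
    for sys_part in (rec, lig):
        offset = len(b.names)
        for i in range(sys_part.n_atoms):
            b.add(
                sys_part.names[i], sys_part.elements[i], sys_part.residue_names[i],
                int(sys_part.residue_indices[i]), sys_part.chain_ids[i],
                sys_part.coords[i], sys_part.partitions[i],
            )
        for u, v in sys_part.bonds:
            b.bond(u + offset, v + offset)
    _build_solvent(b, spec)
    meta = {
        "isomer": spec.ligand_isomer,
        "n_receptor_residues": spec.n_receptor_residues,
        "n_mers": spec.n_mers,
        "cation_species": spec.cation_species,
        "box": tuple(spec.box),
    }
    return b.system(metadata=meta)


# ---------------------------------------------------------------------------
# Event planning and planting
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


class _SiteBank:
    """Deterministic allocator of receptor sites, ligand clusters, waters, ions.

    Receptor sites are drawn from the topmost packing layer. Allocations
    keep a type-dependent planar gap so simultaneous planted events can
    never interfere: 6 Å between two ionic-family sites (whose criterion
    reaches 5 Å between group centers), 5 Å otherwise (hydrogen-bond and
    hydrophobic reaches stay under 4.6 Å).
    """

    IONIC_GAP = 6.0
    DEFAULT_GAP = 5.0

    def __init__(self, system: MolecularSystem):
        self.system = system
        self.used_xy: list[tuple[float, float, str]] = []
        rec = system.partition_indices("receptor")
        res_of = system.residue_indices
        top_z = max(system.coords[i][2] for i in rec if system.names[i] == "CA")
        top = [
            i for i in rec
            if system.names[i] == "CA" and system.coords[i][2] > top_z - 1.0
        ]
        self.top_residues = sorted(
            {int(res_of[i]) for i in top},
            key=lambda r: system.coords[
                [i for i in rec if res_of[i] == r and system.names[i] == "CA"][0]
            ][0],
        )
        self._res_atoms = {
            r: {str(system.names[i]): int(i) for i in rec if res_of[i] == r}
            for r in self.top_residues
        }
        lig = system.partition_indices("ligand")
        self._mer_atoms = {}
        for i in lig:
            self._mer_atoms.setdefault(int(res_of[i]), {})[str(system.names[i])] = int(i)
        # a mer's disjoint clusters (e.g. GCU hydroxyl vs carboxylate) can
        # serve different events; usage is tracked per (mer, cluster)
        self._used_clusters: set[tuple[int, str]] = set()
        self.free_waters = [w for w, _ in system.water_residues()]
        self.free_cations = [int(i) for i in system.partition_indices("cation")]

    def _required_gap(self, fam_a: str, fam_b: str) -> float:
        if fam_a == "ionic" and fam_b == "ionic":
            return self.IONIC_GAP
        return self.DEFAULT_GAP

    def _take_residue(self, want_names: tuple[str, ...],
                      resname: str | None = None, family: str = "polar"):
        # among eligible residues, take the one farthest from every used
        # site (greedy max-min keeps capacity for later allocations)
        best, best_margin = None, -1.0
        for r in self.top_residues:
            atoms = self._res_atoms[r]
            if resname is not None and str(
                self.system.residue_names[atoms["CA"]]
            ) != resname:
                continue
            if not all(n in atoms for n in want_names):
                continue
            x, y = self.system.coords[atoms["CA"]][:2]
            margin = min(
                (math.hypot(x - ux, y - uy) - self._required_gap(family, fam)
                 for ux, uy, fam in self.used_xy),
                default=math.inf,
            )
            if margin >= 0 and margin > best_margin:
                best, best_margin = r, margin
        if best is None:
            raise GenerationError(
                f"no free receptor site with atoms {want_names} "
                f"({'any' if resname is None else resname})"
            )
        atoms = self._res_atoms[best]
        x, y = self.system.coords[atoms["CA"]][:2]
        self.top_residues.remove(best)
        self.used_xy.append((float(x), float(y), family))
        return atoms

    def _take_mer(self, want_names: tuple[str, ...]):
        cluster = want_names[0]
        for m in sorted(self._mer_atoms):
            if (m, cluster) in self._used_clusters:
                continue
            atoms = self._mer_atoms[m]
            if all(n in atoms for n in want_names):
                self._used_clusters.add((m, cluster))
                return atoms
        raise GenerationError(f"no free ligand mer cluster {want_names}")

    def take_water(self) -> int:
        if not self.free_waters:
            raise GenerationError("no free water for planting")
        return self.free_waters.pop()

    def take_cation(self) -> int:
        if not self.free_cations:
            raise GenerationError("no free cation for planting")
        return self.free_cations.pop()


@dataclass(frozen=True)
class _PlannedEvent:
    spec: EventSpec
    receptor_atom: int            # heavy endpoint (or group representative)
    ligand_atom: int              # heavy endpoint / group rep / water O for HBo_water
    mediator: int                 # water O or cation index; -1 for direct
    move_atoms: tuple[int, ...]   # atoms repositioned while the event is active
    anchor: tuple[int, ...]       # atoms defining the placement geometry


#: Allocation priority: events needing scarce receptor residue types are
#: sited first so common events cannot crowd them out.
_PLAN_PRIORITY = {
    "ionic_bridge": 0, "ionic": 1, "water_bridge": 2,
    "HBo_water": 3, "HBo": 4, "HP": 5,
}


def _plan_events(system: MolecularSystem, spec: FixtureSpec,
                 params: AnalysisParams) -> list[_PlannedEvent]:
    bank = _SiteBank(system)
    planned_by_pos: dict[int, _PlannedEvent] = {}
    order = sorted(
        range(len(spec.planted_events)),
        key=lambda k: _PLAN_PRIORITY[spec.planted_events[k].event_type],
    )
    for pos in order:
        ev = spec.planted_events[pos]
        planned_by_pos[pos] = _plan_one(bank, ev)
    return [planned_by_pos[k] for k in range(len(spec.planted_events))]


def _plan_one(bank: "_SiteBank", ev: EventSpec) -> _PlannedEvent:
    system = bank.system
    if ev.event_type == "HBo":
        site = bank._take_residue(("N", "H"))
        mer = bank._take_mer(("O3", "HO3", "C3"))
        return _PlannedEvent(
            ev, site["N"], mer["O3"], -1,
            move_atoms=(mer["O3"], mer["HO3"], mer["C3"]),
            anchor=(site["N"], site["H"]),
        )
    if ev.event_type == "HBo_water":
        site = bank._take_residue(("OG",))
        w = bank.take_water()
        members = _water_members(system, w)
        return _PlannedEvent(
            ev, site["OG"], w, -1, move_atoms=tuple(members),
            anchor=(site["OG"], site["CA"]),
        )
    if ev.event_type == "HP":
        site = bank._take_residue(("CB",))
        mer = bank._take_mer(("C8",))
        return _PlannedEvent(
            ev, site["CB"], mer["C8"], -1,
            move_atoms=(mer["C8"],), anchor=(site["CB"],),
        )
    if ev.event_type == "ionic":
        # any positive side chain: Lys ammonium or Arg guanidinium
        try:
            site = bank._take_residue(("NZ",), resname="LYS", family="ionic")
            rep = site["NZ"]
        except GenerationError:
            site = bank._take_residue(("CZ",), resname="ARG", family="ionic")
            rep = site["CZ"]
        mer = bank._take_mer(("S", "OS1", "OS2", "OS3"))
        group = [mer[n] for n in ("S", "OS1", "OS2", "OS3")]
        return _PlannedEvent(
            ev, rep, mer["S"], -1,
            move_atoms=tuple(group), anchor=(rep,),
        )
    if ev.event_type == "water_bridge":
        site = bank._take_residue(("OG",))
        mer = bank._take_mer(("O3", "HO3", "C3"))
        w = bank.take_water()
        members = _water_members(system, w)
        return _PlannedEvent(
            ev, site["OG"], mer["O3"], w,
            move_atoms=tuple(members) + (mer["O3"], mer["HO3"], mer["C3"]),
            anchor=(site["OG"], site["CA"]),
        )
    if ev.event_type == "ionic_bridge":
        # any carboxylate side chain: Glu or Asp
        try:
            site = bank._take_residue(("CD",), resname="GLU", family="ionic")
            rep = site["CD"]
        except GenerationError:
            site = bank._take_residue(("CG",), resname="ASP", family="ionic")
            rep = site["CG"]
        mer = bank._take_mer(("C6", "O61", "O62"))
        cat = bank.take_cation()
        group = [mer[n] for n in ("C6", "O61", "O62")]
        return _PlannedEvent(
            ev, rep, mer["C6"], cat,
            move_atoms=(cat,) + tuple(group), anchor=(rep,),
        )
    raise GenerationError(f"unhandled event type {ev.event_type}")


def _water_members(system: MolecularSystem, oxygen: int) -> list[int]:
    for oxy, members in system.water_residues():
        if oxy == oxygen:
            return sorted(members)
    raise GenerationError(f"atom {oxygen} is not a water oxygen")


def _place_cluster(coords, atoms, pivot, target, direction):
    """Rigidly move a bonded cluster: pivot atom to ``target``, its mean
    neighbor direction aligned with ``direction``."""
    atoms = list(atoms)
    local = coords[atoms] - coords[pivot]
    others = [a for a in atoms if a != pivot]
    if others:
        mean = (coords[others].mean(axis=0) - coords[pivot])
        norm = np.linalg.norm(mean)
        if norm > 1e-9:
            rot = _rotation_between(mean / norm, direction)
            local = local @ rot.T
    coords[atoms] = target + local


def _plant(coords: np.ndarray, system: MolecularSystem, pe: _PlannedEvent,
           params: AnalysisParams) -> None:
    z = np.array([0.0, 0.0, 1.0])
    ev = pe.spec.event_type
    if ev == "HBo":
        n, h = pe.anchor
        u = coords[h] - coords[n]
        u /= np.linalg.norm(u)
        target = coords[h] + HB_PLANT_DIST * u
        _place_cluster(coords, pe.move_atoms, pe.ligand_atom, target, u)
    elif ev == "HBo_water":
        og, ca = pe.anchor
        u = coords[og] - coords[ca]
        u /= np.linalg.norm(u)
        _plant_water_donation(coords, system, pe.ligand_atom, coords[og], u)
    elif ev == "HP":
        cb = pe.anchor[0]
        target = coords[cb] + HP_PLANT_FRACTION * params.hp_cutoff * z
        coords[pe.ligand_atom] = target
    elif ev == "ionic":
        nz = pe.anchor[0]
        group = list(pe.move_atoms)
        heavy = [a for a in group if system.elements[a] != "H"]
        center = coords[heavy].mean(axis=0)
        target = coords[nz] + IONIC_PLANT_FRACTION * params.ionic_cutoff * z
        coords[group] += target - center
    elif ev == "water_bridge":
        og, ca = pe.anchor
        u = coords[og] - coords[ca]
        u /= np.linalg.norm(u)
        members = _water_members(system, pe.mediator)
        h2_pos, w = _plant_water_donation(coords, system, pe.mediator, coords[og], u)
        # ligand acceptor continues along the second O-H direction
        target = h2_pos + HB_PLANT_DIST * w
        lig_cluster = tuple(a for a in pe.move_atoms if a not in members)
        _place_cluster(coords, lig_cluster, pe.ligand_atom, target, w)
    elif ev == "ionic_bridge":
        cd = pe.anchor[0]
        d = IONIC_PLANT_FRACTION * params.ionic_cutoff
        cation = pe.mediator
        coords[cation] = coords[cd] + d * z
        group = [a for a in pe.move_atoms if a != cation]
        heavy = [a for a in group if system.elements[a] != "H"]
        center = coords[heavy].mean(axis=0)
        coords[group] += (coords[cation] + d * z) - center


def _plant_water_donation(coords, system, oxygen, acceptor_pos, u):
    """Pose a water so H1 donates to an acceptor sitting at ``acceptor_pos``
    whose free direction is ``u``; returns (H2 position, second O-H unit)."""
    members = _water_members(system, oxygen)
    h_atoms = [a for a in members if system.elements[a] == "H"]
    h1, h2 = h_atoms
    h1_pos = acceptor_pos + HB_PLANT_DIST * u
    o_pos = h1_pos + OH_BOND * u
    # second O-H at the water angle from the first; the in-plane component
    # points along +x (never toward the next receptor packing row)
    perp = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], u) * u
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], u) * u
    perp /= np.linalg.norm(perp)
    w = math.cos(WATER_ANGLE) * (-u) + math.sin(WATER_ANGLE) * perp
    h2_pos = o_pos + OH_BOND * w
    coords[oxygen] = o_pos
    coords[h1] = h1_pos
    coords[h2] = h2_pos
    return h2_pos, w


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def schedule_events(
    n_per_type: dict[str, int],
    n_frames: int,
    rng: np.random.Generator,
    min_len: int = 10,
    max_len: int = 40,
) -> tuple[EventSpec, ...]:
    """Random event schedule: each event gets one contiguous frame range."""
    events = []
    for etype, count in n_per_type.items():
        for _ in range(count):
            length = int(rng.integers(min_len, min(max_len, n_frames) + 1))
            start = int(rng.integers(0, max(1, n_frames - length + 1)))
            events.append(EventSpec(etype, start, start + length - 1))
    return tuple(events)


def _rigid_motion(rng: np.random.Generator, amp_rot_deg: float, amp_trans: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    period = float(rng.uniform(50, 200))
    phase = float(rng.uniform(0, 2 * math.pi))

    def apply(coords, frame_idx):
        theta = math.radians(amp_rot_deg) * math.sin(
            2 * math.pi * frame_idx / period + phase
        )
        shift = amp_trans * math.sin(2 * math.pi * frame_idx / (period * 1.7) + phase)
        center = coords.mean(axis=0)
        k = axis
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + math.sin(theta) * kx + (1 - math.cos(theta)) * kx @ kx
        return (coords - center) @ rot.T + center + shift * direction

    return apply


def generate_trajectory(
    spec: FixtureSpec,
    params: AnalysisParams | None = None,
    validate: bool = True,
) -> tuple[Trajectory, GroundTruthLedger]:
    """Deterministic fixture trajectory + ground-truth event ledger.

    Frames are base coordinates + smooth rigid-body motion of receptor and
    ligand, with planted-event atoms repositioned (with >= 10% criterion
    margin) during each event's frame range, then per-atom Gaussian jitter
    of ``spec.jitter_sigma`` Å. With ``validate`` the pre-jitter geometry of
    every active planted event is checked against its detector's predicate
    on the first and last active frame.
    """
    params = params or AnalysisParams(rng_seed=spec.rng_seed)
    system = build_system(spec)
    n_frames = spec.resolved_n_frames
    for ev in spec.planted_events:
        if ev.stop_frame >= n_frames:
            raise GenerationError("planted event extends past the last frame")
        for idx in (ev.receptor_atom, ev.ligand_atom, ev.mediator):
            if idx is not None and not 0 <= idx < system.n_atoms:
                raise GenerationError(f"planted endpoint {idx} does not exist")
    planned = _plan_events(system, spec, params)

    rng = np.random.default_rng(spec.rng_seed)
    move_rec = _rigid_motion(rng, amp_rot_deg=2.0, amp_trans=1.5)
    move_lig = _rigid_motion(rng, amp_rot_deg=3.0, amp_trans=2.0)
    rec_idx = system.partition_indices("receptor")
    lig_idx = system.partition_indices("ligand")

    times = spec.frame_interval_ps * np.arange(1, n_frames + 1)
    frames = np.empty((n_frames, system.n_atoms, 3))
    ledger_rows = []
    for f in range(n_frames):
        coords = system.coords.copy()
        coords[rec_idx] = move_rec(coords[rec_idx], f)
        coords[lig_idx] = move_lig(coords[lig_idx], f)
        active = [pe for pe in planned if f in pe.spec.frames]
        for pe in active:
            _plant(coords, system, pe, params)
            ledger_rows.append((
                f, float(times[f]), pe.spec.event_type,
                pe.receptor_atom, pe.ligand_atom, pe.mediator,
            ))
        if validate and active and f in (
            min(pe.spec.start_frame for pe in active),
            max(pe.spec.stop_frame for pe in active),
        ):
            _self_check(coords, system, active, params)
        if spec.jitter_sigma > 0:
            coords = coords + spec.jitter_sigma * rng.standard_normal(coords.shape)
        frames[f] = coords

    ledger = GroundTruthLedger(pd.DataFrame(
        ledger_rows, columns=GroundTruthLedger.COLUMNS,
    ))
    traj = Trajectory(system=system, times=times, frames=frames)
    return traj, ledger


def _self_check(coords, system, active, params):
    """Assert every active planted event satisfies its detector's criteria."""
    from . import bridges as _bridges
    from . import interactions as _inter

    hb = {
        (r.receptor_atom, r.ligand_atom)
        for r in _inter.detect_hbonds(coords, system, ("receptor", "ligand"), params)
    }
    hbw = {
        (r.receptor_atom, r.ligand_atom)
        for r in _inter.detect_hbonds(
            coords, system, (("receptor", "ligand"), "water"), params
        )
    }
    hp = {
        (r.receptor_atom, r.ligand_atom)
        for r in _inter.detect_hydrophobic(coords, system, params)
    }
    ionic = {
        (r.receptor_atom, r.ligand_atom)
        for r in _inter.detect_ionic(coords, system, params)
    }
    wb = {
        (r.receptor_endpoint, r.ligand_endpoint, r.mediator)
        for r in _bridges.detect_water_bridges(coords, system, params)
    }
    ib = {
        (r.receptor_endpoint, r.ligand_endpoint, r.mediator)
        for r in _bridges.detect_ionic_bridges(coords, system, params)
    }
    for pe in active:
        t = pe.spec.event_type
        ok = {
            "HBo": (pe.receptor_atom, pe.ligand_atom) in hb,
            "HBo_water": (pe.receptor_atom, pe.ligand_atom) in hbw,
            "HP": (pe.receptor_atom, pe.ligand_atom) in hp,
            "ionic": (pe.receptor_atom, pe.ligand_atom) in ionic,
            "water_bridge": (pe.receptor_atom, pe.ligand_atom, pe.mediator) in wb,
            "ionic_bridge": (pe.receptor_atom, pe.ligand_atom, pe.mediator) in ib,
        }[t]
        if not ok:
            raise GenerationError(
                f"planted {t} event failed its own detector predicate"
            )


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

ENERGY_COLUMNS = ("time_ps", "Epr", "Epl", "Esr", "Esl", "Epc", "Esc")


def generate_energy_table(terms: pd.DataFrame, path) -> pd.DataFrame:
    """Write a per-frame component-energy table (TSV) for the accounting stage.

    ``terms`` must hold one row per frame with the six components of the
    binding-energy decomposition plus a ``time_ps`` column. Values round-trip
    exactly through the file.
    """
    missing = set(ENERGY_COLUMNS) - set(terms.columns)
    if missing:
        raise FormatError(f"energy table missing columns {sorted(missing)}")
    out = terms.loc[:, list(ENERGY_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)
    return out
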