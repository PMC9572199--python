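"""Per-frame detection of direct intermolecular interactions.

Three censuses are taken between the two solutes (and, for hydration
analysis, between the solutes and water):

* **HBo** — hydrogen bonds, scored by an energy model with a 25 kJ/mol
  optimum; a bond is counted when its energy reaches the 6.25 kJ/mol
  threshold (25% of the optimum).
* **HP** — hydrophobic contacts: two apolar-flagged heavy atoms within a
  distance cutoff (default 4.5 Å).
* **ionic** — oppositely charged formal-charge groups whose centers lie
  within a cutoff (default 5.0 Å).

Each detector reports per-frame records; :func:`census` aggregates them into
time series with windowed mean ± doubled population STD over the
equilibration window (frames with time strictly greater than the
equilibration time, up to the window end).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    AnalysisParams,
    MolecularSystem,
    Trajectory,
    WindowError,
)

__all__ = [
    "InteractionRecord",
    "hbond_energy",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_ionic",
    "scan_trajectory",
    "census",
    "CensusResult",
    "window_stats",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("HBo", "HP", "ionic")


@dataclass(frozen=True)
class InteractionRecord:
    """One direct contact in one frame.

    ``receptor_atom`` / ``ligand_atom`` are the heavy endpoints on the first
    and second side of the requested partition pair (for the default pair
    these are literally receptor and ligand atoms; for ionic contacts they
    are the charge-group representative atoms). ``energy`` is set for HBo
    records only.
    """

    frame_index: int
    type: str
    receptor_atom: int
    ligand_atom: int
    distance: float
    energy: float | None = None
    donor_hydrogen: int | None = None
    receptor_group: int | None = None
    ligand_group: int | None = None

    @property
    def key(self) -> tuple:
        return (self.type, self.receptor_atom, self.ligand_atom)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_energy(
    d_HA: float,
    donor_angle: float,
    acceptor_angle: float,
    params: AnalysisParams | None = None,
) -> float:
    """Hydrogen-bond energy (kJ/mol) of a donor-H...acceptor triple.

    A finite-range, angle-gated model: the optimum (25 kJ/mol by default) is
    reached for H...acceptor distances up to 2.1 Å with linear decay to zero
    at 2.6 Å, scaled by an angular factor that is the product of linear
    ramps from 100° (zero) to 180° (full) for the donor and acceptor angles.
    The donor angle is measured at the hydrogen (donor-H...acceptor); the
    acceptor angle is the angle between the acceptor->H direction and the
    acceptor's mean covalent-bond direction (180° when H approaches anti to
    the acceptor's bonds; 180° by convention for acceptors without heavy
    neighbors, e.g. water oxygen).
    """
    params = params or AnalysisParams()
    if d_HA <= 0:
        raise ValueError("d_HA must be positive")
    inner, outer = params.hbond_ramp_inner, params.hbond_ramp_outer
    ramp = (outer - max(d_HA, inner)) / (outer - inner)
    ramp = min(max(ramp, 0.0), 1.0)
    span = 180.0 - params.hbond_angle_min
    gate = 1.0
    for theta in (donor_angle, acceptor_angle):
        gate *= min(max((theta - params.hbond_angle_min) / span, 0.0), 1.0)
    return params.hbond_optimum_energy * ramp * gate


def _resolve_pair_side(system: MolecularSystem, side) -> np.ndarray:
    parts = (side,) if isinstance(side, str) else tuple(side)
    return system.partition_indices(*parts)


def _side_key(side) -> tuple:
    return (side,) if isinstance(side, str) else tuple(side)


def _cached_donors(system: MolecularSystem, side) -> list[tuple[int, int]]:
    cache = getattr(system, "_donor_cache", None)
    if cache is None:
        cache = system._donor_cache = {}
    key = _side_key(side)
    if key not in cache:
        cache[key] = system.donors(_resolve_pair_side(system, side))
    return cache[key]


def _cached_acceptors(system: MolecularSystem, side) -> list[int]:
    cache = getattr(system, "_acceptor_cache", None)
    if cache is None:
        cache = system._acceptor_cache = {}
    key = _side_key(side)
    if key not in cache:
        cache[key] = system.acceptors(_resolve_pair_side(system, side))
    return cache[key]


def _acceptor_bond_dirs(system, coords, acceptors):
    """Unit mean covalent-bond direction per acceptor (NaN if no heavy nbr)."""
    dirs = np.full((len(acceptors), 3), np.nan)
    for k, a in enumerate(acceptors):
        nbrs = system.heavy_neighbors(a)
        if not nbrs:
            continue
        v = (coords[nbrs] - coords[a]).mean(axis=0)
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            dirs[k] = v / norm
    return dirs


def _angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle in degrees between rows of v1 and v2."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosv = np.einsum("...i,...i->...", v1, v2) / np.maximum(n1 * n2, 1e-12)
    return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))


def detect_hbonds(
    frame: np.ndarray,
    system: MolecularSystem,
    pair=("receptor", "ligand"),
    params: AnalysisParams | None = None,
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """All donor-H...acceptor triples across the partition pair with energy
    at or above the counting threshold.

    Each side of ``pair`` is a partition name or a tuple of names; donors on
    either side are paired with acceptors on the other. The record's
    endpoints are the heavy donor and the acceptor, ordered (side A, side B).
    """
    params = params or AnalysisParams()
    if frame.shape[0] != system.n_atoms:
        raise ValueError("frame/system atom-count mismatch")
    records = []
    for side_donor, side_acceptor, a_first in (
        (pair[0], pair[1], True), (pair[1], pair[0], False),
    ):
        donors = _cached_donors(system, side_donor)
        acceptors = _cached_acceptors(system, side_acceptor)
        if not donors or not acceptors:
            continue
        acc_idx = np.asarray(acceptors)
        acc_dirs = _acceptor_bond_dirs(system, frame, acceptors)
        tree = cKDTree(frame[acc_idx])
        h_idx = np.asarray([h for _, h in donors])
        d_idx = np.asarray([d for d, _ in donors])
        neighbor_lists = tree.query_ball_point(frame[h_idx], params.hbond_ramp_outer)
        for k, hits in enumerate(neighbor_lists):
            for m in hits:
                a = int(acc_idx[m])
                d, h = int(d_idx[k]), int(h_idx[k])
                if a == d:
                    continue
                d_ha = float(np.linalg.norm(frame[a] - frame[h]))
                if d_ha <= 0:
                    continue
                donor_angle = float(
                    _angle(frame[d] - frame[h], frame[a] - frame[h])
                )
                if np.isnan(acc_dirs[m, 0]):
                    acceptor_angle = 180.0
                else:
                    acceptor_angle = float(
                        _angle(frame[h] - frame[a], acc_dirs[m])
                    )
                energy = hbond_energy(d_ha, donor_angle, acceptor_angle, params)
                if energy >= params.hbond_threshold:
                    rec_atom, lig_atom = (d, a) if a_first else (a, d)
                    records.append(InteractionRecord(
                        frame_index=frame_index, type="HBo",
                        receptor_atom=rec_atom, ligand_atom=lig_atom,
                        distance=d_ha, energy=energy, donor_hydrogen=h,
                    ))
    return records


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

def detect_hydrophobic(
    frame: np.ndarray,
    system: MolecularSystem,
    params: AnalysisParams | None = None,
    pair=("receptor", "ligand"),
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """All hydrophobic-flagged atom pairs across the partition pair within
    the HP cutoff."""
    params = params or AnalysisParams()
    if frame.shape[0] != system.n_atoms:
        raise ValueError("frame/system atom-count mismatch")
    side_a = _resolve_pair_side(system, pair[0])
    side_b = _resolve_pair_side(system, pair[1])
    hydro_a = np.asarray([i for i in side_a if system.is_hydrophobic[i]])
    hydro_b = np.asarray([i for i in side_b if system.is_hydrophobic[i]])
    if len(hydro_a) == 0 or len(hydro_b) == 0:
        return []
    tree = cKDTree(frame[hydro_b])
    records = []
    for k, hits in enumerate(
        tree.query_ball_point(frame[hydro_a], params.hp_cutoff)
    ):
        for m in hits:
            i, j = int(hydro_a[k]), int(hydro_b[m])
            dist = float(np.linalg.norm(frame[i] - frame[j]))
            records.append(InteractionRecord(
                frame_index=frame_index, type="HP",
                receptor_atom=i, ligand_atom=j, distance=dist,
            ))
    return records


# ---------------------------------------------------------------------------
# Ionic interactions
# ---------------------------------------------------------------------------

def detect_ionic(
    frame: np.ndarray,
    system: MolecularSystem,
    params: AnalysisParams | None = None,
    pair=("receptor", "ligand"),
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """Oppositely charged formal-charge groups across the partition pair
    whose heavy-atom centers are within the ionic cutoff.

    Record endpoints are the group representative atoms. Groups with zero
    formal charge are skipped (logged at debug level).
    """
    params = params or AnalysisParams()
    if frame.shape[0] != system.n_atoms:
        raise ValueError("frame/system atom-count mismatch")
    parts_a = (pair[0],) if isinstance(pair[0], str) else tuple(pair[0])
    parts_b = (pair[1],) if isinstance(pair[1], str) else tuple(pair[1])
    records = []
    groups_a, groups_b = [], []
    for g in system.charge_groups:
        part = system.partitions[g.members[0]]
        if g.formal_charge == 0:
            logger.debug("skipping zero-charge group %s", g.label)
            continue
        if part in parts_a:
            groups_a.append(g)
        elif part in parts_b:
            groups_b.append(g)
    for ga in groups_a:
        ca = ga.center(frame, system.elements)
        for gb in groups_b:
            if ga.formal_charge * gb.formal_charge >= 0:
                continue
            cb = gb.center(frame, system.elements)
            dist = float(np.linalg.norm(ca - cb))
            if dist <= params.ionic_cutoff:
                records.append(InteractionRecord(
                    frame_index=frame_index, type="ionic",
                    receptor_atom=ga.representative, ligand_atom=gb.representative,
                    distance=dist,
                    receptor_group=ga.gid, ligand_group=gb.gid,
                ))
    return records


# ---------------------------------------------------------------------------
# Trajectory scans and censuses
# ---------------------------------------------------------------------------

_DETECTORS = {
    "HBo": lambda fr, sys_, pair, p, fi: detect_hbonds(fr, sys_, pair, p, fi),
    "HP": lambda fr, sys_, pair, p, fi: detect_hydrophobic(fr, sys_, p, pair, fi),
    "ionic": lambda fr, sys_, pair, p, fi: detect_ionic(fr, sys_, p, pair, fi),
}


def records_to_frame(records: list[InteractionRecord],
                     times: np.ndarray | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "frame": r.frame_index,
            "time_ps": np.nan if times is None else float(times[r.frame_index]),
            "type": r.type,
            "receptor_atom": r.receptor_atom,
            "ligand_atom": r.ligand_atom,
            "distance": r.distance,
            "energy": np.nan if r.energy is None else r.energy,
            "donor_hydrogen": -1 if r.donor_hydrogen is None else r.donor_hydrogen,
        })
    return pd.DataFrame(
        rows,
        columns=["frame", "time_ps", "type", "receptor_atom", "ligand_atom",
                 "distance", "energy", "donor_hydrogen"],
    )


def scan_trajectory(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    pair=("receptor", "ligand"),
    types=INTERACTION_TYPES,
) -> pd.DataFrame:
    """Run the requested detectors on every frame; one row per record."""
    params = params or AnalysisParams()
    all_records: list[InteractionRecord] = []
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        for t in types:
            all_records.extend(_DETECTORS[t](frame, traj.system, pair, params, f))
    return records_to_frame(all_records, traj.times)


def window_stats(values: np.ndarray, times: np.ndarray,
                 params: AnalysisParams) -> dict:
    """Population mean and doubled STD over the equilibration window.

    Included frames have time strictly greater than ``equilibration_time``
    and at most ``window_end``.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    mask = (times > params.equilibration_time) & (times <= params.window_end)
    if not mask.any():
        raise WindowError(
            f"no frames in window ({params.equilibration_time}, "
            f"{params.window_end}] ps"
        )
    included = values[mask]
    mean = float(included.mean())
    std = float(included.std(ddof=0))
    return {"mean": mean, "doubled_std": 2.0 * std, "n_frames": int(mask.sum())}


@dataclass
class CensusResult:
    """Per-frame interaction counts plus windowed summary statistics."""

    per_frame: pd.DataFrame       # columns: frame, time_ps, one per type
    summary: dict                 # type -> {"mean", "doubled_std", "n_frames"}
    records: pd.DataFrame         # raw per-record table


def census(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    pair=("receptor", "ligand"),
    types=INTERACTION_TYPES,
    records: pd.DataFrame | None = None,
) -> CensusResult:
    """Count interactions per frame and summarize over the analysis window.

    The summary holds the windowed mean and doubled population STD per type
    (the error-bar convention used throughout the reports).
    """
    params = params or AnalysisParams()
    if records is None:
        records = scan_trajectory(traj, params, pair, types)
    per_frame = pd.DataFrame({"frame": np.arange(traj.n_frames),
                              "time_ps": traj.times})
    for t in types:
        sub = records[records["type"] == t]
        counts = sub.groupby("frame").size()
        per_frame[t] = counts.reindex(per_frame["frame"], fill_value=0).to_numpy()
    summary = {
        t: window_stats(per_frame[t].to_numpy(), traj.times, params) for t in types
    }
    return CensusResult(per_frame=per_frame, summary=summary, records=records)
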