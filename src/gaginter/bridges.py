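"""Mediated receptor-ligand contacts: water bridges and ionic bridges.

A *water bridge* exists in a frame when one water molecule simultaneously
forms a hydrogen bond (by the same energy criterion as the direct census) to
a receptor atom and to a ligand atom. An *ionic bridge* exists when one
cation simultaneously forms an ionic interaction (same distance criterion as
the direct census) with a negatively charged receptor group and a negatively
charged ligand group. Anions never mediate bridges.

Bridges are labeled by the elements of the bridged heavy endpoints around
the mediator species — e.g. ``C-Ca-C`` for a Ca2+ ion between a glutamate
carboxylate and a ligand carboxylate, ``S-Ca-C`` when the ligand endpoint is
a sulfate (represented by its sulfur). Bridge lifetime is per-frame: no
minimum-duration filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisParams, MolecularSystem, Trajectory
from .interactions import detect_hbonds, detect_ionic, window_stats

__all__ = [
    "BridgeRecord",
    "detect_water_bridges",
    "detect_ionic_bridges",
    "scan_bridges",
    "bridge_census",
    "BridgeCensusResult",
]

BRIDGE_KINDS = ("water", "ionic")


@dataclass(frozen=True)
class BridgeRecord:
    """One mediated contact in one frame.

    ``mediator`` is the water oxygen or the cation atom index; endpoints are
    heavy atoms (water bridges) or charge-group representative atoms (ionic
    bridges). ``class_label`` encodes endpoint elements around the mediator
    species, e.g. ``"C-Ca-C"`` or ``"O-W-O"`` (W = water).
    """

    frame_index: int
    kind: str
    mediator: int
    receptor_endpoint: int
    ligand_endpoint: int
    class_label: str

    @property
    def key(self) -> tuple:
        return (self.kind, self.receptor_endpoint, self.ligand_endpoint,
                self.mediator)


def detect_water_bridges(
    frame: np.ndarray,
    system: MolecularSystem,
    params: AnalysisParams | None = None,
    frame_index: int = 0,
) -> list[BridgeRecord]:
    """One record per (water, receptor atom, ligand atom) combination where
    the water is hydrogen-bonded to both solutes in this frame.

    A single water bridging m receptor atoms and n ligand atoms yields
    m x n records (distinct endpoint-pair triples).
    """
    params = params or AnalysisParams()
    water_of = getattr(system, "_water_of_cache", None)
    if water_of is None:
        water_of = {}
        for oxy, members in system.water_residues():
            for m in members:
                water_of[m] = oxy
        system._water_of_cache = water_of

    def solute_contacts(solute: str) -> dict[int, set[int]]:
        """water oxygen -> heavy solute endpoints H-bonded to that water."""
        out: dict[int, set[int]] = {}
        for rec in detect_hbonds(frame, system, (solute, "water"), params,
                                 frame_index):
            oxy = water_of[rec.ligand_atom]
            out.setdefault(oxy, set()).add(rec.receptor_atom)
        return out

    rec_side = solute_contacts("receptor")
    lig_side = solute_contacts("ligand")
    records = []
    for oxy in sorted(set(rec_side) & set(lig_side)):
        for r in sorted(rec_side[oxy]):
            for l in sorted(lig_side[oxy]):
                label = f"{system.elements[r]}-W-{system.elements[l]}"
                records.append(BridgeRecord(
                    frame_index=frame_index, kind="water", mediator=oxy,
                    receptor_endpoint=r, ligand_endpoint=l, class_label=label,
                ))
    return records


def detect_ionic_bridges(
    frame: np.ndarray,
    system: MolecularSystem,
    params: AnalysisParams | None = None,
    frame_index: int = 0,
    coordination_oxygens: tuple[int, ...] = (),
) -> list[BridgeRecord]:
    """One record per cation simultaneously within the ionic cutoff of a
    negative receptor group and a negative ligand group (center distances,
    as in the direct ionic census).

    ``coordination_oxygens`` optionally adds individual ligand oxygen atoms
    (e.g. ring or hydroxyl oxygens) as single-atom coordination endpoints;
    they are labeled by their element (O), giving classes like ``C-Ca-O``.
    """
    params = params or AnalysisParams()
    cations = system.partition_indices("cation")
    if len(cations) == 0:
        return []
    neg_rec = [
        g for g in system.charge_groups_in("receptor") if g.formal_charge < 0
    ]
    neg_lig = [
        g for g in system.charge_groups_in("ligand") if g.formal_charge < 0
    ]
    lig_extra = [int(i) for i in coordination_oxygens]
    records = []
    for cat in cations:
        cpos = frame[cat]
        species = str(system.elements[cat])
        rec_hits = [
            g for g in neg_rec
            if np.linalg.norm(g.center(frame, system.elements) - cpos)
            <= params.ionic_cutoff
        ]
        if not rec_hits:
            continue
        lig_hits: list[tuple[int, str]] = [
            (g.representative, str(system.elements[g.representative]))
            for g in neg_lig
            if np.linalg.norm(g.center(frame, system.elements) - cpos)
            <= params.ionic_cutoff
        ]
        lig_hits += [
            (i, str(system.elements[i])) for i in lig_extra
            if np.linalg.norm(frame[i] - cpos) <= params.ionic_cutoff
        ]
        for g in rec_hits:
            rep_elem = str(system.elements[g.representative])
            for lig_rep, lig_elem in lig_hits:
                records.append(BridgeRecord(
                    frame_index=frame_index, kind="ionic", mediator=int(cat),
                    receptor_endpoint=g.representative, ligand_endpoint=lig_rep,
                    class_label=f"{rep_elem}-{species}-{lig_elem}",
                ))
    return records


def scan_bridges(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    kinds=BRIDGE_KINDS,
) -> pd.DataFrame:
    """Run the bridge detectors on every frame; one row per record."""
    params = params or AnalysisParams()
    rows = []
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        records: list[BridgeRecord] = []
        if "water" in kinds:
            records.extend(detect_water_bridges(frame, traj.system, params, f))
        if "ionic" in kinds:
            records.extend(detect_ionic_bridges(frame, traj.system, params, f))
        for r in records:
            rows.append({
                "frame": f, "time_ps": float(traj.times[f]), "kind": r.kind,
                "mediator": r.mediator, "receptor_endpoint": r.receptor_endpoint,
                "ligand_endpoint": r.ligand_endpoint, "class_label": r.class_label,
            })
    return pd.DataFrame(
        rows,
        columns=["frame", "time_ps", "kind", "mediator", "receptor_endpoint",
                 "ligand_endpoint", "class_label"],
    )


@dataclass
class BridgeCensusResult:
    per_frame: pd.DataFrame   # frame, time_ps, water, ionic
    summary: dict             # kind -> stats; "by_class" -> label -> stats
    records: pd.DataFrame


def bridge_census(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    kinds=BRIDGE_KINDS,
    records: pd.DataFrame | None = None,
) -> BridgeCensusResult:
    """Per-frame bridge counts with windowed mean ± doubled STD, split by
    kind and by class label."""
    params = params or AnalysisParams()
    if records is None:
        records = scan_bridges(traj, params, kinds)
    per_frame = pd.DataFrame({"frame": np.arange(traj.n_frames),
                              "time_ps": traj.times})
    summary: dict = {"by_class": {}}
    for kind in kinds:
        sub = records[records["kind"] == kind]
        counts = sub.groupby("frame").size()
        per_frame[kind] = counts.reindex(per_frame["frame"], fill_value=0).to_numpy()
        summary[kind] = window_stats(per_frame[kind].to_numpy(), traj.times, params)
    for label, sub in records.groupby("class_label"):
        counts = sub.groupby("frame").size()
        series = counts.reindex(np.arange(traj.n_frames), fill_value=0).to_numpy()
        summary["by_class"][label] = window_stats(series, traj.times, params)
    return BridgeCensusResult(per_frame=per_frame, summary=summary, records=records)
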