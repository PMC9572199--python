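"""Superposition-based stability analysis: RMSD series, per-atom RMSF,
aggregation by receptor subdomain and ligand mer group, and determination of
the equilibration onset.

RMSD is computed after a least-squares optimal rigid superposition (Kabsch,
proper rotation) of each frame onto a reference frame over a fit selection
(receptor backbone plus ligand ring atoms by default). RMSF is the per-atom
root-mean-square fluctuation about the atom's time-mean position inside the
analysis window, computed after superposing all frames on the receptor
backbone to remove global tumbling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AnalysisParams,
    DomainScheme,
    GeometryError,
    MerGroupScheme,
    MolecularSystem,
    Trajectory,
    WindowError,
    assign_domain,
    assign_mer_group,
)

__all__ = [
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "RMSFProfile",
    "equilibration_onset",
    "backbone_selection",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")
#: Ligand atoms counted as "backbone" for superposition: the sugar ring
#: carbons/oxygen and the glycosidic oxygens.
LIGAND_RING_NAMES = ("C1", "O5", "C5", "C3", "C4", "O13", "O14")


def backbone_selection(system: MolecularSystem,
                       include_ligand: bool = True) -> np.ndarray:
    """Boolean mask: receptor backbone N/CA/C/O (+ ligand ring atoms)."""
    mask = np.zeros(system.n_atoms, dtype=bool)
    for i in system.partition_indices("receptor"):
        if system.names[i] in BACKBONE_NAMES:
            mask[i] = True
    if include_ligand:
        for i in system.partition_indices("ligand"):
            if system.names[i] in LIGAND_RING_NAMES:
                mask[i] = True
    return mask


def _as_mask(selection, n_atoms: int) -> np.ndarray:
    sel = np.asarray(selection)
    if sel.dtype == bool:
        return sel
    mask = np.zeros(n_atoms, dtype=bool)
    mask[sel] = True
    return mask


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` over the
    selected atoms; ``rmsd`` is the minimized value over that selection. The
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise GeometryError("coordinate sets differ in shape")
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        mask = _as_mask(selection, mobile.shape[0])
        sel_m, sel_r = mobile[mask], reference[mask]
    if sel_m.shape[0] < 3:
        raise GeometryError("need at least 3 atoms to superpose")
    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    am, ar = sel_m - cm, sel_r - cr
    if np.linalg.matrix_rank(am, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) selection")
    h = am.T @ ar
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    fitted = am @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ar) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ rotation.T + translation


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection=None,
    rmsd_selection=None,
) -> pd.DataFrame:
    """Per-frame superposed RMSD against a stored reference frame.

    The rigid fit is computed over ``selection`` (default: receptor backbone
    + ligand ring); ``rmsd_selection`` (default: same) chooses the atoms the
    deviation is measured on, which allows measuring displacement of atoms
    excluded from the fit.
    """
    system = traj.system
    if selection is None:
        selection = backbone_selection(system)
    fit_mask = _as_mask(selection, system.n_atoms)
    out_mask = fit_mask if rmsd_selection is None else _as_mask(
        rmsd_selection, system.n_atoms
    )
    ref = traj.frames[reference_frame]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.frames[f], ref, fit_mask)
        fitted = apply_transform(traj.frames[f], rot, trans)
        diff = fitted[out_mask] - ref[out_mask]
        values[f] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return pd.DataFrame({"time_ps": traj.times, "rmsd": values})


@dataclass
class RMSFProfile:
    """Per-atom RMSF plus aggregation by receptor subdomain / ligand mer group.

    ``group_sums`` maps group label -> summed RMSF over member atoms, the
    comparison statistic used across complexes (sums, not means, so that
    group values are conserved: their total equals the per-atom total over
    grouped atoms).
    """

    per_atom: pd.DataFrame       # atom_index, rmsf
    group_sums: dict[str, float]

    def total(self) -> float:
        return float(self.per_atom["rmsf"].sum())


def rmsf(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    selection=None,
    domain_scheme: DomainScheme | None = None,
    mer_scheme: MerGroupScheme | None = None,
    fit_selection=None,
) -> RMSFProfile:
    """Windowed per-atom RMSF with subdomain / mer-group sums.

    Frames inside the analysis window are superposed on the receptor
    backbone (``fit_selection``) first; RMSF is then the square root of the
    time-mean squared deviation from each atom's time-mean position.
    Receptor atoms aggregate by subdomain label (``unassigned`` collects
    residues outside the scheme); ligand atoms aggregate by mer group
    (``mer_group_k``).
    """
    params = params or AnalysisParams()
    system = traj.system
    mask = traj.window_mask(params.equilibration_time, params.window_end)
    if not mask.any():
        raise WindowError("RMSF window selects no frames")
    if fit_selection is None:
        fit_selection = backbone_selection(system, include_ligand=False)
    fit_mask = _as_mask(fit_selection, system.n_atoms)
    sel_mask = (
        np.ones(system.n_atoms, dtype=bool) if selection is None
        else _as_mask(selection, system.n_atoms)
    )
    idx = np.where(mask)[0]
    ref = traj.frames[idx[0]]
    stacked = np.empty((len(idx), system.n_atoms, 3))
    for k, f in enumerate(idx):
        rot, trans, _ = superpose(traj.frames[f], ref, fit_mask)
        stacked[k] = apply_transform(traj.frames[f], rot, trans)
    mean_pos = stacked.mean(axis=0)
    dev2 = np.sum((stacked - mean_pos) ** 2, axis=2).mean(axis=0)
    values = np.sqrt(dev2)

    atom_idx = np.where(sel_mask)[0]
    per_atom = pd.DataFrame({"atom_index": atom_idx, "rmsf": values[atom_idx]})

    if domain_scheme is None:
        n_res = int(system.metadata.get(
            "n_receptor_residues",
            max((int(system.residue_indices[i])
                 for i in system.partition_indices("receptor")), default=585),
        ))
        domain_scheme = DomainScheme().scaled(n_res)
    if mer_scheme is None:
        lig = system.partition_indices("ligand")
        n_mers = int(system.metadata.get(
            "n_mers",
            max((int(system.residue_indices[i]) for i in lig), default=0),
        ))
        mer_scheme = MerGroupScheme(n_mers=n_mers) if n_mers else None

    group_sums: dict[str, float] = {}
    for i in atom_idx:
        part = system.partitions[i]
        if part == "receptor":
            label = assign_domain(int(system.residue_indices[i]), domain_scheme)
        elif part == "ligand" and mer_scheme is not None:
            label = f"mer_group_{assign_mer_group(int(system.residue_indices[i]), mer_scheme)}"
        else:
            continue
        group_sums[label] = group_sums.get(label, 0.0) + float(values[i])
    return RMSFProfile(per_atom=per_atom, group_sums=group_sums)


def equilibration_onset(
    series: pd.DataFrame,
    params: AnalysisParams | None = None,
    mode: str = "default",
    window: int = 10,
    slope_tol: float = 1e-3,
) -> float:
    """Equilibration onset time (ps) of an RMSD series.

    ``default`` mode returns the configured equilibration time (40 000 ps),
    the convention used for all reported statistics. ``auto`` mode returns
    the first time from which the rolling-mean slope of the series stays
    below ``slope_tol`` (Å/ps); if no such plateau exists a warning is
    logged and the configured value is returned.
    """
    import logging

    params = params or AnalysisParams()
    if mode == "default":
        return float(params.equilibration_time)
    if mode != "auto":
        raise ValueError("mode must be 'default' or 'auto'")
    times = series["time_ps"].to_numpy(float)
    values = series["rmsd"].to_numpy(float)
    if len(values) < 2 * window:
        raise WindowError("series too short for plateau detection")
    rolling = pd.Series(values).rolling(window, min_periods=1).mean().to_numpy()
    valid = ~np.isnan(rolling)
    rt, rv = times[valid], rolling[valid]
    slopes = np.abs(np.diff(rv) / np.diff(rt))
    flat = slopes < slope_tol
    # first index from which all later slopes stay flat
    for k in range(len(flat)):
        if flat[k:].all():
            return float(rt[k])
    logging.getLogger(__name__).warning(
        "no plateau found; falling back to configured equilibration time"
    )
    return float(params.equilibration_time)
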