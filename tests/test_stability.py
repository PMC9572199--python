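"""Superposition, RMSD/RMSF, grouping sums, equilibration onset."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import gaginter as gi
from gaginter.core import GeometryError, WindowError
from gaginter.stability import (
    apply_transform,
    backbone_selection,
    equilibration_onset,
)


def _cloud(n, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 5.0


class TestSuperpose:
    def test_identity(self):
        x = _cloud(20)
        rot, trans, rmsd = gi.superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_pure_translation_removed(self):
        x = _cloud(20)
        rot, trans, rmsd = gi.superpose(x + np.array([5.0, 0, 0]), x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_transform_removed(self):
        x = _cloud(30, seed=2)
        r = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = r.apply(x) + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = gi.superpose(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_kabsch(self):
        """Cross-check the minimized RMSD against scipy's align_vectors."""
        a = _cloud(25, seed=3)
        b = _cloud(25, seed=4)
        _, _, rmsd = gi.superpose(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)
        rot_sp, _ = Rotation.align_vectors(bc, ac)
        ref = np.sqrt(np.mean(np.sum((rot_sp.apply(ac) - bc) ** 2, axis=1)))
        assert rmsd == pytest.approx(ref, rel=1e-9)

    def test_single_displacement_law(self):
        """One displaced atom after fitting on the rest -> rmsd = d/sqrt(N)."""
        n, d = 50, 2.5
        x = _cloud(n, seed=5)
        moved = x.copy()
        moved[7] += np.array([0, 0, d])
        fit_sel = np.ones(n, bool)
        fit_sel[7] = False
        rot, trans, _ = gi.superpose(moved, x, fit_sel)
        fitted = apply_transform(moved, rot, trans)
        rmsd_all = np.sqrt(np.mean(np.sum((fitted - x) ** 2, axis=1)))
        assert rmsd_all == pytest.approx(d / np.sqrt(n), abs=1e-6)

    def test_optimality_against_random_transforms(self):
        a = _cloud(25, seed=6)
        b = _cloud(25, seed=7)
        _, _, best = gi.superpose(a, b)
        rng = np.random.default_rng(8)
        for _ in range(100):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(size=3)
            cand = rot.apply(a) + shift
            rmsd = np.sqrt(np.mean(np.sum(
                (cand - cand.mean(0) - (b - b.mean(0))) ** 2, axis=1)))
            assert best <= rmsd + 1e-9

    def test_proper_rotation(self):
        # mirror-image target must still yield det = +1
        a = _cloud(10, seed=9)
        b = a.copy()
        b[:, 0] *= -1
        rot, _, _ = gi.superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_degenerate_selection_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            gi.superpose(line, line)


def _static_traj(n_frames=10, n_atoms=40, seed=0):
    base = _cloud(n_atoms, seed)
    system = gi.MolecularSystem(
        names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
        residue_names=["ALA"] * n_atoms,
        residue_indices=list(range(1, n_atoms + 1)),
        chain_ids=["A"] * n_atoms,
        coords=base,
        partitions=["receptor"] * n_atoms,
    ).annotate()
    frames = np.repeat(base[None], n_frames, axis=0)
    times = 100.0 * np.arange(1, n_frames + 1)
    return gi.Trajectory(system=system, times=times, frames=frames)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        traj = _static_traj()
        series = gi.rmsd_series(traj, selection=np.arange(traj.system.n_atoms))
        assert np.allclose(series["rmsd"], 0.0, atol=1e-10)

    def test_drift_then_plateau(self):
        """A chain that drifts rigidly then stops: fitted RMSD of a
        non-fitted displaced atom plateaus at the planted offset / sqrt(N)."""
        traj = _static_traj(n_frames=20)
        frames = traj.frames.copy()
        offsets = np.concatenate([np.linspace(0, 3.0, 10), np.full(10, 3.0)])
        for k, off in enumerate(offsets):
            frames[k, 0, 2] += off
        traj2 = gi.Trajectory(traj.system, traj.times, frames)
        sel = np.ones(traj.system.n_atoms, bool)
        sel[0] = False
        series = gi.rmsd_series(traj2, selection=sel, rmsd_selection=None)
        series_all = gi.rmsd_series(
            traj2, selection=sel,
            rmsd_selection=np.ones(traj.system.n_atoms, bool))
        n = traj.system.n_atoms
        assert np.allclose(series["rmsd"], 0.0, atol=1e-9)
        assert series_all["rmsd"].iloc[-1] == pytest.approx(
            3.0 / np.sqrt(n), abs=1e-6)
        assert np.all(np.diff(series_all["rmsd"].iloc[:10]) > 0)

    def test_jitter_plateau_sqrt3_sigma(self):
        """Isotropic Gaussian jitter vs a clean reference -> RMSD = sigma*sqrt(3)."""
        sigma = 0.5
        traj = _static_traj(n_frames=30, n_atoms=600, seed=1)
        rng = np.random.default_rng(42)
        frames = traj.frames.copy()
        frames[1:] += sigma * rng.standard_normal(frames[1:].shape)
        traj2 = gi.Trajectory(traj.system, traj.times, frames)
        series = gi.rmsd_series(traj2,
                                selection=np.arange(traj.system.n_atoms))
        plateau = series["rmsd"].iloc[1:].mean()
        assert plateau == pytest.approx(sigma * np.sqrt(3), rel=0.10)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        traj = _static_traj()
        params = gi.AnalysisParams(equilibration_time=100.0, window_end=1e4)
        profile = gi.rmsf(traj, params,
                          fit_selection=np.arange(traj.system.n_atoms))
        assert np.allclose(profile.per_atom["rmsf"], 0.0, atol=1e-12)

    def test_two_point_oscillation_amplitude(self):
        """An atom alternating +/- a about its mean has RMSF exactly a."""
        a = 0.8
        traj = _static_traj(n_frames=10)
        frames = traj.frames.copy()
        frames[:, 5, 0] += a * np.array([1, -1] * 5)
        traj2 = gi.Trajectory(traj.system, traj.times, frames)
        sel = np.ones(traj.system.n_atoms, bool)
        sel[5] = False
        params = gi.AnalysisParams(equilibration_time=50.0, window_end=1e4)
        profile = gi.rmsf(traj2, params, fit_selection=sel)
        row = profile.per_atom.set_index("atom_index").loc[5, "rmsf"]
        assert row == pytest.approx(a, abs=1e-10)

    def test_group_sums_partition_and_conserve(self, planted_traj):
        traj, _ = planted_traj
        params = gi.AnalysisParams(equilibration_time=500.0,
                                   window_end=float(traj.times[-1]))
        profile = gi.rmsf(traj, params)
        mer_groups = [k for k in profile.group_sums if k.startswith("mer_group")]
        assert sorted(mer_groups) == [f"mer_group_{g}" for g in range(1, 5)]
        lig = traj.system.partition_indices("ligand")
        per_atom = profile.per_atom.set_index("atom_index")["rmsf"]
        lig_total = per_atom.loc[lig].sum()
        assert sum(profile.group_sums[k] for k in mer_groups) == \
            pytest.approx(lig_total, rel=1e-9)
        rec_groups = [k for k in profile.group_sums
                      if not k.startswith("mer_group")]
        rec = traj.system.partition_indices("receptor")
        assert sum(profile.group_sums[k] for k in rec_groups) == \
            pytest.approx(per_atom.loc[rec].sum(), rel=1e-9)

    def test_invariant_under_global_rigid_motion(self, planted_traj):
        traj, _ = planted_traj
        params = gi.AnalysisParams(equilibration_time=500.0,
                                   window_end=float(traj.times[-1]))
        base = gi.rmsf(traj, params)
        rot = Rotation.from_euler("zyx", [15, -30, 45], degrees=True)
        moved = np.array([rot.apply(fr) + np.array([3.0, -1.0, 2.0])
                          for fr in traj.frames])
        shifted = gi.Trajectory(traj.system, traj.times, moved)
        again = gi.rmsf(shifted, params)
        for k, v in base.group_sums.items():
            assert again.group_sums[k] == pytest.approx(v, abs=1e-6)

    def test_empty_window_raises(self):
        traj = _static_traj()
        with pytest.raises(WindowError):
            gi.rmsf(traj, gi.AnalysisParams(equilibration_time=5000.0,
                                            window_end=6000.0))


class TestEquilibrationOnset:
    def test_default_mode_returns_configured_time(self):
        series = pd.DataFrame({"time_ps": [100.0, 200.0],
                               "rmsd": [9.0, 1.0]})
        assert gi.equilibration_onset(series) == 40000.0

    def test_constant_series_auto_onset_is_first_time(self):
        times = 100.0 * np.arange(1, 101)
        series = pd.DataFrame({"time_ps": times, "rmsd": np.full(100, 2.5)})
        onset = gi.equilibration_onset(series, mode="auto")
        assert onset == times[0] + 0  # rolling window start
        assert onset <= times[10]

    def test_step_series_auto_onset_near_step(self):
        times = 100.0 * np.arange(1, 1001)
        rmsd = np.where(times <= 40000.0, 8.0, 2.0)
        series = pd.DataFrame({"time_ps": times, "rmsd": rmsd})
        onset = gi.equilibration_onset(series, mode="auto", window=10)
        assert abs(onset - 40000.0) <= 10 * 100.0

    def test_no_plateau_falls_back(self):
        times = 100.0 * np.arange(1, 101)
        series = pd.DataFrame({"time_ps": times, "rmsd": 0.1 * times})
        onset = gi.equilibration_onset(series, mode="auto", slope_tol=1e-9)
        assert onset == 40000.0
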