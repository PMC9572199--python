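"""Binding-energy accounting, SASA, ranking and the isomer contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gaginter as gi
from gaginter.energetics import (
    ELEMENT_RADII,
    REFERENCE_RANKING_CS4,
    REFERENCE_RANKING_CS6,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestBindingEnergy:
    def test_zero_terms(self):
        assert gi.binding_energy(gi.EnergyTerms(0, 0, 0, 0, 0, 0)) == (0, 0)

    def test_sign_bookkeeping(self):
        ebind, eob = gi.binding_energy(
            gi.EnergyTerms(0, 0, 0, 0, Epc=-100.0, Esc=0.0))
        assert ebind == 100.0 and eob == -100.0

    @settings(max_examples=100, deadline=None)
    @given(epr=finite, epl=finite, esr=finite, esl=finite, epc=finite,
           esc=finite)
    def test_accounting_identity(self, epr, epl, esr, esl, epc, esc):
        """Ebind + Epc + Esc - (Epr+Epl+Esr+Esl) = 0 to machine precision."""
        ebind, eob = gi.binding_energy(
            gi.EnergyTerms(epr, epl, esr, esl, epc, esc))
        residual = ebind + epc + esc - (epr + epl + esr + esl)
        assert abs(residual) <= 1e-9 * max(1.0, abs(ebind))
        assert eob == -ebind

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gi.EnergyTerms(np.nan, 0, 0, 0, 0, 0)


class TestWindowAverage:
    def _series(self, eob):
        times = 100.0 * np.arange(1, len(eob) + 1)
        return gi.BindingEnergySeries(times=times, eob=np.asarray(eob, float))

    def test_constant(self):
        params = gi.AnalysisParams(equilibration_time=100.0, window_end=1e5)
        stats = gi.window_average(self._series([-2000.0] * 10), params)
        assert stats["mean"] == -2000.0 and stats["doubled_std"] == 0.0

    def test_alternating_closed_form(self):
        params = gi.AnalysisParams(equilibration_time=50.0, window_end=1e5)
        stats = gi.window_average(self._series([-1000.0, -3000.0] * 5), params)
        assert stats["mean"] == pytest.approx(-2000.0)
        assert stats["doubled_std"] == pytest.approx(2000.0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(0)
        eob = rng.normal(-1500, 300, size=200)
        series = self._series(eob)
        params = gi.AnalysisParams(equilibration_time=5000.0,
                                   window_end=20000.0)
        stats = gi.window_average(series, params)
        mask = (series.times > 5000.0) & (series.times <= 20000.0)
        assert stats["mean"] == np.mean(eob[mask])
        assert stats["doubled_std"] == 2 * np.std(eob[mask])


class TestRanking:
    def test_reference_cs6_grand_mean(self):
        assert REFERENCE_RANKING_CS6["mean_eob"].mean() == pytest.approx(-1655.5)

    def test_rank_from_solution_means(self):
        means = {row.complex_id: [row.mean_eob]
                 for row in REFERENCE_RANKING_CS6.itertuples()}
        docking = {row.complex_id: row.docking_rank
                   for row in REFERENCE_RANKING_CS6.itertuples()}
        table = gi.rank_complexes(means, docking_ranks=docking)
        top = table.iloc[0]
        assert top["md_rank"] == 1 and top["docking_rank"] == 2
        assert top["mean_eob"] == -2522.0

    def test_three_solution_average(self):
        table = gi.rank_complexes({
            "a": [-1000.0, -1200.0, -1100.0], "b": [-2000.0, -1900.0, -2100.0],
        })
        assert list(table["complex_id"]) == ["b", "a"]
        assert table.loc[table["complex_id"] == "a", "mean_eob"].item() == \
            pytest.approx(-1100.0)

    def test_single_complex(self):
        table = gi.rank_complexes({"only": [-500.0]})
        assert list(table["md_rank"]) == [1]

    def test_tie_keeps_input_order(self):
        table = gi.rank_complexes({"z_first": [-10.0], "a_second": [-10.0]})
        assert list(table["complex_id"]) == ["z_first", "a_second"]

    def test_output_is_permutation_and_shift_invariant(self):
        rng = np.random.default_rng(1)
        means = {f"c{k}": [float(v)] for k, v in
                 enumerate(rng.normal(-1500, 400, 8))}
        table = gi.rank_complexes(means)
        assert sorted(table["complex_id"]) == sorted(means)
        shifted = gi.rank_complexes(
            {k: [v[0] + 123.0] for k, v in means.items()})
        assert list(shifted["complex_id"]) == list(table["complex_id"])

    def test_missing_docking_rank_reported_absent(self):
        table = gi.rank_complexes({"a": [-1.0], "b": [-2.0]},
                                  docking_ranks={"a": 1})
        row_b = table[table["complex_id"] == "b"].iloc[0]
        assert pd.isna(row_b["docking_rank"])


class TestIsomerContrast:
    def test_reference_tables_give_about_15_percent(self):
        contrast = gi.isomer_contrast(REFERENCE_RANKING_CS4,
                                      REFERENCE_RANKING_CS6)
        assert contrast == pytest.approx(15.0, abs=0.5)

    def test_identical_tables_zero(self):
        assert gi.isomer_contrast(REFERENCE_RANKING_CS6,
                                  REFERENCE_RANKING_CS6) == 0.0

    def test_double_magnitude_fifty_percent(self):
        t6 = REFERENCE_RANKING_CS6.copy()
        t4 = t6.copy()
        t4["mean_eob"] = 2.0 * t4["mean_eob"]
        assert gi.isomer_contrast(t4, t6) == pytest.approx(50.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            gi.isomer_contrast(REFERENCE_RANKING_CS4.iloc[:0],
                               REFERENCE_RANKING_CS6)


def _atoms_system(entries):
    return gi.MolecularSystem(
        names=[e[0] for e in entries],
        elements=[e[1] for e in entries],
        residue_names=["LIG"] * len(entries),
        residue_indices=[1] * len(entries),
        chain_ids=["B"] * len(entries),
        coords=np.array([e[2] for e in entries], float),
        partitions=["ligand"] * len(entries),
    )


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        system = _atoms_system([("C1", "C", (0, 0, 0))])
        per_atom, total = gi.sasa(system, probe_radius=1.4)
        expected = 4 * np.pi * (ELEMENT_RADII["C"] + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.005)

    def test_far_separated_additivity(self):
        sep = _atoms_system([("C1", "C", (0, 0, 0)), ("O1", "O", (50, 0, 0))])
        _, total = gi.sasa(sep)
        iso_c = 4 * np.pi * (ELEMENT_RADII["C"] + 1.4) ** 2
        iso_o = 4 * np.pi * (ELEMENT_RADII["O"] + 1.4) ** 2
        assert total == pytest.approx(iso_c + iso_o, rel=0.005)

    def test_per_atom_bounded_by_isolated_sphere(self):
        system = _atoms_system([("C1", "C", (0, 0, 0)), ("C2", "C", (1.8, 0, 0))])
        per_atom, total = gi.sasa(system)
        iso = 4 * np.pi * (ELEMENT_RADII["C"] + 1.4) ** 2
        assert np.all(per_atom <= iso * 1.001)
        assert total == per_atom.sum()

    def test_two_overlapping_spheres_vs_grid_oracle(self):
        """Dense surface-point integration as an independent oracle."""
        d = 2.0
        system = _atoms_system([("C1", "C", (0, 0, 0)), ("C2", "C", (d, 0, 0))])
        _, total = gi.sasa(system, n_sphere_points=4000)
        # oracle: Fibonacci surface points on each expanded sphere, keep
        # those outside the other expanded sphere
        r = ELEMENT_RADII["C"] + 1.4
        n = 200000
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5 ** 0.5) * k
        pts = r * np.column_stack([
            np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
            np.cos(phi)])
        centers = np.array([[0, 0, 0], [d, 0, 0]])
        oracle = 0.0
        for i, c in enumerate(centers):
            other = centers[1 - i]
            keep = np.linalg.norm(pts + c - other, axis=1) > r
            oracle += 4 * np.pi * r ** 2 * keep.mean()
        assert total == pytest.approx(oracle, rel=0.02)

    def test_unknown_element_raises(self):
        system = _atoms_system([("X1", "Xx", (0, 0, 0))])
        with pytest.raises(LookupError):
            gi.sasa(system)


class TestSolvation:
    @pytest.mark.parametrize("area,cost,expected", [
        (100.0, 0.65, 65.0), (0.0, 0.65, 0.0), (42.0, 1.0, 42.0),
    ])
    def test_product(self, area, cost, expected):
        assert gi.solvation_energy(area, cost) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            gi.solvation_energy(-1.0)
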