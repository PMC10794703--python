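"""SASA quadrature, buried areas, solvation energies, and colour maps."""

import math

import numpy as np
import pytest

from fibrilstab import (
    FibrilModel,
    HelicalParameters,
    buried_area,
    expand_symmetry,
    load_asp_table,
    make_layer,
    residue_energy_colormap,
    shrake_rupley,
    stabilization_energy,
)
from fibrilstab.model import ModelError
from fibrilstab.solvation import ASPConfigError, ASPTable, DegenerateInputError

from conftest import sasa_grid_oracle, small_layer_spec, toy_atoms


def isolated_area(r, probe=1.4):
    return 4.0 * math.pi * (r + probe) ** 2


class TestShrakeRupley:
    def test_single_atom_equals_closed_form(self):
        a = shrake_rupley(np.zeros((1, 3)), np.array([1.9]), probe=1.4, n_points=960)
        assert a[0] == pytest.approx(isolated_area(1.9), rel=1e-12)

    def test_two_separated_atoms_keep_isolated_value(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        a = shrake_rupley(coords, np.array([1.9, 1.4]), probe=1.4, n_points=960)
        assert a[0] == pytest.approx(isolated_area(1.9), rel=1e-12)
        assert a[1] == pytest.approx(isolated_area(1.4), rel=1e-12)

    def test_buried_atom_has_zero_area(self):
        # centre atom of a tight octahedron-plus-centre cluster
        d = 2.0
        coords = np.array(
            [[0, 0, 0], [d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0],
             [0, 0, d], [0, 0, -d]], float
        )
        a = shrake_rupley(coords, np.full(7, 1.9), probe=1.4, n_points=960)
        assert a[0] == 0.0

    @pytest.mark.parametrize("n_atoms", [2, 5, 10])
    def test_matches_grid_oracle_within_two_percent(self, n_atoms):
        rng = np.random.default_rng(n_atoms)
        coords = rng.uniform(-2.5, 2.5, (n_atoms, 3))
        radii = rng.uniform(1.4, 1.9, n_atoms)
        impl = shrake_rupley(coords, radii, probe=1.4, n_points=960)
        oracle = sasa_grid_oracle(coords, radii, probe=1.4, arc=0.1)
        np.testing.assert_allclose(impl, oracle, rtol=0.02, atol=0.5)

    def test_agrees_with_independent_library_implementation(self, closed_layer):
        """Cross-check against biotite's Shrake-Rupley on a real-size layer."""
        biotite_struc = pytest.importorskip("biotite.structure")
        n = closed_layer.n_atoms
        arr = biotite_struc.AtomArray(n)
        arr.coord = closed_layer.coords().astype(np.float32)
        arr.element = np.array([a.element for a in closed_layer.atoms])
        arr.atom_name = np.array([a.name for a in closed_layer.atoms])
        arr.res_name = np.array([a.residue_name for a in closed_layer.atoms])
        arr.res_id = np.array([a.residue_number for a in closed_layer.atoms])
        arr.chain_id = np.array(["A"] * n)
        ref = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=1000,
            vdw_radii=closed_layer.radii(),
        )
        mine = shrake_rupley(
            closed_layer.coords(), closed_layer.radii(), probe=1.4, n_points=1000
        )
        assert float(np.abs(mine - ref).mean()) < 0.5  # A^2 per atom

    def test_quadrature_convergence_under_doubling(self, closed_layer):
        c, r = closed_layer.coords(), closed_layer.radii()
        a1 = shrake_rupley(c, r, n_points=480).sum()
        a2 = shrake_rupley(c, r, n_points=960).sum()
        assert abs(a2 - a1) / a2 < 0.005

    def test_coincident_atoms_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(DegenerateInputError):
            shrake_rupley(coords, np.array([1.9, 1.9]))


class TestBuriedArea:
    def test_isolated_layer_zero_burial(self):
        layer = make_layer(small_layer_spec())
        dA, _ = buried_area(layer, 0, n_points=480)
        np.testing.assert_allclose(dA, 0.0, atol=1e-9)

    def test_stacking_buries_area_and_is_monotone_per_atom(self):
        # the same central layer scored alone, in a 3-layer sub-stack, and
        # in the full 5-stack: per-atom SASA never grows with more context
        layer = make_layer(small_layer_spec())
        s5 = expand_symmetry(layer, HelicalParameters(-1.3, 4.8), 5)
        central = s5.layer(2)
        sub3 = s5.with_atoms(a for a in s5.atoms if 1 <= a.layer_index <= 3)
        pos = {a.position: i for i, a in enumerate(sub3.atoms)}
        idx3 = np.array([pos[a.position] for a in central.atoms])
        a_iso = shrake_rupley(central.coords(), central.radii(), n_points=480)
        a3 = shrake_rupley(sub3.coords(), sub3.radii(), n_points=480)[idx3]
        a5 = shrake_rupley(s5.coords(), s5.radii(), n_points=480)[s5.layer_indices(2)]
        assert np.all(a3 <= a_iso + 1e-9)
        assert np.all(a5 <= a3 + 1e-9)
        dA, _ = buried_area(s5, 2, n_points=480)
        assert dA.sum() > 0
        assert np.all(dA <= a_iso + 1e-9)  # never bury more than the reference

    def test_boundary_layer_warns(self):
        layer = make_layer(small_layer_spec())
        stack = expand_symmetry(layer, HelicalParameters(-1.3, 4.8), 3)
        _, warnings = buried_area(stack, 0, n_points=120)
        assert warnings and "boundary" in warnings[0]

    def test_central_burial_converges_from_5_to_7_layers(self):
        layer = make_layer(small_layer_spec())
        params = HelicalParameters(-1.3, 4.8)
        asp = load_asp_table()
        e5 = stabilization_energy(
            expand_symmetry(layer, params, 5), asp, n_points=480
        ).chain_energy
        e7 = stabilization_energy(
            expand_symmetry(layer, params, 7), asp, n_points=480
        ).chain_energy
        assert abs(e7 - e5) / abs(e7) < 0.01


class TestStabilizationEnergy:
    def test_zero_asp_gives_zero_energy(self, small_fibril):
        zero = ASPTable({k: 0.0 for k in load_asp_table().classes}, "zero")
        prof = stabilization_energy(small_fibril, zero, n_points=240)
        assert prof.chain_energy == 0.0
        assert (prof.per_atom["energy_kcal_mol"] == 0).all()

    def test_additivity_atom_residue_chain(self, small_fibril):
        prof = stabilization_energy(small_fibril, n_points=240)
        total_atoms = prof.per_atom["energy_kcal_mol"].sum()
        total_residues = prof.per_residue.sum()
        assert prof.chain_energy == pytest.approx(total_atoms, rel=1e-9)
        assert prof.chain_energy == pytest.approx(total_residues, rel=1e-9)

    def test_burial_of_apolar_carbon_is_stabilizing(self, small_fibril):
        """All-carbon-dominated backbone burial must come out negative."""
        prof = stabilization_energy(small_fibril, n_points=240)
        assert prof.chain_energy < 0

    def test_single_layer_expands_via_helical_params(self):
        layer = make_layer(small_layer_spec())
        layer.helical = HelicalParameters(-1.3, 4.8)
        prof = stabilization_energy(layer, stack_layers=5, n_points=240)
        assert prof.context["stack_layers"] == 5
        assert prof.context["scored_layer"] == 2
        assert prof.chain_energy < 0

    def test_single_layer_without_params_fails(self):
        layer = make_layer(small_layer_spec())
        with pytest.raises(ModelError):
            stabilization_energy(layer, stack_layers=5, n_points=240)

    def test_missing_sigma_names_the_atom(self, small_fibril):
        bad = ASPTable({"C_APOLAR": 16.0}, "incomplete")
        with pytest.raises(ASPConfigError, match=r"N_O_NEUTRAL"):
            stabilization_energy(small_fibril, bad, n_points=120)

    def test_reference_choice_recorded_in_context(self, small_fibril):
        prof = stabilization_energy(
            small_fibril, reference="FULLY_EXTENDED", n_points=240
        )
        assert prof.context["reference"] == "FULLY_EXTENDED"


class TestHandSummedFixture:
    def test_three_residue_fixture_matches_pipeline(self):
        """Sum(dA_i * sigma_i) accumulated by hand equals the pipeline."""
        from dataclasses import replace

        layer = make_layer(small_layer_spec())
        three = layer.with_atoms(
            a for a in layer.atoms if a.residue_number in (11, 12, 13)
        )
        stack = expand_symmetry(three, HelicalParameters(-1.3, 4.8), 3)
        prof = stabilization_energy(stack, n_points=480)

        # independent accumulation: plain python loops over raw SASA calls
        asp = load_asp_table()
        full = shrake_rupley(stack.coords(), stack.radii(), 1.4, 480)
        central = stack.layer(1)
        alone = shrake_rupley(central.coords(), central.radii(), 1.4, 480)
        idx = stack.layer_indices(1)
        hand_total = 0.0
        for k, a in enumerate(central.atoms):
            dA = alone[k] - full[idx[k]]
            hand_total += -asp.sigma(a) * dA / 1000.0
        assert prof.chain_energy == pytest.approx(hand_total, abs=1e-6)


class TestResidueEnergyColormap:
    def test_all_zero_profile_lands_in_single_neutral_bin(self, small_fibril):
        zero = ASPTable({k: 0.0 for k in load_asp_table().classes}, "zero")
        prof = stabilization_energy(small_fibril, zero, n_points=120)
        table = residue_energy_colormap(prof)
        assert table["bin"].nunique() == 1
        assert table["color"].iloc[0] == "#f7f7f7"

    def test_monotone_energies_monotone_bins(self, small_fibril):
        prof = stabilization_energy(small_fibril, n_points=240)
        prof.per_residue.iloc[:] = np.linspace(-4.0, 2.5, len(prof.per_residue))
        table = residue_energy_colormap(prof)
        assert (np.diff(table["bin"]) >= 0).all()
        assert table["bin"].iloc[0] == 0 and table["bin"].iloc[-1] == 5

    def test_custom_bin_edges_echoed(self, small_fibril):
        prof = stabilization_energy(small_fibril, n_points=240)
        palette = {"edges_kcal_mol": [-1.0, 0.0], "colors": ["r", "w", "b"]}
        table = residue_energy_colormap(prof, palette)
        assert set(table["color"]) <= {"r", "w", "b"}
        neg = table.loc[table["energy_kcal_mol"] < -1.0, "color"]
        assert (neg == "r").all()
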