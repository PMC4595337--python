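import numpy as np
import pytest

from discons.disorder import DisorderProfile
from discons.errors import InputError
from discons.io_formats import Atom, Chain, Residue, StructureModel
from discons.structure_analysis import (
    FlexibilityCall,
    assign_secondary_structure,
    classify_flexibility,
    compute_surface_areas,
    count_partners,
    disordered_region_ss_fractions,
    find_interface_residues,
    regular_fraction,
    shrake_rupley,
)
from discons.synthetic_data import ComplexSpec, extended_chain, generate_complex, ideal_alpha_helix

from conftest import brute_force_pair_counts


def single_atom_residue(i, xyz, name="X1"):
    return Residue(i, "ALA", [Atom(name, "C", np.asarray(xyz, float))])


def make_two_chain(protein_atoms, rna_atoms):
    """protein_atoms: list of lists of xyz per residue; rna_atoms: list of xyz."""
    prot = [Residue(i, "ALA", [Atom(f"X{k}", "C", np.asarray(p, float))
                               for k, p in enumerate(atoms)])
            for i, atoms in enumerate(protein_atoms)]
    rna = [Residue(j, "U", [Atom("P", "P", np.asarray(p, float))])
           for j, p in enumerate(rna_atoms)]
    return StructureModel(1, [Chain("A", "protein", prot), Chain("B", "rna", rna)])


class TestInterface:
    def test_distant_chains_have_empty_interface(self):
        st = make_two_chain([[(0, 0, 0)]], [(100.0, 0, 0)])
        result = find_interface_residues(st, "A", "B")
        assert result.interface_residues == set()
        assert result.interface_fraction == 0.0

    def test_five_pair_boundary_is_inclusive(self):
        # residue 0: exactly 5 atoms at 4.9 A from one RNA atom -> interface
        # residue 1: only 4 such atoms -> not interface
        five = [(4.9 * np.cos(a), 4.9 * np.sin(a), 0.0)
                for a in np.linspace(0, np.pi, 5)]
        four = [(50 + 4.9 * np.cos(a), 4.9 * np.sin(a), 0.0)
                for a in np.linspace(0, np.pi, 4)]
        st = make_two_chain([five, four], [(0, 0, 0), (50, 0, 0)])
        result = find_interface_residues(st, "A", "B")
        assert result.interface_residues == {0}
        assert result.atom_pair_count.tolist() == [5, 4]

    def test_exactly_at_cutoff_counts(self):
        atoms = [(5.0, 0, 0)] * 5
        st = make_two_chain([atoms], [(0, 0, 0)])
        assert find_interface_residues(st, "A", "B").interface_residues == {0}

    def test_planted_interface_recovered_exactly(self, planted_complex):
        structure, truth = planted_complex
        result = find_interface_residues(structure, "A", "B")
        assert result.interface_residues == truth["interface_residues"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        planted = set(rng.choice(40, size=rng.integers(1, 8), replace=False).tolist())
        spec = ComplexSpec(40, 30, planted, contact_atoms_per_residue=int(rng.integers(5, 9)),
                           seed=seed)
        structure, _ = generate_complex(spec)
        fast = find_interface_residues(structure, "A", "B")
        brute = brute_force_pair_counts(structure, "A", "B")
        assert fast.atom_pair_count.tolist() == brute.tolist()

    def test_missing_chain_is_error(self, planted_complex):
        with pytest.raises(InputError):
            find_interface_residues(planted_complex[0], "A", "Z")


class TestPartners:
    def test_isolated_chain_has_no_partner(self):
        st = make_two_chain([[(0, 0, 0)]], [(100.0, 0, 0)])
        assert count_partners(st, "A") == 0

    def test_three_chain_complex_counts_only_touching(self):
        spec = ComplexSpec(30, 20, {2, 5, 8, 11, 14, 17}, seed=2,
                           decoy_protein_chain=True)
        st, _ = generate_complex(spec)
        assert count_partners(st, "A") == 1
        assert count_partners(st, "C") == 0

    def test_atom_distance_relation_symmetric(self):
        spec = ComplexSpec(30, 30, {0, 4, 8, 12, 16, 20}, seed=3)
        st, _ = generate_complex(spec)
        # 6 residues of A touch B and >= 6 nucleotides of B touch A
        assert count_partners(st, "A") == 1
        assert count_partners(st, "B") == 1

    def test_invariant_to_chain_order(self):
        spec = ComplexSpec(30, 20, {2, 5, 8, 11, 14, 17}, seed=2,
                           decoy_protein_chain=True)
        st, _ = generate_complex(spec)
        reordered = StructureModel(1, list(reversed(st.chains)))
        assert count_partners(reordered, "A") == count_partners(st, "A")


class TestSASA:
    def test_two_sphere_buried_area_matches_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([1.7, 1.7])
        areas = shrake_rupley(coords, radii, n_points=960)
        R, d = 1.7 + 1.4, 3.0
        cap = 2 * np.pi * R * (R - d / 2)           # buried spherical cap
        expected = 4 * np.pi * R**2 - cap
        for a in areas:
            assert abs(a - expected) / expected < 0.02

    def test_960_points_agree_with_10x_density(self):
        helix_a = ideal_alpha_helix(10, chain_id="A")
        helix_b = ideal_alpha_helix(10, chain_id="B", offset=(0, 0, 6.0))
        st = StructureModel(1, [helix_a, helix_b])
        coarse = compute_surface_areas(st, "A", n_points=960)
        fine = compute_surface_areas(st, "A", n_points=9600)
        assert abs(coarse.interface_area - fine.interface_area) / fine.interface_area < 0.02

    def test_distant_chains_bury_nothing(self):
        a = ideal_alpha_helix(8, chain_id="A")
        b = ideal_alpha_helix(8, chain_id="B", offset=(0, 0, 100.0))
        st = StructureModel(1, [a, b])
        areas = compute_surface_areas(st, "A")
        assert abs(areas.interface_area) < 1.0

    def test_symmetric_dimer_interfaces_equal(self):
        a = ideal_alpha_helix(12, chain_id="A")
        b = ideal_alpha_helix(12, chain_id="B", offset=(0, 0, 6.0))
        st = StructureModel(1, [a, b])
        ia = compute_surface_areas(st, "A").interface_area
        ib = compute_surface_areas(st, "B").interface_area
        assert ia > 50.0                       # the dimer really buries surface
        assert ia == pytest.approx(ib, abs=1e-6)

    def test_single_chain_warns_and_reports_zero_interface(self):
        st = StructureModel(1, [ideal_alpha_helix(8, chain_id="A")])
        with pytest.warns(UserWarning):
            areas = compute_surface_areas(st, "A")
        assert areas.interface_area == pytest.approx(0.0)


class TestFlexibility:
    @pytest.mark.parametrize("asa,iface,side", [
        (30.0, 10.0, "ordered"),
        (70.0, 40.0, "disordered_folding_upon_binding"),
        (40.0, 40.0, "disordered_folding_upon_binding"),   # boundary inclusive
    ])
    def test_threshold_line_of_80(self, asa, iface, side):
        from discons.structure_analysis import SurfaceAreas
        areas = SurfaceAreas("A", 1, asa, 0.0, asa - 2 * iface)
        call = classify_flexibility(areas)
        assert isinstance(call, FlexibilityCall)
        assert call.asa_per_residue == asa and call.interface_per_residue == iface
        assert call.side == side


class TestSecondaryStructure:
    def test_ideal_alpha_helix_interior(self):
        st = StructureModel(1, [ideal_alpha_helix(20)])
        labels = assign_secondary_structure(st, "A")
        assert all(l == "helix_alpha" for l in labels[2:17])

    def test_extended_isolated_chain_has_no_regular_structure(self):
        st = StructureModel(1, [extended_chain(20)])
        labels = assign_secondary_structure(st, "A")
        assert not any(l in ("helix_alpha", "helix_310", "strand") for l in labels)

    def test_nucleic_chain_rejected(self, planted_complex):
        with pytest.raises(InputError):
            assign_secondary_structure(planted_complex[0], "B")

    def test_regular_fraction_hand_count(self):
        labels = ["helix_alpha"] * 2 + ["helix_310"] + ["strand"] * 2 + ["turn"] * 3 \
            + ["unclassified"] * 2
        assert regular_fraction(labels) == pytest.approx(0.5)


class TestDisorderedSSFractions:
    def test_hand_count(self):
        labels = ["helix_alpha", "strand", "turn", "turn", "unclassified"]
        profile = DisorderProfile("x", [0.9, 0.9, 0.9, 0.9, 0.1])
        helix, strand, regular = disordered_region_ss_fractions(labels, profile)
        assert (helix, strand, regular) == (0.25, 0.25, 0.5)

    def test_all_turn_gives_zeroes(self):
        profile = DisorderProfile("x", [0.9, 0.9])
        assert disordered_region_ss_fractions(["turn", "turn"], profile) == (0, 0, 0)

    def test_no_disordered_residues_reported_missing(self):
        profile = DisorderProfile("x", [0.1, 0.1])
        result = disordered_region_ss_fractions(["turn", "turn"], profile)
        assert all(np.isnan(v) for v in result)
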