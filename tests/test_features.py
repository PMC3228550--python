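"""Per-residue descriptors and patch feature vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epitopepatch.features import (BLOSUM62_DIAG, PSSM_ALPHABET, PSSMProfile,
                                   ard_weights, assemble_patch_vector,
                                   chain_conservation, composition_feature,
                                   conservation_scores, contact_number,
                                   read_pssm, vector_header)
from epitopepatch.patches import ResiduePatch, enumerate_patches
from epitopepatch.structure import Atom, Residue, Structure
from epitopepatch.surface import SurfaceAnnotation
from epitopepatch.synthetic import generate_pssm


def _patch(distances, central=("A", 1, "")):
    adjacent = [(("A", i + 2, ""), float(d), True)
                for i, d in enumerate(sorted(distances))]
    return ResiduePatch(central=central, adjacent=adjacent, mode="thick",
                        size=len(distances) + 1)


class TestArdWeights:
    def test_equidistant_neighbours_share_weight_equally(self):
        s = ard_weights(_patch([2.0, 2.0, 2.0, 2.0]))
        np.testing.assert_allclose(s, 0.25)

    def test_two_neighbour_printed_formula(self):
        s = ard_weights(_patch([1.0, 3.0]))
        np.testing.assert_allclose(s, [0.75, 0.25])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.5, max_value=30.0), min_size=2,
                    max_size=19))
    def test_normalisation_and_strict_monotonicity(self, distances):
        patch = _patch(distances)
        s = ard_weights(patch)
        # independent re-evaluation of the normalised inverse distances
        p = 1.0 / patch.distances
        np.testing.assert_allclose(s, p / p.sum(), atol=1e-12)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        d = patch.distances
        for i in range(len(d) - 1):
            if d[i] < d[i + 1]:
                assert s[i] > s[i + 1]

    def test_zero_distance_is_hard_error(self):
        patch = ResiduePatch(central=("A", 1, ""),
                             adjacent=[(("A", 2, ""), 0.0, True)],
                             mode="thick", size=2)
        with pytest.raises(ValueError, match="non-positive"):
            ard_weights(patch)


class TestConservation:
    def test_score_zero_at_and_above_the_diagonal(self):
        pssm = PSSMProfile(sequence="W", scores=np.full((1, 20), 12.0))
        assert conservation_scores(pssm)[0] == 0.0  # 12 >= B_WW = 11

    def test_deficit_below_diagonal(self):
        scores = np.zeros((1, 20))
        scores[0, PSSM_ALPHABET.index("A")] = 1
        pssm = PSSMProfile(sequence="A", scores=scores)
        assert conservation_scores(pssm)[0] == 3.0  # |1 - 4|

    def test_full_grid_against_rule(self):
        for aa in PSSM_ALPHABET:
            b = BLOSUM62_DIAG[aa]
            for m in range(-5, 16):
                scores = np.zeros((1, 20))
                scores[0, PSSM_ALPHABET.index(aa)] = m
                got = conservation_scores(PSSMProfile(sequence=aa, scores=scores))[0]
                assert got == (abs(m - b) if m < b else 0.0)

    def test_blosum_diagonal_matches_biopython(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        for aa, value in BLOSUM62_DIAG.items():
            assert blosum[aa, aa] == value


class TestPSSMReader:
    def test_generated_pssm_roundtrip(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        text = generate_pssm(seq, conserved_positions=set(range(0, 20, 2)), seed=5)
        pssm = read_pssm(text)
        assert pssm.sequence == seq
        assert pssm.scores.shape == (20, 20)
        scores = conservation_scores(pssm)
        assert all(scores[i] == 0.0 for i in range(0, 20, 2))
        assert all(scores[i] > 0.0 for i in range(1, 20, 2))

    def test_forty_column_variant_uses_first_twenty(self):
        text = generate_pssm("AC", conserved_positions={0}, seed=0)
        lines = text.splitlines()
        out = []
        for line in lines:
            fields = line.split()
            if fields and fields[0].isdigit():
                line = line + "  " + "  ".join(["50"] * 20)
            out.append(line)
        wide = read_pssm("\n".join(out))
        assert np.array_equal(wide.scores, read_pssm(text).scores)

    def test_garbage_input_is_error(self):
        with pytest.raises(ValueError, match="PSSM"):
            read_pssm("not a matrix\nat all\n")


class TestComposition:
    def test_even_two_type_split(self):
        res = {}
        for i in range(20):
            res[("A", i + 1, "")] = "ALA" if i < 10 else "GLY"
        structure = Structure(
            id="t", roles={"A": "antigen"},
            chains={"A": [Residue(chain_id="A", seq_pos=(i + 1, ""), aa_type=aa,
                                  atoms=[Atom(name="CA", element="C",
                                              coord=[float(i), 0, 0])])
                          for i, aa in enumerate(res.values())]})
        patch = ResiduePatch(central=("A", 1, ""),
                             adjacent=[(("A", i + 2, ""), float(i + 1), True)
                                       for i in range(19)],
                             mode="thick", size=20)
        values = composition_feature(patch, structure)
        np.testing.assert_allclose(values, 0.5)

    def test_matches_counting_oracle_on_fixture(self, fixture_structure,
                                                fixture_patches):
        patch = fixture_patches[0]
        values = composition_feature(patch, fixture_structure)
        types = [fixture_structure.get_residue(rid).aa_type
                 for rid in patch.residue_ids]
        for value, aa in zip(values, types):
            assert value == pytest.approx(types.count(aa) / patch.size)


class TestContactNumber:
    def test_isolated_residue_has_no_contacts(self):
        s = Structure(id="t", roles={"A": "antigen"},
                      chains={"A": [Residue(chain_id="A", seq_pos=(1, ""),
                                            aa_type="ALA",
                                            atoms=[Atom(name="CA", element="C",
                                                        coord=[0, 0, 0])])]})
        assert contact_number(s, ("A", 1, "")) == 0

    def test_pair_below_threshold_counts_once_each(self):
        residues = [Residue(chain_id="A", seq_pos=(i + 1, ""), aa_type="ALA",
                            atoms=[Atom(name="CA", element="C",
                                        coord=[i * 9.9, 0, 0])])
                    for i in range(2)]
        s = Structure(id="t", chains={"A": residues}, roles={"A": "antigen"})
        assert contact_number(s, ("A", 1, "")) == 1
        assert contact_number(s, ("A", 2, "")) == 1

    def test_matches_bruteforce_scan(self, fixture_structure):
        antigen = fixture_structure.antigen_residues()
        for res in antigen[:10]:
            ca = res.atom("CA").coord
            brute = sum(
                1 for other in antigen if other.id != res.id
                and np.linalg.norm(other.atom("CA").coord - ca) < 10.0)
            assert contact_number(fixture_structure, res.id) == brute


class TestAssembly:
    @pytest.mark.parametrize("n,expected", [(12, 84), (20, 140)])
    def test_vector_length_is_seven_per_residue(self, n, expected,
                                                fixture_structure,
                                                fixture_annotations):
        patches = enumerate_patches(fixture_structure, fixture_annotations, n=n)
        conservation = {r.id: 1.0 for r in fixture_structure.antigen_residues()}
        vec = assemble_patch_vector(patches[0], fixture_structure,
                                    fixture_annotations, conservation)
        assert vec.shape == (expected,)
        assert len(vector_header(n)) == expected

    def test_hand_built_expectation_table(self):
        residues = [
            Residue(chain_id="A", seq_pos=(1, ""), aa_type="ALA",
                    atoms=[Atom(name="CA", element="C", coord=[0, 0, 0])]),
            Residue(chain_id="A", seq_pos=(2, ""), aa_type="ALA",
                    atoms=[Atom(name="CA", element="C", coord=[1, 0, 0])]),
            Residue(chain_id="A", seq_pos=(3, ""), aa_type="GLY",
                    atoms=[Atom(name="CA", element="C", coord=[3, 0, 0])]),
        ]
        s = Structure(id="t", chains={"A": residues}, roles={"A": "antigen"})
        ann = {
            ("A", 1, ""): SurfaceAnnotation(40.0, 0.4, True, "helix"),
            ("A", 2, ""): SurfaceAnnotation(30.0, 0.3, True, "sheet"),
            ("A", 3, ""): SurfaceAnnotation(20.0, 0.2, True, "coil"),
        }
        conservation = {("A", 1, ""): 2.0, ("A", 2, ""): 0.0, ("A", 3, ""): 5.0}
        patch = ResiduePatch(central=("A", 1, ""),
                             adjacent=[(("A", 2, ""), 1.0, True),
                                       (("A", 3, ""), 3.0, True)],
                             mode="thick", size=3)
        vec = assemble_patch_vector(patch, s, ann, conservation)
        expected = [
            0.4, 2.0, 0.0, 2 / 3, 1, 0, 0,      # central ALA, helix
            0.3, 0.0, 0.75, 2 / 3, 0, 1, 0,     # nearest ALA at d=1, sheet
            0.2, 5.0, 0.25, 1 / 3, 0, 0, 1,     # GLY at d=3, coil
        ]
        np.testing.assert_allclose(vec, expected, atol=1e-12)

    def test_one_hot_and_ard_invariants_on_fixture(self, fixture_structure,
                                                   fixture_annotations,
                                                   fixture_patches):
        conservation = {r.id: 0.5 for r in fixture_structure.antigen_residues()}
        vec = assemble_patch_vector(fixture_patches[0], fixture_structure,
                                    fixture_annotations, conservation)
        per = vec.reshape(-1, 7)
        np.testing.assert_allclose(per[:, 4:].sum(axis=1), 1.0)
        assert per[0, 2] == 0.0  # central ARD sentinel
        assert per[1:, 2].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.isfinite(vec))

    def test_contact_number_column_appended_when_requested(
            self, fixture_structure, fixture_annotations, fixture_patches):
        conservation = {r.id: 0.0 for r in fixture_structure.antigen_residues()}
        vec = assemble_patch_vector(fixture_patches[0], fixture_structure,
                                    fixture_annotations, conservation,
                                    include_contact_number=True)
        assert vec.shape == (8 * 20,)
        header = vector_header(20, include_contact_number=True)
        assert header[7] == "c_contact_number"

    def test_missing_conservation_names_residue(self, fixture_structure,
                                                fixture_annotations,
                                                fixture_patches):
        with pytest.raises(KeyError, match="conservation"):
            assemble_patch_vector(fixture_patches[0], fixture_structure,
                                  fixture_annotations, conservation={})

    def test_chain_conservation_requires_matching_sequence(self, fixture_structure):
        n = len(fixture_structure.antigen_residues())
        wrong = PSSMProfile(sequence="A" * (n + 1),
                            scores=np.zeros((n + 1, 20)))
        with pytest.raises(ValueError, match="does not match"):
            chain_conservation(fixture_structure, {"A": wrong})
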