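import math

import numpy as np
import pytest

from intercoev import contacts as ct
from intercoev import simulate as sim
from intercoev.errors import MappingError

from conftest import make_msa


def write_pdb(path, atoms):
    """atoms: list of (name, resname, chain, resseq, x, y, z)."""
    with open(path, "w") as fh:
        for serial, (name, resname, chain, resseq, x, y, z) in enumerate(atoms, 1):
            fh.write(
                f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}\n"
            )
        fh.write("END\n")


@pytest.fixture
def two_residue_model(tmp_path):
    path = tmp_path / "pair.pdb"
    write_pdb(
        path,
        [
            ("CA", "ALA", "A", 1, 0.0, -1.5, 0.0),
            ("CB", "ALA", "A", 1, 0.0, 0.0, 0.0),
            ("CA", "ALA", "B", 1, 0.0, 0.0, 9.4),
            ("CB", "ALA", "B", 1, 0.0, 0.0, 7.9),
        ],
    )
    return ct.read_structure(path)


class TestDistances:
    def test_cbeta_euclidean(self, two_residue_model):
        d = ct.residue_distance(two_residue_model, "A", (1, ""), "B", (1, ""), "cbeta")
        assert d == pytest.approx(7.9)

    def test_symmetry(self, two_residue_model):
        d1 = ct.residue_distance(two_residue_model, "A", (1, ""), "B", (1, ""), "cbeta")
        d2 = ct.residue_distance(two_residue_model, "B", (1, ""), "A", (1, ""), "cbeta")
        assert d1 == pytest.approx(d2)

    def test_glycine_falls_back_to_calpha(self, tmp_path):
        path = tmp_path / "gly.pdb"
        write_pdb(
            path,
            [
                ("CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
                ("CA", "ALA", "B", 1, 0.0, 0.0, 6.5),
                ("CB", "ALA", "B", 1, 0.0, 0.0, 5.0),
            ],
        )
        model = ct.read_structure(path)
        d = ct.residue_distance(model, "A", (1, ""), "B", (1, ""), "cbeta")
        assert d == pytest.approx(5.0)

    def test_min_heavy_at_most_cbeta(self, two_residue_model):
        d_cb = ct.residue_distance(two_residue_model, "A", (1, ""), "B", (1, ""), "cbeta")
        d_min = ct.residue_distance(
            two_residue_model, "A", (1, ""), "B", (1, ""), "min_heavy"
        )
        assert d_min <= d_cb + 1e-9

    def test_missing_residue_masked(self, two_residue_model):
        d = ct.residue_distance(two_residue_model, "A", (99, ""), "B", (1, ""), "cbeta")
        assert math.isnan(d)


class TestEquivalentChains:
    @pytest.fixture
    def tetramer_model(self, tmp_path):
        path = tmp_path / "tet.pdb"
        write_pdb(
            path,
            [
                ("CB", "ALA", "A", 1, 0.0, 0.0, 0.0),
                ("CB", "ALA", "B", 1, 0.0, 0.0, 9.2),
                ("CB", "ALA", "D", 1, 0.0, 0.0, 7.5),
            ],
        )
        return ct.read_structure(path)

    def test_minimum_over_chain_pairs(self, tetramer_model):
        d = ct.min_over_equivalent_chains(
            tetramer_model, ["A"], ["B", "D"], (1, ""), (1, "")
        )
        assert d == pytest.approx(7.5)

    def test_single_chain_reduces_to_plain_distance(self, tetramer_model):
        d = ct.min_over_equivalent_chains(tetramer_model, ["A"], ["B"], (1, ""), (1, ""))
        assert d == pytest.approx(9.2)

    def test_empty_group_error(self, tetramer_model):
        with pytest.raises(ValueError):
            ct.min_over_equivalent_chains(tetramer_model, [], ["B"], (1, ""), (1, ""))


class TestMapping:
    def make_model(self, tmp_path, seq, chain="A", start=1):
        aa3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
               "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU"}
        atoms = []
        for i, aa in enumerate(seq):
            atoms.append(("CA", aa3[aa], chain, start + i, float(3 * i), 0.0, 0.0))
        path = tmp_path / "map.pdb"
        write_pdb(path, atoms)
        return ct.read_structure(path)

    def test_identity_mapping_on_matching_sequence(self, tmp_path):
        msa = make_msa(["ACDEFGHIKL", "ACDEFGH-KL"])
        model = self.make_model(tmp_path, "ACDEFGHIKL")
        mapping = ct.map_columns_to_residues(msa, "s1", model, "A")
        assert mapping.mapped_columns == list(range(1, 11))
        assert mapping[1] == (1, "") and mapping[10] == (10, "")

    def test_truncated_chain_shifts_mapping(self, tmp_path):
        msa = make_msa(["ACDEFGHIKL"])
        model = self.make_model(tmp_path, "DEFGHIKL", start=3)
        mapping = ct.map_columns_to_residues(msa, "s1", model, "A")
        assert 1 not in mapping and 2 not in mapping
        assert mapping[3] == (3, "")
        assert mapping[10] == (10, "")

    def test_gap_columns_unmapped(self, tmp_path):
        msa = make_msa(["AC-EFGHIKL", "ACDEFGHIKL"])
        model = self.make_model(tmp_path, "ACEFGHIKL")
        mapping = ct.map_columns_to_residues(msa, "s1", model, "A")
        assert 3 not in mapping
        assert mapping[4] == (3, "")

    def test_wrong_protein_identity_floor(self, tmp_path):
        msa = make_msa(["LLLLLLLLLL"])
        model = self.make_model(tmp_path, "ACDEFGHIKA")
        with pytest.raises(MappingError):
            ct.map_columns_to_residues(msa, "s1", model, "A")


class TestLabelContacts:
    @pytest.fixture
    def toy(self, tmp_path):
        path = tmp_path / "toy.pdb"
        truth = [(1, 2), (3, 1)]
        sim.toy_structure(truth, L_A=4, L_B=3, path=path)
        return ct.read_structure(path), truth

    def test_recovers_planted_contacts(self, toy):
        model, truth = toy
        cmap = ct.label_contacts(
            ct.identity_mapping(4, "A"), ct.identity_mapping(3, "B"), model, 4, 3
        )
        positives = {(i + 1, j + 1) for i, j in zip(*np.nonzero(cmap.labels))}
        assert positives == set(truth)

    def test_exact_8A_pair_is_negative(self, tmp_path):
        path = tmp_path / "edge.pdb"
        write_pdb(
            path,
            [
                ("CB", "ALA", "A", 1, 0.0, 0.0, 0.0),
                ("CB", "ALA", "B", 1, 0.0, 0.0, 8.0),
                ("CB", "ALA", "A", 2, 100.0, 0.0, 0.0),
                ("CB", "ALA", "B", 2, 100.0, 0.0, 7.999),
            ],
        )
        model = ct.read_structure(path)
        cmap = ct.label_contacts(
            ct.identity_mapping(2, "A"), ct.identity_mapping(2, "B"), model, 2, 2
        )
        assert not cmap.labels[0, 0]  # 8.000 A: strictly less-than fails
        assert cmap.labels[1, 1]      # 7.999 A passes

    def test_functional_definition_requires_listed_residue(self, toy):
        model, truth = toy
        functional = {("A", 1)}  # only the first planted pair involves residue A:1
        cmap = ct.label_contacts(
            ct.identity_mapping(4, "A"),
            ct.identity_mapping(3, "B"),
            model, 4, 3,
            definition="cbeta8+functional",
            functional_residues=functional,
        )
        positives = {(i + 1, j + 1) for i, j in zip(*np.nonzero(cmap.labels))}
        assert positives == {(1, 2)}

    def test_unknown_definition_error(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            ct.label_contacts(
                ct.identity_mapping(4, "A"), ct.identity_mapping(3, "B"),
                model, 4, 3, definition="cbeta9",
            )

    def test_threshold_monotonicity(self, toy):
        model, _ = toy
        cmap8 = ct.label_contacts(
            ct.identity_mapping(4, "A"), ct.identity_mapping(3, "B"), model, 4, 3
        )
        stricter = cmap8.distances < 4.0
        assert np.all(cmap8.labels[stricter])


class TestViewerAttributes:
    def test_roundtrip(self, tmp_path):
        values = {("A", 5): 1.5, ("A", 7): -0.25, ("B", 2): 3.0}
        path = tmp_path / "attrs.txt"
        ct.write_viewer_attributes(values, path, attribute="neglog10P")
        name, back = ct.read_viewer_attributes(path)
        assert name == "neglog10P"
        assert back == values

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "attrs.txt"
        ct.write_viewer_attributes({}, path)
        name, back = ct.read_viewer_attributes(path)
        assert back == {}
        assert path.read_text().startswith("attribute:")

    def test_significance_transform_monotone(self, tmp_path):
        pvals = {("A", 1): 0.5, ("A", 2): 0.01, ("A", 3): 1e-6}
        values = {k: -math.log10(v) for k, v in pvals.items()}
        path = tmp_path / "attrs.txt"
        ct.write_viewer_attributes(values, path)
        _, back = ct.read_viewer_attributes(path)
        ordered = sorted(pvals, key=lambda k: pvals[k])
        assert [back[k] for k in ordered] == sorted(back.values(), reverse=True)
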