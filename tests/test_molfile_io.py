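"""Connection-table I/O: parsing, writing, SD/RXN handling, tweak dialect."""

import io

import pytest

from molpat.fixtures import GeneratorParams, generate_molecule
from molpat.molfile_io import (BondOrder, MolfileError, SDFileError,
                               iter_rdfile, iter_sdfile, parse_molfile,
                               parse_rxnfile, write_molfile, write_rxnfile,
                               write_sdfile)
from molpat.perception import molecule_from_document, perceive


def graph_signature(doc):
    atoms = [(a.element, a.charge, a.isotope_delta) for a in doc.atoms]
    bonds = sorted((min(b.a1, b.a2), max(b.a1, b.a2), int(b.order), int(b.stereo))
                   for b in doc.bonds)
    return atoms, bonds


class TestParseMolfile:
    def test_ethyl_acetate_figure(self, molfiles):
        doc = parse_molfile(molfiles["ethyl_acetate"])
        assert doc.n_atoms == 6
        assert doc.n_bonds == 5
        assert sum(1 for b in doc.bonds if b.order == BondOrder.DOUBLE) == 1

    def test_benzene_counts(self, molfiles):
        doc = parse_molfile(molfiles["benzene_kekule_a"])
        assert (doc.n_atoms, doc.n_bonds) == (6, 6)

    def test_properties_block_supersedes_atom_charge(self):
        # atom-block codes 3 (+1) on atom 1; M CHG gives -1 on atom 2 and
        # resets every atom-block charge per the format rules
        text = (
            "test\n\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 N   0  3  0  0  0  0  0  0  0  0  0  0\n"
            "    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "  1  2  1  0\n"
            "M  CHG  1   2  -1\n"
            "M  END\n")
        doc = parse_molfile(text)
        assert doc.atoms[0].charge == 0
        assert doc.atoms[1].charge == -1

    @pytest.mark.parametrize("mangle, fragment", [
        (lambda t: t.replace("V2000", "V3000"), "V3000"),
        (lambda t: "\n".join(t.splitlines()[:6]), "truncated"),
        (lambda t: t.replace(t.splitlines()[3], "  x  5"), "counts"),
    ])
    def test_malformed_input_names_the_problem(self, molfiles, mangle, fragment):
        with pytest.raises(MolfileError) as err:
            parse_molfile(mangle(molfiles["ethyl_acetate"]))
        assert fragment.lower() in str(err.value).lower()

    def test_error_carries_line_number(self, molfiles):
        text = molfiles["ethyl_acetate"].replace("  1  2  1", "  1  9  1")
        with pytest.raises(MolfileError) as err:
            parse_molfile(text)
        assert err.value.line is not None


class TestWriteMolfile:
    def test_round_trip_named_fixtures(self, molfiles):
        for name, text in molfiles.items():
            doc = parse_molfile(text)
            again = parse_molfile(write_molfile(doc))
            assert graph_signature(doc) == graph_signature(again), name

    def test_round_trip_generated_molecules(self):
        for seed in range(200):
            doc = generate_molecule(GeneratorParams(seed=seed))
            again = parse_molfile(write_molfile(doc))
            assert graph_signature(doc) == graph_signature(again)

    def test_capacity_limit(self):
        doc = generate_molecule(GeneratorParams(seed=0, min_atoms=5, max_atoms=5))
        doc.atoms = doc.atoms * 250  # 1250 atoms
        with pytest.raises(MolfileError):
            write_molfile(doc)


class TestTweakDialect:
    def test_tweaked_benzene_flags_all_atoms(self, molfiles):
        mol = perceive(molfiles["benzene_kekule_a"])
        doc = parse_molfile(write_molfile(mol, tweaked=True))
        assert doc.tweak_flag
        assert all(a.aromatic_flag for a in doc.atoms)
        assert all(b.aromatic_flag for b in doc.bonds)

    def test_tweaked_cyclohexane_carries_no_flags(self, molfiles):
        mol = perceive(molfiles["cyclohexane"])
        doc = parse_molfile(write_molfile(mol, tweaked=True))
        assert doc.tweak_flag
        assert not any(b.aromatic_flag for b in doc.bonds)

    def test_tweak_transparency_for_oracle_parser(self, molfiles):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        for name in ("benzene_kekule_a", "caffeine", "diazepam", "furan"):
            mol = perceive(molfiles[name])
            plain = Chem.MolFromMolBlock(write_molfile(mol, tweaked=False))
            tweaked = Chem.MolFromMolBlock(write_molfile(mol, tweaked=True))
            assert Chem.MolToSmiles(plain) == Chem.MolToSmiles(tweaked), name

    def test_tweak_flag_survives_round_trip(self, molfiles):
        mol = perceive(molfiles["furan"])
        doc = parse_molfile(write_molfile(mol, tweaked=True))
        doc2 = parse_molfile(write_molfile(doc, tweaked=True))
        assert doc2.tweak_flag
        assert [a.aromatic_flag for a in doc.atoms] == [a.aromatic_flag for a in doc2.atoms]


class TestSDFiles:
    def make_sd(self, molfiles, names, fields=None):
        docs = [parse_molfile(molfiles[n]) for n in names]
        return write_sdfile([(d, fields or {}) for d in docs])

    def test_three_record_file(self, molfiles):
        text = self.make_sd(molfiles, ["benzene_kekule_a", "furan", "pyridine"])
        records = list(iter_sdfile(text))
        assert len(records) == 3

    def test_data_fields_are_captured(self, molfiles):
        text = self.make_sd(molfiles, ["ethyl_acetate"], fields={"MW": "88.11"})
        (_, fields), = iter_sdfile(text)
        assert fields["MW"] == "88.11"

    def test_empty_file_yields_nothing(self):
        assert list(iter_sdfile("")) == []

    def test_bad_record_fails_fast_but_is_skipped_in_tolerant_mode(self, molfiles):
        good = self.make_sd(molfiles, ["furan"])
        bad = "garbage\nrecord\n$$$$\n"
        with pytest.raises(SDFileError) as err:
            list(iter_sdfile(bad + good))
        assert err.value.record == 1
        records = list(iter_sdfile(bad + good, tolerant=True))
        assert len(records) == 1


class TestRXNFiles:
    def test_imine_formation_partition(self, rxnfiles):
        rxn = parse_rxnfile(rxnfiles["imine_formation"])
        assert len(rxn.reactants) == 2
        assert len(rxn.products) == 2

    def test_atom_maps_balanced(self, rxnfiles):
        rxn = parse_rxnfile(rxnfiles["imine_formation"])
        r_classes = {m for side, _, _, m in rxn.atom_maps if side == "reactant"}
        p_classes = {m for side, _, _, m in rxn.atom_maps if side == "product"}
        assert r_classes == p_classes != set()

    def test_unmapped_reaction_has_no_maps(self, molfiles):
        from molpat.molfile_io import ReactionDocument

        rxn = ReactionDocument(reactants=[parse_molfile(molfiles["ethanol"])],
                               products=[parse_molfile(molfiles["acetaldehyde"])])
        again = parse_rxnfile(write_rxnfile(rxn))
        assert again.atom_maps == []

    def test_count_mismatch_rejected(self, rxnfiles):
        text = rxnfiles["imine_formation"].replace("  2  2", "  3  2", 1)
        with pytest.raises(MolfileError):
            parse_rxnfile(text)

    def test_round_trip_all_fixtures(self, rxnfiles):
        for name, text in rxnfiles.items():
            rxn = parse_rxnfile(text)
            again = parse_rxnfile(write_rxnfile(rxn))
            assert len(again.reactants) == len(rxn.reactants)
            assert again.atom_maps == rxn.atom_maps


def test_rdfile_extracts_reactions_and_data(rxnfiles):
    rd = ("$RDFILE 1\n$DATM today\n$RFMT\n" + rxnfiles["imine_formation"]
          + "$DTYPE yield\n$DATUM 85\n")
    (record, fields), = iter_rdfile(rd)
    assert len(record.reactants) == 2
    assert fields == {"yield": "85"}
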