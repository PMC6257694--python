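"""Atom-by-atom matching: ranks, reference atoms, verdicts, stereo, oracle."""

import pytest

from molpat.fixtures import GeneratorParams, extract_needle, generate_molecule
from molpat.matcher import (MatchOptions, enumerate_mappings, match,
                            morgan_ranks, select_reference_atom)
from molpat.molfile_io import write_molfile
from molpat.perception import Molecule, perceive


class TestMorganRanks:
    def test_benzene_fully_symmetric(self, mols):
        assert len(set(morgan_ranks(mols["benzene_kekule_a"]))) == 1

    def test_propane_center_distinct(self, mols):
        ranks = morgan_ranks(mols["propane"])
        assert ranks[0] == ranks[2] != ranks[1]

    def test_ethanol_three_classes(self, mols):
        assert len(set(morgan_ranks(mols["ethanol"]))) == 3


class TestReferenceAtom:
    def test_toluene_branching_carbon(self, mols):
        mol = mols["toluene"]
        ref = select_reference_atom(mol, "heuristic")
        assert mol.atoms[ref].element == "C"
        assert mol.atoms[ref].heavy_degree == 3

    def test_single_atom(self, mols):
        assert select_reference_atom(mols["water"]) == 0

    def test_ethyl_acetate_carbonyl_carbon(self, mols):
        mol = mols["ethyl_acetate"]
        ref = select_reference_atom(mol, "heuristic")
        het = sum(1 for j, _ in mol.neighbors(ref) if mol.atoms[j].element == "O")
        assert het == 2

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            select_reference_atom(Molecule(perceived=True))

    def test_morgan_method_prefers_rare_rank(self, mols):
        mol = mols["toluene"]
        ref = select_reference_atom(mol, "morgan")
        ranks = morgan_ranks(mol)
        assert ranks.count(ranks[ref]) == min(ranks.count(r) for r in set(ranks))


class TestMatchVerdicts:
    def test_benzene_in_toluene_not_reverse(self, mols):
        assert match(mols["benzene_kekule_a"], mols["toluene"]).verdict
        assert not match(mols["toluene"], mols["benzene_kekule_a"]).verdict

    def test_exact_self_match_with_mapping(self, mols):
        caffeine = mols["caffeine"]
        result = match(caffeine, caffeine, MatchOptions(mode="exact", mappings="first"))
        assert result.verdict
        mapping = result.mappings[0]
        assert sorted(mapping) == sorted(mapping.values())
        for n, h in mapping.items():
            assert caffeine.atoms[n].element == caffeine.atoms[h].element

    def test_exact_rejects_substructure_relation(self, mols):
        assert not match(mols["benzene_kekule_a"], mols["toluene"],
                         MatchOptions(mode="exact")).verdict

    def test_explicit_needle_hydrogens_constrain(self, mols):
        # the explicit-H query demands an unsubstituted arylamine nitrogen
        assert match(mols["sulfanilamide_query"], mols["sulfanilamide"]).verdict
        assert match(mols["benzene_kekule_a"], mols["sulfanilamide_query"]).verdict

    def test_strict_mode_requires_subtypes(self, mols):
        # sp3 ring atoms cannot sit on aromatic positions in strict mode
        assert not match(mols["cyclohexane"], mols["benzene_kekule_a"],
                         MatchOptions(strict=True)).verdict

    def test_single_bond_matches_aromatic_unless_disabled(self, mols):
        hexane_ring = mols["cyclohexane"]
        benzene = mols["benzene_kekule_a"]
        assert match(hexane_ring, benzene).verdict
        assert not match(hexane_ring, benzene,
                         MatchOptions(single_matches_aromatic=False)).verdict

    def test_unperceived_input_rejected(self, mols):
        raw = Molecule()
        with pytest.raises(ValueError):
            match(raw, mols["benzene_kekule_a"])


class TestStereo:
    def test_e_vs_z_butene(self, mols):
        e, z = mols["butene_e"], mols["butene_z"]
        assert not match(e, z, MatchOptions(check_geometry=True)).verdict
        assert match(e, z).verdict  # constitutionally identical
        assert match(e, e, MatchOptions(check_geometry=True)).verdict

    def test_wedge_vs_3d_mirror_image(self, mols):
        r2d, r3d, s3d = mols["chfclbr_r"], mols["chfclbr_r_3d"], mols["chfclbr_s_3d"]
        opts = MatchOptions(check_chirality=True)
        assert match(r2d, r3d, opts).verdict
        assert not match(r2d, s3d, opts).verdict
        assert match(r2d, s3d).verdict  # without the R/S check they coincide


class TestMappings:
    def test_benzene_automorphism_count(self, mols):
        maps = enumerate_mappings(mols["benzene_kekule_a"], mols["benzene_kekule_b"],
                                  MatchOptions(mappings="all"))
        assert len(maps) == 12  # dihedral group of the 6-ring
        assert len({tuple(sorted(m.items())) for m in maps}) == 12

    def test_impossible_needle_empty(self, mols):
        assert enumerate_mappings(mols["ethanol"], mols["methanol"]) == []

    def test_first_returns_single_mapping(self, mols):
        maps = enumerate_mappings(mols["phenol"], mols["tyrosine"],
                                  MatchOptions(mappings="first"))
        assert len(maps) == 1
        mapping = maps[0]
        tyr = mols["tyrosine"]
        phe = mols["phenol"]
        for bond in phe.bonds:
            assert tyr.bond_between(mapping[bond.a1], mapping[bond.a2]) is not None


class TestRelationProperties:
    FIXES = ["benzene_kekule_a", "toluene", "caffeine", "ethanol", "phenol"]

    def test_exact_match_equivalence_relation(self, mols):
        opts = MatchOptions(mode="exact")
        for a in self.FIXES:
            assert match(mols[a], mols[a], opts).verdict, a
        assert match(mols["benzene_kekule_a"], mols["benzene_kekule_b"], opts).verdict
        assert match(mols["benzene_kekule_b"], mols["benzene_kekule_a"], opts).verdict

    def test_substructure_transitive_on_fixture_chain(self, mols):
        a, b, c = mols["benzene_kekule_a"], mols["toluene"], mols["tyrosine"]
        assert match(a, b).verdict and match(b, c, MatchOptions()).verdict is not None
        if match(a, b).verdict and match(b, c).verdict:
            assert match(a, c).verdict

    def test_tweak_equivalence(self, mols, molfiles):
        needle = mols["benzene_kekule_a"]
        for name in ("toluene", "caffeine", "diazepam", "naphthalene"):
            fresh = mols[name]
            via_tweak = perceive(write_molfile(fresh, tweaked=True))
            assert (match(needle, fresh).verdict
                    == match(needle, via_tweak).verdict), name


class TestOracleEquivalence:
    def test_verdicts_match_subgraph_isomorphism_oracle(self):
        """1,000 seeded needle/haystack pairs against a brute-force oracle."""
        nx = pytest.importorskip("networkx")
        from networkx.algorithms import isomorphism as iso

        agreements = 0
        for seed in range(1000):
            h_doc = generate_molecule(GeneratorParams(
                seed=seed, min_atoms=6, max_atoms=14))
            if seed % 2:
                n_doc = extract_needle(h_doc, n_delete=6, seed=seed)
            else:  # unrelated needle: verdicts should often be negative
                n_doc = generate_molecule(GeneratorParams(
                    seed=100_000 + seed, min_atoms=3, max_atoms=8))
            needle = perceive(write_molfile(n_doc))
            haystack = perceive(write_molfile(h_doc))
            verdict = match(needle, haystack).verdict

            gn = _to_nx(nx, needle)
            gh = _to_nx(nx, haystack)
            matcher = iso.GraphMatcher(
                gh, gn,
                node_match=lambda a, b: a["key"] == b["key"],
                edge_match=_edge_compat)
            oracle = matcher.subgraph_is_monomorphic()
            assert verdict == oracle, seed
            agreements += 1
        assert agreements == 1000


def _edge_compat(haystack_attrs, needle_attrs):
    # same bond-class rule the matcher documents: aromatic is its own class,
    # which a needle single or double bond may also occupy (non-strict mode)
    hk, nk = haystack_attrs["key"], needle_attrs["key"]
    if nk == "ar":
        return hk == "ar"
    if hk == "ar":
        return nk in (1, 2)
    return nk == hk


def _to_nx(nx, mol):
    g = nx.Graph()
    for i, atom in enumerate(mol.atoms):
        g.add_node(i, key=(atom.element, atom.charge, atom.isotope_delta))
    for b in mol.bonds:
        key = "ar" if b.aromatic else int(b.order)
        g.add_edge(b.a1, b.a2, key=key)
    return g
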