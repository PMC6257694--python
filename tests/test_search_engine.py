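"""Two-stage search: indexing, pre-selection completeness, similarity,
functional-group and reaction queries."""

import pytest

from molpat.descriptors import (compute_molstat, dictionary_fingerprint,
                                hashed_fingerprint, tanimoto)
from molpat.fixtures import (GeneratorParams, builtin_molecules,
                             builtin_reactions, extract_needle,
                             generate_molecule)
from molpat.functional_groups import POSITION, detect_groups
from molpat.matcher import MatchOptions, match
from molpat.molfile_io import parse_molfile, write_molfile
from molpat.perception import perceive
from molpat.search_engine import (IndexError_, ReactionIndex, StructureIndex,
                                  reaction_fg_search)


@pytest.fixture(scope="module")
def seeded_index(molfiles, small_dictionary):
    """200-record index: random drug-like molecules plus named fixtures."""
    idx = StructureIndex(dictionary=small_dictionary)
    named = ["caffeine", "sulfanilamide", "diazepam", "ethyl_acetate",
             "toluene", "naphthalene", "quinoline", "benzene_kekule_a",
             "nag_glycoside", "phenol"]
    for name in named:
        idx.add(molfiles[name], id=name)
    for seed in range(190):
        idx.add(write_molfile(generate_molecule(GeneratorParams(
            seed=1000 + seed, min_atoms=8, max_atoms=22))), id=f"G{seed:03d}")
    return idx


@pytest.fixture(scope="module")
def reaction_index(rxnfiles, small_dictionary):
    idx = ReactionIndex(dictionary=small_dictionary)
    for name, text in rxnfiles.items():
        idx.add(text, id=name)
    return idx


class TestIndexing:
    def test_compound_record_descriptors(self, molfiles, small_dictionary):
        idx = StructureIndex(dictionary=small_dictionary)
        record = idx.add(molfiles["ethyl_acetate"], id="ea")
        assert record.fg.has("ester")
        assert record.popcount == record.hashed_fp.popcount()

    def test_dictionary_identity_is_odd(self, molfiles, small_dictionary):
        idx = StructureIndex(dictionary=small_dictionary)
        record = idx.add(molfiles["benzene_kekule_b"], id="bz")
        assert record.dict_fp.value % 2 == 1

    def test_duplicate_id_rejected(self, molfiles, small_dictionary):
        idx = StructureIndex(dictionary=small_dictionary)
        idx.add(molfiles["furan"], id="x")
        with pytest.raises(IndexError_):
            idx.add(molfiles["furan"], id="x")

    def test_stored_descriptor_integrity(self, seeded_index):
        """Recomputing descriptors from the stored tweaked molfiles
        reproduces the stored segments bit-exactly."""
        for record in seeded_index.records()[:40]:
            mol = perceive(record.molfile)
            assert hashed_fingerprint(mol) == record.hashed_fp, record.id
            assert detect_groups(mol).segments == record.fg.segments, record.id
            assert compute_molstat(mol).as_tuple() == record.molstat.as_tuple(), record.id

    def test_unparseable_record_rejected_with_diagnostic(self, small_dictionary):
        idx = StructureIndex(dictionary=small_dictionary)
        with pytest.raises(IndexError_) as err:
            idx.add("not a molfile", id="bad")
        assert "bad" in str(err.value)


class TestSubstructureSearch:
    def test_indexed_query_found_exactly(self, seeded_index, molfiles):
        result = seeded_index.substructure_search(
            molfiles["caffeine"], MatchOptions(mode="exact"))
        assert "caffeine" in result.hits
        assert len(result) >= 1

    def test_candidates_not_fewer_than_hits(self, seeded_index, molfiles):
        result = seeded_index.substructure_search(molfiles["caffeine"])
        assert "caffeine" in result.hits
        assert result.candidates >= len(result.hits)

    def test_hits_equal_brute_force_over_index(self, seeded_index, molfiles):
        queries = [molfiles["benzene_kekule_a"], molfiles["ethyl_acetate"],
                   molfiles["phenol"]]
        for seed in (50, 51, 52):
            doc = generate_molecule(GeneratorParams(seed=1000 + seed,
                                                    min_atoms=8, max_atoms=22))
            queries.append(write_molfile(extract_needle(doc, n_delete=5, seed=seed)))
        engine_opts = MatchOptions(single_matches_aromatic=False)
        for query in queries:
            q = perceive(query)
            expected = sorted(r.id for r in seeded_index.records()
                              if match(q, r.molecule, engine_opts).verdict)
            got = sorted(seeded_index.substructure_search(query).hits)
            assert got == expected

    def test_dictionary_identity_shortcut(self, seeded_index, molfiles):
        # benzene IS a dictionary entry: the search runs without matching and
        # must return exactly the records whose stored benzene bit is set
        result = seeded_index.substructure_search(molfiles["benzene_kekule_b"])
        expected = sorted(r.id for r in seeded_index.records() if r.dict_fp.get(1))
        assert sorted(result.hits) == expected
        q = perceive(molfiles["benzene_kekule_b"])
        brute = sorted(r.id for r in seeded_index.records()
                       if match(q, r.molecule,
                                MatchOptions(single_matches_aromatic=False)).verdict)
        assert sorted(result.hits) == brute


class TestSimilaritySearch:
    def test_self_query_ranks_first(self, seeded_index, molfiles):
        ranked = seeded_index.similarity_search(molfiles["diazepam"], min_score=0.0)
        assert ranked[0][0] == "diazepam"
        assert ranked[0][1] == 1.0

    def test_unfiltered_ranking_matches_exhaustive_tanimoto(self, seeded_index, molfiles):
        query = perceive(molfiles["caffeine"])
        qfp = hashed_fingerprint(query)
        expected = sorted(((r.id, tanimoto(qfp, r.hashed_fp))
                           for r in seeded_index.records()),
                          key=lambda p: (-p[1], p[0]))
        got = seeded_index.similarity_search(molfiles["caffeine"], min_score=0.0)
        assert got == expected

    def test_popcount_prefilter_never_drops_qualifying_record(self, seeded_index, molfiles):
        query = perceive(molfiles["naphthalene"])
        qfp = hashed_fingerprint(query)
        for threshold in (0.3, 0.5, 0.8):
            got = dict(seeded_index.similarity_search(molfiles["naphthalene"],
                                                      min_score=threshold))
            for r in seeded_index.records():
                true_score = tanimoto(qfp, r.hashed_fp)
                if true_score >= threshold:
                    assert r.id in got and got[r.id] == true_score

    def test_min_score_validation(self, seeded_index, molfiles):
        with pytest.raises(ValueError):
            seeded_index.similarity_search(molfiles["phenol"], min_score=1.5)


class TestFunctionalGroupSearch:
    def test_sulfanilamide_pattern(self, seeded_index):
        result = seeded_index.functional_group_search(
            [POSITION["primary_aromatic_amine"], POSITION["sulfonamide"]])
        assert "sulfanilamide" in result.hits

    def test_empty_selection_returns_everything(self, seeded_index):
        assert len(seeded_index.functional_group_search([])) == len(seeded_index)

    def test_hits_equal_descriptor_scan(self, seeded_index):
        positions = [POSITION["aromatic"], POSITION["heterocycle"]]
        expected = sorted(r.id for r in seeded_index.records()
                          if r.fg.has("aromatic") and r.fg.has("heterocycle"))
        assert sorted(seeded_index.functional_group_search(positions).hits) == expected

    def test_fg_hits_superset_of_substructure_hits(self, seeded_index, molfiles):
        """The group query built from a structure's own groups can only
        widen the substructure hit set (explicit-H sulfanilamide query)."""
        sub = set(seeded_index.substructure_search(molfiles["sulfanilamide_query"]).hits)
        fg = set(seeded_index.functional_group_search(
            [POSITION["primary_aromatic_amine"], POSITION["sulfonamide"]]).hits)
        assert "sulfanilamide" in sub
        assert sub <= fg


class TestSqliteBackend:
    def test_same_results_as_memory_backend(self, molfiles, small_dictionary, tmp_path):
        mem = StructureIndex(dictionary=small_dictionary)
        sql = StructureIndex(dictionary=small_dictionary, backend="sqlite",
                             db_path=str(tmp_path / "c.db"))
        for idx in (mem, sql):
            for name in ("caffeine", "sulfanilamide", "toluene", "quinoline",
                         "ethyl_acetate", "cyclohexane"):
                idx.add(molfiles[name], id=name)
            for seed in range(30):
                idx.add(write_molfile(generate_molecule(GeneratorParams(
                    seed=seed, min_atoms=8, max_atoms=18))), id=f"G{seed}")
        for query in (molfiles["toluene"], molfiles["ethyl_acetate"]):
            assert (sorted(mem.substructure_search(query).hits)
                    == sorted(sql.substructure_search(query).hits))
        positions = [POSITION["aromatic"]]
        assert (sorted(mem.functional_group_search(positions).hits)
                == sorted(sql.functional_group_search(positions).hits))


class TestReactionIndex:
    def test_cumulative_or_law(self, reaction_index, small_dictionary):
        dictionary = [perceive(t) for t in small_dictionary]
        for record in reaction_index.records():
            mols = record.reactant_molecules
            acc = hashed_fingerprint(mols[0])
            for m in mols[1:]:
                acc = acc | hashed_fingerprint(m)
            assert acc == record.reactant_hashed, record.id
            acc_fg = detect_groups(mols[0]).bits
            for m in mols[1:]:
                acc_fg = acc_fg | detect_groups(m).bits
            assert acc_fg == record.reactant_fg, record.id

    def test_imine_only_on_product_side(self, reaction_index):
        record = reaction_index.record("imine_formation")
        pos = POSITION["imine"]
        assert not record.reactant_fg.get(pos)
        assert record.product_fg.get(pos)

    def test_single_reactant_cumulative_identity(self, rxnfiles, small_dictionary, molfiles):
        from molpat.molfile_io import ReactionDocument, write_rxnfile

        rxn = ReactionDocument(reactants=[parse_molfile(molfiles["ethanol"])],
                               products=[parse_molfile(molfiles["acetaldehyde"])])
        idx = ReactionIndex(dictionary=small_dictionary)
        record = idx.add(write_rxnfile(rxn), id="ox")
        assert record.reactant_hashed == hashed_fingerprint(perceive(molfiles["ethanol"]))

    def test_empty_product_list_rejected(self, rxnfiles, small_dictionary):
        text = rxnfiles["urea_formation"].replace("  2  1", "  2  0", 1)
        text = text[: text.rfind("$MOL")]
        idx = ReactionIndex(dictionary=small_dictionary)
        with pytest.raises(Exception):
            idx.add(text, id="broken")


class TestReactionSearch:
    def test_indexed_reaction_matches_itself(self, reaction_index, rxnfiles):
        for name, text in rxnfiles.items():
            assert name in reaction_index.reaction_search(text).hits

    def test_map_check_accepts_consistent_query(self, reaction_index, rxnfiles):
        assert "imine_formation" in reaction_index.reaction_search(
            rxnfiles["imine_formation"], check_maps=True).hits

    def test_half_reaction_products_only(self, reaction_index, molfiles):
        from molpat.molfile_io import ReactionDocument, write_rxnfile

        # a products-only query hits every reaction producing the pattern
        half = ReactionDocument(products=[parse_molfile(molfiles["dimethylurea"])])
        text = write_rxnfile(half)
        # a RXN with zero reactants is legal as a query
        result = reaction_index.reaction_search(text)
        assert result.hits == ["urea_formation"]

    def test_hits_equal_brute_force(self, reaction_index, rxnfiles):
        from molpat.molfile_io import parse_rxnfile

        engine_opts = MatchOptions(single_matches_aromatic=False)
        for name, text in rxnfiles.items():
            query = parse_rxnfile(text)
            q_react = [perceive(d) for d in query.reactants]
            q_prod = [perceive(d) for d in query.products]
            expected = []
            for record in reaction_index.records():
                ok = (all(any(match(q, c, engine_opts).verdict
                              for c in record.reactant_molecules)
                          for q in q_react)
                      and all(any(match(q, c, engine_opts).verdict
                                  for c in record.product_molecules)
                              for q in q_prod))
                if ok:
                    expected.append(record.id)
            got = reaction_index.reaction_search(text).hits
            assert sorted(got) == sorted(expected)


class TestReactionFGModes:
    def test_created_mode(self, reaction_index):
        hits = reaction_fg_search(reaction_index, [POSITION["imine"]], "created").hits
        assert hits == ["imine_formation"]

    def test_lost_mode_complement(self, reaction_index):
        assert reaction_fg_search(reaction_index, [POSITION["imine"]], "lost").hits == []
        hits = reaction_fg_search(reaction_index, [POSITION["isocyanate"]], "lost").hits
        assert hits == ["urea_formation"]

    def test_hydrazide_created(self, reaction_index):
        hits = reaction_fg_search(reaction_index, [POSITION["hydrazide"]], "created").hits
        assert hits == ["hydrazide_formation"]

    def test_in_reactants_vs_in_products(self, reaction_index):
        pos = [POSITION["isocyanate"]]
        assert reaction_fg_search(reaction_index, pos, "in_reactants").hits == ["urea_formation"]
        assert reaction_fg_search(reaction_index, pos, "in_products").hits == []

    def test_unknown_mode_rejected(self, reaction_index):
        with pytest.raises(ValueError):
            reaction_fg_search(reaction_index, [0], "sideways")
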