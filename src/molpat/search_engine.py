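"""Indexed two-stage structure and reaction search.

Stage 1 (pre-selection) works purely on stored descriptors: molstat
counter dominance, hashed-fingerprint bit containment, dictionary bit
containment — conditions a relational backend evaluates with ``<=`` and
bitwise AND.  Stage 2 confirms every surviving candidate by atom-by-atom
matching.  Functional-group searches skip stage 2 entirely: the mask
predicates on the fg01..fg08 segments are the whole query.

Two interchangeable backends store the records: a plain in-memory list
and an embedded SQLite database whose column layout mirrors the
fg01..fg08 / fingerprint-segment schema (so the mask predicates run as
real SQL ``&`` conditions).
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from . import fixtures as _fixtures
from .descriptors import (Bitstring, Molstat, compute_molstat,
                          dictionary_fingerprint, hashed_fingerprint,
                          identity_entry, tanimoto)
from .functional_groups import (FGDescriptor, detect_groups, encode_group_query,
                                mask_predicates, satisfies_masks)
from .matcher import MatchOptions, enumerate_mappings, match
from .molfile_io import (MolfileDocument, ReactionDocument, iter_sdfile,
                         parse_molfile, parse_rxnfile, write_molfile)
from .perception import Molecule, perceive


@dataclass
class CompoundRecord:
    id: str
    molfile: str                      # tweaked molfile text
    hashed_fp: Bitstring
    dict_fp: Bitstring
    fg: FGDescriptor
    molstat: Molstat
    popcount: int
    molecule: Molecule = None

    @property
    def fg_segments(self) -> list[int]:
        return self.fg.segments


@dataclass
class ReactionRecord:
    id: str
    rxn_text: str
    reactant_molfiles: list[str]
    product_molfiles: list[str]
    reactant_hashed: Bitstring
    reactant_dict: Bitstring
    reactant_fg: Bitstring
    product_hashed: Bitstring
    product_dict: Bitstring
    product_fg: Bitstring
    reactant_molecules: list[Molecule] = field(default_factory=list)
    product_molecules: list[Molecule] = field(default_factory=list)


@dataclass
class SearchResult:
    hits: list[str]
    candidates: int

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


class IndexError_(ValueError):
    pass


def _screening_opts(opts: MatchOptions | None) -> MatchOptions:
    """Stage-2 options for indexed searches.

    Indexed searches always compare bonds by exact class (an aromatic bond
    only matches an aromatic bond): fragment fingerprints and dictionary
    bits are rendered on those classes, so descriptor pre-selection is
    complete only under the same rule.  A Kekulé-drawn aromatic query is
    unaffected — perception turns its ring bonds aromatic before matching.
    """
    opts = opts or MatchOptions()
    if opts.single_matches_aromatic:
        opts = MatchOptions(**{**opts.__dict__, "single_matches_aromatic": False})
    return opts


def _index_molecule(mol_text: str, dictionary: Sequence[Molecule]):
    doc = parse_molfile(mol_text)
    mol = perceive(doc)
    return (
        mol,
        write_molfile(mol, tweaked=True),
        hashed_fingerprint(mol),
        dictionary_fingerprint(mol, dictionary),
        detect_groups(mol),
        compute_molstat(mol),
    )


class StructureIndex:
    """Searchable compound collection with precomputed descriptors."""

    def __init__(self, dictionary: Iterable[str] | None = None,
                 backend: Literal["memory", "sqlite"] = "memory",
                 db_path: str = ":memory:", stage2_batch: int = 64):
        dict_texts = list(dictionary) if dictionary is not None else _fixtures.default_dictionary()
        self.dictionary: list[Molecule] = [perceive(t) for t in dict_texts]
        self.backend = backend
        self.stage2_batch = stage2_batch
        self._records: dict[str, CompoundRecord] = {}
        self._conn: sqlite3.Connection | None = None
        if backend == "sqlite":
            self._conn = sqlite3.connect(db_path)
            self._create_schema()

    # -- indexing --------------------------------------------------------
    def index_structure(self, mol_text: str, id: str | None = None) -> CompoundRecord:
        rid = id if id is not None else f"M{len(self._records) + 1:06d}"
        if rid in self._records:
            raise IndexError_(f"duplicate record id {rid!r}")
        try:
            mol, tweaked, hashed, dict_fp, fg, molstat = _index_molecule(mol_text, self.dictionary)
        except Exception as exc:
            raise IndexError_(f"record {rid!r} rejected: {exc}") from exc
        record = CompoundRecord(
            id=rid, molfile=tweaked, hashed_fp=hashed, dict_fp=dict_fp,
            fg=fg, molstat=molstat, popcount=hashed.popcount(), molecule=mol)
        self._records[rid] = record
        if self._conn is not None:
            self._insert_sql(record)
        return record

    add = index_structure

    def add_sdfile(self, stream, tolerant: bool = True) -> list[CompoundRecord]:
        out = []
        for k, (doc, fields) in enumerate(iter_sdfile(stream, tolerant=tolerant), start=1):
            rid = fields.get("ID") or doc.title.strip() or f"SD{k:06d}"
            try:
                out.append(self.index_structure(write_molfile(doc), id=rid))
            except IndexError_:
                if not tolerant:
                    raise
        return out

    def __len__(self):
        return len(self._records)

    def __contains__(self, rid: str):
        return rid in self._records

    def record(self, rid: str) -> CompoundRecord:
        return self._records[rid]

    def records(self) -> list[CompoundRecord]:
        return list(self._records.values())

    # -- sqlite backend ---------------------------------------------------
    def _create_schema(self) -> None:
        fp_cols = ", ".join(f"fp{i + 1:02d} INTEGER" for i in range(16))
        fg_cols = ", ".join(f"fg{i + 1:02d} INTEGER" for i in range(8))
        ms_cols = ", ".join(f"ms_{name} INTEGER" for name in Molstat.counter_names())
        self._conn.execute(
            f"CREATE TABLE IF NOT EXISTS compounds (id TEXT PRIMARY KEY, molfile TEXT, "
            f"popcount INTEGER, dict_fp TEXT, ring_method TEXT, {fp_cols}, {fg_cols}, {ms_cols})")

    def _insert_sql(self, r: CompoundRecord) -> None:
        fp_segs = r.hashed_fp.segments_u32()
        fg_segs = r.fg.segments
        ms = list(r.molstat.as_tuple())
        cols = (["id", "molfile", "popcount", "dict_fp", "ring_method"]
                + [f"fp{i + 1:02d}" for i in range(16)]
                + [f"fg{i + 1:02d}" for i in range(8)]
                + [f"ms_{n}" for n in Molstat.counter_names()])
        values = ([r.id, r.molfile, r.popcount, json.dumps(r.dict_fp.segments_u32()),
                   r.molecule.rings.method] + fp_segs + fg_segs + ms)
        self._conn.execute(
            f"INSERT INTO compounds ({', '.join(cols)}) VALUES ({', '.join('?' * len(cols))})",
            values)
        self._conn.commit()

    def _sql_stage1(self, query_fp: Bitstring, query_ms: Molstat,
                    use_ring_counters: bool) -> list[str]:
        conditions, params = [], []
        for i, seg in enumerate(query_fp.segments_u32()):
            if seg:
                conditions.append(f"(fp{i + 1:02d} & ? = ?)")
                params += [seg, seg]
        for name in Molstat.counter_names():
            if name in Molstat._RING_DEPENDENT:
                if not use_ring_counters:
                    continue
                # fallback ring sets may undercount: never prune on them
                conditions.append(f"(ms_{name} >= ? OR ring_method = 'fallback')")
            else:
                conditions.append(f"(ms_{name} >= ?)")
            params.append(getattr(query_ms, name))
        where = " AND ".join(conditions) or "1=1"
        rows = self._conn.execute(f"SELECT id FROM compounds WHERE {where}", params)
        return [row[0] for row in rows]

    # -- searches ---------------------------------------------------------
    def substructure_search(self, query_mol_text: str,
                            opts: MatchOptions | None = None) -> SearchResult:
        opts = _screening_opts(opts)
        query = perceive(query_mol_text)
        query_fp = hashed_fingerprint(query)
        query_ms = compute_molstat(query)
        query_dict = dictionary_fingerprint(query, self.dictionary)

        plain = (opts.mode == "substructure" and not opts.strict
                 and not opts.check_geometry and not opts.check_chirality
                 and not opts.charge_agnostic)
        if plain and query_dict.get(0):
            # identity shortcut: the query IS a dictionary fragment, so the
            # stored substructure bit answers the search without matching
            k = identity_entry(query, self.dictionary)
            hits = [r.id for r in self._records.values() if r.dict_fp.get(k + 1)]
            return SearchResult(hits=hits, candidates=len(hits))

        use_rings = query.rings.method == "SAR"
        if self._conn is not None:
            stage1_ids = set(self._sql_stage1(query_fp, query_ms, use_rings))
        else:
            stage1_ids = None

        candidates = []
        for r in self._records.values():
            if stage1_ids is not None:
                if r.id not in stage1_ids:
                    continue
            else:
                if not query_fp.issubset(r.hashed_fp):
                    continue
                if not r.molstat.dominates(
                        query_ms,
                        use_ring_counters=use_rings and r.molecule.rings.method == "SAR"):
                    continue
            if not query_dict.issubset(r.dict_fp | Bitstring(r.dict_fp.length, 1)):
                continue  # every set dictionary bit (identity bit aside) must be stored
            candidates.append(r)

        hits = []
        for start in range(0, len(candidates), self.stage2_batch):
            for r in candidates[start:start + self.stage2_batch]:
                if match(query, r.molecule, opts).verdict:
                    hits.append(r.id)
        return SearchResult(hits=hits, candidates=len(candidates))

    def similarity_search(self, query_mol_text: str, min_score: float = 0.0,
                          molstat_margin: float | None = None) -> list[tuple[str, float]]:
        if not 0.0 <= min_score <= 1.0:
            raise ValueError("min_score must lie in [0, 1]")
        query = perceive(query_mol_text)
        query_fp = hashed_fingerprint(query)
        query_ms = compute_molstat(query)
        qp = query_fp.popcount()
        out = []
        for r in self._records.values():
            if molstat_margin is not None and not query_ms.within_margin(r.molstat, molstat_margin):
                continue
            if min_score > 0 and qp and r.popcount:
                # Tanimoto <= min(p_q, p_r) / max(p_q, p_r): a cheap stored-popcount bound
                if min(qp, r.popcount) / max(qp, r.popcount) < min_score:
                    continue
            score = tanimoto(query_fp, r.hashed_fp)
            if score >= min_score:
                out.append((r.id, score))
        out.sort(key=lambda pair: (-pair[1], pair[0]))
        return out

    def functional_group_search(self, positions: Iterable[int]) -> SearchResult:
        segments = encode_group_query(positions)
        predicates = mask_predicates(segments)
        if self._conn is not None:
            where = " AND ".join(f"(fg{col:02d} & {mask} = {mask})" for col, mask in predicates) or "1=1"
            hits = [row[0] for row in self._conn.execute(f"SELECT id FROM compounds WHERE {where}")]
        else:
            hits = [r.id for r in self._records.values()
                    if satisfies_masks(r.fg_segments, predicates)]
        return SearchResult(hits=hits, candidates=len(hits))


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

def _cumulative(bitstrings: Sequence[Bitstring]) -> Bitstring:
    out = Bitstring(bitstrings[0].length)
    for bs in bitstrings:
        out = out | bs
    return out


class ReactionIndex:
    """Searchable reaction collection with cumulative fingerprints."""

    def __init__(self, dictionary: Iterable[str] | None = None):
        dict_texts = list(dictionary) if dictionary is not None else _fixtures.default_dictionary()
        self.dictionary: list[Molecule] = [perceive(t) for t in dict_texts]
        self._records: dict[str, ReactionRecord] = {}

    def index_reaction(self, rxn_text: str, id: str | None = None) -> ReactionRecord:
        rid = id if id is not None else f"R{len(self._records) + 1:06d}"
        if rid in self._records:
            raise IndexError_(f"duplicate reaction id {rid!r}")
        rxn = parse_rxnfile(rxn_text)
        if not rxn.reactants or not rxn.products:
            raise IndexError_(f"reaction {rid!r} rejected: empty reactant or product list")
        record = self._build_record(rid, rxn_text, rxn)
        self._records[rid] = record
        return record

    add = index_reaction

    def _build_record(self, rid: str, rxn_text: str, rxn: ReactionDocument) -> ReactionRecord:
        def descriptors(docs):
            mols = [perceive(d) for d in docs]
            hashed = _cumulative([hashed_fingerprint(m) for m in mols])
            dict_fp = _cumulative([dictionary_fingerprint(m, self.dictionary) for m in mols])
            fg = _cumulative([detect_groups(m).bits for m in mols])
            return mols, hashed, dict_fp, fg

        r_mols, r_hashed, r_dict, r_fg = descriptors(rxn.reactants)
        p_mols, p_hashed, p_dict, p_fg = descriptors(rxn.products)
        return ReactionRecord(
            id=rid, rxn_text=rxn_text,
            reactant_molfiles=[write_molfile(m, tweaked=True) for m in r_mols],
            product_molfiles=[write_molfile(m, tweaked=True) for m in p_mols],
            reactant_hashed=r_hashed, reactant_dict=r_dict, reactant_fg=r_fg,
            product_hashed=p_hashed, product_dict=p_dict, product_fg=p_fg,
            reactant_molecules=r_mols, product_molecules=p_mols)

    def __len__(self):
        return len(self._records)

    def record(self, rid: str) -> ReactionRecord:
        return self._records[rid]

    def records(self) -> list[ReactionRecord]:
        return list(self._records.values())

    def reaction_search(self, query_rxn_text: str, check_maps: bool = False,
                        opts: MatchOptions | None = None) -> SearchResult:
        opts = _screening_opts(opts)
        query = parse_rxnfile(query_rxn_text)
        q_react = [perceive(d) for d in query.reactants]
        q_prod = [perceive(d) for d in query.products]
        q_r_hashed = _cumulative([hashed_fingerprint(m) for m in q_react]) if q_react else None
        q_p_hashed = _cumulative([hashed_fingerprint(m) for m in q_prod]) if q_prod else None

        hits = []
        n_candidates = 0
        for r in self._records.values():
            if q_r_hashed is not None and not q_r_hashed.issubset(r.reactant_hashed):
                continue
            if q_p_hashed is not None and not q_p_hashed.issubset(r.product_hashed):
                continue
            n_candidates += 1
            if self._confirm(q_react, q_prod, r, check_maps, opts):
                hits.append(r.id)
        return SearchResult(hits=hits, candidates=n_candidates)

    def _confirm(self, q_react, q_prod, record: ReactionRecord,
                 check_maps: bool, opts: MatchOptions) -> bool:
        if not check_maps:
            return (all(any(match(q, c, opts).verdict for c in record.reactant_molecules)
                        for q in q_react)
                    and all(any(match(q, c, opts).verdict for c in q_prod_side(record))
                            for q in q_prod))
        map_opts = MatchOptions(**{**opts.__dict__, "mappings": "all"})
        r_embeds = _side_embeddings(q_react, record.reactant_molecules, map_opts)
        p_embeds = _side_embeddings(q_prod, record.product_molecules, map_opts)
        if r_embeds is None or p_embeds is None:
            return False
        for r_choice in r_embeds:
            r_map = _map_classes(q_react, record.reactant_molecules, r_choice)
            for p_choice in p_embeds:
                p_map = _map_classes(q_prod, record.product_molecules, p_choice)
                if _maps_consistent(r_map, p_map):
                    return True
        return False


def q_prod_side(record: ReactionRecord) -> list[Molecule]:
    return record.product_molecules


def _side_embeddings(queries, candidates, opts) -> list[list[tuple[int, dict[int, int]]]] | None:
    """All combinations of (candidate index, embedding) choices per query molecule."""
    per_query = []
    for q in queries:
        choices = []
        for ci, c in enumerate(candidates):
            for emb in enumerate_mappings(q, c, opts):
                choices.append((ci, emb))
        if not choices:
            return None
        per_query.append(choices)
    import itertools
    return [list(combo) for combo in itertools.product(*per_query)]


def _map_classes(queries, candidates, choice) -> dict[int, tuple[int, int]]:
    """query map class -> (candidate molecule index, candidate map class)."""
    out = {}
    for qi, (ci, emb) in enumerate(choice):
        for q_atom, c_atom in emb.items():
            q_cls = queries[qi].atoms[q_atom].atom_map
            if q_cls:
                c_cls = candidates[ci].atoms[c_atom].atom_map
                out[q_cls] = (ci, c_cls)
    return out


def _maps_consistent(r_map: dict[int, tuple[int, int]],
                     p_map: dict[int, tuple[int, int]]) -> bool:
    """Mapped query atom pairs must land on candidate atoms sharing a map class."""
    for q_cls in set(r_map) & set(p_map):
        (_, r_c_cls), (_, p_c_cls) = r_map[q_cls], p_map[q_cls]
        if r_c_cls == 0 or r_c_cls != p_c_cls:
            return False
    return True


FG_MODES = ("in_reactants", "in_products", "lost", "created")


def reaction_fg_search(index: ReactionIndex, positions: Iterable[int],
                       mode: str) -> SearchResult:
    """Functional-group query over a reaction index in one of four modes.

    ``lost``/``created`` are evaluated on the cumulative bitstrings: a bit
    must be set on one side and clear on the other, which is exactly what
    the stored per-side segments can answer (a group present on both sides
    in different molecules is neither lost nor created).
    """
    if mode not in FG_MODES:
        raise ValueError(f"mode must be one of {FG_MODES}")
    segments = encode_group_query(positions)
    predicates = mask_predicates(segments)
    hits = []
    for r in index.records():
        r_seg = r.reactant_fg.segments_u32()
        p_seg = r.product_fg.segments_u32()
        if mode == "in_reactants":
            ok = satisfies_masks(r_seg, predicates)
        elif mode == "in_products":
            ok = satisfies_masks(p_seg, predicates)
        elif mode == "lost":
            ok = all(r_seg[col - 1] & mask == mask and p_seg[col - 1] & mask == 0
                     for col, mask in predicates)
        else:  # created
            ok = all(p_seg[col - 1] & mask == mask and r_seg[col - 1] & mask == 0
                     for col, mask in predicates)
        if ok:
            hits.append(r.id)
    return SearchResult(hits=hits, candidates=len(hits))
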