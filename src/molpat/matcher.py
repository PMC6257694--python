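"""Atom-by-atom structure matching.

The query ("needle") is matched into the candidate ("haystack") by
backtracking from a preferentially unique reference atom, chosen either by
a fast branching/heteroatom heuristic or from Morgan extended-connectivity
ranks.  Atom pairs are compared on chemical element (plus hybridization
subtype in strict mode), charge and isotope; bond pairs on order with
aromatic bonds forming their own class.  Exact mode demands a bijection on
heavy atoms with equal bond multisets.  Optional stereo checks compare
double-bond geometry (E/Z, from 2D coordinates) and tetrahedral parity
(R/S, from wedge-augmented 2D or true 3D coordinates) across the mapping.

Explicit hydrogens in the needle are constraints: they are folded into the
heavy-atom graph at perception time and matched against the haystack
atom's total (explicit + implicit) hydrogen count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

from .molfile_io import BondOrder, BondStereo
from .perception import Molecule, PerceivedBond, explicit_hydrogens
from .periodic import is_heteroatom


@dataclass
class MatchOptions:
    mode: Literal["substructure", "exact"] = "substructure"
    strict: bool = False
    check_geometry: bool = False   # E/Z on double bonds
    check_chirality: bool = False  # R/S parity on stereocenters
    mappings: Literal["none", "first", "all"] = "none"
    charge_agnostic: bool = False
    single_matches_aromatic: bool = True  # needle single/double vs aromatic haystack bond


@dataclass
class MatchResult:
    verdict: bool
    mappings: list[dict[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Morgan canonical ranks
# ---------------------------------------------------------------------------

def morgan_ranks(mol: Molecule) -> list[int]:
    """Extended-connectivity ranks, refined until the class count stabilizes.

    Ties between equal-connectivity atoms are broken by (element, charge,
    subtype); fully symmetric atoms (benzene carbons) share a rank.
    """
    if not mol.perceived:
        raise ValueError("molecule must be perceived")
    n = len(mol.atoms)
    if n == 0:
        return []
    ec = [len(mol.neighbors(i)) for i in range(n)]
    n_classes = len(set(ec))
    while True:
        nxt = [ec[i] * (n + 1) + sum(ec[j] for j, _ in mol.neighbors(i)) for i in range(n)]
        nxt_classes = len(set(nxt))
        if nxt_classes <= n_classes:
            break
        ec, n_classes = nxt, nxt_classes
    keys = sorted({(mol.atoms[i].element, mol.atoms[i].charge, mol.atoms[i].subtype, ec[i])
                   for i in range(n)})
    rank_of = {key: r for r, key in enumerate(keys)}
    return [rank_of[(mol.atoms[i].element, mol.atoms[i].charge, mol.atoms[i].subtype, ec[i])]
            for i in range(n)]


def select_reference_atom(mol: Molecule, method: Literal["heuristic", "morgan"] = "heuristic") -> int:
    """Pick a (preferentially unique) starting atom for the match recursion."""
    if not mol.atoms:
        raise ValueError("cannot select a reference atom in an empty molecule")
    if method == "morgan":
        ranks = morgan_ranks(mol)
        counts = {r: ranks.count(r) for r in set(ranks)}
        return min(range(len(mol.atoms)), key=lambda i: (counts[ranks[i]], i))
    element_count: dict[str, int] = {}
    for atom in mol.atoms:
        element_count[atom.element] = element_count.get(atom.element, 0) + 1
    best = None
    best_key = None
    for i, atom in enumerate(mol.atoms):
        het = sum(1 for j, _ in mol.neighbors(i) if is_heteroatom(mol.atoms[j].element))
        key = (len(mol.neighbors(i)), het, -element_count[atom.element])
        if best_key is None or key > best_key:
            best, best_key = i, key
    return best


# ---------------------------------------------------------------------------
# compatibility predicates
# ---------------------------------------------------------------------------

def _atoms_compatible(needle: Molecule, haystack: Molecule, ni: int, hi: int,
                      opts: MatchOptions, needle_explicit_h: list[int]) -> bool:
    na, ha = needle.atoms[ni], haystack.atoms[hi]
    if na.element != ha.element:
        return False
    if na.isotope_delta != ha.isotope_delta:
        return False
    if na.charge != ha.charge and not (opts.charge_agnostic and na.charge == 0):
        return False
    if opts.strict and na.subtype != ha.subtype:
        return False
    if opts.mode == "exact":
        if na.attached_hydrogens != ha.attached_hydrogens:
            return False
    else:
        # explicit needle hydrogens are matching constraints
        if ha.attached_hydrogens < needle_explicit_h[ni]:
            return False
        if len(haystack.neighbors(hi)) < len(needle.neighbors(ni)):
            return False
    return True


def _bonds_compatible(nb: PerceivedBond, hb: PerceivedBond, opts: MatchOptions) -> bool:
    if nb.aromatic or nb.order == BondOrder.AROMATIC_INPUT:
        return hb.aromatic or hb.order == BondOrder.AROMATIC_INPUT
    if hb.aromatic or hb.order == BondOrder.AROMATIC_INPUT:
        return (opts.mode != "exact" and not opts.strict and opts.single_matches_aromatic
                and nb.order in (BondOrder.SINGLE, BondOrder.DOUBLE))
    return nb.order == hb.order


# ---------------------------------------------------------------------------
# the recursive match
# ---------------------------------------------------------------------------

def _match_order(needle: Molecule, ref: int) -> list[int]:
    """BFS order from the reference atom (assumes a connected needle)."""
    from collections import deque

    order = [ref]
    seen = {ref}
    queue = deque([ref])
    while queue:
        v = queue.popleft()
        for w, _ in needle.neighbors(v):
            if w not in seen:
                seen.add(w)
                order.append(w)
                queue.append(w)
    for i in range(len(needle.atoms)):  # disconnected needles: remaining atoms last
        if i not in seen:
            order.append(i)
            seen.add(i)
    return order


def _embeddings(needle: Molecule, haystack: Molecule, opts: MatchOptions,
                ) -> Iterator[dict[int, int]]:
    n_needle = len(needle.atoms)
    if n_needle == 0:
        yield {}
        return
    if n_needle > len(haystack.atoms):
        return
    if opts.mode == "exact" and (n_needle != len(haystack.atoms)
                                 or len(needle.bonds) != len(haystack.bonds)):
        return

    needle_h = explicit_hydrogens(needle)
    ref = select_reference_atom(needle)
    order = _match_order(needle, ref)
    pos_in_order = {atom: k for k, atom in enumerate(order)}

    # local match matrix: per-pair atom compatibility, computed once
    compat = [[_atoms_compatible(needle, haystack, ni, hi, opts, needle_h)
               for hi in range(len(haystack.atoms))] for ni in range(n_needle)]

    assignment: dict[int, int] = {}
    used: set[int] = set()

    def candidates(ni: int) -> Iterator[int]:
        mapped_neighbors = [(w, b) for w, b in needle.neighbors(ni) if w in assignment]
        if mapped_neighbors:
            w0, b0 = mapped_neighbors[0]
            for hi, hb in haystack.neighbors(assignment[w0]):
                if _bonds_compatible(b0, hb, opts):
                    yield hi
        else:
            yield from range(len(haystack.atoms))

    def extend(k: int) -> Iterator[dict[int, int]]:
        if k == n_needle:
            yield dict(assignment)
            return
        ni = order[k]
        for hi in candidates(ni):
            if hi in used or not compat[ni][hi]:
                continue
            ok = True
            for w, nb in needle.neighbors(ni):
                if w in assignment:
                    hb = haystack.bond_between(hi, assignment[w])
                    if hb is None or not _bonds_compatible(nb, hb, opts):
                        ok = False
                        break
            if not ok:
                continue
            assignment[ni] = hi
            used.add(hi)
            yield from extend(k + 1)
            del assignment[ni]
            used.discard(hi)

    for mapping in extend(0):
        if opts.mode == "exact" and len(set(mapping.values())) != len(haystack.atoms):
            continue
        if opts.check_geometry and not _geometry_consistent(needle, haystack, mapping):
            continue
        if opts.check_chirality and not _chirality_consistent(needle, haystack, mapping):
            continue
        yield mapping


def match(needle: Molecule, haystack: Molecule, opts: MatchOptions | None = None) -> MatchResult:
    """Substructure or exact match; see :class:`MatchOptions`."""
    opts = opts or MatchOptions()
    if not needle.perceived or not haystack.perceived:
        raise ValueError("both molecules must be perceived before matching")
    result = MatchResult(verdict=False)
    for mapping in _embeddings(needle, haystack, opts):
        result.verdict = True
        if opts.mappings == "none":
            break
        result.mappings.append(mapping)
        if opts.mappings == "first":
            break
    return result


def enumerate_mappings(needle: Molecule, haystack: Molecule,
                       opts: MatchOptions | None = None) -> list[dict[int, int]]:
    """All distinct embeddings (global match matrix mode), or at most one."""
    opts = opts or MatchOptions()
    if opts.mappings == "none":
        opts = MatchOptions(**{**opts.__dict__, "mappings": "all"})
    return match(needle, haystack, opts).mappings


# ---------------------------------------------------------------------------
# stereochemistry
# ---------------------------------------------------------------------------

def _side_sign(ax: float, ay: float, bx: float, by: float, px: float, py: float) -> float:
    """Sign of the cross product (b-a) x (p-a): which side of line ab is p on."""
    return (bx - ax) * (py - ay) - (by - ay) * (px - ax)


def _double_bond_config(mol: Molecule, bond: PerceivedBond,
                        ref1: int, ref2: int) -> int | None:
    """+1 when the two reference substituents lie on the same side, -1 opposite."""
    a, b = mol.atoms[bond.a1], mol.atoms[bond.a2]
    s1 = _side_sign(a.x, a.y, b.x, b.y, mol.atoms[ref1].x, mol.atoms[ref1].y)
    s2 = _side_sign(a.x, a.y, b.x, b.y, mol.atoms[ref2].x, mol.atoms[ref2].y)
    if abs(s1) < 1e-9 or abs(s2) < 1e-9:
        return None
    return 1 if (s1 > 0) == (s2 > 0) else -1


def _geometry_consistent(needle: Molecule, haystack: Molecule,
                         mapping: dict[int, int]) -> bool:
    for bond in needle.bonds:
        if bond.order != BondOrder.DOUBLE or bond.aromatic:
            continue
        subs1 = sorted(w for w, _ in needle.neighbors(bond.a1) if w != bond.a2)
        subs2 = sorted(w for w, _ in needle.neighbors(bond.a2) if w != bond.a1)
        if not subs1 or not subs2:
            continue
        n_config = _double_bond_config(needle, bond, subs1[0], subs2[0])
        if n_config is None:
            continue
        h_bond = haystack.bond_between(mapping[bond.a1], mapping[bond.a2])
        h_config = _double_bond_config(haystack, h_bond, mapping[subs1[0]], mapping[subs2[0]])
        if h_config is not None and h_config != n_config:
            return False
    return True


def _wedge_z(mol: Molecule, center: int, neighbor: int) -> float:
    bond = mol.bond_between(center, neighbor)
    if bond.stereo == BondStereo.UP and bond.a1 == center:
        return 1.0
    if bond.stereo == BondStereo.DOWN and bond.a1 == center:
        return -1.0
    return 0.0


def _tetra_parity(mol: Molecule, center: int, ordered_neighbors: list[int]) -> int | None:
    """Sign of the signed tetrahedron volume spanned by three neighbours.

    Uses true 3D coordinates when present, otherwise the 2D projection
    augmented with wedge (+1) / hash (-1) z offsets.
    """
    is_3d = any(abs(a.z) > 1e-9 for a in mol.atoms)
    c = mol.atoms[center]
    vecs = []
    any_wedge = False
    for nb in ordered_neighbors:
        a = mol.atoms[nb]
        z = a.z if is_3d else _wedge_z(mol, center, nb)
        if not is_3d and z != 0.0:
            any_wedge = True
        vecs.append((a.x - c.x, a.y - c.y, z - (c.z if is_3d else 0.0)))
    if not is_3d and not any_wedge:
        return None
    (x1, y1, z1), (x2, y2, z2), (x3, y3, z3) = vecs[:3]
    det = (x1 * (y2 * z3 - z2 * y3) - y1 * (x2 * z3 - z2 * x3)
           + z1 * (x2 * y3 - y2 * x3))
    if abs(det) < 1e-9:
        return None
    return 1 if det > 0 else -1


def _chirality_consistent(needle: Molecule, haystack: Molecule,
                          mapping: dict[int, int]) -> bool:
    for ni in range(len(needle.atoms)):
        neighbors = sorted(w for w, _ in needle.neighbors(ni))
        if len(neighbors) < 3:
            continue
        n_parity = _tetra_parity(needle, ni, neighbors[:3])
        if n_parity is None:
            continue
        h_parity = _tetra_parity(haystack, mapping[ni], [mapping[w] for w in neighbors[:3]])
        if h_parity is not None and h_parity != n_parity:
            return False
    return True
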