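"""Molecular perception: ring search, aromaticity, atom subtypes.

The perceived :class:`Molecule` is the in-memory container every other
module operates on.  Perception runs in three stages:

1. ring search — the set of all rings (every simple cycle up to a size
   bound), falling back to a smallest-set-of-smallest-rings cycle basis
   when a highly condensed system pushes the cycle count past a budget;
2. aromaticity — each ring is tested against the Hückel rule (4n+2 π
   electrons, uninterrupted conjugation), with the π-electron bookkeeping
   spelled out in :func:`_ring_pi_electrons`;
3. subtype assignment — sp/sp2/sp3 hybridization classes per atom, with an
   aromatic variant for atoms on aromatic rings.

Perception is idempotent, and a molfile parsed from the "tweaked" dialect
can skip stages 1-2 entirely because the aromatic flags are already in the
file (:func:`perceive` honours them when ``trust_tweak`` is on).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .molfile_io import (BondOrder, BondStereo, MolfileDocument, RawAtom,
                         RawBond, Radical, parse_molfile)
from .periodic import HALOGENS, implicit_hydrogens, is_heteroatom

DEFAULT_MAX_RING_SIZE = 26
DEFAULT_RING_BUDGET = 1024


@dataclass
class PerceivedAtom:
    element: str
    charge: int = 0
    isotope_delta: int = 0
    radical: Radical = Radical.NONE
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    atom_map: int = 0
    aromatic: bool = False
    subtype: str = "sp3"          # one of sp3 / sp2 / sp / ar
    heavy_degree: int = 0
    attached_hydrogens: int = 0   # explicit neighbours + implicit by valence
    warnings: tuple[str, ...] = ()


@dataclass
class PerceivedBond:
    a1: int  # 0-based atom indices on the perceived molecule
    a2: int
    order: BondOrder = BondOrder.SINGLE
    stereo: BondStereo = BondStereo.NONE
    aromatic: bool = False
    ring_membership: int = 0

    def other(self, i: int) -> int:
        return self.a2 if i == self.a1 else self.a1


@dataclass
class RingSet:
    rings: list[tuple[int, ...]] = field(default_factory=list)
    method: str = "SAR"  # or "fallback"

    def __len__(self) -> int:
        return len(self.rings)

    def __iter__(self):
        return iter(self.rings)


@dataclass
class Molecule:
    atoms: list[PerceivedAtom] = field(default_factory=list)
    bonds: list[PerceivedBond] = field(default_factory=list)
    rings: RingSet = field(default_factory=RingSet)
    perceived: bool = False
    title: str = ""
    comment: str = ""

    # -- graph helpers -------------------------------------------------
    def neighbors(self, i: int) -> list[tuple[int, PerceivedBond]]:
        return self._adjacency[i]

    @property
    def _adjacency(self) -> list[list[tuple[int, PerceivedBond]]]:
        adj = getattr(self, "_adj_cache", None)
        if adj is None or len(adj) != len(self.atoms):
            adj = [[] for _ in self.atoms]
            for bond in self.bonds:
                adj[bond.a1].append((bond.a2, bond))
                adj[bond.a2].append((bond.a1, bond))
            object.__setattr__(self, "_adj_cache", adj)
        return adj

    def invalidate(self) -> None:
        if hasattr(self, "_adj_cache"):
            object.__delattr__(self, "_adj_cache")

    def bond_between(self, i: int, j: int) -> PerceivedBond | None:
        for k, bond in self.neighbors(i):
            if k == j:
                return bond
        return None

    def ring_membership(self, i: int) -> int:
        return sum(1 for ring in self.rings if i in ring)


def molecule_from_document(doc: MolfileDocument) -> Molecule:
    """Lift a parsed document into an unperceived molecule.

    Explicit hydrogen atoms are folded into their heavy neighbour's
    ``attached_hydrogens`` count; the perceived graph is heavy-atom only.
    Hydrogens bonded to nothing, to each other, or isotopically labelled
    (D/T) are kept as graph atoms.
    """
    is_plain_h = []
    h_partner: dict[int, int] = {}
    h_bond_count = [0] * len(doc.atoms)
    for bond in doc.bonds:
        h_bond_count[bond.a1 - 1] += 1
        h_bond_count[bond.a2 - 1] += 1
    for idx, atom in enumerate(doc.atoms):
        plain = (atom.element == "H" and atom.charge == 0 and atom.isotope_delta == 0
                 and atom.radical == Radical.NONE and h_bond_count[idx] == 1)
        is_plain_h.append(plain)
    for bond in doc.bonds:
        i, j = bond.a1 - 1, bond.a2 - 1
        if is_plain_h[i] and not is_plain_h[j] and bond.order == BondOrder.SINGLE:
            h_partner[i] = j
        elif is_plain_h[j] and not is_plain_h[i] and bond.order == BondOrder.SINGLE:
            h_partner[j] = i

    keep = [idx for idx in range(len(doc.atoms)) if idx not in h_partner]
    remap = {old: new for new, old in enumerate(keep)}
    mol = Molecule(title=doc.title, comment=doc.comment)
    explicit_h = [0] * len(keep)
    for old in h_partner.values():
        if old in remap:
            explicit_h[remap[old]] += 1
    for old in keep:
        a = doc.atoms[old]
        mol.atoms.append(PerceivedAtom(
            element=a.element, charge=a.charge, isotope_delta=a.isotope_delta,
            radical=a.radical, x=a.x, y=a.y, z=a.z, atom_map=a.atom_map,
            aromatic=a.aromatic_flag,
        ))
    for bond in doc.bonds:
        i, j = bond.a1 - 1, bond.a2 - 1
        if i in h_partner or j in h_partner:
            continue
        mol.bonds.append(PerceivedBond(
            a1=remap[i], a2=remap[j], order=bond.order, stereo=bond.stereo,
            aromatic=bond.aromatic_flag,
        ))
    for idx, n_h in enumerate(explicit_h):
        mol.atoms[idx].attached_hydrogens = n_h  # explicit part; implicit added later
    object.__setattr__(mol, "_explicit_h", explicit_h)
    return mol


def explicit_hydrogens(mol: Molecule) -> list[int]:
    """Per-atom count of hydrogens that were explicit in the input."""
    return list(getattr(mol, "_explicit_h", [0] * len(mol.atoms)))


# ---------------------------------------------------------------------------
# ring perception
# ---------------------------------------------------------------------------

class RingBudgetExceeded(Exception):
    pass


def _simple_cycles(adj: list[list[int]], max_size: int, budget: int) -> list[tuple[int, ...]]:
    """All simple cycles up to ``max_size``, each listed once.

    A cycle is emitted rooted at its smallest atom index with its second
    vertex smaller than its last, which removes rotations and reflections.
    Raises :class:`RingBudgetExceeded` when more than ``budget`` cycles
    exist within the size bound.
    """
    n = len(adj)
    cycles: list[tuple[int, ...]] = []
    for start in range(n):
        stack: list[tuple[int, list[int]]] = [(start, [start])]
        on_path = {start}
        path: list[int] = []

        def dfs(v: int, path: list[int], on_path: set[int]):
            for w in adj[v]:
                if w == start and len(path) >= 3:
                    if path[1] < path[-1]:
                        cycles.append(tuple(path))
                        if len(cycles) > budget:
                            raise RingBudgetExceeded
                elif w > start and w not in on_path and len(path) < max_size:
                    on_path.add(w)
                    path.append(w)
                    dfs(w, path, on_path)
                    path.pop()
                    on_path.remove(w)

        dfs(start, [start], {start})
    return cycles


def _sssr(mol: Molecule) -> list[tuple[int, ...]]:
    """A smallest-set-of-smallest-rings cycle basis (greedy over GF(2))."""
    n_cycles = len(mol.bonds) - len(mol.atoms) + _n_components(mol)
    if n_cycles <= 0:
        return []
    bond_index = {}
    for bi, bond in enumerate(mol.bonds):
        bond_index[(bond.a1, bond.a2)] = bi
        bond_index[(bond.a2, bond.a1)] = bi

    candidates: list[tuple[int, ...]] = []
    seen = set()
    for bond in mol.bonds:
        cyc = _shortest_cycle_through(mol, bond)
        if cyc:
            key = _canonical_cycle(cyc)
            if key not in seen:
                seen.add(key)
                candidates.append(cyc)
    candidates.sort(key=len)

    pivots: dict[int, int] = {}  # leading bit -> reduced row (GF(2) elimination)
    chosen: list[tuple[int, ...]] = []
    for cyc in candidates:
        vec = 0
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            vec |= 1 << bond_index[(a, b)]
        reduced = vec
        while reduced:
            lead = reduced.bit_length() - 1
            if lead not in pivots:
                pivots[lead] = reduced
                chosen.append(cyc)
                break
            reduced ^= pivots[lead]
        if len(chosen) == n_cycles:
            break
    return chosen


def _n_components(mol: Molecule) -> int:
    seen: set[int] = set()
    comps = 0
    for s in range(len(mol.atoms)):
        if s in seen:
            continue
        comps += 1
        stack = [s]
        seen.add(s)
        while stack:
            v = stack.pop()
            for w, _ in mol.neighbors(v):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
    return comps


def _shortest_cycle_through(mol: Molecule, bond: PerceivedBond) -> tuple[int, ...] | None:
    # BFS from a1 to a2 avoiding the bond itself
    from collections import deque
    prev = {bond.a1: -1}
    queue = deque([bond.a1])
    while queue:
        v = queue.popleft()
        if v == bond.a2:
            path = []
            while v != -1:
                path.append(v)
                v = prev[v]
            return tuple(path)
        for w, b in mol.neighbors(v):
            if b is bond or w in prev:
                continue
            prev[w] = v
            queue.append(w)
    return None


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    n = len(cycle)
    best = None
    doubled = list(cycle) + list(cycle)
    for variant in (doubled, doubled[::-1]):
        for off in range(n):
            cand = tuple(variant[off:off + n])
            if cand[0] == min(cycle) and (best is None or cand < best):
                best = cand
    return best


def perceive_rings(mol: Molecule,
                   max_ring_size: int = DEFAULT_MAX_RING_SIZE,
                   ring_budget: int = DEFAULT_RING_BUDGET) -> RingSet:
    """Ring search: set of all rings, SSSR fallback for condensed systems."""
    adj = [[w for w, _ in mol.neighbors(i)] for i in range(len(mol.atoms))]
    try:
        rings = _simple_cycles(adj, max_ring_size, ring_budget)
        ring_set = RingSet(rings=rings, method="SAR")
    except RingBudgetExceeded:
        ring_set = RingSet(rings=_sssr(mol), method="fallback")
    mol.rings = ring_set
    ring_edges: dict[tuple[int, int], int] = {}
    for ring in ring_set:
        for a, b in zip(ring, ring[1:] + ring[:1]):
            key = (min(a, b), max(a, b))
            ring_edges[key] = ring_edges.get(key, 0) + 1
    for bond in mol.bonds:
        bond.ring_membership = ring_edges.get((min(bond.a1, bond.a2), max(bond.a1, bond.a2)), 0)
    return ring_set


# ---------------------------------------------------------------------------
# aromaticity
# ---------------------------------------------------------------------------

_LONE_PAIR_DONORS = {"N", "O", "S", "P", "Se", "As"}


def _ring_pi_electrons(mol: Molecule, ring: Sequence[int]) -> int | None:
    """π-electron count of a ring, or None if conjugation is interrupted.

    Per-atom contributions: an atom engaged in any double bond (or an
    aromatic-input bond) provides one electron of that π system — unless
    every such double bond points to a heteroatom outside the ring, the
    mesomeric exocyclic C=X case (2-/4-pyridones), which contributes
    nothing but does not interrupt conjugation.  A saturated ring atom
    contributes a full lone pair when it has one (furan O, pyrrole N,
    carbanion), nothing when it is an empty-p-orbital center (tropylium
    C+), and breaks the ring otherwise (sp3 CH2 of cyclohexane).
    """
    ring_set = set(ring)
    total = 0
    for i in ring:
        atom = mol.atoms[i]
        doubles = [bond for _, bond in mol.neighbors(i) if bond.order == BondOrder.DOUBLE]
        has_aromatic_input = any(b.order == BondOrder.AROMATIC_INPUT for _, b in mol.neighbors(i))
        if has_aromatic_input:
            total += 1
        elif doubles:
            exo_het_only = all(
                bond.other(i) not in ring_set and is_heteroatom(mol.atoms[bond.other(i)].element)
                for bond in doubles)
            total += 0 if exo_het_only else 1
        elif any(b.order == BondOrder.TRIPLE for _, b in mol.neighbors(i)):
            return None
        else:
            if atom.element == "C":
                if atom.charge < 0:
                    total += 2
                elif atom.charge > 0:
                    total += 0
                else:
                    return None  # saturated carbon: no p orbital
            elif atom.element in _LONE_PAIR_DONORS:
                if atom.element in ("N", "P") and atom.charge > 0:
                    return None  # quaternized: lone pair consumed
                total += 2
            else:
                return None
    return total


def perceive_aromaticity(mol: Molecule) -> Molecule:
    """Classify every perceived ring with the 4n+2 Hückel rule, set flags."""
    for atom in mol.atoms:
        atom.aromatic = False
    for bond in mol.bonds:
        bond.aromatic = False
    for ring in mol.rings:
        bonds = [mol.bond_between(a, b) for a, b in zip(ring, ring[1:] + ring[:1])]
        if all(b is not None and b.order == BondOrder.AROMATIC_INPUT for b in bonds):
            aromatic = True  # trust explicit aromatic input bonds
        else:
            pi = _ring_pi_electrons(mol, ring)
            aromatic = pi is not None and pi >= 2 and pi % 4 == 2
        if aromatic:
            for i in ring:
                mol.atoms[i].aromatic = True
            for b in bonds:
                b.aromatic = True
    return mol


# ---------------------------------------------------------------------------
# subtypes, hydrogen counts, valence checks
# ---------------------------------------------------------------------------

def _bond_order_sum(mol: Molecule, i: int) -> int:
    total = 0.0
    for _, bond in mol.neighbors(i):
        total += 1.5 if bond.order == BondOrder.AROMATIC_INPUT else float(int(bond.order))
    import math
    return math.ceil(total - 1e-9)


def assign_atom_subtypes(mol: Molecule) -> Molecule:
    """sp / sp2 / sp3 classes from explicit multiplicities, 'ar' on aromatics."""
    from .periodic import default_valences
    for i, atom in enumerate(mol.atoms):
        orders = [b.order for _, b in mol.neighbors(i)]
        n_double = sum(1 for o in orders if o == BondOrder.DOUBLE)
        n_triple = sum(1 for o in orders if o == BondOrder.TRIPLE)
        if atom.aromatic:
            atom.subtype = "ar"
        elif n_triple or n_double >= 2:
            atom.subtype = "sp"
        elif n_double or BondOrder.AROMATIC_INPUT in orders:
            atom.subtype = "sp2"
        else:
            atom.subtype = "sp3"
        atom.heavy_degree = len(mol.neighbors(i))
        order_sum = _bond_order_sum(mol, i)
        explicit_h = explicit_hydrogens(mol)[i]
        atom.attached_hydrogens = explicit_h + implicit_hydrogens(
            atom.element, atom.charge, order_sum + explicit_h)
        valences = default_valences(atom.element, atom.charge)
        if valences and order_sum + explicit_h > max(valences):
            atom.warnings = atom.warnings + (
                f"valence {order_sum + explicit_h} exceeds maximum {max(valences)}",)
    return mol


def perceive(source: MolfileDocument | Molecule | str,
             max_ring_size: int = DEFAULT_MAX_RING_SIZE,
             ring_budget: int = DEFAULT_RING_BUDGET,
             trust_tweak: bool = True) -> Molecule:
    """Full perception pipeline; accepts molfile text, a document or a molecule.

    For documents parsed from the tweaked dialect (``tweak_flag`` set) the
    stored aromatic flags are trusted and the ring search is still run
    (descriptors need the ring list) but aromaticity detection is skipped.
    Pass ``trust_tweak=False`` to force full re-perception.
    """
    tweaked = False
    if isinstance(source, str):
        source = parse_molfile(source)
    if isinstance(source, MolfileDocument):
        tweaked = source.tweak_flag
        mol = molecule_from_document(source)
    else:
        mol = source
        if mol.perceived:
            return mol
    perceive_rings(mol, max_ring_size=max_ring_size, ring_budget=ring_budget)
    if not (tweaked and trust_tweak):
        perceive_aromaticity(mol)
    assign_atom_subtypes(mol)
    mol.perceived = True
    return mol
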