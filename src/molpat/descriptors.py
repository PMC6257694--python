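"""Pre-selection descriptors: molstat counters, hashed and dictionary
fingerprints, plus the bit-vector utilities shared by the whole package.

All bitstrings are fixed-length bit vectors backed by a Python integer and
viewable as unsigned 32-bit segments (segment ``i`` holds bits
``32*i .. 32*i+31``, bit ``p`` at position ``p mod 32``), which is the
layout relational backends store and query with bitwise AND.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

from .molfile_io import BondOrder
from .periodic import HALOGENS, is_heteroatom
from .perception import Molecule

HASHED_FP_BITS = 512
FG_BITS = 256
MAX_PATHS = 10 ** 6


class PathOverflowError(RuntimeError):
    """Linear-fragment enumeration exceeded the per-molecule path cap."""


class Bitstring:
    """Fixed-length bit vector with a 32-bit unsigned segment view."""

    __slots__ = ("length", "value")

    def __init__(self, length: int, value: int = 0):
        if length % 32:
            length = 32 * ((length + 31) // 32)
        self.length = length
        self.value = value & ((1 << length) - 1)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_positions(cls, length: int, positions: Iterable[int]) -> "Bitstring":
        bs = cls(length)
        for p in positions:
            bs.set(p)
        return bs

    @classmethod
    def from_segments(cls, segments: Sequence[int]) -> "Bitstring":
        value = 0
        for i, seg in enumerate(segments):
            value |= (seg & 0xFFFFFFFF) << (32 * i)
        return cls(32 * len(segments), value)

    @classmethod
    def from_ascii(cls, bits: str) -> "Bitstring":
        bs = cls(len(bits))
        for i, ch in enumerate(bits):
            if ch == "1":
                bs.set(i)
        return bs

    # -- mutation / access ----------------------------------------------
    def set(self, position: int) -> None:
        if not 0 <= position < self.length:
            raise IndexError(f"bit position {position} out of range 0..{self.length - 1}")
        self.value |= 1 << position

    def get(self, position: int) -> bool:
        return bool(self.value >> position & 1)

    def positions(self) -> list[int]:
        return [i for i in range(self.length) if self.value >> i & 1]

    def popcount(self) -> int:
        return self.value.bit_count()

    def density(self) -> float:
        return self.popcount() / self.length

    # -- views ----------------------------------------------------------
    def segments_u32(self) -> list[int]:
        return [(self.value >> (32 * i)) & 0xFFFFFFFF for i in range(self.length // 32)]

    def ascii(self) -> str:
        return "".join("1" if self.value >> i & 1 else "0" for i in range(self.length))

    # -- algebra ---------------------------------------------------------
    def __and__(self, other: "Bitstring") -> "Bitstring":
        self._check(other)
        return Bitstring(self.length, self.value & other.value)

    def __or__(self, other: "Bitstring") -> "Bitstring":
        self._check(other)
        return Bitstring(self.length, self.value | other.value)

    def issubset(self, other: "Bitstring") -> bool:
        self._check(other)
        return self.value & ~other.value == 0

    def _check(self, other: "Bitstring") -> None:
        if self.length != other.length:
            raise ValueError(f"bitstring length mismatch: {self.length} vs {other.length}")

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Bitstring) and other.length == self.length
                and other.value == self.value)

    def __repr__(self) -> str:
        return f"Bitstring({self.length}, popcount={self.popcount()})"


def tanimoto(a: Bitstring, b: Bitstring) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints score 1 by convention."""
    union = (a | b).popcount()
    if union == 0:
        return 1.0
    return (a & b).popcount() / union


# ---------------------------------------------------------------------------
# molstat
# ---------------------------------------------------------------------------

@dataclass
class Molstat:
    """Ordered integer counters of discrete structural statistics.

    Counters used for substructure pre-selection are deliberately
    cumulative where an exactly-k definition would not be monotone under
    subgraph embedding: ``n_C_1het`` counts carbons with *at least* one
    heteroatom neighbour (2het: at least two, ...), and ``n_C_sp2`` counts
    carbons engaged in at least one multiple or aromatic bond.
    """
    n_atoms: int = 0
    n_bonds: int = 0
    n_rings: int = 0
    n_C: int = 0
    n_C_sp: int = 0
    n_C_sp2: int = 0
    n_C_1het: int = 0
    n_C_2het: int = 0
    n_C_3plus_het: int = 0
    n_CO_single: int = 0
    n_CO_double: int = 0
    n_CN_anyorder: int = 0
    n_ring_size_3: int = 0
    n_ring_size_4: int = 0
    n_ring_size_5: int = 0
    n_ring_size_6: int = 0
    n_ring_size_7: int = 0
    n_ring_size_8: int = 0
    n_ring_size_9: int = 0
    n_ring_size_10: int = 0
    n_ring_size_11: int = 0
    n_ring_size_12: int = 0
    n_ring_size_13plus: int = 0
    n_rings_with_N: int = 0
    n_rings_with_O: int = 0
    n_rings_with_S: int = 0
    n_heteroatoms: int = 0
    n_halogens: int = 0
    n_charged_atoms: int = 0

    _RING_DEPENDENT = frozenset({
        "n_rings", "n_ring_size_3", "n_ring_size_4", "n_ring_size_5",
        "n_ring_size_6", "n_ring_size_7", "n_ring_size_8", "n_ring_size_9",
        "n_ring_size_10", "n_ring_size_11", "n_ring_size_12",
        "n_ring_size_13plus", "n_rings_with_N", "n_rings_with_O",
        "n_rings_with_S",
    })

    @classmethod
    def counter_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in self.counter_names())

    def dominates(self, query: "Molstat", use_ring_counters: bool = True) -> bool:
        """True when every query counter is <= the corresponding counter here."""
        for name in self.counter_names():
            if not use_ring_counters and name in self._RING_DEPENDENT:
                continue
            if getattr(query, name) > getattr(self, name):
                return False
        return True

    def within_margin(self, other: "Molstat", margin: float) -> bool:
        return all(abs(a - b) <= margin for a, b in zip(self.as_tuple(), other.as_tuple()))


def compute_molstat(mol: Molecule) -> Molstat:
    if not mol.perceived:
        raise ValueError("molecule must be perceived before computing molstat")
    ms = Molstat()
    ms.n_atoms = len(mol.atoms)
    ms.n_bonds = len(mol.bonds)
    ms.n_rings = len(mol.rings)
    for i, atom in enumerate(mol.atoms):
        if atom.element == "C":
            ms.n_C += 1
            orders = [b.order for _, b in mol.neighbors(i)]
            n_double = sum(1 for o in orders if o == BondOrder.DOUBLE)
            n_triple = sum(1 for o in orders if o == BondOrder.TRIPLE)
            if n_triple or n_double >= 2:
                ms.n_C_sp += 1
            if atom.aromatic or n_double or n_triple or BondOrder.AROMATIC_INPUT in orders:
                ms.n_C_sp2 += 1
            n_het = sum(1 for j, _ in mol.neighbors(i) if is_heteroatom(mol.atoms[j].element))
            if n_het >= 1:
                ms.n_C_1het += 1
            if n_het >= 2:
                ms.n_C_2het += 1
            if n_het >= 3:
                ms.n_C_3plus_het += 1
        elif atom.element != "H":
            ms.n_heteroatoms += 1
            if atom.element in HALOGENS:
                ms.n_halogens += 1
        if atom.charge:
            ms.n_charged_atoms += 1
    for bond in mol.bonds:
        e1 = mol.atoms[bond.a1].element
        e2 = mol.atoms[bond.a2].element
        pair = {e1, e2}
        if pair == {"C", "O"}:
            if not bond.aromatic and bond.order == BondOrder.SINGLE:
                ms.n_CO_single += 1
            elif not bond.aromatic and bond.order == BondOrder.DOUBLE:
                ms.n_CO_double += 1
        if pair == {"C", "N"}:
            ms.n_CN_anyorder += 1
    for ring in mol.rings:
        size = len(ring)
        if size >= 13:
            ms.n_ring_size_13plus += 1
        elif size >= 3:
            setattr(ms, f"n_ring_size_{size}", getattr(ms, f"n_ring_size_{size}") + 1)
        elements = {mol.atoms[i].element for i in ring}
        if "N" in elements:
            ms.n_rings_with_N += 1
        if "O" in elements:
            ms.n_rings_with_O += 1
        if "S" in elements:
            ms.n_rings_with_S += 1
    return ms


# ---------------------------------------------------------------------------
# linear fragments and the hashed fingerprint
# ---------------------------------------------------------------------------

_BOND_TOKEN = {BondOrder.SINGLE: "-", BondOrder.DOUBLE: "=",
               BondOrder.TRIPLE: "#", BondOrder.AROMATIC_INPUT: "~"}


def _atom_token(mol: Molecule, i: int) -> str:
    atom = mol.atoms[i]
    return atom.element.lower() if atom.aromatic else atom.element


def _bond_token(bond) -> str:
    return "~" if bond.aromatic else _BOND_TOKEN[bond.order]


def _render_path(mol: Molecule, path: Sequence[int]) -> str:
    parts = [_atom_token(mol, path[0])]
    for a, b in zip(path, path[1:]):
        parts.append(_bond_token(mol.bond_between(a, b)))
        parts.append(_atom_token(mol, b))
    forward = "".join(parts)
    backward = "".join(reversed(parts))
    return min(forward, backward)


def linear_fragments(mol: Molecule, min_atoms: int = 3, max_atoms: int = 8) -> Counter:
    """Multiset of canonical strings for every simple path of 3-8 atoms.

    Each undirected path is counted once.  Aromatic atoms render lowercase
    and aromatic bonds as ``~`` regardless of the input Kekulé structure,
    so the fragment set is invariant under Kekulé rewriting.
    """
    if not mol.perceived:
        raise ValueError("molecule must be perceived before fragment enumeration")
    frags: Counter = Counter()
    n_paths = 0
    for start in range(len(mol.atoms)):
        stack = [(start, [start], {start})]
        while stack:
            v, path, on_path = stack.pop()
            if min_atoms <= len(path) and path[0] <= path[-1]:
                frags[_render_path(mol, path)] += 1
                n_paths += 1
                if n_paths > MAX_PATHS:
                    raise PathOverflowError(
                        f"more than {MAX_PATHS} linear fragments in one molecule")
            if len(path) < max_atoms:
                for w, _ in mol.neighbors(v):
                    if w not in on_path:
                        stack.append((w, path + [w], on_path | {w}))
    return frags


def _bkdr_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) & 0xFFFFFFFF
    return h


def _djb_hash(text: str) -> int:
    h = 5381
    for ch in text:
        h = (h * 33 + ord(ch)) & 0xFFFFFFFF
    return h


def fragment_bits(fragment: str, n_bits: int = HASHED_FP_BITS) -> tuple[int, int]:
    """The two pseudo-random bit positions a fragment string maps to."""
    return _bkdr_hash(fragment) % n_bits, _djb_hash(fragment) % n_bits


def hashed_fingerprint(mol: Molecule) -> Bitstring:
    """512-bit path fingerprint: two hash-determined bits per fragment string."""
    fp = Bitstring(HASHED_FP_BITS)
    for fragment in linear_fragments(mol):
        b1, b2 = fragment_bits(fragment)
        fp.set(b1)
        fp.set(b2)
    return fp


# ---------------------------------------------------------------------------
# dictionary fingerprint
# ---------------------------------------------------------------------------

def dictionary_fingerprint(mol: Molecule, dictionary: Sequence[Molecule]) -> Bitstring:
    """Per-dictionary-entry substructure bits, identity flag in the LSB.

    Bit ``k+1`` is set when dictionary entry ``k`` is a substructure of
    ``mol``; bit 0 (so the numeric value is odd) when ``mol`` is
    graph-identical to one of the entries.  The width is the dictionary
    size + 1, rounded up to a 32-bit boundary.

    Matching uses exact bond classes (an aromatic bond only matches an
    aromatic bond): this descriptor exists for pre-selection, which is only
    sound when fragment rendering and matching agree on bond classes.
    """
    from .matcher import MatchOptions, match  # deferred: matcher builds on descriptors' siblings

    capacity = 32 * ((len(dictionary) + 1 + 31) // 32)
    fp = Bitstring(capacity)
    opts = MatchOptions(mode="substructure", single_matches_aromatic=False)
    identical = False
    for k, entry in enumerate(dictionary):
        if match(entry, mol, opts).verdict:
            fp.set(k + 1)
            if not identical and match(entry, mol, MatchOptions(mode="exact")).verdict:
                identical = True
    if identical:
        fp.set(0)
    return fp


def identity_entry(mol: Molecule, dictionary: Sequence[Molecule]) -> int | None:
    """Index of the dictionary entry graph-identical to ``mol``, if any."""
    from .matcher import MatchOptions, match

    for k, entry in enumerate(dictionary):
        if match(entry, mol, MatchOptions(mode="exact")).verdict:
            return k
    return None
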