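"""Element data: symbols, default valences and implicit-hydrogen rules.

Only the information needed for connection-table perception is kept:
standard bonding valences (used to derive implicit hydrogen counts from a
V2000 connection table, which stores no hydrogen counts) and a couple of
element class predicates used throughout the descriptor code.
"""

from __future__ import annotations

# Symbols accepted in molfile atom blocks.  Wildcards of the MDL spec are
# carried through untouched (they never receive implicit hydrogens).
ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U",
}

WILDCARDS = {"A", "Q", "*", "L", "LP", "R#", "X", "D", "T"}

HALOGENS = {"F", "Cl", "Br", "I", "At"}

# Default bonding valences.  Multi-valent S and P pick the smallest listed
# valence that accommodates the explicit bond-order sum.
_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,), "B": (3,), "C": (4,), "Si": (4,),
    "N": (3,), "P": (3, 5), "As": (3, 5),
    "O": (2,), "S": (2, 4, 6), "Se": (2, 4, 6), "Te": (2, 4, 6),
    "F": (1,), "Cl": (1,), "Br": (1,), "I": (1,), "At": (1,),
}


def is_heteroatom(symbol: str) -> bool:
    """Anything that is neither carbon nor hydrogen."""
    return symbol not in ("C", "H")


def default_valences(symbol: str, charge: int) -> tuple[int, ...]:
    """Charge-adjusted valence alternatives for an element, () if unknown.

    Group-V/VI elements gain a bonding slot per positive charge and lose one
    per negative charge (N+ binds 4, O- binds 1); carbon and boron lose a
    slot for either charge sign (both CH3+ and CH3- carry three bonds).
    """
    base = _VALENCES.get(symbol)
    if base is None:
        return ()
    if symbol in ("C", "B", "Si"):
        return tuple(max(0, v - abs(charge)) for v in base)
    return tuple(max(0, v + charge) for v in base)


def implicit_hydrogens(symbol: str, charge: int, bond_order_sum: int) -> int:
    """Implicit H count from the standard-valence convention, floored at 0."""
    for v in default_valences(symbol, charge):
        if v >= bond_order_sum:
            return v - bond_order_sum
    return 0
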