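"""Rule-based functional-group perception.

The classifier walks the atom and bond lists of a perceived molecule and
dispatches on local environments, the way a chemist reads a structure: a
C=O double bond triggers carboxyl-derivative discrimination (ester vs
amide vs acid chloride vs anhydride ... by inspecting the heteroatoms on
the carbonyl carbon and *their* substituents), an sp3 nitrogen is an amine
only if nothing disqualifies it (no heteroatom neighbour as in hydrazines
and hydroxylamines, no acyl or sulfonyl residue as in amides and
sulfonamides).  It is this combined presence-and-absence logic that makes
group descriptors more than substructure hits.

Detected groups populate a fixed-position 256-bit descriptor viewable as
eight unsigned 32-bit segments (fg01..fg08), the layout a relational
backend queries with bitwise-AND mask predicates.  The bit-position
registry below is this package's own stable numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .descriptors import FG_BITS, Bitstring
from .molfile_io import BondOrder
from .perception import Molecule
from .periodic import HALOGENS, is_heteroatom

# ---------------------------------------------------------------------------
# registry: bit position -> (key, English name)
# ---------------------------------------------------------------------------

_REGISTRY: tuple[tuple[str, str], ...] = (
    ("cation", "cation"),
    ("anion", "anion"),
    ("carbonyl", "carbonyl compound"),
    ("aldehyde", "aldehyde"),
    ("ketone", "ketone"),
    ("thiocarbonyl", "thiocarbonyl compound"),
    ("imine", "imine"),
    ("hydrazone", "hydrazone"),
    ("oxime", "oxime"),
    ("ketene", "ketene"),
    ("carboxylic_acid_deriv", "carboxylic acid derivative"),
    ("carboxylic_acid", "carboxylic acid"),
    ("carboxylate", "carboxylate salt"),
    ("ester", "carboxylic acid ester"),
    ("lactone", "lactone"),
    ("acid_halide", "carboxylic acid halide"),
    ("acid_chloride", "acid chloride"),
    ("anhydride", "carboxylic acid anhydride"),
    ("carboxamide", "carboxamide"),
    ("primary_carboxamide", "primary carboxamide"),
    ("secondary_carboxamide", "secondary carboxamide"),
    ("tertiary_carboxamide", "tertiary carboxamide"),
    ("lactam", "lactam"),
    ("hydrazide", "carboxylic acid hydrazide"),
    ("imide", "imide"),
    ("amidine", "amidine"),
    ("nitrile", "nitrile"),
    ("isocyanate", "isocyanate"),
    ("isothiocyanate", "isothiocyanate"),
    ("urea", "urea"),
    ("carbamate", "carbamate"),
    ("carbonate", "carbonic acid derivative"),
    ("amine", "amine"),
    ("primary_amine", "primary amine"),
    ("secondary_amine", "secondary amine"),
    ("tertiary_amine", "tertiary amine"),
    ("primary_aromatic_amine", "primary aromatic amine"),
    ("quaternary_ammonium", "quaternary ammonium salt"),
    ("hydrazine", "hydrazine derivative"),
    ("hydroxylamine", "hydroxylamine derivative"),
    ("nitro", "nitro compound"),
    ("nitroso", "nitroso compound"),
    ("azide", "azide"),
    ("diazo", "diazo compound"),
    ("azo", "azo compound"),
    ("hydroxy", "hydroxy compound"),
    ("alcohol", "alcohol"),
    ("primary_alcohol", "primary alcohol"),
    ("secondary_alcohol", "secondary alcohol"),
    ("tertiary_alcohol", "tertiary alcohol"),
    ("phenol", "phenol"),
    ("enol", "enol"),
    ("ether", "ether"),
    ("acetal", "acetal"),
    ("hemiacetal", "hemiacetal"),
    ("epoxide", "epoxide"),
    ("thiol", "thiol"),
    ("thioether", "thioether"),
    ("disulfide", "disulfide"),
    ("thioester", "thiocarboxylic acid ester"),
    ("sulfoxide", "sulfoxide"),
    ("sulfone", "sulfone"),
    ("sulfonic_acid_deriv", "sulfonic acid derivative"),
    ("sulfonic_acid", "sulfonic acid"),
    ("sulfonamide", "sulfonamide"),
    ("guanidine", "guanidine"),
    ("isonitrile", "isonitrile"),
    ("alkene", "alkene"),
    ("alkyne", "alkyne"),
    ("halogen_deriv", "halogen derivative"),
    ("alkyl_halide", "alkyl halide"),
    ("aryl_halide", "aryl halide"),
    ("aryl_fluoride", "aryl fluoride"),
    ("aryl_chloride", "aryl chloride"),
    ("aryl_bromide", "aryl bromide"),
    ("aryl_iodide", "aryl iodide"),
    ("phosphoric_acid_deriv", "phosphoric acid derivative"),
    ("phosphate_ester", "phosphoric acid ester"),
    ("heterocycle", "heterocyclic compound"),
    ("aromatic", "aromatic compound"),
)

POSITION: dict[str, int] = {key: pos for pos, (key, _) in enumerate(_REGISTRY)}
NAME: dict[str, str] = {key: name for key, name in _REGISTRY}
NAME_TO_KEY: dict[str, str] = {name: key for key, name in _REGISTRY}


def registry() -> tuple[tuple[int, str, str], ...]:
    """(bit position, group key, English name) for every registered group."""
    return tuple((pos, key, name) for pos, (key, name) in enumerate(_REGISTRY))


@dataclass
class FGDescriptor:
    bits: Bitstring

    @property
    def segments(self) -> list[int]:
        """fg01..fg08 as unsigned 32-bit integers."""
        return self.bits.segments_u32()

    def keys(self) -> list[str]:
        return [_REGISTRY[p][0] for p in self.bits.positions() if p < len(_REGISTRY)]

    def names(self) -> list[str]:
        return [_REGISTRY[p][1] for p in self.bits.positions() if p < len(_REGISTRY)]

    def has(self, key: str) -> bool:
        return self.bits.get(POSITION[key])

    def ascii(self) -> str:
        return self.bits.ascii()


# ---------------------------------------------------------------------------
# local-environment helpers
# ---------------------------------------------------------------------------

def _single_neighbors(mol: Molecule, i: int):
    return [(j, b) for j, b in mol.neighbors(i)
            if b.order == BondOrder.SINGLE and not b.aromatic]


def _double_neighbors(mol: Molecule, i: int):
    return [(j, b) for j, b in mol.neighbors(i)
            if b.order == BondOrder.DOUBLE and not b.aromatic]


def _is_carbonyl_c(mol: Molecule, i: int) -> bool:
    return (mol.atoms[i].element == "C" and not mol.atoms[i].aromatic
            and any(mol.atoms[j].element == "O" for j, _ in _double_neighbors(mol, i)))


def _is_thiocarbonyl_c(mol: Molecule, i: int) -> bool:
    return (mol.atoms[i].element == "C" and not mol.atoms[i].aromatic
            and any(mol.atoms[j].element == "S" for j, _ in _double_neighbors(mol, i)))


def _is_sulfonyl_s(mol: Molecule, i: int) -> bool:
    return (mol.atoms[i].element == "S"
            and sum(1 for j, _ in _double_neighbors(mol, i)
                    if mol.atoms[j].element == "O") >= 2)


def _is_acyl(mol: Molecule, i: int) -> bool:
    """Carbon or sulfur that makes an attached N an amide/sulfonamide N."""
    return _is_carbonyl_c(mol, i) or _is_thiocarbonyl_c(mol, i) or _is_sulfonyl_s(mol, i)


def _bond_in_ring(mol: Molecule, bond) -> bool:
    return bond.ring_membership > 0


# ---------------------------------------------------------------------------
# per-element dispatch
# ---------------------------------------------------------------------------

def _check_carbon(mol: Molecule, i: int, hit) -> None:
    atom = mol.atoms[i]
    doubles = _double_neighbors(mol, i)
    singles = _single_neighbors(mol, i)
    triples = [(j, b) for j, b in mol.neighbors(i) if b.order == BondOrder.TRIPLE]

    for j, _ in triples:
        if mol.atoms[j].element == "N":
            hit("nitrile")
        elif mol.atoms[j].element == "C" and not atom.aromatic:
            hit("alkyne")

    o_doubles = [j for j, _ in doubles if mol.atoms[j].element == "O"]
    n_doubles = [j for j, _ in doubles if mol.atoms[j].element == "N"]
    c_doubles = [j for j, _ in doubles if mol.atoms[j].element == "C"]
    s_doubles = [j for j, _ in doubles if mol.atoms[j].element == "S"]

    if c_doubles and not atom.aromatic and not any(mol.atoms[j].aromatic for j in c_doubles):
        hit("alkene")
    if s_doubles:
        hit("thiocarbonyl")

    if o_doubles and n_doubles:
        # N=C=O and relatives are cumulated systems, not carboxyl derivatives
        if len(mol.neighbors(i)) == 2:
            hit("isocyanate")
            return
    if s_doubles and n_doubles and len(mol.neighbors(i)) == 2:
        hit("isothiocyanate")
        return

    if o_doubles:
        _check_carbonyl(mol, i, o_doubles, singles, c_doubles, hit)
    elif n_doubles and not atom.aromatic:
        _check_imino_carbon(mol, i, n_doubles, singles, hit)


def _check_carbonyl(mol: Molecule, i: int, o_doubles, singles, c_doubles, hit) -> None:
    """Discriminate the carboxyl derivatives around a C=O carbon."""
    atom = mol.atoms[i]
    if len(o_doubles) >= 2:
        return  # CO2-like cumulated carbon
    if c_doubles:
        hit("ketene")
        return
    hit("carbonyl")

    het_singles = [(j, b) for j, b in singles if is_heteroatom(mol.atoms[j].element)]
    o_single = [(j, b) for j, b in het_singles if mol.atoms[j].element == "O"]
    n_single = [(j, b) for j, b in het_singles if mol.atoms[j].element == "N"]
    s_single = [(j, b) for j, b in het_singles if mol.atoms[j].element == "S"]
    x_single = [(j, b) for j, b in het_singles if mol.atoms[j].element in HALOGENS]

    if not het_singles:
        if atom.attached_hydrogens >= 1:
            hit("aldehyde")
        elif sum(1 for j, _ in singles if mol.atoms[j].element == "C") >= 2 \
                or any(mol.atoms[j].element == "C" and b.aromatic for j, b in mol.neighbors(i)):
            hit("ketone")
        return

    if len(n_single) >= 2:
        hit("carboxylic_acid_deriv")
        hit("urea")
        return
    if n_single and o_single:
        hit("carboxylic_acid_deriv")
        hit("carbamate")
        return
    if len(o_single) >= 2:
        hit("carboxylic_acid_deriv")
        if any(_other_is_carbonyl(mol, j, i) for j, _ in o_single):
            hit("anhydride")
        else:
            hit("carbonate")
        return

    if o_single:
        j, bond = o_single[0]
        o_atom = mol.atoms[j]
        hit("carboxylic_acid_deriv")
        if _other_is_carbonyl(mol, j, i):
            hit("anhydride")
        elif o_atom.attached_hydrogens >= 1:
            hit("carboxylic_acid")
        elif o_atom.charge < 0 and len(mol.neighbors(j)) == 1:
            hit("carboxylate")
        else:
            hit("ester")
            o_c_bond = next((b for k, b in mol.neighbors(j) if k != i), None)
            if _bond_in_ring(mol, bond) and o_c_bond is not None and _bond_in_ring(mol, o_c_bond):
                hit("lactone")
        return

    if n_single:
        j, bond = n_single[0]
        hit("carboxylic_acid_deriv")
        n_atom = mol.atoms[j]
        if any(mol.atoms[k].element in ("N", "O") for k, _ in _single_neighbors(mol, j) if k != i):
            if any(mol.atoms[k].element == "N" for k, _ in _single_neighbors(mol, j) if k != i):
                hit("hydrazide")
            else:
                hit("hydroxylamine")  # N-acyl hydroxylamine keeps the N-O flag
            return
        acyl_count = sum(1 for k, _ in _single_neighbors(mol, j) if _is_carbonyl_c(mol, k))
        if acyl_count >= 2:
            hit("imide")
            return
        hit("carboxamide")
        if n_atom.attached_hydrogens >= 2:
            hit("primary_carboxamide")
        elif n_atom.attached_hydrogens == 1:
            hit("secondary_carboxamide")
        else:
            hit("tertiary_carboxamide")
        if _bond_in_ring(mol, bond):
            hit("lactam")
        return

    if s_single:
        j, _ = s_single[0]
        if any(k != i and mol.atoms[k].element == "C" for k, _ in mol.neighbors(j)):
            hit("carboxylic_acid_deriv")
            hit("thioester")
        return

    if x_single:
        hit("carboxylic_acid_deriv")
        hit("acid_halide")
        if mol.atoms[x_single[0][0]].element == "Cl":
            hit("acid_chloride")


def _other_is_carbonyl(mol: Molecule, o_idx: int, exclude: int) -> bool:
    return any(k != exclude and _is_carbonyl_c(mol, k) for k, _ in mol.neighbors(o_idx))


def _check_imino_carbon(mol: Molecule, i: int, n_doubles, singles, hit) -> None:
    j = n_doubles[0]
    n_atom = mol.atoms[j]
    if n_atom.aromatic:
        return
    n_single_on_c = [k for k, _ in singles if mol.atoms[k].element == "N"]
    n_subst_on_n = [k for k, _ in _single_neighbors(mol, j) if k != i]
    if any(mol.atoms[k].element == "N" for k in n_subst_on_n):
        hit("hydrazone")
        return
    if any(mol.atoms[k].element == "O" for k in n_subst_on_n):
        hit("oxime")
        return
    if len(n_single_on_c) >= 2:
        hit("guanidine")
        return
    if n_single_on_c:
        hit("amidine")
        return
    if any(mol.atoms[k].element == "O" for k, _ in singles):
        return  # imino ether / imidate: outside the registry
    hit("imine")


def _check_nitrogen(mol: Molecule, i: int, hit) -> None:
    atom = mol.atoms[i]
    singles = _single_neighbors(mol, i)
    doubles = _double_neighbors(mol, i)
    triples = [(j, b) for j, b in mol.neighbors(i) if b.order == BondOrder.TRIPLE]

    o_neighbors = [j for j, _ in mol.neighbors(i) if mol.atoms[j].element == "O"]
    n_doubles = [j for j, _ in doubles if mol.atoms[j].element == "N"]
    o_doubles = [j for j, _ in doubles if mol.atoms[j].element == "O"]

    # nitro: N with two terminal oxygens, at least one double-bonded
    terminal_o = [j for j in o_neighbors if len(mol.neighbors(j)) == 1]
    if len(terminal_o) >= 2 and o_doubles:
        hit("nitro")
        return
    if o_doubles and len(mol.neighbors(i)) == 2 \
            and any(mol.atoms[j].element == "C" for j, _ in singles):
        hit("nitroso")
        return

    if len(n_doubles) == 2:
        hit("azide")  # central nitrogen of N=N=N
        return
    if n_doubles and any(mol.atoms[j].element == "C" for j, _ in doubles):
        hit("diazo")
        return
    if triples and any(mol.atoms[j].element == "N" for j, _ in triples):
        # diazonium R-N#N+ or the inner azide nitrogen
        if any(mol.atoms[j].element == "C" for j, _ in singles):
            hit("diazo")
        return
    if triples and any(mol.atoms[j].element == "C" and len(mol.neighbors(j)) == 1
                       for j, _ in triples):
        pass  # nitrile carbon handles C#N; isonitrile has the lone terminal C
    if any(mol.atoms[j].element == "C" and b.order == BondOrder.TRIPLE
           and len(mol.neighbors(j)) == 1 for j, b in mol.neighbors(i)):
        hit("isonitrile")
        return

    if n_doubles and not atom.aromatic:
        c_on_both = [k for k, _ in _single_neighbors(mol, n_doubles[0])]
        if any(mol.atoms[k].element == "C" for k, _ in singles) \
                and any(mol.atoms[k].element == "C" for k in c_on_both):
            hit("azo")
        return

    if doubles or atom.aromatic or triples:
        return  # unsaturated N: imine/azomethine handled at the carbon

    # --- saturated nitrogen ------------------------------------------------
    if atom.charge > 0 and len(singles) == 4:
        hit("quaternary_ammonium")
        return
    acylated = any(_is_acyl(mol, j) for j, _ in singles)
    het_neighbors = [j for j, _ in singles if mol.atoms[j].element in ("N", "O")]
    if het_neighbors:
        if not acylated:
            for j in het_neighbors:
                if mol.atoms[j].element == "N":
                    other_acyl = any(_is_acyl(mol, k) for k, _ in _single_neighbors(mol, j))
                    if not other_acyl:
                        hit("hydrazine")
                else:
                    hit("hydroxylamine")
        return
    if acylated:
        return  # amide / sulfonamide nitrogen, assigned at the acyl center
    c_neighbors = [j for j, _ in singles if mol.atoms[j].element == "C"]
    if not c_neighbors or atom.charge != 0:
        return
    hit("amine")
    if len(c_neighbors) == 1:
        hit("primary_amine")
        if mol.atoms[c_neighbors[0]].aromatic:
            hit("primary_aromatic_amine")
    elif len(c_neighbors) == 2:
        hit("secondary_amine")
    elif len(c_neighbors) == 3:
        hit("tertiary_amine")


def _check_oxygen(mol: Molecule, i: int, hit) -> None:
    atom = mol.atoms[i]
    if atom.aromatic:
        return
    singles = _single_neighbors(mol, i)
    c_singles = [j for j, _ in singles if mol.atoms[j].element == "C"]
    if any(b.order == BondOrder.DOUBLE for _, b in mol.neighbors(i)):
        return  # carbonyl / nitro / sulfonyl oxygens handled at the partner

    if atom.attached_hydrogens >= 1 and len(c_singles) == 1:
        c = c_singles[0]
        c_atom = mol.atoms[c]
        if _is_carbonyl_c(mol, c) or _is_sulfonyl_s(mol, c):
            return  # acid OH, assigned at the acyl center
        hit("hydroxy")
        if c_atom.aromatic:
            hit("phenol")
            return
        if any(b.order == BondOrder.DOUBLE and mol.atoms[k].element == "C"
               for k, b in mol.neighbors(c)):
            hit("enol")
            return
        other_o = [k for k, _ in _single_neighbors(mol, c)
                   if k != i and mol.atoms[k].element == "O"]
        if other_o:
            hit("hemiacetal")
            return
        hit("alcohol")
        carbon_neighbors = sum(1 for k, _ in mol.neighbors(c) if mol.atoms[k].element == "C")
        if carbon_neighbors <= 1:
            hit("primary_alcohol")
        elif carbon_neighbors == 2:
            hit("secondary_alcohol")
        else:
            hit("tertiary_alcohol")
        return

    if len(c_singles) == 2:
        if any(_is_carbonyl_c(mol, j) or _is_thiocarbonyl_c(mol, j) for j in c_singles):
            return  # ester bridge oxygen
        hit("ether")
        if any(len(r) == 3 and i in r for r in mol.rings):
            hit("epoxide")


def _check_acetal_carbon(mol: Molecule, i: int, hit) -> None:
    """sp3 carbon with two single-bonded -OR oxygens is an acetal center."""
    atom = mol.atoms[i]
    if atom.element != "C" or atom.aromatic:
        return
    if any(b.order != BondOrder.SINGLE or b.aromatic for _, b in mol.neighbors(i)):
        return
    or_oxygens = 0
    oh_oxygens = 0
    for j, _ in mol.neighbors(i):
        o = mol.atoms[j]
        if o.element != "O" or o.aromatic:
            continue
        has_other_c = any(k != i and mol.atoms[k].element == "C" for k, _ in mol.neighbors(j))
        if has_other_c:
            or_oxygens += 1
        elif o.attached_hydrogens >= 1:
            oh_oxygens += 1
    if or_oxygens >= 2:
        hit("acetal")
    elif or_oxygens == 1 and oh_oxygens >= 1:
        hit("hemiacetal")


def _check_sulfur(mol: Molecule, i: int, hit) -> None:
    atom = mol.atoms[i]
    if atom.aromatic:
        return
    singles = _single_neighbors(mol, i)
    o_doubles = [j for j, _ in _double_neighbors(mol, i) if mol.atoms[j].element == "O"]
    c_singles = [j for j, _ in singles if mol.atoms[j].element == "C"]
    n_singles = [j for j, _ in singles if mol.atoms[j].element == "N"]
    o_singles = [j for j, _ in singles if mol.atoms[j].element == "O"]
    s_singles = [j for j, _ in singles if mol.atoms[j].element == "S"]

    if len(o_doubles) >= 2:
        hit("sulfonic_acid_deriv")
        if n_singles:
            hit("sulfonamide")
        elif any(mol.atoms[j].attached_hydrogens >= 1 for j in o_singles):
            hit("sulfonic_acid")
        elif len(c_singles) >= 2:
            hit("sulfone")
        return
    if len(o_doubles) == 1 and len(c_singles) >= 2:
        hit("sulfoxide")
        return
    if atom.attached_hydrogens >= 1 and c_singles and not _is_carbonyl_c(mol, c_singles[0]):
        hit("thiol")
        return
    if s_singles:
        hit("disulfide")
        return
    if len(c_singles) == 2 and not any(_is_carbonyl_c(mol, j) for j in c_singles):
        hit("thioether")


def _check_phosphorus(mol: Molecule, i: int, hit) -> None:
    o_doubles = [j for j, _ in _double_neighbors(mol, i) if mol.atoms[j].element == "O"]
    o_singles = [j for j, _ in _single_neighbors(mol, i) if mol.atoms[j].element == "O"]
    if o_doubles and len(o_singles) >= 2:
        hit("phosphoric_acid_deriv")
        if any(any(k != i and mol.atoms[k].element == "C" for k, _ in mol.neighbors(j))
               for j in o_singles):
            hit("phosphate_ester")


def _check_halogen(mol: Molecule, i: int, hit) -> None:
    atom = mol.atoms[i]
    partners = [j for j, _ in mol.neighbors(i) if mol.atoms[j].element == "C"]
    if not partners:
        return
    c = partners[0]
    if _is_carbonyl_c(mol, c):
        return  # acid halide, assigned at the carbonyl
    hit("halogen_deriv")
    if mol.atoms[c].aromatic:
        hit("aryl_halide")
        hit({"F": "aryl_fluoride", "Cl": "aryl_chloride",
             "Br": "aryl_bromide", "I": "aryl_iodide"}.get(atom.element, "aryl_halide"))
    else:
        hit("alkyl_halide")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def detect_groups(mol: Molecule) -> FGDescriptor:
    """Classify every functional group of a perceived molecule."""
    if not mol.perceived:
        raise ValueError("molecule must be perceived before group detection")
    bits = Bitstring(FG_BITS)

    def hit(key: str) -> None:
        bits.set(POSITION[key])

    for i, atom in enumerate(mol.atoms):
        if atom.charge > 0:
            hit("cation")
        elif atom.charge < 0:
            hit("anion")
        element = atom.element
        if element == "C":
            _check_carbon(mol, i, hit)
            _check_acetal_carbon(mol, i, hit)
        elif element == "N":
            _check_nitrogen(mol, i, hit)
        elif element == "O":
            _check_oxygen(mol, i, hit)
        elif element == "S":
            _check_sulfur(mol, i, hit)
        elif element == "P":
            _check_phosphorus(mol, i, hit)
        elif element in HALOGENS:
            _check_halogen(mol, i, hit)

    if any(any(is_heteroatom(mol.atoms[i].element) for i in ring) for ring in mol.rings):
        hit("heterocycle")
    if any(atom.aromatic for atom in mol.atoms):
        hit("aromatic")
    return FGDescriptor(bits)


def group_names(mol: Molecule) -> list[str]:
    return detect_groups(mol).names()


def encode_group_query(positions: Iterable[int]) -> list[int]:
    """Encode selected global bit positions as eight unsigned 32-bit segments."""
    segments = [0] * (FG_BITS // 32)
    for p in positions:
        if not 0 <= p < FG_BITS:
            raise ValueError(f"bit position {p} outside 0..{FG_BITS - 1}")
        segments[p // 32] |= 1 << (p % 32)
    return segments


def encode_group_query_by_key(keys: Iterable[str]) -> list[int]:
    return encode_group_query(POSITION[k] for k in keys)


def mask_predicates(segments: Sequence[int]) -> list[tuple[int, int]]:
    """(1-based segment column, mask) pairs: stored & mask == mask per segment."""
    if len(segments) != FG_BITS // 32:
        raise ValueError(f"expected {FG_BITS // 32} segments, got {len(segments)}")
    return [(i + 1, seg) for i, seg in enumerate(segments) if seg]


def satisfies_masks(stored_segments: Sequence[int], predicates: Sequence[tuple[int, int]]) -> bool:
    return all(stored_segments[col - 1] & mask == mask for col, mask in predicates)
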