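"""Deterministic test inputs: named molecules, toy reactions, and a seeded
random molecule generator.

The named fixtures are shipped as plain-text V2000 molfiles inside the
package data tree; the reactions are assembled at run time from component
molfiles with hand-assigned, balanced atom-atom maps.  The generator
produces connected, valence-clean molecular graphs with a drug-like
profile by default (10-40 heavy atoms, about 70 % carbon, on average two
to three rings) so that descriptor statistics can be sampled without any
external data set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .molfile_io import (BondOrder, MolfileDocument, RawAtom, RawBond,
                         ReactionDocument, parse_molfile, write_rxnfile)

_DATA = resources.files(__package__) / "fixtures_data"

_NAMES = [p.name[:-4] for p in _DATA.iterdir() if p.name.endswith(".mol")]

#: default fragment dictionary: common carbocyclic and heterocyclic ring systems
DEFAULT_DICTIONARY_NAMES = (
    "benzene_kekule_a", "pyridine", "pyrimidine", "pyrazine", "pyridazine",
    "furan", "thiophene", "pyrrole", "imidazole", "pyrazole", "oxazole",
    "thiazole", "naphthalene", "quinoline", "isoquinoline", "indole",
    "cyclopentane", "cyclohexane", "piperidine", "piperazine", "morpholine",
    "tetrahydrofuran",
)


def fixture_text(name: str) -> str:
    path = _DATA / f"{name}.mol"
    if not path.is_file():
        raise KeyError(f"no fixture molecule named {name!r}")
    return path.read_text()


def builtin_molecules() -> dict[str, str]:
    """Mapping of fixture name to molfile text for every shipped molecule."""
    return {name: fixture_text(name) for name in sorted(_NAMES)}


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

# (reactants, products): each molecule is (fixture name, {atom index: map class})
_REACTIONS: dict[str, tuple[list[tuple[str, dict[int, int]]], list[tuple[str, dict[int, int]]]]] = {
    # amine + aldehyde -> imine + water
    "imine_formation": (
        [("methylamine", {0: 2, 1: 1}), ("acetaldehyde", {0: 4, 1: 3, 2: 5})],
        [("n_methyl_ethanimine", {0: 4, 1: 3, 2: 1, 3: 2}), ("water", {0: 5})],
    ),
    # ester + hydrazine -> carboxylic acid hydrazide + alcohol
    "hydrazide_formation": (
        [("methyl_acetate", {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}), ("hydrazine", {0: 6, 1: 7})],
        [("acetohydrazide", {0: 4, 1: 3, 2: 5, 3: 6, 4: 7}), ("methanol", {0: 1, 1: 2})],
    ),
    # isocyanate + amine -> urea
    "urea_formation": (
        [("methyl_isocyanate", {0: 1, 1: 2, 2: 3, 3: 4}), ("methylamine", {0: 5, 1: 6})],
        [("dimethylurea", {0: 1, 1: 2, 2: 3, 3: 4, 4: 6, 5: 5})],
    ),
}


def _mapped_document(name: str, maps: dict[int, int]) -> MolfileDocument:
    doc = parse_molfile(fixture_text(name))
    for idx, cls in maps.items():
        doc.atoms[idx].atom_map = cls
    return doc


def builtin_reactions() -> dict[str, str]:
    """Named toy reactions as RXN file texts with consistent atom maps."""
    out = {}
    for name, (reactants, products) in _REACTIONS.items():
        rxn = ReactionDocument(
            reactants=[_mapped_document(n, m) for n, m in reactants],
            products=[_mapped_document(n, m) for n, m in products],
        )
        out[name] = write_rxnfile(rxn, name=name)
    return out


def default_dictionary() -> list[str]:
    """Molfile texts of the default ring-system fragment dictionary."""
    return [fixture_text(name) for name in DEFAULT_DICTIONARY_NAMES]


# ---------------------------------------------------------------------------
# seeded random molecule generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Knobs of the random molecule generator; defaults are drug-like."""
    seed: int = 0
    min_atoms: int = 10
    max_atoms: int = 40
    element_weights: dict[str, float] = field(default_factory=lambda: {
        "C": 0.70, "N": 0.12, "O": 0.12, "S": 0.03, "F": 0.01, "Cl": 0.02,
    })
    ring_closure_prob: float = 0.09   # per atom; ~2-3 rings at 25-30 atoms
    double_bond_prob: float = 0.15    # per eligible bond
    triple_bond_prob: float = 0.02
    charge_prob: float = 0.0

    def __post_init__(self):
        probs = list(self.element_weights.values()) + [
            self.ring_closure_prob, self.double_bond_prob,
            self.triple_bond_prob, self.charge_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.min_atoms <= self.max_atoms:
            raise ValueError("need 1 <= min_atoms <= max_atoms")


_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1, "P": 3}


def generate_molecule(params: GeneratorParams | None = None) -> MolfileDocument:
    """Draw a connected, valence-clean random molecule; seed-deterministic."""
    params = params or GeneratorParams()
    rng = random.Random(params.seed)
    n = rng.randint(params.min_atoms, params.max_atoms)
    elements = list(params.element_weights)
    weights = [params.element_weights[e] for e in elements]

    doc = MolfileDocument(title=f"generated seed={params.seed}", program="  molpat")
    free: list[int] = []  # remaining valence per atom
    bonds: set[tuple[int, int]] = set()

    def add_atom(element: str) -> int:
        doc.atoms.append(RawAtom(element=element))
        free.append(_MAX_VALENCE[element])
        return len(doc.atoms) - 1

    add_atom("C")  # guarantee an attachable seed atom
    for _ in range(n - 1):
        attachable = [i for i in range(len(doc.atoms)) if free[i] >= 1]
        parent = rng.choice(attachable)
        element = rng.choices(elements, weights)[0]
        if free[parent] == 1 and _MAX_VALENCE[element] == 1 and len(doc.atoms) < n - 1:
            element = "C"  # avoid dead-ending the growth on a halogen pair
        child = add_atom(element)
        doc.bonds.append(RawBond(a1=parent + 1, a2=child + 1))
        bonds.add((parent, child))
        free[parent] -= 1
        free[child] -= 1

    # ring closures between distant atoms with spare valence
    for i in range(len(doc.atoms)):
        if rng.random() >= params.ring_closure_prob:
            continue
        partners = [j for j in range(len(doc.atoms))
                    if j != i and free[i] >= 1 and free[j] >= 1
                    and (min(i, j), max(i, j)) not in bonds
                    and (i, j) not in bonds and (j, i) not in bonds
                    and _graph_distance(doc, i, j) >= 3]
        if partners:
            j = rng.choice(partners)
            doc.bonds.append(RawBond(a1=i + 1, a2=j + 1))
            bonds.add((min(i, j), max(i, j)))
            free[i] -= 1
            free[j] -= 1

    # promote some bonds to double/triple where valence allows
    for bond in doc.bonds:
        i, j = bond.a1 - 1, bond.a2 - 1
        r = rng.random()
        if r < params.triple_bond_prob and free[i] >= 2 and free[j] >= 2:
            bond.order = BondOrder.TRIPLE
            free[i] -= 2
            free[j] -= 2
        elif r < params.triple_bond_prob + params.double_bond_prob \
                and free[i] >= 1 and free[j] >= 1:
            bond.order = BondOrder.DOUBLE
            free[i] -= 1
            free[j] -= 1

    if params.charge_prob:
        for idx, atom in enumerate(doc.atoms):
            if atom.element == "N" and free[idx] >= 1 and rng.random() < params.charge_prob:
                atom.charge = 1  # ammonium-type nitrogen keeps its valence legal
    return doc


def _graph_distance(doc: MolfileDocument, a: int, b: int) -> int:
    from collections import deque
    adj: dict[int, list[int]] = {}
    for bond in doc.bonds:
        adj.setdefault(bond.a1 - 1, []).append(bond.a2 - 1)
        adj.setdefault(bond.a2 - 1, []).append(bond.a1 - 1)
    dist = {a: 0}
    queue = deque([a])
    while queue:
        v = queue.popleft()
        if v == b:
            return dist[v]
        for w in adj.get(v, []):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return 10 ** 9


def extract_needle(doc: MolfileDocument, n_delete: int, seed: int = 0) -> MolfileDocument:
    """Delete up to ``n_delete`` singly-bonded leaf atoms: a guaranteed
    substructure needle.

    Only leaves attached through a single bond are removed, so rings,
    multiple bonds and hence the perception flags (aromaticity, subtypes)
    of every remaining atom are identical in needle and haystack — which
    keeps the needle's descriptors a subset of the haystack's.
    """
    rng = random.Random(seed)
    atoms = [RawAtom(**a.__dict__) for a in doc.atoms]
    bonds = [RawBond(**b.__dict__) for b in doc.bonds]
    for _ in range(n_delete):
        degree: dict[int, int] = {i: 0 for i in range(len(atoms))}
        single_leaf_ok: dict[int, bool] = {}
        for b in bonds:
            degree[b.a1 - 1] += 1
            degree[b.a2 - 1] += 1
        for b in bonds:
            for end in (b.a1 - 1, b.a2 - 1):
                if degree[end] == 1:
                    single_leaf_ok[end] = b.order == BondOrder.SINGLE
        leaves = [i for i, d in degree.items() if d == 1 and single_leaf_ok.get(i)]
        if not leaves or len(atoms) <= 2:
            break
        drop = rng.choice(leaves)
        bonds = [b for b in bonds if drop not in (b.a1 - 1, b.a2 - 1)]
        remap = {old: new for new, old in enumerate(i for i in range(len(atoms)) if i != drop)}
        atoms = [a for i, a in enumerate(atoms) if i != drop]
        for b in bonds:
            b.a1 = remap[b.a1 - 1] + 1
            b.a2 = remap[b.a2 - 1] + 1
    return MolfileDocument(title="needle", atoms=atoms, bonds=bonds)
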