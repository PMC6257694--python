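# molpat

Structure, substructure and functionality-pattern search for small-molecule
collections, built on MDL V2000 connection tables.

Compound archives answer two kinds of chemical questions: "which entries
contain this exact arrangement of atoms?" (substructure search, a subgraph
isomorphism problem) and "which entries carry this chemistry?" (an ester, a
sulfonamide, a primary aromatic amine — regardless of the surrounding
scaffold). `molpat` implements both, the way production chemical databases
do it: every structure is analyzed once at registration time, the analysis
is stored as compact binary descriptors, and queries are answered by a fast
descriptor pre-selection followed — only where necessary — by recursive
atom-by-atom comparison.

The package is aimed at anyone curating or mining small to medium
structure/reaction collections from Python or the shell: the library API is
the primary interface, a thin `molpat` command covers the classic
analyze/match workflows, and `examples/` holds one short narrative script
per capability.

## What is computed

**Perception.** A molfile is lifted to a perceived molecular graph: the set
of all rings (every simple cycle up to 26 atoms, falling back to a smallest
set of smallest rings for highly condensed systems), aromaticity by the
Hückel rule (4n+2 π electrons with uninterrupted conjugation, including
charged rings such as tropylium/cyclopentadienide, heteroatom lone-pair
donors such as furan, and mesomeric exocyclic carbonyls as in the
pyridones), and per-atom hybridization subtypes (sp/sp²/sp³ plus an
aromatic class). Perception results can be persisted inside spec-unused
molfile columns ("tweaked" molfiles) so later searches skip the whole ring
and aromaticity machinery.

**Descriptors**, stored per compound record:

- *molstat* — an ordered vector of integer counters (atoms, bonds, rings by
  size, C–O/C=O/C–N fragments, heteroatom and halogen counts, ...);
- *hashed fingerprint* — each linear path of 3–8 atoms is rendered as a
  canonical atom/bond string and sets two hash-determined bits of a 512-bit
  vector;
- *dictionary fingerprint* — one bit per entry of an exchangeable fragment
  dictionary (62-entry ring-system dictionaries are typical; a default is
  shipped), with the least significant bit flagging exact identity between
  input and dictionary entry;
- *functional-group descriptor* — a fixed-position 256-bit vector over a
  rule-based classifier of 80 registered groups, viewable as eight unsigned
  32-bit segments (`fg01..fg08`), which lets a relational backend evaluate
  a group query as `WHERE (fg01 & 8 = 8) AND (fg02 & 66 = 66)`.

**Search.** Substructure queries run the two-stage process (molstat
dominance + fingerprint bit containment, then matching); similarity queries
rank by Tanimoto score |A∧B|/|A∨B| on hashed fingerprints with a stored
popcount bound as prefilter; functional-group queries are pure bit masks;
reaction queries use cumulative (bitwise-OR) per-side fingerprints and
support group patterns *present in reactants / present in products / lost /
created*, plus atom-map-consistent structure search.

## Worked example

```python
from molpat import StructureIndex
from molpat.fixtures import builtin_molecules
from molpat.functional_groups import POSITION

molfiles = builtin_molecules()
idx = StructureIndex()
for name in ("caffeine", "sulfanilamide", "toluene", "phenol", "diazepam"):
    idx.add(molfiles[name], id=name)

result = idx.substructure_search(molfiles["benzene_kekule_a"])
print(sorted(result.hits), result.candidates)

fg = idx.functional_group_search(
    [POSITION["primary_aromatic_amine"], POSITION["sulfonamide"]])
print(list(fg))
```

prints

```
['diazepam', 'phenol', 'sulfanilamide', 'toluene'] 4
['sulfanilamide']
```

The benzene query finds the four records with a benzene ring (caffeine has
none), and pre-selection admitted exactly those four candidates — no
fruitless atom-by-atom comparison happened. The group query picks out
sulfanilamide alone: only it carries *both* an unsubstituted arylamine and
a sulfonamide. Running the same query from the shell:

```
$ molpat analyze -g sulfanilamide.mol
amine
primary amine
primary aromatic amine
sulfonic acid derivative
sulfonamide
aromatic compound

$ molpat match benzene.mol toluene.mol benzene.mol
1:T
2:T
```

See `examples/` for perception, matching (including E/Z and R/S checks),
similarity ranking, reaction modes and query encoding.

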