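# Methods

This note records the models, conventions and numerical choices behind
`molpat`, and what the shipped tests do and do not demonstrate.

## Perceived molecular graph

Connection tables are parsed from MDL V2000 molfiles. Plain explicit
hydrogens (uncharged, unlabelled, degree 1) are folded into their heavy
neighbour's hydrogen count; the perceived graph is heavy-atom only.
Implicit hydrogens come from standard bonding valences (C 4, N 3, O 2,
S 2/4/6, P 3/5, halogens 1), adjusted by formal charge (N⁺ binds 4, O⁻
binds 1, charged carbon binds 3) and floored at zero. Multi-valent S and P
take the smallest listed valence accommodating the explicit bond-order
sum. A valence excess never aborts perception; it attaches a warning to
the atom.

### Ring search

The default ring set is the *set of all rings*: every simple cycle up to
`max_ring_size` atoms, enumerated by a rooted DFS that emits each cycle
once (rooted at its smallest atom index, direction fixed). `max_ring_size`
defaults to 26 — the molstat counters distinguish ring sizes up to "13 or
more", so the bound must comfortably exceed 13. When a condensed polycycle
would produce more than `ring_budget` (default 1024) cycles, the search
falls back to a smallest-set-of-smallest-rings basis: shortest cycles
through each bond, accepted greedily under GF(2) independence until the
cyclomatic number is reached. Cubane under a budget of 6 yields the
expected 5-ring basis (12 bonds − 8 atoms + 1).

### Aromaticity

Each ring is tested against the Hückel rule: every member must offer a p
orbital and the π electrons must total 4n+2. Per-atom contributions:

| ring-atom environment | π electrons |
|---|---|
| engaged in any double bond (or aromatic-input bond) | 1 |
| all double bonds exocyclic to heteroatoms (pyridone-type C=O) | 0, conjugation intact |
| saturated N, O, S, P with an available lone pair | 2 |
| carbanion centre | 2 |
| carbocation centre | 0 |
| saturated carbon, quaternized N, triple bond in ring | interrupts — ring not aromatic |

This bookkeeping reproduces furan, the tropylium cation, the
cyclopentadienyl anion and both pyridones as aromatic, while cyclohexane
(no p orbitals) and cyclooctatetraene (8 π electrons) fail, and it is
invariant under the input Kekulé structure. A ring drawn entirely with
aromatic-type input bonds is accepted as aromatic directly, since electron
counting on such input is ill-defined. One known consequence of the
mesomeric rule: fully conjugated cyclic amides (the uracil-type ring of
caffeine) perceive as aromatic, so their N–C(=O) bonds are aromatic bonds
and the amide classifier does not fire inside such rings. Fixture-level
group expectations avoid relying on that corner.

### Subtypes

sp: a triple bond or two double bonds; sp²: at least one double bond;
sp³ otherwise; atoms on aromatic rings take the aromatic class. Subtypes
participate in strict-mode matching and in the Morgan rank tie-break.

## Descriptors

**Molstat** is an ordered vector of 29 integer counters. Counters used in
substructure pre-selection must be monotone under subgraph embedding, so
the carbon/heteroatom environment counters are cumulative by design:
`n_C_1het` counts carbons with *at least* one heteroatom neighbour
(`n_C_2het` at least two, …), and `n_C_sp2` counts carbons with at least
one multiple or aromatic bond. An exactly-one definition would let a query
carbon gain a second heteroatom neighbour in a true superstructure and be
wrongly pruned. Ring-derived counters are only compared when both sides'
ring sets came from the set-of-all-rings method, because a fallback basis
may undercount.

**Hashed fingerprint.** Every simple path of 3–8 atoms is rendered as an
alternating atom/bond token string (elements, lowercase when aromatic;
`-`, `=`, `#`, `~` for the bond classes), canonicalized as the
lexicographically smaller of the two reading directions, and fed to two
independent string hashes — a BKDR-style polynomial (base 131) and a
DJB-style hash (base 33, offset 5381) — each reduced modulo 512. The two
resulting positions are set in a 512-bit vector. Rendering aromatic
systems by their perceived class (not the Kekulé input) makes the
fingerprint Kekulé-invariant and keeps screening sound. Path enumeration
is capped at 10⁶ paths per molecule with an explicit overflow error.

**Dictionary fingerprint.** Bit k+1 records that dictionary entry k is a
substructure; bit 0 (an odd numeric value) records graph identity with
some entry, which lets an identity query be answered from stored bits
without any matching. A 22-entry default dictionary of common ring
systems ships with the package; the dictionary is exchangeable.

**Functional groups.** A dispatch classifier walks atoms and bonds: a C=O
carbon triggers carboxyl-derivative discrimination (acid, ester, lactone,
amide incl. primary/secondary/tertiary and lactam, hydrazide, imide,
anhydride, carbamate, urea, acid halide, thioester…), sulfur branches on
its oxidation pattern (sulfonamide, sulfone, sulfoxide, sulfonic acid),
and saturated nitrogens are amines only in the absence of disqualifiers —
no N/O neighbour (hydrazine, hydroxylamine) and no acyl or sulfonyl
residue (amide, sulfonamide). The registry holds 80 groups at fixed bit
positions 0–79 of the 256-bit descriptor; the numbering is this package's
own stable convention. Group semantics are literal-connectivity only: no
tautomer enumeration, charged forms classified as drawn.

## Matching

The needle is matched by backtracking from a reference atom chosen either
by the branching/heteroatom heuristic (maximal heavy degree, then
heteroatom neighbours, then element rarity) or by rarest Morgan rank
(extended-connectivity refinement until the class count stabilizes, ties
broken by element/charge/subtype). Atom pairs must agree on element,
charge and isotope (a charge-agnostic option relaxes neutral query
atoms); strict mode adds the hybridization subtype. Bond classes: aromatic
matches aromatic; in the standalone matcher's lenient default a query
single or double bond may also sit on an aromatic candidate bond. Exact
mode requires a heavy-atom bijection, equal bond counts and equal hydrogen
counts. Explicit query hydrogens are constraints satisfied by the
candidate's total (explicit + implicit) hydrogen count.

Stereochemistry is compared across the mapping, not named: E/Z by the side
signs of reference substituents relative to the double-bond axis in 2D
coordinates, R/S by the sign of the signed tetrahedron volume over three
ordered neighbours, taken from true 3D coordinates or from a wedge/hash
augmented 2D projection. Features lacking coordinates or wedges are
silently not compared.

## Two-stage search

Stage 1 keeps a record when every query molstat counter is ≤ the stored
counter, every set query fingerprint bit is stored, and every set
dictionary bit is stored; similarity search instead uses per-counter
margins and the popcount bound T(a,b) ≤ min(p_a,p_b)/max(p_a,p_b). Stage 2
confirms candidates by matching. **Indexed searches compare bonds by exact
class** (aromatic only matches aromatic): the lenient single-on-aromatic
rule cannot be combined with path-fragment screening, because an isolated
C=C query embedded in an aromatic ring renders different fragment strings
and would be pruned — completeness of pre-selection takes precedence, and
a Kekulé-drawn aromatic query is unaffected since perception normalizes it
first. Stage-2 candidates are processed in batches (configurable, default
64).

Reaction records store cumulative (bitwise-OR) hashed/dictionary/group
fingerprints per side; molstat is not used for reactions. The lost/created
group modes are evaluated on those cumulative bitstrings, which means a
group present on both sides in different molecules counts as neither lost
nor created — the schema-level semantics of per-side descriptors. The
atom-map check accepts a hit when some combination of per-molecule
embeddings sends every mapped query pair (same class on both sides) onto
candidate atoms sharing a candidate map class.

Both a pure in-memory backend and an embedded SQLite backend (columns
`fg01..fg08`, `fp01..fp16`, per-counter molstat columns; mask predicates
as SQL `&` conditions) implement the same stage-1 semantics; the
dictionary containment condition is applied in Python in both.

## Synthetic data

The generator grows a random spanning tree over 10–40 heavy atoms
(attachment respects remaining valence), adds ring closures between atoms
at graph distance ≥ 3 (per-atom probability 0.09, averaging two to three
rings at typical sizes), then promotes bonds to double (p = 0.15) or
triple (p = 0.02) where valence allows. Element draw: C 0.70, N 0.12,
O 0.12, S 0.03, F 0.01, Cl 0.02; univalent elements become leaves
automatically. The profile emulates a drug-like population well enough for
descriptor statistics — the mean hashed-fingerprint bit density over 500
draws lands near one third, the regime binary path fingerprints are
designed for. What it does not emulate: realistic functional-group
frequencies, stereochemistry, charge states (off by default) or synthetic
accessibility, so passing tests say nothing about retrieval *rates* on
real archives — only about correctness and completeness of the machinery.

Needle extraction deletes only singly-bonded leaf atoms, which provably
leaves rings, multiplicities and hence all perception flags of the
remaining atoms untouched: the needle is a guaranteed substructure whose
descriptors are subsets of the haystack's, the property the screening
soundness suite exercises over 500 pairs.

## Numerical and interface choices

- Bit vectors are Python integers; segment i of the 32-bit view holds bits
  32i..32i+31 with bit p at position p mod 32. Tanimoto of two empty
  fingerprints is defined as 1.
- Tweaked molfiles store the per-atom aromatic flag in the atom-block
  `rrr` not-used field (columns 55–57) and the per-bond flag in the
  bond-block `xxx` not-used field (columns 13–15), with the token
  `CMTWEAK` in the header program line. Both fields are ignored by
  conforming readers (verified against an independent parser); the
  deprecated H-designator column was rejected because common readers
  interpret it as a hydrogen-count constraint.
- V3000 input is rejected explicitly; query features (atom lists,
  R-groups) and Sgroup blocks are out of scope.
- SD iteration is fail-fast by default and tolerant (skip bad records) on
  request; `M CHG`/`M RAD` property lines supersede all atom-block
  charges, per the format's precedence rule.
- Search problem sizes in the test suite (200-record indexes, 1,000
  matcher oracle pairs, 500 screening pairs) were chosen as the smallest
  populations that exercise every pre-selection path while keeping the
  whole suite in the tens of seconds.

## Known limitations

- About 80 functional groups are registered, not the several hundred of
  mature classifiers; the bit positions are package-specific.
- Aromatic-input (type 4) bonds are trusted, not kekulized; electron
  counting on partially aromatic-typed input is approximate.
- The stereo comparison checks parity consistency only; it does not assign
  CIP descriptors and ignores centres without wedges or 3D coordinates.
- No tautomer awareness anywhere: groups, fingerprints and matching all
  operate on the literal connection table.
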