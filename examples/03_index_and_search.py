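"""Two-stage structure search over an indexed collection.

Builds a small index (named fixtures plus seeded random molecules), then
runs a substructure search, a Tanimoto similarity ranking and a
functional-group query.  The candidate count shows how descriptor
pre-selection narrows the collection before any atom-by-atom matching.
"""

from molpat import StructureIndex
from molpat.fixtures import GeneratorParams, builtin_molecules, generate_molecule
from molpat.functional_groups import POSITION
from molpat.molfile_io import write_molfile

molfiles = builtin_molecules()
idx = StructureIndex()
for name in ("caffeine", "sulfanilamide", "toluene", "phenol", "diazepam"):
    idx.add(molfiles[name], id=name)
for seed in range(45):
    idx.add(write_molfile(generate_molecule(GeneratorParams(seed=seed))), id=f"G{seed:02d}")

result = idx.substructure_search(molfiles["benzene_kekule_a"])
print(f"benzene substructure: {len(result)} hits "
      f"out of {result.candidates} stage-1 candidates, {len(idx)} records")
print("hits:", sorted(result.hits))

for rid, score in idx.similarity_search(molfiles["caffeine"], min_score=0.4):
    print(f"similar to caffeine: {rid}  Tanimoto={score:.2f}")

fg_hits = idx.functional_group_search(
    [POSITION["primary_aromatic_amine"], POSITION["sulfonamide"]])
print("aryl-NH2 + sulfonamide pattern:", list(fg_hits))
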