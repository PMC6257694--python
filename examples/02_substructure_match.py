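"""Atom-by-atom matching: verdicts, mappings and stereo discrimination.

Benzene is found inside toluene but not the other way around; the E and Z
butenes are constitutionally identical, so only the geometry check can
tell them apart.
"""

from molpat import MatchOptions, enumerate_mappings, match, perceive
from molpat.fixtures import builtin_molecules

mols = {name: perceive(text) for name, text in builtin_molecules().items()}

print("benzene in toluene:", match(mols["benzene_kekule_a"], mols["toluene"]).verdict)
print("toluene in benzene:", match(mols["toluene"], mols["benzene_kekule_a"]).verdict)

maps = enumerate_mappings(mols["benzene_kekule_a"], mols["benzene_kekule_b"],
                          MatchOptions(mappings="all"))
print("benzene self-embeddings:", len(maps), "(the dihedral symmetry of the 6-ring)")

e, z = mols["butene_e"], mols["butene_z"]
print("E = Z without geometry check:", match(e, z).verdict)
print("E = Z with geometry check:  ", match(e, z, MatchOptions(check_geometry=True)).verdict)
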