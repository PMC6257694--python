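"""Perceive a molecule and read off its descriptors.

Loads the ethyl acetate fixture, runs ring/aromaticity/subtype perception,
then prints the detected functional groups, the molstat counters that feed
database pre-selection, and the 256-bit group descriptor as the eight
32-bit segments a relational backend would store in fg01..fg08.
"""

from molpat import compute_molstat, detect_groups, perceive
from molpat.fixtures import builtin_molecules

mol = perceive(builtin_molecules()["ethyl_acetate"])

fg = detect_groups(mol)
print("functional groups:", ", ".join(fg.names()))
print("fg segments (fg01..fg08):", fg.segments)

ms = compute_molstat(mol)
print(f"molstat: {ms.n_atoms} heavy atoms, {ms.n_bonds} bonds, "
      f"{ms.n_CO_double} C=O, {ms.n_CO_single} C-O")
# The single set group family (ester) and the zero ring count identify the
# acyclic ester; the segments are what a functional-group query matches.
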