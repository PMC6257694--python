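"""Reaction indexing and the four functional-group reaction modes.

Indexes three toy reactions and asks which of them create an imine, lose
an isocyanate, and so on — questions answered purely on the cumulative
per-side group descriptors, without any structure matching.
"""

from molpat import ReactionIndex, reaction_fg_search
from molpat.fixtures import builtin_reactions
from molpat.functional_groups import POSITION

ridx = ReactionIndex()
for name, text in builtin_reactions().items():
    ridx.add(text, id=name)

for key, mode in [("imine", "created"), ("isocyanate", "lost"),
                  ("hydrazide", "created"), ("urea", "created")]:
    hits = reaction_fg_search(ridx, [POSITION[key]], mode).hits
    print(f"{key!r} {mode}: {hits}")

# Structure-level reaction search with atom-map verification:
text = builtin_reactions()["imine_formation"]
print("self search with map check:", ridx.reaction_search(text, check_maps=True).hits)
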