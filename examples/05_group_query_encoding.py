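"""Encoding a functional-group selection as segment masks.

A selection of group bit positions becomes eight unsigned 32-bit segments;
each non-zero segment yields one bitwise-AND predicate of the form
``fgNN & mask = mask`` — the entire search condition a relational backend
needs.
"""

from molpat import encode_group_query, mask_predicates

selection = {3, 33, 38}
segments = encode_group_query(selection)
print("selected bit positions:", sorted(selection))
print("segments fg01..fg08:", segments)
for col, mask in mask_predicates(segments):
    print(f"SQL condition: fg{col:02d} & {mask} = {mask}")
# Position 3 lands in segment 1 as 2^3 = 8; positions 33 and 38 land in
# segment 2 as 2^1 + 2^6 = 66.
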