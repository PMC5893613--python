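"""Measure a dendritic tree: branchlets, lengths, membrane area.

Builds a synthetic VS-like morphology (two trunks, ~450 branchlets) and
prints its summary morphometrics, the quantities usually tabulated for
reconstructed cells. Swap in `read_swc("my_cell.swc")` for a real
reconstruction.
"""

from vscable import SynthMorphSpec, branchlet_table, make_vs_like_tree, morphometrics

tree = make_vs_like_tree(SynthMorphSpec(seed=0))
met = morphometrics(tree)

print(f"cell: {tree.name}")
print(f"total dendritic length : {met.total_dendritic_length:8.0f} μm")
print(f"total membrane area    : {met.total_membrane_area:8.0f} μm²")
print(f"average diameter       : {met.average_diameter:8.2f} μm (length-weighted)")
print(f"avg terminal diameter  : {met.average_terminal_diameter:8.2f} μm")
print(f"branchlets / terminals : {met.n_branchlets} / {met.n_terminals}")

table = branchlet_table(tree)
print("\nfirst branchlets (maximal unbranched sections):")
print(table.head(5).to_string(index=False))
# Each row is one branchlet; the sum of length_um over all rows equals the
# total dendritic length exactly — branchlets partition the arbor.
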