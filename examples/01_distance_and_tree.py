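"""Event-weighted distances between single metaphases and a rooted NJ tree.

Builds four small karyotypes by hand — a normal male mouse cell, a cell
with one extra chr3, a cell carrying one nonreciprocal translocation
t(2;4), and the same cell after whole-genome duplication — then prints
their pairwise distances and the Newick tree rooted on the euploid
CONTROL outgroup.
"""

from karyoevo import (
    MetaphaseKaryotype,
    NORMAL_MALE_COUNTS,
    StructuralEvent,
    build_distance_matrix,
    neighbor_joining,
    parse_event_notation,
    root_with_outgroup,
)


def cell(cell_id, counts, events=()):
    return MetaphaseKaryotype(cell_id, "demo", counts, tuple(events))


normal = cell("normal", dict(NORMAL_MALE_COUNTS))

gain3 = dict(NORMAL_MALE_COUNTS)
gain3["3"] += 1
trisomy3 = cell("trisomy3", gain3)

nrt = parse_event_notation("t(2;4)")
c = dict(NORMAL_MALE_COUNTS)
c["2"] -= 1
c["4"] -= 1                      # the derivative consumes one copy of each
nrt_cell = cell("nrt", c, [nrt])

cw = {k: 2 * v for k, v in c.items()}   # WGD doubles every body
nrt_wgd_cell = cell("nrt_wgd", cw, [nrt.with_copies(2)])

matrix = build_distance_matrix([normal, trisomy3, nrt_cell, nrt_wgd_cell],
                               include_control=True)
print("labels:", matrix.labels)
print(matrix.values)
print()
print("d(normal, trisomy3) =", matrix["normal", "trisomy3"],
      "# one gain = weight 1")
print("d(normal, nrt)      =", matrix["normal", "nrt"],
      "# de novo NRT = weight 5")
print("d(normal, nrt_wgd)  =", matrix["normal", "nrt_wgd"],
      "# NRT + WGD = 5 + 1 = 6, not 10")

tree = root_with_outgroup(neighbor_joining(matrix), "CONTROL")
print()
print("rooted tree:", tree.to_newick())
print("root-to-leaf path lengths (accumulated event weight):")
for leaf, length in sorted(tree.root_to_leaf_lengths().items()):
    print(f"  {leaf:10s} {length:.1f}")
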