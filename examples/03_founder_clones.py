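"""Founder-clone identification, evolutionary ordering, and seeding flags.

From a simulated tumor sample: build the event-weighted NJ tree rooted on
the normal CONTROL cell, extract founder clones (maximal clades sharing an
identical event set), order them by genotype containment with WGD treated
as irreversible, and report parallel/polyclonal seeding across sites.
"""

from karyoevo import (
    SimulationConfig,
    build_distance_matrix,
    identify_founder_clones,
    infer_seeding_pattern,
    neighbor_joining,
    order_founder_clones,
    root_with_outgroup,
    simulate_case,
)

case = simulate_case(SimulationConfig(seed=2, n_sites=3,
                                      generate_cnv=False))

all_fcs = []
for sample in case.samples:
    tree = root_with_outgroup(
        neighbor_joining(build_distance_matrix(sample.cells)))
    fcs = identify_founder_clones(tree, sample.cells)
    lineage = order_founder_clones(fcs)
    print(f"{sample.sample_id}: {len(fcs)} founder clones")
    for fc in lineage.fcs:
        print(f"  {fc.fc_id}: {len(fc.member_cells)} cells, "
              f"wgd={fc.genotype.wgd}, "
              f"{len(fc.genotype.events)} structural events, "
              f"parent={fc.parent_fc}")
    all_fcs += [fc for fc in fcs]

report = infer_seeding_pattern(all_fcs, case.site_of_cell)
print()
print("parallel seeding (one clone, several sites):",
      report.parallel_seeding or "none")
print("polyclonal seeding (one site, several clones):",
      report.polyclonal_seeding or "none")
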