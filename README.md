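# karyoevo

Single-cell karyotype clonal-evolution analysis for mouse tumor cytogenetics.

Spectral karyotyping (SKY) resolves, for every metaphase cell, the copy
number of each chromosome and its structural rearrangements — nonreciprocal
translocations `t(a;b)`, reciprocal translocations `t(a;b)&t(b;a)`, fusions
`f(a;b)` and rings `ring(a;a)`. Because a nonreciprocal translocation (NRT)
has a unique breakpoint at single-nucleotide resolution, an NRT shared by two
cells marks a common ancestor, which makes per-metaphase karyotypes a
single-cell lineage record. `karyoevo` turns tables of such karyotypes, and
matched 10-kb binned copy-ratio profiles from whole-genome sequencing, into
quantitative clonal-evolution analyses:

- **WGD calling** — a mouse cell with ≥ 50 chromosomal bodies (ploidy 2.5)
  is called whole-genome duplicated (sub-4N); below, near-2N.
- **Clonality and acquisition timing** — an event carried by > 50% of a
  sample's metaphases is clonal (a *cNRT*). In sub-4N cells, 2 NRT copies
  with 2 intact partner copies mean the NRT predates WGD (cNRT²ᴺ); 1 copy
  with 3 partner copies means 4N-stage acquisition (cNRT⁴ᴺ). The cNRT²ᴺ /
  cNRT⁴ᴺ pattern classifies a case as multifocal Type 2 vs single-mass
  Type 1.
- **Event-weighted phylogenies** — pairwise distances between metaphases
  weight every chromosome gain/loss at 1, a de novo NRT at 5 (its breakpoint
  is a unique lineage identifier), and WGD at 1 (one genetic event despite
  doubling 40 chromosomes): a cell that acquired an NRT at 2N and then
  doubled its genome is at distance 5 + 1 = 6 from normal, not 10. Trees are
  built by neighbor joining and rooted on a euploid CONTROL outgroup, so the
  root-to-leaf path length is the accumulated somatic event weight.
- **Founder clones** — maximal clades sharing an identical event set are
  founder clones (FCs); their genotypes, ordered by containment with WGD
  treated as irreversible (2N → 4N only), give the clonal lineage and
  parallel/polyclonal seeding calls across anatomical sites.
- **Inter-lineage sharing null** — `p = (n_d/n_r)/(n_a − 1)` over randomly
  sampled metaphase pairs quantifies how often NRT sharing crosses animals
  (lineages); an exhaustive pair enumeration is provided as the exact
  reference.
- **CNV trees** — per-chromosome `log2(ci/median(c))` from SKY counts vs
  per-chromosome medians of 10-kb binned WGS log2 ratios; L1 distance
  `Σᵢ |rₐⁱ − r_bⁱ|` between binned profiles feeding NJ trees for
  single-cell-derived clones; and shared/private segment-event partitions
  for the trunk/branch "manual" trees of bulk samples.
- **Forward simulator** — generation-synchronous karyotype evolution with
  gains/losses, uniquely-breakpointed NRT acquisition, one WGD per lineage
  followed by gradual chromosome loss into the 60–80 range, multi-site
  seeding, and matched binned CNV output, all with replayable ground truth.

## Worked example

```python
from karyoevo import (MetaphaseKaryotype, NORMAL_MALE_COUNTS,
                      build_distance_matrix, neighbor_joining,
                      parse_event_notation, root_with_outgroup)

normal = MetaphaseKaryotype("normal", "demo", dict(NORMAL_MALE_COUNTS))
nrt = parse_event_notation("t(2;4)")
c = dict(NORMAL_MALE_COUNTS); c["2"] -= 1; c["4"] -= 1
nrt_cell = MetaphaseKaryotype("nrt", "demo", c, (nrt,))
cw = {k: 2 * v for k, v in c.items()}
nrt_wgd = MetaphaseKaryotype("nrt_wgd", "demo", cw, (nrt.with_copies(2),))

m = build_distance_matrix([normal, nrt_cell, nrt_wgd], include_control=True)
print(m["normal", "nrt"], m["normal", "nrt_wgd"])
tree = root_with_outgroup(neighbor_joining(m), "CONTROL")
print(tree.to_newick())
```

prints

```
5.0 6.0
(CONTROL:0.000000,(normal:0.000000,(nrt:0.000000,nrt_wgd:1.000000):5.000000):0.000000);
```

— the NRT-bearing cell sits 5 weighted events from normal, its
genome-doubled descendant one more (the WGD), and the rooted tree places
both on a single branch 5 from the euploid ancestor. The `examples/`
directory has one short script per capability (distances and trees,
simulation and case typing, founder clones, the sharing null, CNV trees,
Fisher counts); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library:

```sh
karyoevo simulate --seed 1 --scenario TYPE2 --out fixtures/
karyoevo tree --input fixtures/karyotypes.tsv --sample M1_T1 --out tree.nwk
karyoevo fisher --table 8 6 1 8
```

## File formats

- **Karyotype TSV** — header `cell_id sample_id animal_id site passage
  chr1..chr19 chrX chrY events`; `events` is a semicolon-joined list of
  notation strings, with optional `xN` (copies) and `@id` (breakpoint tag)
  suffixes; a JSON mirror carries the same schema.
- **Bin tables** — `chrom start end log2_ratio` on a 10-kb grid, or a
  Control-FREEC-style `chrom start ratio` file (linear ratios converted to
  log2).
- **Trees** — Newick with 6-decimal branch lengths; founder-clone lineages
  export as JSON and Graphviz DOT.

See `docs/methods.md` for the model, parameter defaults, numerical choices,
and what the synthetic generator does and does not emulate.
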