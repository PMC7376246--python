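# Methods

## The data and what it is assumed to mean

The unit of observation is a metaphase: one mitotic cell in which every
chromosome was counted and painted. A karyotype here is (i) a copy number
for each of the 21 mouse chromosomes (chr1–19, X, Y) and (ii) a set of
structural events in a small ISCN-like grammar — nonreciprocal
translocations `t(a;b)` (NRTs), reciprocal translocations `t(a;b)&t(b;a)`,
fusions `f(a;b)` and rings `ring(a;a)` — each with a copy count and an
optional breakpoint tag. Two analytical assumptions carry all the lineage
inference:

1. **An NRT breakpoint is unique.** The chance that two independent cells
   produce the same translocation with the same single-nucleotide breakpoint
   is negligible, so a shared NRT identity implies a shared ancestor. Event
   identity is the tuple (kind, ordered participants, breakpoint tag); when
   tags are absent, identity degrades to kind + participants, which is safe
   within one animal and is the default scoping.
2. **WGD is one event and is irreversible.** A whole-genome duplication
   doubles every chromosome and every derivative in one step; lineages never
   return from sub-4N to near-2N.

`total_count` counts every chromosomal body on the spread — intact
chromosomes plus each derivative copy — since that is what a cytogeneticist
counts. The WGD call is `total_count >= 50` (mouse ploidy 2.5); the boundary
value 50 falls on the WGD side, consistent with a bimodal count distribution
split at ploidy 2.5.

## Clonality and acquisition timing

An event is clonal in a sample iff carried by strictly more than half of
its metaphases. For a clonal NRT, acquisition timing relative to WGD is
read off the modal copy pattern among sub-4N carriers:

- modal NRT copies = 2 → acquired at the 2N stage and doubled with the
  genome (cNRT²ᴺ; such cells carry 2 intact copies of each participant);
- modal NRT copies = 1 with modal intact-participant count ≥ 3 → acquired
  in a 4N cell (cNRT⁴ᴺ);
- only near-2N carriers with one copy → cNRT²ᴺ in its single-copy state;
- anything else, including modal ties, → undetermined. Ties break toward
  undetermined deliberately: post-WGD chromosome losses can erode either
  pattern, and guessing would convert honest ambiguity into silent error.

A case (animal) is Type 2 if any clonal NRT classifies as cNRT²ᴺ, else
Type 1 if any classifies as cNRT⁴ᴺ, else undetermined. This is the
karyotype-based correlate of the multifocal vs single-mass growth patterns;
radiographic classification is out of scope.

## The event-weighted distance

Each chromosomal event converts to distance weight 1, with two exceptions:
a de novo NRT acquisition weighs 5 (it is the high-confidence lineage
identifier) and WGD weighs 1 (one genetic process, not 40 gains). The
distance between two cells is computed on canonical profiles:

- a WGD flag (from the count threshold);
- per-chromosome deviations of **material copy number** from the
  ploidy-scaled baseline (2 per autosome, X=1, Y=1 for male mice,
  configurable; doubled in WGD cells). Material copy number credits each
  derivative to its participants, so a copy-neutral translocation changes
  only the event term — this is what makes "normal vs NRT-then-WGD" come
  out as exactly 5 + 1 = 6 even though the NRT-bearing cell has only 2
  intact copies of each participant;
- the event set with ploidy-normalized copies: an event present in exactly
  one profile contributes its acquisition weight (5 for NRT, 1 otherwise);
  present in both, it contributes the copy difference after dividing by 2
  in a WGD cell where the event predates the WGD (≥ 2 copies; single-copy
  events in a WGD cell are treated as post-WGD).

The per-chromosome term uses |Δcount| — each unit of copy difference is one
gain/loss event. The distance is symmetric and zero exactly on equal
canonical profiles, but the triangle inequality is not guaranteed;
neighbor joining accepts such dissimilarities. One known distortion: a
pre-WGD gain appears as a deviation of 2 against the doubled baseline and
is charged 2 rather than 1. Only WGD and NRT acquisitions receive the
single-event discount, which matches the stated weighting rules; the
root-to-leaf correlation checks below bound the practical effect.

## Tree building

Neighbor joining is implemented directly (Q-criterion, Saitou–Nei branch
lengths) so its two free choices are pinned: Q ties break to the
lexicographically smallest pair of subtree labels (each subtree keyed by
its smallest leaf label), and a negative branch estimate is clamped to zero
with the deficit moved to its sibling, preserving the joined pair's path
length. On additive matrices the algorithm is exact; the suite verifies
exact recovery for every unrooted topology on up to 6 leaves with integer
branch lengths.

A synthetic euploid CONTROL cell (40 chromosomes, no events) is appended as
outgroup; rooting places the root at the CONTROL end of its pendant edge,
so root-to-leaf path length reads as accumulated somatic event weight.
Newick output uses fixed 6-decimal branch lengths and is byte-deterministic
for identical input.

## Founder clones and lineage ordering

Founder clones (FCs) are maximal clades of the rooted tree whose member
cells share an identical structural-event set and WGD flag. Because equal
cells sit at distance zero and zero-length edges resolve arbitrarily,
clades with identical genotypes are merged into one FC. An FC's genotype is
the intersection of its members' canonical profiles: shared events with
minimum copies, plus per-chromosome deviations on which all members agree.
Clades of ≥ 2 cells are full FCs; singletons are kept but flagged
low-confidence (cluster choice is a judgment call on real trees).

Ordering uses genotype containment: G can parent H iff G's events are a
subset of H's, WGD is monotone, and deviations are consistent — same-ploidy
children may only extend gains/losses, while crossing WGD doubles G's
deviations and then allows erosion by random losses (a doubled loss may
deepen but not revert; a doubled gain must remain a gain). Each FC's parent
is the containing FC with the most events (the closest ancestor); when two
incomparable candidates tie, both are recorded and the edge is left
unresolved rather than guessed. Site annotations of member cells yield the
seeding report: an FC spanning several sites is parallel seeding, a site
holding several FCs is polyclonal seeding.

## The inter-lineage sharing null

Pairs of metaphases are sampled uniformly with replacement (self-pairs
rejected) from the pooled cohort; `n_r` counts pairs sharing ≥ 1 NRT
identity, `n_d` those from different animals, and
`p = (n_d / n_r) / (n_a − 1)`, the 1/(n_a − 1) factor normalizing for an
inter-lineage pair being (n_a − 1)× as likely as an intra-lineage one under
uniform pairing. The estimate is seed-reproducible; `exact_interlineage_p`
enumerates all C(n, 2) pairs and is the exact reference the Monte-Carlo
estimator is tested against (within 3 binomial standard errors at 10⁵
pairs on a 30-cell cohort). With no sharing pair observed the estimate is
flagged undefined and reported as 0.

## CNV profiles

Binned profiles are 0-based half-open 10-kb windows carrying log2 copy
ratios relative to a matched normal (0 = balanced). The SKY-side
per-chromosome value is `log2(ci / median(c))` with ci the mean count of
chromosome i over cells and the median taken over chromosomes 1–19 and X
(Y excluded); by default ci uses material copy number so derivatives count
toward their participants. Note the formula is median-normalized raw
counts: in a male genome the single X scores as a loss, whereas
ratio-vs-matched-normal bins score it 0 — comparisons on male karyotypes
should expect that one discordant point, and the matched-data tests use
sex-balanced karyotypes where the two definitions coincide.

The WGS side is the per-chromosome median of bin values (robust to focal
events); agreement is summarized by the Pearson r over shared chromosomes.
The clone-tree distance is the plain L1 sum over shared bins — a true
metric — with NJ and an all-zero outgroup on top. Segment events are
maximal contiguous runs of bins beyond ±0.3 log2 (configurable; the
upstream caller's internal thresholds are not published), events covering
≥ 95% of a chromosome's binned span are excluded as whole-chromosome (and
as terminal-bin-artifact protection), and events with identical boundaries
and direction in ≥ 2 samples are shared. The "manual" tree is the
containment tree of carrier sample-sets under a virtual root: the trunk
edge carries the all-shared event count, each leaf branch the private
count, reproducing length-proportional-to-event-count drawings
deterministically.

## The synthetic generator

`simulate_case` grows a population from one normal male founder with
synchronous divisions (every cell divides once per generation; 8
generations = 256 final cells by default) and samples 20 cells per site at
the end. Per daughter per division: each chromosome gains with p = 0.003
and loses with p = 0.003 (never to zero), an NRT arises with p = 0.02
(unique breakpoint, consuming one intact copy of each participant), a
fusion with p = 0.004, a ring with p = 0.002. The scenario plants the
clonal structure: Type 2 acquires the founding NRT at generation 1 and WGD
at generation 3 inside the NRT lineage, keeping a near-2N NRT
subpopulation for the SVZ site; Type 1 applies WGD at generation 1 and the
founding NRT immediately after, in the 4N cell, and suppresses NRT
acquisition in non-WGD cells (its defining property). After WGD each
descendant division sheds a Binomial(excess, 0.4) number of bodies toward
a per-lineage target drawn uniformly from [60, 80], each loss removing one
copy of a body present in ≥ 2 copies — losses are therefore mosaic across
the clone, the founder's modal copy pattern survives, and a 2-copy
founding NRT occasionally drops to one copy, producing the honest
undetermined acquisition calls the classifier must tolerate. Sites draw
90% of their cells from the designated dominant clone and the rest from a
minor pool (parallel seeding: the WGD clone populates several parenchymal
sites; polyclonal seeding: a later-marked subclone shares a site).

No event rates are published for this system; the defaults above were
chosen once to reproduce the qualitative regime — near-total clonality of
the founding NRT, sub-4N totals averaging ~70, a few subclonal background
events per sample — and are documented as arbitrary. The generator does
not model selection or fitness, cell death, spatial structure, breakpoint
sequence, multiple WGDs per lineage, or SKY mis-calls; passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative assumptions, not robustness to measurement error in real
spreads.

Matched CNV output maps each site's dominant-clone exemplar karyotype to
bins: material copies per chromosome, divided by the normal baseline and
then by the median relative value over chr1–19 and X (so normal is flat
zero and pure WGD cancels), Gaussian noise of σ = 0.1 per bin, zero-copy
bins floored at −5, and an optional focal driver deletion (a homozygous
40-kb-scale loss on chr11 by default) overlaid on the whole tumor lineage
so that tumor sites share it with identical boundaries. The default genome
is mm9 at 10-kb bins; tests use a scaled-down genome (20–100 bins per
chromosome) purely for speed, as the math is grid-size-agnostic.

Every sampled cell carries a replayable operation ledger; replaying it must
reproduce the cell's counts and events exactly, which the suite asserts for
all sampled cells. Exports (karyotype TSV, bin tables, true tree Newick,
ledger JSON) are byte-identical across runs at a fixed seed.

## Statistics

The two-sided Fisher exact p is computed by explicit hypergeometric
enumeration with fixed margins: all tables whose probability is at most
that of the observed table (with the customary 1 + 1e-7 relative slack
against floating-point ties) are summed. Degenerate margins return p = 1
with a warning. The suite checks agreement with an independent factorial
enumeration oracle on every table with total ≤ 30 and with the standard
scipy implementation. Proportion reports give raw pairwise p-values by
default; Holm step-down adjustment is available behind a flag.

## Determinism and seeds

All randomness flows from explicit integer seeds: the simulator from
`SimulationConfig.seed`, the sharing estimator from its `seed` argument,
the pipeline from one root seed. NJ, Newick serialization, table writers
and report renderers are seed-free and byte-deterministic; two runs on the
same inputs and seeds produce identical files.

## Known limitations

- The event-weighted distance is not a metric and mildly over-charges
  pre-WGD copy-number changes (see above); NJ branch lengths inherit the
  distortion. Root-to-leaf lengths still track true accumulated event
  weight with Spearman ≥ 0.9 per simulated case.
- Acquisition classification depends on modal copy patterns; heavy post-WGD
  loss can erase them, which surfaces as undetermined rather than as a
  wrong class (~5% of clonal NRTs under default simulation conditions).
- Cross-animal event identity without breakpoint tags falls back to
  notation equality; cohorts mixing tagged and untagged events should tag
  consistently.
- Unobserved intermediate founder clones can be proposed with
  `predict_intermediate_fcs` (the genotype intersection of two observed
  same-ploidy FCs, when strictly above their common ancestors), but they
  are flagged predicted with no member cells and are not inserted into
  lineages automatically; ambiguous parentage is likewise reported, not
  resolved.
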