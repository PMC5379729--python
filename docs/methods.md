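# Methods

## The calling model

The caller operates on precomputed pairwise alignment blocks: half-open
intervals on the focal genome, one table row per (species, interval,
identity). Identity is defined as matched columns over focal-genome non-gap
bases — every downstream threshold is phrased relative to the focal region,
so identity and coverage then share one coordinate system. Strand is
ignored; chaining/netting of raw aligner output is out of scope and the
synthetic generator emits block tables directly.

Two filters define a call:

* **Non-mammal conservation.** Per species, qualifying blocks (identity ≥
  `min_identity`, default 0.40, inclusive) are unioned; a per-base sweep
  counts distinct species, and maximal intervals with depth ≥
  `min_nonmammal_species` (default 2) are kept, optionally bridging gaps ≤
  `merge_gap` (default 0 — no bridging, so call sets err on the
  conservative, fragmented side), then filtered to length strictly >
  `min_length` (default 1000 bp).
* **Mammal support.** A mammal supports a candidate when the union of its
  qualifying blocks (identity ≥ `mammal_min_identity`, default 0.40)
  intersected with the candidate covers strictly more than
  `mammal_min_coverage` (default 0.40) of the candidate's length; candidates
  with more than `max_mammal_support` (default 8) supporters are dropped.

Threshold inclusivity is deliberate and asymmetric: identity cutoffs are
inclusive ("no less than"), length and coverage cutoffs strict ("longer
than"). The boundary cases — identity exactly 0.40 retained, length exactly
1000 rejected, coverage exactly 40% not support, 8 supporters pass / 9
fail — are pinned by unit tests.

The ≥2-species condition is enforced per base (depth of distinct species),
the stricter of the two defensible readings; `support_mode="region"` offers
the laxer one (any interval covered by ≥1 qualifying species counts when at
least 2 species overlap it anywhere). Mammal coverage is always measured
against the final merged candidate, not individual blocks. Output ordering
is lexicographic (chrom, start) with supporter lists sorted by species id,
so runs are deterministic.

The sensitivity grid reruns the caller over identity × coverage pairs
(defaults 0.40/0.50/0.60 × 0.40/0.20/0). The identity axis moves both the
non-mammal and the mammal-side identity (they are one "similarity
threshold" conceptually); coverage 0 means any overlapping mammal counts as
support — the strictest cell. Count monotonicity in identity is guaranteed
under the generator's conditions (each planted region is covered at a
single identity, so regions vanish whole as the threshold rises); on
arbitrary inputs a conserved interval could in principle split into two
qualifying pieces, so monotonicity is asserted over tested datasets, not
claimed as a theorem.

## Positional-bias test

Each chromosome is split into two terminal zones of `end_fraction` (default
0.10, deliberately exposed — "ends" has no canonical definition) and a
middle. Regions are assigned to zones by midpoint (unambiguous,
order-independent; straddling regions are not split), densities are per bp
of zone so unequal zone sizes cannot bias the comparison, and the per-
chromosome differences d = density_end − density_mid enter a one-sided
paired t-test (t = mean(d)·√n / sd(d), Student t with n−1 df, H1: mean >
0). sd = 0 yields a degenerate result (p = NaN) with a warning rather than
a crash. Under uniform placement the test's empirical type-I error at α =
0.05 measures 0.03–0.05 over 1000 replicates (12 chromosomes × ~24 regions
each; mildly conservative because zone counts are small and discrete).

## Composition

Foreground (called regions) and background (whole genome) label fractions
are computed by a boundary sweep with coordinate compression; overlapping
annotations are resolved by an explicit priority list (first label wins)
and unannotated bases receive a designated default label, so fractions sum
to exactly 1 on both sides. Gene-biotype priority: protein_coding >
lincRNA > antisense > other > non_gene. Chromatin priority follows the
7-class segmentation order (Heterochrom, Txn, Enhancer, Promoter,
Repressed, Insulator, Repetitive). A per-base numpy reference implementation
lives in the test suite and is checked against the sweep on random tracks.

## Window profiles

w1 = [start−flank, start), w2 = [start, start+edge), w3 = the middle,
w4 = [end−edge, end), w5 = [end, end+flank), with flank = edge = 300 bp by
default. Fixed windows are binned at `fixed_bin_size` bp per bin (default
10); w3, whose length varies across regions, is rescaled to `middle_bins`
(default 300) bins by proportional per-base assignment, implemented as
differences of the linearly interpolated prefix sum — per-bin values are
weighted means whose weights sum to the window length, so total covered
bases are conserved exactly. Per-bin values are averaged across regions
unweighted; windows clipped at chromosome boundaries and empty middles
contribute missing values excluded from the mean with count bookkeeping
(for GC, N bases are likewise excluded from the denominator). Histone
tracks average signal values (mean of overlapping interval values per base,
0 where uncovered) instead of covered fraction. The genome-wide mean of
each feature is attached as a flat reference level.

The GC calibration check uses 200 regions of 20 kb with 50 bp fixed bins:
at that size every bin mean pools ≥ 10,000 bases, so on a uniform-random
genome the per-bin standard error is ~0.005 and the whole curve sits within
0.02 of 0.5.

## Phylogenetic event counting

Per-region trees are built from aligned homologous sequences by p-distance
(mismatches over both-non-gap columns) and neighbor joining with the
Saitou–Nei Q-criterion; ties are broken by the lexicographically smallest
species pair, making the reconstruction fully deterministic. NJ replaces
likelihood-based reconstruction deliberately: only the topology feeds the
SPR stage, NJ is exact on additive distances (verified on fixed 5- and
8-leaf trees and cross-checked against scikit-bio), and it needs no
external optimizer. The unrooted NJ tree is rooted at a user-designated
outgroup leaf (the most basal non-mammal lineage in the synthetic tree).

The minimum number of rooted subtree-prune-and-regraft moves between the
region tree and the species tree (pruned to their common leaf set) lower-
bounds the number of transfer events: each discordant placement needs at
least one move. The search first collapses maximal pendant subtrees common
to both trees into composite leaves (verified not to change the distance
against an uncollapsed brute-force search), then runs bidirectional
breadth-first search over SPR neighbourhoods with canonical-form
deduplication. Levels are expanded in full and the minimum over all
meeting states is kept until no shorter undiscovered path can exist, which
makes the result exact; it is validated against a full-enumeration BFS over
all 105 rooted 5-leaf topologies. Every result carries a witness move
sequence (pruned-clade leaf set, regraft-position leaf set) whose replay is
checked to reproduce the target topology. Exact search is capped at 12
leaves (after collapsing) and `max_d` = 6 moves; beyond the move cap a
bounded outcome (`exceeded=True`, lower bound `max_d`+1) is returned rather
than an error. Fewer than 4 common leaves carry no rooted-topology signal:
the event count is 0 with a warning. Multifurcations in input trees are
resolved deterministically (lexicographic) with a warning, since rooted SPR
is defined here on binary trees.

## Synthetic data

The generator's defaults mirror the study conditions the pipeline targets:
a panel of 41 mammals and 12 non-mammals; planted regions of 1500 bp fully
covered by exactly 2 non-mammal species at identity 0.60 (a ≥ 0.15 margin
above the 0.40 threshold, so calls are insensitive to small identity
noise); 0 planted mammal supporters by default, or — in the spoiler
negative control — 9 mammals each covering 60% of the plant at identity
0.50, which passes the non-mammal filter and fails the ≤ 8 cap. Background
blocks are Poisson per species per chromosome (default 0.2 blocks/kb, i.e.
~13% genome coverage per mammal) with uniform starts, log-normal lengths
(median 500 bp, clipped to [50, 5000]), and per-clade identities: mammals
N(0.70, 0.05), non-mammals N(0.20, 0.08) truncated to [0.02, 0.45] — so
spurious qualifying non-mammal blocks are possible (identity can reach
0.45 > 0.40) but two-species 1 kb pileups are rare, keeping precision
meaningful. Background blocks that would overlap a planted region are
rejected: the planted signal is precisely that mammals align *elsewhere*,
and rejection keeps the truth record's support counts exact. Plants are
placed non-overlapping, one plant-length clear of chromosome boundaries
and of each other; an end-placement flag forces a chosen fraction of
midpoints into terminal zones to create a known positional bias for testing
the paired t-test's power.

Sequence sets for the phylogenetic stage evolve along the species-tree
topology under single-parameter (Jukes–Cantor) substitution at a fixed
per-branch rate (default 0.02 — small enough that p-distances stay nearly
additive at 2 kb); the recipient's sequence is then replaced by a 1%-
diverged copy of the donor's. Only topology matters downstream, so no
indel process, rate heterogeneity, or branch-length realism is modelled.

What passing synthetic tests does *not* show: real chain/net alignments
have correlated block structure, alignment error, lineage-specific gene
loss that mimics transfer, and repeat-driven spurious homology — none of
which the generator emulates. Recovery results here certify the interval
logic and threshold semantics, not real-data sensitivity or specificity.

## Numerical and scale choices

Everything is deterministic under the configured seed (numpy Generator
seeded per stage; all outputs byte-identical across reruns, covered by a
test). Chromosomes in the test suite are 50–200 kb and 2 per dataset
(2.2 Mb for the GC calibration), sizes at which the per-base oracle
comparisons stay exact and cheap; the interval implementation itself is
O(n log n) in block count and independent of chromosome length. File
formats are plain text throughout (TSV blocks/panel/sizes, BED6
annotations, FASTA, Newick, JSON sidecars); block identities are written
with full float precision so round-trips are exact.

## Known limitations

* HGT vs lineage-specific loss cannot be distinguished by conservation
  screening alone; the event count is a lower bound under the
  transfer interpretation.
* `merge_gap = 0` fragments regions interrupted by short alignment gaps;
  bridging is available but changes length-threshold semantics.
* The SPR engine is exponential beyond its caps; large discordant trees
  get bounded results, not exact distances.
* The NJ stage assumes the homologous-sequence alignment is given;
  homolog discovery and multiple alignment are out of scope.
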