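# Methods

## Problem setting

`paleokaryo` reconstructs ancestral gene orders at internal nodes of a
rooted species tree from the gene orders of extant genomes and a table of
syntenically validated homolog pairs, then uses those reconstructions to ask
genome-history questions: how the ancestral chromosomes map onto modern ones
(chromosome painting), how many inter-chromosomal exchanges each lineage has
accumulated ("choppiness"), what the relative ploidy of two lineages is
(syntenic depth), and which rooted topologies are compatible with the peak
structure of Ks / similarity distributions ("trees in the peaks").

The package targets paleopolyploid plant genomes — lineages shaped by
whole-genome duplications (WGD) followed by fractionation (loss of one
member of most duplicate pairs) and structural rearrangement — where
sequence-level phylogenetics is confounded and gene order carries much of
the signal.

## Gene families and generalized adjacencies

Families are the connected components of the homolog-pair graph: a gene
homologous to any member of a family belongs to that family.  Families with
more than `max_copies_per_genome` members in one genome (default 5, enough
for a two-WGD history plus noise) are flagged oversize and excluded from
ancestral inference; they are retained for reporting.  Family ids are the
lexicographically smallest member gene id, so the partition is deterministic.

A *generalized adjacency* is observed for every unordered pair of genes
within a sliding window of `w` consecutive genes (default 7): two genes at
rank distance `1 <= d <= w-1` on the same chromosome contribute one
adjacency joining their **facing ends** — the 3'-in-reading-orientation end
of the left gene and the 5'-in-reading-orientation end of the right gene,
resolved through strand.  Facing ends are the ends that would fuse if the
intervening genes were lost, which is what makes window adjacencies robust
to fractionation.  Same-family (tandem) pairs are excluded by default
because self-loops have no meaning in end matching.

On an intact chromosome of `n` genes the adjacency count is exactly
`sum_{d=1..w-1} (n-d)`; this closed form is property-tested against the
extractor.

## Candidate weighting and end matching

An internal non-root ancestor has three incident branches partitioning the
leaves into three subtrees (two descendant clades and the outgroup-side
complement).  A family-pair adjacency observed in at least two of the three
subtrees becomes a candidate, weighted 2 or 3 by the number of supporting
subtrees; repeated sightings inside one subtree do not raise the weight, and
a pair's several window distances collapse to one candidate.  For the root,
which lacks an incoming edge, a two-subtree fallback assigns weight 2 only.

Families present in at least two subtrees become protogenes of the
ancestor; each contributes two end nodes.  Candidates contribute weighted
edges between end nodes, and a maximum-weight matching (blossom algorithm,
`networkx.max_weight_matching`) selects the heaviest compatible adjacency
set; matched edges plus the intrinsic edge joining each protogene's two
ends decompose into paths (linear contigs) and occasional cycles.

Two numerical choices matter here:

- **Observed ports, not all ports.**  Support counting ignores reading
  direction, but the matcher only offers the end-side combinations actually
  observed in some genome.  Offering all four end-to-end ports lets every
  candidate pair close into a two-cycle worth twice its weight, which beats
  any chain under the near-uniform weights this problem produces and
  degenerates the solution into length-2 circles.  With observed ports,
  complementary-port two-cycles still arise occasionally (e.g. after
  inversions) and are resolved by linearization.  A flag (`all_ports`)
  restores the full relaxation for experimentation.
- **Shortest-distance tie-break.**  With weights confined to {2, 3}, a
  matching that chains families through distance-2 window pairs can tie the
  true neighbor chain.  Edge weights are perturbed by
  `-1e-6 * (min observed distance - 1)`; the perturbation across any
  matching is far below the unit gap between integer-weight optima, so the
  matcher still returns an integer-optimal matching (verified against an
  exhaustive oracle), while preferring adjacencies observed at rank
  distance 1.  Determinism additionally relies on inserting nodes and edges
  in sorted order; inference uses no random numbers anywhere.

Cycles are linearized by deleting a minimum-weight join (ties: the
lexicographically smallest family pair).  Contig ids are assigned after
sorting contigs by length and canonical family sequence, so outputs are
reproducible byte for byte.

## Protochromosome assembly

Each contig is profiled by where its families occur today: the occurrence
matrix counts, per (genome, chromosome) column, the contig's families with
at least one member gene there.  Rows are converted to proportions so long
and short contigs cluster by distribution rather than size; similarity is
the Pearson correlation of row proportions (constant rows get correlation
0), distance is `1 - r`, and a complete-linkage dendrogram is cut at
exactly `k` clusters.  `k` is a user parameter (default 7, the ancestral
eudicot chromosome number); a linkage-tree newick and an advisory
mean-silhouette report over a k range are emitted for inspection but never
override `k`.  Contigs with all-zero rows go to an
`unplaced` bucket.  Within each protochromosome, contigs are ordered by the
median rank of their families on the protochromosome's best-matching
chromosome of a chosen reference genome (ties by contig id; contigs absent
from the reference go last).

## Painting, choppiness, syntenic depth

Painting labels each gene of a modern genome with the protochromosome of
its family (`unpainted` if none), optionally smooths labels by majority
vote in a `smooth_window`-gene window (default 1 = off), merges maximal
runs shorter than `min_segment` genes (default 5) into the larger flanking
run's label, and emits maximal runs as half-open rank segments.  The
defaults keep true translocation segments while suppressing single-gene
transposition noise; `min_segment=1` disables merging for calibration work.

Choppiness is the number of boundaries between differently painted segments
within a chromosome, summed over chromosomes.  Unpainted runs are
transparent (a boundary across one counts once if the flanking painted
labels differ), and label changes at chromosome ends are not counted, so
fissions and fusions are not exchanges under this definition.  The metric is
invariant to whole-chromosome reversal.  Against ground-truth ancestors a
reciprocal translocation contributes exactly two boundaries, and a lineage
always shows at most as many exchanges against a nearer ancestor as against
a farther one — the qualitative pattern used to place rearrangements in
time.

Syntenic depth of a target genome under a query genome is computed from
synteny blocks: per-gene-rank coverage (number of query blocks spanning a
position) is summarized per bin of `bin` ranks (default 50) by its median —
the median, not the block count, so fragmented blocks from one query
subgenome are not double-counted — and the modal depth over covered bins is
reported.  The reciprocal ratio of modal depths reads out relative
subgenome numbers (a one-WGD lineage vs a hexaploid-history lineage gives
2:3).

## Peaks and trees in the peaks

Ks (or percent-similarity) values for a genome pair are smoothed with a
Gaussian KDE (Silverman bandwidth by default; a fixed absolute bandwidth is
available for reproducibility).  Local maxima whose basin (between
flanking density minima) holds at least `min_mass` of the total mass
(default 0.05) become peaks; a peak's interval is the contiguous
half-height span around its mode, a pragmatic operationalization of a peak
"range".  Fewer than 30 values is an error suggesting pooling.

The topology scan enumerates all `(2n-3)!!` rooted binary topologies on
the sampled taxa (capped at 8 leaves).  For a given topology, each leaf
pair's primary (highest-mass) peak attaches to the pair's most recent
common ancestor node; a node's value is the mass-weighted mean of attached
modes and its interval the union span.  A topology is consistent iff peaks
attached to one node mutually overlap, and every ancestral node precedes
(greater Ks; lower similarity) or overlaps each of its descendant nodes.
Paralog (WGD) peaks are reported but not used as constraints by default:
the speciation peaks carry the topology signal, and mixing event types
would entangle ploidy history with branching order.  An option
(`--use-paralog-peaks`) adds the constraint that each genome's WGD peaks
must be younger than (or overlap) the divergence value of every node above
that leaf, since a lineage-specific duplication postdates the lineage's
origin.

## The simulator

The bundled generator produces the statistical structure the analyses
assume, with full ground truth.  A root genome of `n_chromosomes x
genes_per_chromosome` unique genes (defaults 7 x 150) evolves along a
rooted tree whose branch lengths are in Ks units; the Ks clock and the
branch-length axis coincide (no rate variation), which keeps peak-based
topology recovery exact by construction.  Per branch, in order: WGDs (each
either a *doubling* of every chromosome or an *addition* merging in one
more copy of the branch-ancestral chromosome set — the two-step hexaploidy:
tetraploid + donated third genome = 3 subgenomes), one fractionation pass
deleting each WGD-created duplicate copy independently with the branch's
probability, then inversions (uniform lengths, default 2-20 genes, strand
flipped), reciprocal terminal-segment translocations, fusions and
fissions.

Translocation breakpoints are rejection-sampled so that both cuts fall
inside runs of uniform ancestral origin and both rejoined flanks differ in
origin: each translocation then paints as exactly two new boundaries,
giving clean choppiness ground truth.

Every divergence (speciation or duplication) is recorded in a per-gene
genealogy; a homolog pair's Ks is the genealogical path length through its
divergence event plus `Normal(0, sigma)` noise truncated at zero (default
sigma 0.05), so ortholog Ks equals the species path through the MRCA and
WGD-paralog Ks equals twice the WGD-to-tip distance.  Similarity is
emitted as `100 - 30*Ks` (clipped to [0, 100]) with matching noise — a
mirrored axis, as the analyses assume.  Synteny blocks are emitted from
ground truth as gap-tolerant chains of same-family anchors (at least 5
anchors, per-step gaps of at most 5 ranks on both sides, so fractionation
holes do not shatter blocks) rather than re-detected, since synteny
detection itself is out of scope.

The event log records every sampled breakpoint; `replay()` re-applies it
and regenerates each genome exactly, which is tested.

The `preset_eudicot` configuration encodes the study conditions the
analyses are exercised under: a six-leaf clock-like tree
`(Ranu,(Prot,((Buxus,Tetra),(coreA,coreB))))` with one WGD on the
Buxus-like branch, two successive WGDs on the Tetracentron-like branch, and
doubling + addition on the core stem; fractionation 0.2 on the WGD
branches (0.3 on the core stem, where modal copy number 3 emerges), five
inversions and one clean translocation per branch.  Post-fractionation
modal copy numbers are 2 (Buxus-like), 4 (Tetracentron-like) and 3 (core),
and reciprocal syntenic depth between the Buxus-like and core leaves is
2:3.

### What the simulator does not emulate

Real Ks estimation noise is neither Gaussian nor homoscedastic, rates vary
across lineages and sites, tandem arrays and transposed duplicates are
absent, fractionation is unbiased between subgenomes (no subgenome
dominance), and synteny blocks come from ground truth rather than from an
aligner.  Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to every pathology of
real data.

## Problem sizes and determinism

Tests and the acceptance script run the full default problem size (7 x 150
root genes; six-genome preset with up to ~3500-gene leaves).  A
reconstruction at one ancestor takes a few seconds; the complete acceptance
script runs in well under a minute.  All randomness flows from a single
integer seed through `numpy.random.default_rng`; inference itself is
seed-free and deterministic for fixed inputs.

## Known limitations

- The root reconstruction has only two subtrees and weight-2 candidates;
  its contigs are correspondingly less reliable than those of internal
  ancestors.
- Contig orientation across contigs is not assigned; protochromosome order
  is reference-guided, so a heavily rearranged reference degrades ordering
  (not clustering).
- Choppiness counts label boundaries; a definition that also counted
  fissions/fusions would differ by the number of those events.
- Peak intervals are half-height spans; very overlapping mixtures merge
  into single peaks before their components separate.
- Topology enumeration is exact and therefore capped at 8 leaves.
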