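# paleokaryo

Ancestral gene-order reconstruction and genome-history analysis for
paleopolyploid genomes.

Many plant lineages descend from whole-genome duplications (WGD) followed
by fractionation — the loss of one member of most duplicated gene pairs —
and by inversions, translocations, fusions and fissions.  In such genomes,
gene order carries phylogenetic and karyotypic signal that sequence-level
analyses miss.  `paleokaryo` is for comparative genomicists who have gene
orders for a set of extant genomes, syntenically validated homolog pairs
(with Ks and/or percent similarity), and a rooted species tree, and who
want to:

- reconstruct the **ancestral gene order** at internal tree nodes,
- assemble reconstructed contigs into **protochromosomes**,
- **paint** modern chromosomes by ancestral chromosome of origin and count
  inter-chromosomal exchanges ("choppiness"),
- profile **syntenic depth** (relative ploidy, e.g. 2:3) between genomes,
- screen all rooted topologies against Ks / similarity peak structure
  ("trees in the peaks").

A bundled genome-evolution simulator generates ground-truth datasets with
lineage-specific WGDs (including a two-step hexaploidy), fractionation and
rearrangements, and is used throughout the test suite.

## The method in brief

Gene families are the connected components of the homology graph.  For a
window of w = 7 consecutive genes, every gene pair at rank distance
d ≤ w−1 yields a *generalized adjacency* joining the pair's facing ends —
evidence that survives local gene loss and window-internal inversions.  An
ancestor node's three incident branches split the leaves into three
subtrees; an adjacency seen in ≥ 2 subtrees is a candidate with weight
w(a) ∈ {2, 3}, the number of supporting subtrees.  A maximum-weight
matching over protogene ends,

&nbsp;&nbsp;max Σ<sub>a∈M</sub> w(a)  subject to each gene end matched at most once,

yields the heaviest compatible adjacency set, whose paths are the ancestral
contigs (occasional cycles are broken at a minimum-weight join).  Contigs
are clustered into k protochromosomes by complete linkage on the
correlation of their occurrence profiles across modern chromosomes, and
ordered along a reference genome.  Painting, choppiness and syntenic depth
then compare modern genomes with the reconstruction, and the topology scan
enumerates all (2n−3)!! rooted binary topologies, keeping those whose
node-wise peak values *precede or overlap* their descendants'.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a six-genome eudicot-like dataset (seven ancestral chromosomes,
one WGD on the Buxus-like branch, two on the Tetracentron-like branch, a
two-step hexaploidy on the core stem, fractionation and rearrangements),
then run the full pipeline:

```
$ paleokaryo simulate --seed 17 --out sim/
wrote sim (6 genomes, 70343 pairs)

$ paleokaryo reconstruct --genes sim/gene_orders.tsv --pairs sim/homolog_pairs.tsv \
      --tree sim/tree.nwk --ancestor n_cru --out contigs.tsv
8 contigs, total matched weight 3113, 1 cycles linearized

$ paleokaryo assemble --genes sim/gene_orders.tsv --pairs sim/homolog_pairs.tsv \
      --contigs contigs.tsv --k 7 --reference Ranu --out ancestor.tsv
7 protochromosomes, sizes [209, 180, 150, 150, 150, 150, 61], 0 unplaced
```

The 1050 ancestral families are recovered as 8 contigs assembled into 7
protochromosomes (one ancestral chromosome, split by a translocation below
the ancestor, is reassembled from two contigs: 209 + 61 ≈ 2 × 150 − loss).

```
$ paleokaryo treescan --pairs sim/homolog_pairs.tsv --genes sim/gene_orders.tsv \
      --out verdicts.tsv
1/945 topologies consistent
((((Buxus,Tetra),(coreA,coreB)),Prot),Ranu);
```

Of all 945 rooted topologies on the six genomes, exactly one is consistent
with the ortholog Ks peak structure — the generating tree, with the
Buxus-like + Tetracentron-like clade sister to the core pair.

```
$ paleokaryo depth --blocks sim/blocks.tsv --genes sim/gene_orders.tsv \
      --target Buxus --bin 25
Prot    1
Ranu    1
Tetra   4
coreA   3
coreB   3
```

Each Buxus-like region is syntenic to 1 region of the unduplicated
genomes, 4 of the twice-doubled Tetracentron-like genome and 3 of the
hexaploid-history core genomes — the modal depths read out each lineage's
subgenome count.  `paleokaryo run-all --dir sim/ --out run/` chains all
eight stages (families, adjacencies, reconstruct, assemble, paint,
choppiness, depth, treescan) and writes a manifest with the resolved
configuration and input checksums; a second run on the same inputs
reproduces identical outputs.

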