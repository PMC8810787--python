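"""Core domain types shared by every pipeline stage.

Gene order is the primary coordinate axis: every internal position is a
0-based rank along a chromosome.  Physical coordinates, when present in the
input, are 0-based half-open (BED convention) and are used only to assign
ranks and to emit painting intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")

#: label used for genes whose ancestral origin cannot be assigned
UNPAINTED = "unpainted"


@dataclass
class Gene:
    """A gene placed on a chromosome of one genome.

    ``rank`` is the 0-based gene-order index along its chromosome; ranks on a
    chromosome are consecutive ``0..n-1``.  ``strand`` is ``'+'`` or ``'-'``.
    ``family_id`` is assigned later by homology clustering (``None`` until
    then).
    """

    gene_id: str
    genome_id: str
    chromosome_id: str
    rank: int
    strand: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )


@dataclass
class Genome:
    """An ordered, stranded gene list per chromosome."""

    genome_id: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g.genome_id != self.genome_id:
                    raise ValueError(
                        f"gene {g.gene_id} carries genome {g.genome_id}, "
                        f"expected {self.genome_id}"
                    )
                if g.chromosome_id != chrom or g.rank != i:
                    raise ValueError(
                        f"gene {g.gene_id}: rank/chromosome inconsistent"
                    )
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id}")
                seen.add(g.gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def genes(self):
        for genes in self.chromosomes.values():
            yield from genes


def genes_by_id(genomes: dict[str, Genome]) -> dict[str, Gene]:
    """Index all genes of a genome collection by gene_id (must be unique)."""
    index: dict[str, Gene] = {}
    for genome in genomes.values():
        for g in genome.genes():
            if g.gene_id in index:
                raise ValueError(f"duplicate gene_id across genomes: {g.gene_id}")
            index[g.gene_id] = g
    return index


@dataclass
class HomologPair:
    """A syntenically validated homolog pair with divergence proxies.

    At least one of ``ks`` (synonymous substitutions per site) and
    ``similarity`` (percent, 0..100) must be present.
    """

    gene_a: str
    gene_b: str
    ks: float | None = None
    similarity: float | None = None
    pair_class: str = "unknown"  # ortholog | paralog | unknown

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")
        if self.ks is None and self.similarity is None:
            raise ValueError(
                f"pair {self.gene_a}/{self.gene_b}: ks and similarity both missing"
            )

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class SyntenyBlock:
    """A pair of syntenic intervals, in gene-rank units, half-open."""

    block_id: str
    query_genome: str
    query_chromosome: str
    query_start: int
    query_end: int
    target_genome: str
    target_chromosome: str
    target_start: int
    target_end: int

    def __post_init__(self) -> None:
        if not (self.query_start < self.query_end
                and self.target_start < self.target_end):
            raise ValueError(f"block {self.block_id}: empty interval")


@dataclass
class ObservedAdjacency:
    """A generalized adjacency observed in one genome.

    Two genes at gene-rank distance ``1 <= d <= w-1`` on the same chromosome
    contribute one adjacency joining their *facing* ends — the ends that would
    fuse if the intervening genes were lost.  Sides are in reading
    orientation: 0 = 5'-most end, 1 = 3'-most end.
    """

    genome_id: str
    chromosome_id: str
    gene_a: str
    gene_b: str
    family_a: str
    family_b: str
    side_a: int
    side_b: int
    distance: int

    @property
    def family_pair(self) -> frozenset[str]:
        return frozenset((self.family_a, self.family_b))


@dataclass
class CandidateAdjacency:
    """An adjacency supported in >= 2 of an ancestor node's three subtrees.

    ``min_distance`` is the smallest gene-rank distance at which the family
    pair was observed in any genome; it only breaks ties between matchings
    of equal subtree-support weight.
    """

    families: frozenset[str]
    weight: int
    subtrees: frozenset[int]
    genomes: frozenset[str]
    min_distance: int = 1
    #: end-side combinations observed for this pair, as (side on the
    #: lexicographically first family, side on the second); empty means
    #: "unknown", letting the matcher offer all four ports
    end_pairs: frozenset[tuple[int, int]] = frozenset()


@dataclass
class AncestralContig:
    """A linearly ordered run of protogenes (family ids) with join weights."""

    contig_id: str
    families: list[str]
    join_weights: list[int]
    circular: bool = False
    linearized_from_cycle: bool = False

    def __post_init__(self) -> None:
        expected = len(self.families) if self.circular else len(self.families) - 1
        if len(self.join_weights) != max(expected, 0):
            raise ValueError(
                f"contig {self.contig_id}: {len(self.families)} families need "
                f"{expected} joins, got {len(self.join_weights)}"
            )

    def __len__(self) -> int:
        return len(self.families)


@dataclass
class ProtoChromosome:
    """An assembled ancestral chromosome: ordered contigs of protogenes."""

    protochromosome_id: str
    contigs: list[AncestralContig] = field(default_factory=list)

    @property
    def n_protogenes(self) -> int:
        return sum(len(c) for c in self.contigs)

    def families(self) -> list[str]:
        out: list[str] = []
        for c in self.contigs:
            out.extend(c.families)
        return out
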