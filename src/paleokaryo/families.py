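"""Disjoint gene families and window-based generalized adjacencies.

Families are the transitive closure of homology: a gene homologous with any
member of a family belongs to that family, so families are the connected
components of the homolog-pair graph.  Generalized adjacencies pair the
facing ends of any two genes lying within a small window of consecutive
genes, which makes ancestral adjacency evidence robust to local gene loss
and to inversions with breakpoints inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .datamodel import Gene, Genome, HomologPair, ObservedAdjacency

DEFAULT_WINDOW = 7
DEFAULT_MAX_COPIES = 5


@dataclass
class GeneFamily:
    family_id: str
    members: set[str] = field(default_factory=set)
    copy_counts: dict[str, int] = field(default_factory=dict)  # genome -> n
    oversize: bool = False


@dataclass
class FamilySet:
    """Families plus the gene -> family index used downstream."""

    families: dict[str, GeneFamily]
    family_of: dict[str, str]

    @property
    def oversize_ids(self) -> set[str]:
        return {fid for fid, f in self.families.items() if f.oversize}

    def presence(self, fid: str) -> set[str]:
        """Genomes in which family ``fid`` has at least one member."""
        return {g for g, n in self.families[fid].copy_counts.items() if n > 0}


def build_families(pairs: list[HomologPair],
                   genomes: dict[str, Genome],
                   max_copies_per_genome: int = DEFAULT_MAX_COPIES) -> FamilySet:
    """Cluster homolog pairs into disjoint families (connected components).

    Families with more than ``max_copies_per_genome`` members in any one
    genome are flagged ``oversize``: they stay in the set for reporting but
    are excluded from ancestral inference, where highly duplicated families
    would flood the adjacency graph with ambiguous evidence.  family_id is
    the lexicographically smallest member gene_id (deterministic).
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)

    genome_of = {g.gene_id: g.genome_id
                 for gm in genomes.values() for g in gm.genes()}

    families: dict[str, GeneFamily] = {}
    family_of: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        fid = min(comp)
        fam = GeneFamily(family_id=fid, members=set(comp))
        for gene_id in comp:
            gid = genome_of.get(gene_id)
            if gid is not None:
                fam.copy_counts[gid] = fam.copy_counts.get(gid, 0) + 1
            family_of[gene_id] = fid
        fam.oversize = any(n > max_copies_per_genome
                           for n in fam.copy_counts.values())
        families[fid] = fam
    return FamilySet(families=families, family_of=family_of)


def _facing_sides(gi: Gene, gj: Gene) -> tuple[int, int]:
    # facing ends: the chromosomally-right end of gi and the left end of gj,
    # expressed in reading orientation (0 = 5'-most, 1 = 3'-most)
    side_a = 1 if gi.strand == "+" else 0
    side_b = 0 if gj.strand == "+" else 1
    return side_a, side_b


def extract_generalized_adjacencies(
        genome: Genome,
        family_set: FamilySet,
        w: int = DEFAULT_WINDOW,
        include_tandem: bool = False) -> list[ObservedAdjacency]:
    """Emit one adjacency per unordered gene pair within a window of ``w``.

    For genes at ranks i < j with ``j - i <= w - 1`` on one chromosome the
    adjacency joins the 3'-in-reading-orientation end of the left gene to the
    5'-in-reading-orientation end of the right gene (strand-resolved).  Pairs
    whose families are unassigned or oversize are skipped.  Same-family
    (tandem) pairs are skipped by default: self-loops break end-matching
    semantics; ``include_tandem`` records them for reporting only.
    """
    if w < 2:
        raise ValueError(f"window must be >= 2, got {w}")
    family_of = family_set.family_of
    oversize = family_set.oversize_ids
    out: list[ObservedAdjacency] = []
    for chrom, genes in genome.chromosomes.items():
        n = len(genes)
        for i in range(n):
            gi = genes[i]
            fa = family_of.get(gi.gene_id)
            if fa is None or fa in oversize:
                continue
            for j in range(i + 1, min(i + w, n)):
                gj = genes[j]
                fb = family_of.get(gj.gene_id)
                if fb is None or fb in oversize:
                    continue
                if fa == fb and not include_tandem:
                    continue
                side_a, side_b = _facing_sides(gi, gj)
                out.append(ObservedAdjacency(
                    genome_id=genome.genome_id, chromosome_id=chrom,
                    gene_a=gi.gene_id, gene_b=gj.gene_id,
                    family_a=fa, family_b=fb,
                    side_a=side_a, side_b=side_b, distance=j - i))
    return out


def adjacency_table_rows(adjacencies: list[ObservedAdjacency]) -> list[tuple]:
    """Rows for the debugging adjacency dump TSV."""
    return [(a.genome_id, a.chromosome_id, a.gene_a, a.gene_b, a.family_a,
             a.family_b, a.side_a, a.side_b, a.distance) for a in adjacencies]
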