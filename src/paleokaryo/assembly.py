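"""Cluster ancestral contigs into protochromosomes.

Contigs descending from the same ancestral chromosome tend to land on the
same modern chromosomes, so we score each contig by where its protogene
families occur today, correlate those occurrence profiles, and cut a
complete-linkage dendrogram at k clusters (k = 7 reconstructs the ancestral
eudicot karyotype).  Profiles are row proportions, not raw counts, so long
and short contigs cluster by distribution rather than size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import AncestralContig, Genome, ProtoChromosome
from .families import FamilySet

log = logging.getLogger(__name__)

DEFAULT_K = 7

UNPLACED = "unplaced"


def map_contigs(contigs: list[AncestralContig],
                genomes: dict[str, Genome],
                family_set: FamilySet) -> pd.DataFrame:
    """Occurrence matrix: contigs x modern (genome, chromosome) columns.

    Entry = number of the contig's protogene families with at least one
    member gene on that chromosome.
    """
    chrom_sets: dict[str, set[tuple[str, str]]] = {}
    for genome in genomes.values():
        for chrom, genes in genome.chromosomes.items():
            for g in genes:
                fid = family_set.family_of.get(g.gene_id)
                if fid is not None:
                    chrom_sets.setdefault(fid, set()).add(
                        (genome.genome_id, chrom))

    columns = sorted({(gm.genome_id, c)
                      for gm in genomes.values() for c in gm.chromosomes})
    col_index = {c: i for i, c in enumerate(columns)}
    data = np.zeros((len(contigs), len(columns)), dtype=int)
    ids = []
    for r, contig in enumerate(sorted(contigs, key=lambda c: c.contig_id)):
        ids.append(contig.contig_id)
        for fid in contig.families:
            for col in chrom_sets.get(fid, ()):
                data[r, col_index[col]] += 1
    matrix = pd.DataFrame(
        data, index=ids, columns=pd.MultiIndex.from_tuples(
            columns, names=["genome", "chromosome"]))
    n_zero = int((matrix.sum(axis=1) == 0).sum())
    if n_zero:
        log.info("%d contigs occur on no modern chromosome", n_zero)
    return matrix


def _correlation_distance(props: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(props)
    corr = np.nan_to_num(corr, nan=0.0)  # constant rows carry no signal
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    return squareform(dist, checks=False)


def cluster_contigs(matrix: pd.DataFrame, k: int = DEFAULT_K,
                    contigs: list[AncestralContig] | None = None
                    ) -> tuple[list[ProtoChromosome], list[str]]:
    """Complete-linkage clustering of contig co-occurrence into k clusters.

    Similarity is the Pearson correlation of row-proportion vectors;
    distance is 1 - correlation.  Zero-occurrence contigs go to an
    ``unplaced`` bucket.  Returns (protochromosomes, unplaced contig ids);
    protochromosome ids are "1".."k", numbered by smallest member contig id.
    """
    matrix = matrix.sort_index()
    nonzero = matrix.index[matrix.sum(axis=1) > 0]
    unplaced = [cid for cid in matrix.index if cid not in set(nonzero)]
    n = len(nonzero)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside 1..{n} (nonzero contigs)")

    counts = matrix.loc[nonzero].to_numpy(dtype=float)
    props = counts / counts.sum(axis=1, keepdims=True)
    if n == 1:
        labels = np.array([1])
    else:
        linkage = hierarchy.linkage(_correlation_distance(props),
                                    method="complete")
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")

    by_label: dict[int, list[str]] = {}
    for cid, lab in zip(nonzero, labels):
        by_label.setdefault(int(lab), []).append(cid)
    contig_by_id = {c.contig_id: c for c in contigs} if contigs else {}

    protos = []
    for i, lab in enumerate(sorted(by_label, key=lambda l: min(by_label[l])),
                            start=1):
        proto = ProtoChromosome(protochromosome_id=str(i))
        for cid in sorted(by_label[lab]):
            proto.contigs.append(
                contig_by_id.get(cid) or
                AncestralContig(contig_id=cid, families=[], join_weights=[]))
        protos.append(proto)
    return protos, unplaced


def silhouette_report(matrix: pd.DataFrame,
                      k_range: range = range(2, 13)) -> dict[int, float]:
    """Mean silhouette width of the complete-linkage cut at each k.

    Advisory only: the report helps choose k but never overrides the user's
    value.  Computed on the same 1 - correlation distances as the
    clustering.
    """
    matrix = matrix.sort_index()
    nonzero = matrix.index[matrix.sum(axis=1) > 0]
    counts = matrix.loc[nonzero].to_numpy(dtype=float)
    props = counts / counts.sum(axis=1, keepdims=True)
    n = len(nonzero)
    dist = squareform(_correlation_distance(props))
    linkage = hierarchy.linkage(squareform(dist, checks=False),
                                method="complete")
    report: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        widths = []
        for i in range(n):
            same = labels == labels[i]
            same[i] = False
            if not same.any():
                widths.append(0.0)
                continue
            a = dist[i][same].mean()
            b = min(dist[i][labels == lab].mean()
                    for lab in set(labels) if lab != labels[i])
            widths.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        report[k] = float(np.mean(widths))
    return report


def cluster_linkage_newick(matrix: pd.DataFrame) -> str:
    """The complete-linkage dendrogram over nonzero contigs, as newick."""
    matrix = matrix.sort_index()
    nonzero = matrix.index[matrix.sum(axis=1) > 0]
    counts = matrix.loc[nonzero].to_numpy(dtype=float)
    props = counts / counts.sum(axis=1, keepdims=True)
    linkage = hierarchy.linkage(_correlation_distance(props), method="complete")
    tree = hierarchy.to_tree(linkage)

    def _fmt(node) -> str:
        if node.is_leaf():
            return nonzero[node.id]
        return f"({_fmt(node.left)},{_fmt(node.right)})"

    return _fmt(tree) + ";"


def order_within(protochromosomes: list[ProtoChromosome],
                 genomes: dict[str, Genome],
                 family_set: FamilySet,
                 reference_genome_id: str) -> list[ProtoChromosome]:
    """Order contigs within each protochromosome along a reference genome.

    Each protochromosome picks the reference chromosome carrying most copies
    of its families; contigs sort by the median reference rank of their
    families' gene copies there (ties by contig_id).  Contigs with no family
    on the reference go last.
    """
    ref = genomes[reference_genome_id]
    ranks: dict[str, dict[str, list[int]]] = {}  # chrom -> family -> ranks
    for chrom, genes in ref.chromosomes.items():
        d = ranks.setdefault(chrom, {})
        for g in genes:
            fid = family_set.family_of.get(g.gene_id)
            if fid is not None:
                d.setdefault(fid, []).append(g.rank)

    out = []
    for proto in protochromosomes:
        fams = set(proto.families())
        best_chrom = max(
            ref.chromosomes,
            key=lambda c: (sum(len(ranks[c].get(f, ())) for f in fams), c),
            default=None)
        chrom_ranks = ranks.get(best_chrom, {})

        def sort_key(contig: AncestralContig):
            hits = [r for f in contig.families for r in chrom_ranks.get(f, ())]
            if not hits:
                log.info("contig %s has no family on reference; placed last",
                         contig.contig_id)
                return (1, 0.0, contig.contig_id)
            return (0, float(np.median(hits)), contig.contig_id)

        ordered = sorted(proto.contigs, key=sort_key)
        out.append(ProtoChromosome(
            protochromosome_id=proto.protochromosome_id, contigs=ordered))
    return out


def proto_of_family(protochromosomes: list[ProtoChromosome]) -> dict[str, str]:
    """family_id -> protochromosome_id map, the input to chromosome painting."""
    out: dict[str, str] = {}
    for proto in protochromosomes:
        for fid in proto.families():
            out[fid] = proto.protochromosome_id
    return out
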