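"""Readers and writers for the external formats the pipeline touches.

All tabular I/O is UTF-8, tab-delimited; lines starting with ``#`` are
ignored.  Gene-order input comes as a BED-like TSV or as GFF3 (gene features
only); trees are newick; paintings are written as BED with a protochromosome
label column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import pandas as pd

from .datamodel import (
    AncestralContig,
    Gene,
    Genome,
    HomologPair,
    ProtoChromosome,
    SyntenyBlock,
)

log = logging.getLogger(__name__)

_NA = {"", "NA", "NaN", "nan", "na", "."}

BED_LIKE_COLUMNS = ["genome", "chromosome", "start", "end", "strand", "gene_id"]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------

def read_gene_orders(path: str | Path, format: str = "bed_like",
                     genome_id: str | None = None) -> dict[str, Genome]:
    """Load gene orders and assign dense 0-based ranks per chromosome.

    Ranks follow ascending start coordinate; ties are broken by gene_id
    lexicographic order (deterministic, seed-free).

    Parameters
    ----------
    format:
        ``"bed_like"`` — TSV with header columns genome, chromosome, start,
        end, strand, gene_id; or ``"gff3"`` — standard GFF3, gene features
        only (requires ``genome_id`` since GFF3 carries no genome column).
    """
    if format == "bed_like":
        df = _read_tsv(path)
        missing = [c for c in BED_LIKE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    elif format == "gff3":
        if genome_id is None:
            raise ValueError("gff3 input needs an explicit genome_id")
        df = _read_gff3_genes(path, genome_id)
    else:
        raise ValueError(f"unknown gene-order format {format!r}")

    df = df.copy()
    df["start"] = df["start"].astype(int)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id(s): {sorted(set(dup))}")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")

    genomes: dict[str, Genome] = {}
    for (gid, chrom), sub in df.groupby(["genome", "chromosome"], sort=True):
        sub = sub.sort_values(["start", "gene_id"], kind="mergesort")
        genome = genomes.setdefault(gid, Genome(genome_id=gid))
        genome.chromosomes[chrom] = [
            Gene(gene_id=r.gene_id, genome_id=gid, chromosome_id=chrom,
                 rank=i, strand=r.strand)
            for i, r in enumerate(sub.itertuples())
        ]
    for g in genomes.values():
        g.validate()
    return genomes


def _read_gff3_genes(path: str | Path, genome_id: str) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = _read_tsv(path, names=cols, header=None)
    df = df[df["type"] == "gene"].copy()

    def _gene_id(attrs: str) -> str:
        for part in attrs.split(";"):
            k, _, v = part.strip().partition("=")
            if k == "ID":
                return v
        raise ValueError(f"GFF3 gene feature without ID attribute: {attrs!r}")

    # GFF3 is 1-based closed; internally we only use starts for ordering
    return pd.DataFrame({
        "genome": genome_id,
        "chromosome": df["seqid"],
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "strand": df["strand"],
        "gene_id": df["attributes"].map(_gene_id),
    })


def write_gene_orders(genomes: dict[str, Genome], path: str | Path) -> None:
    rows = []
    for genome in genomes.values():
        for g in genome.genes():
            # synthetic physical coordinates from ranks keep the round trip exact
            rows.append((g.genome_id, g.chromosome_id, g.rank * 1000,
                         g.rank * 1000 + 500, g.strand, g.gene_id))
    pd.DataFrame(rows, columns=BED_LIKE_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homolog pairs
# ---------------------------------------------------------------------------

def read_homolog_pairs(path: str | Path,
                       genomes: dict[str, Genome] | None = None,
                       on_unknown_gene: str = "warn") -> list[HomologPair]:
    """Read a SynMap-style homolog-pair TSV.

    Rows with both ks and similarity missing are dropped (count logged);
    symmetric duplicates keep the first occurrence.  Pairs naming genes
    absent from ``genomes`` are dropped with a warning by default
    (``on_unknown_gene="error"`` raises instead).
    """
    df = _read_tsv(path)
    for c in ("gene_a", "gene_b", "ks", "similarity", "pair_class"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")

    known: set[str] | None = None
    if genomes is not None:
        known = {g.gene_id for gm in genomes.values() for g in gm.genes()}

    def _num(x) -> float | None:
        if x is None or (isinstance(x, float) and pd.isna(x)) or str(x) in _NA:
            return None
        return float(x)

    pairs: list[HomologPair] = []
    seen: set[frozenset[str]] = set()
    n_dropped_na = n_dropped_unknown = 0
    for r in df.itertuples():
        ks, sim = _num(r.ks), _num(r.similarity)
        if ks is None and sim is None:
            n_dropped_na += 1
            continue
        if known is not None and (r.gene_a not in known or r.gene_b not in known):
            if on_unknown_gene == "error":
                raise ValueError(
                    f"pair {r.gene_a}/{r.gene_b}: gene absent from loaded genomes")
            n_dropped_unknown += 1
            continue
        key = frozenset((r.gene_a, r.gene_b))
        if key in seen:
            continue
        seen.add(key)
        cls = r.pair_class if str(r.pair_class) not in _NA else "unknown"
        pairs.append(HomologPair(gene_a=r.gene_a, gene_b=r.gene_b, ks=ks,
                                 similarity=sim, pair_class=cls))
    if n_dropped_na:
        log.info("dropped %d pairs with both ks and similarity missing",
                 n_dropped_na)
    if n_dropped_unknown:
        log.warning("dropped %d pairs naming unknown genes", n_dropped_unknown)
    return pairs


def write_homolog_pairs(pairs: list[HomologPair], path: str | Path) -> None:
    rows = [(p.gene_a, p.gene_b,
             "NA" if p.ks is None else f"{p.ks:.6g}",
             "NA" if p.similarity is None else f"{p.similarity:.6g}",
             p.pair_class) for p in pairs]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "ks", "similarity",
                                "pair_class"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def read_species_tree(path: str | Path,
                      outgroup: str | None = None) -> dendropy.Tree:
    """Parse a rooted binary newick species tree.

    A root trifurcation is collapsed into rooted binary form via a named
    ``outgroup`` leaf; any other non-binary node is a hard error.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    root = tree.seed_node
    if len(root.child_nodes()) == 3:
        if outgroup is None:
            raise ValueError(
                "root trifurcation: provide an outgroup leaf to root the tree")
        taxa = [t.label for t in tree.taxon_namespace]
        if outgroup not in taxa:
            raise ValueError(f"unknown outgroup {outgroup!r}; leaves are {taxa}")
        node = tree.find_node_with_taxon_label(outgroup)
        el = node.edge.length
        tree.reroot_at_edge(
            node.edge,
            length1=None if el is None else el / 2,
            length2=None if el is None else el / 2,
            update_bipartitions=False)
    check_binary(tree)
    return tree


def check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            label = node_label(node) or "<unnamed>"
            raise ValueError(
                f"non-binary node {label!r} with {len(kids)} children")


def node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def parse_tree_string(newick: str, **kw) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    check_binary(tree)
    return tree


# ---------------------------------------------------------------------------
# ancestor tables
# ---------------------------------------------------------------------------

def write_ancestor(protochromosomes: list[ProtoChromosome],
                   path: str | Path) -> None:
    """Write an assembled ancestor as TSV.

    Columns: protochromosome_id, position (0-based along the
    protochromosome), family_id, contig_id, adjacency_support (weight of the
    join to the previous protogene; 0 at contig starts).
    """
    rows = []
    for proto in protochromosomes:
        pos = 0
        for contig in proto.contigs:
            for i, fam in enumerate(contig.families):
                support = 0 if i == 0 else contig.join_weights[i - 1]
                rows.append((proto.protochromosome_id, pos, fam,
                             contig.contig_id, support))
                pos += 1
    pd.DataFrame(rows, columns=["protochromosome_id", "position", "family_id",
                                "contig_id", "adjacency_support"]).to_csv(
        path, sep="\t", index=False)


def read_ancestor(path: str | Path) -> list[ProtoChromosome]:
    df = _read_tsv(path)
    df["position"] = df["position"].astype(int)
    df["adjacency_support"] = df["adjacency_support"].astype(int)
    protos: list[ProtoChromosome] = []
    for pid, sub in df.groupby("protochromosome_id", sort=True):
        sub = sub.sort_values("position")
        proto = ProtoChromosome(protochromosome_id=str(pid))
        for cid, csub in sub.groupby("contig_id", sort=False):
            fams = list(csub["family_id"])
            joins = list(csub["adjacency_support"])[1:]
            proto.contigs.append(AncestralContig(
                contig_id=str(cid), families=fams, join_weights=joins))
        protos.append(proto)
    return protos


def write_contigs(contigs: list[AncestralContig], path: str | Path) -> None:
    """Contig TSV: contig_id, position, family_id, join_weight (to previous)."""
    rows = []
    for c in contigs:
        for i, fam in enumerate(c.families):
            rows.append((c.contig_id, i, fam,
                         0 if i == 0 else c.join_weights[i - 1]))
    pd.DataFrame(rows, columns=["contig_id", "position", "family_id",
                                "join_weight"]).to_csv(path, sep="\t",
                                                       index=False)


def read_contigs(path: str | Path) -> list[AncestralContig]:
    df = _read_tsv(path)
    df["position"] = df["position"].astype(int)
    df["join_weight"] = df["join_weight"].astype(int)
    contigs = []
    for cid, sub in df.groupby("contig_id", sort=True):
        sub = sub.sort_values("position")
        contigs.append(AncestralContig(
            contig_id=str(cid), families=list(sub["family_id"]),
            join_weights=list(sub["join_weight"])[1:]))
    return contigs


# ---------------------------------------------------------------------------
# paintings (BED) and synteny blocks
# ---------------------------------------------------------------------------

def write_painting(painting: "dict[str, list[tuple[int, int, str]]]",
                   path: str | Path) -> None:
    """Write painted segments as BED: chromosome, start, end, label.

    Intervals are half-open 0-based gene ranks.
    """
    rows = []
    for chrom in sorted(painting):
        for start, end, label in painting[chrom]:
            rows.append((chrom, start, end, label))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_painting(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    df = _read_tsv(path, header=None,
                   names=["chromosome", "start", "end", "label"])
    out: dict[str, list[tuple[int, int, str]]] = {}
    for r in df.itertuples():
        out.setdefault(r.chromosome, []).append(
            (int(r.start), int(r.end), r.label))
    for segs in out.values():
        segs.sort()
    return out


BLOCK_COLUMNS = ["block_id", "query_genome", "query_chromosome", "query_start",
                 "query_end", "target_genome", "target_chromosome",
                 "target_start", "target_end"]


def write_synteny_blocks(blocks: list[SyntenyBlock], path: str | Path) -> None:
    rows = [tuple(getattr(b, c) for c in BLOCK_COLUMNS) for b in blocks]
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_synteny_blocks(path: str | Path) -> list[SyntenyBlock]:
    df = _read_tsv(path)
    for c in ("query_start", "query_end", "target_start", "target_end"):
        df[c] = df[c].astype(int)
    return [SyntenyBlock(**{c: getattr(r, c) for c in BLOCK_COLUMNS})
            for r in df.itertuples()]
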