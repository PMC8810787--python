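"""Chromosome painting, inter-chromosomal exchange counts, syntenic depth.

Painting projects an ancestral karyotype onto a modern genome: each gene is
labeled by the protochromosome its family belongs to, labels are optionally
smoothed, and maximal same-label runs become segments.  The number of
boundaries between differently painted segments within a chromosome — its
"choppiness" — counts the inter-chromosomal exchanges accumulated since the
ancestor, so a genome shows fewer exchanges against a nearer ancestor than
against a more distant one.  Syntenic depth — how many regions of one genome
are syntenic to a given region of another — reads out relative ploidy
(e.g. a 2:3 reciprocal depth between a tetraploid-history and a
hexaploid-history genome).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Genome, SyntenyBlock, UNPAINTED

DEFAULT_MIN_SEGMENT = 5
DEFAULT_SMOOTH_WINDOW = 1


@dataclass
class Painting:
    """Per-chromosome segmentation of a modern genome by ancestral source.

    Segments are half-open gene-rank intervals tiling ``0..n`` with no
    overlap; adjacent segments carry distinct labels.
    """

    genome_id: str
    ancestor_id: str
    segments: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            pos = 0
            prev = None
            for start, end, label in segs:
                if start != pos or end <= start:
                    raise ValueError(f"{chrom}: segments do not tile")
                if label == prev:
                    raise ValueError(f"{chrom}: unmerged adjacent segments")
                pos, prev = end, label


@dataclass
class ExchangeReport:
    genome_id: str
    ancestor_id: str
    per_chromosome: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_chromosome.values())


# ---------------------------------------------------------------------------
# painting
# ---------------------------------------------------------------------------

def _smooth(labels: list[str], window: int) -> list[str]:
    if window <= 1:
        return labels
    half = window // 2
    out = []
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        votes = Counter(labels[lo:hi])
        top = votes.most_common()
        best = max(top, key=lambda kv: (kv[1], kv[0] == labels[i]))[0]
        out.append(best)
    return out


def _runs(labels: list[str]) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def _merge_short(runs: list[tuple[int, int, str]],
                 min_segment: int) -> list[tuple[int, int, str]]:
    """Absorb runs shorter than ``min_segment`` into their larger flank.

    Repeatedly relabels the shortest offending run to the flanking label
    backed by the longer neighboring run (ties: left flank), then re-merges,
    until every remaining run reaches the threshold or only one run is left.
    """
    runs = list(runs)
    while len(runs) > 1:
        lengths = [(end - start, i) for i, (start, end, _) in enumerate(runs)]
        size, i = min(lengths, key=lambda t: (t[0], t[1]))
        if size >= min_segment:
            break
        start, end, _ = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is not None and (right is None
                                 or left[1] - left[0] >= right[1] - right[0]):
            label = left[2]
        else:
            label = right[2]
        runs[i] = (start, end, label)
        merged = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1] = (merged[-1][0], r[1], r[2])
            else:
                merged.append(r)
        runs = merged
    return runs


def paint(genome: Genome,
          proto_of_family: dict[str, str],
          family_of: dict[str, str],
          min_segment: int = DEFAULT_MIN_SEGMENT,
          smooth_window: int = DEFAULT_SMOOTH_WINDOW,
          ancestor_id: str = "ancestor") -> Painting:
    """Paint each chromosome of ``genome`` by protochromosome of origin.

    Each gene takes the protochromosome of its family (or ``unpainted``);
    labels are majority-vote smoothed over ``smooth_window`` genes
    (default 1 = off), runs shorter than ``min_segment`` are merged into
    their flanking majority label, and maximal runs are emitted as segments.

    ``family_of`` maps gene_id -> family_id (e.g. ``FamilySet.family_of``).
    """
    painting = Painting(genome_id=genome.genome_id, ancestor_id=ancestor_id)
    for chrom, genes in genome.chromosomes.items():
        labels = []
        for g in genes:
            fid = family_of.get(g.gene_id)
            labels.append(proto_of_family.get(fid, UNPAINTED)
                          if fid is not None else UNPAINTED)
        labels = _smooth(labels, smooth_window)
        runs = _merge_short(_runs(labels), min_segment)
        painting.segments[chrom] = runs
    painting.validate()
    return painting


def count_exchanges(painting: Painting) -> ExchangeReport:
    """Choppiness: within-chromosome boundaries between distinct painted labels.

    Unpainted runs are transparent — a boundary across one counts once if
    the flanking painted labels differ.  Label changes at chromosome ends
    are not counted; fission/fusion events are therefore not exchanges under
    this definition.
    """
    per_chrom = {}
    for chrom, segs in painting.segments.items():
        painted = [label for _, _, label in segs if label != UNPAINTED]
        per_chrom[chrom] = sum(
            1 for a, b in zip(painted, painted[1:]) if a != b)
    return ExchangeReport(genome_id=painting.genome_id,
                          ancestor_id=painting.ancestor_id,
                          per_chromosome=per_chrom)


# ---------------------------------------------------------------------------
# syntenic depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    target_genome: str
    bin_size: int
    #: query genome -> modal depth over covered bins
    modal_depth: dict[str, int]
    #: query genome -> Counter of depth -> number of bins (covered bins only)
    histogram: dict[str, Counter]


def syntenic_depth(blocks: list[SyntenyBlock],
                   target: str,
                   genomes: dict[str, Genome],
                   bin_size: int = 50) -> DepthProfile:
    """Depth of syntenic coverage of ``target`` by each query genome.

    Per-gene-rank coverage (number of query blocks spanning the position) is
    summarized per bin of ``bin_size`` ranks as the median coverage, so
    fragmented blocks from one query subgenome are not double-counted inside
    a bin.  The modal depth over covered (depth > 0) bins is reported per
    query genome.
    """
    if bin_size < 1:
        raise ValueError(f"bin size must be >= 1, got {bin_size}")
    tg = genomes[target]
    lengths = {chrom: len(genes) for chrom, genes in tg.chromosomes.items()}

    coverage: dict[str, dict[str, np.ndarray]] = {}
    for b in blocks:
        if b.target_genome != target or b.query_genome == target:
            continue
        if b.target_chromosome not in lengths:
            continue
        cov = coverage.setdefault(b.query_genome, {
            c: np.zeros(n, dtype=int) for c, n in lengths.items()
        })[b.target_chromosome]
        cov[b.target_start:min(b.target_end, len(cov))] += 1

    modal: dict[str, int] = {}
    hist: dict[str, Counter] = {}
    for query, per_chrom in coverage.items():
        counter = Counter()
        for chrom, cov in per_chrom.items():
            for lo in range(0, lengths[chrom], bin_size):
                d = int(np.median(cov[lo:lo + bin_size]))
                if d > 0:
                    counter[d] += 1
        hist[query] = counter
        modal[query] = (max(counter, key=lambda d: (counter[d], -d))
                        if counter else 0)
    return DepthProfile(target_genome=target, bin_size=bin_size,
                        modal_depth=modal, histogram=hist)


def depth_ratio(blocks: list[SyntenyBlock],
                genome_a: str, genome_b: str,
                genomes: dict[str, Genome],
                bin_size: int = 50) -> str:
    """Reciprocal syntenic-depth ratio "a:b" between two genomes.

    ``a`` is the modal number of ``genome_a`` regions syntenic to a region
    of ``genome_b`` (depth measured on ``genome_b``), and vice versa — so
    the ratio mirrors the relative subgenome numbers of the two lineages.
    """
    on_b = syntenic_depth(blocks, genome_b, genomes, bin_size)
    on_a = syntenic_depth(blocks, genome_a, genomes, bin_size)
    a = on_b.modal_depth.get(genome_a, 0)
    b = on_a.modal_depth.get(genome_b, 0)
    return f"{a}:{b}"
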