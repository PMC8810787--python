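"""Genome-evolution simulator producing ground truth for the pipeline.

An ancestral genome of ``n_chromosomes`` x ``genes_per_chromosome`` unique
genes evolves along a rooted species tree whose branch lengths are in Ks
units (the Ks clock and the branch-length axis coincide; no rate
variation).  Per branch, in order: whole-genome duplications (each
duplicating every chromosome, at a stated fraction along the branch),
a fractionation pass deleting each WGD-created duplicate copy independently
with the branch's probability, then inversions, reciprocal translocations,
fusions and fissions.  Every divergence (speciation or WGD) is recorded in a
per-gene genealogy, so any homolog pair's true Ks is the genealogical path
length through its divergence event, plus Gaussian noise truncated at zero.

Reciprocal translocations swap terminal segments of two chromosomes and are
sampled so that each creates exactly two new ancestral-origin boundaries
(cuts fall inside same-origin runs, and the rejoined flanks differ in
origin), giving clean painting ground truth.

The event log records every sampled breakpoint; replaying it regenerates
each genome exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datamodel import Gene, Genome, HomologPair, SyntenyBlock
from .io import check_binary, node_label

DEFAULT_N_CHROMOSOMES = 7
DEFAULT_GENES_PER_CHROMOSOME = 150
DEFAULT_KS_SIGMA = 0.05
#: percent-similarity drop per Ks unit in the mirrored similarity axis
SIMILARITY_SCALE = 30.0


@dataclass
class BranchEvents:
    """Event schedule for one branch (keyed by its child node's label)."""

    wgd_times: tuple[float, ...] = ()  # fractions in (0,1) along the branch
    #: per-WGD mode: "doubling" duplicates every chromosome; "addition"
    #: merges in one more copy of the branch-ancestral chromosome set (the
    #: two-step hexaploidy: tetraploid + donated third genome -> 3 copies).
    #: Empty tuple means all "doubling".
    wgd_modes: tuple[str, ...] = ()
    fractionation: float = 0.0  # deletion prob per WGD-created copy
    n_inversions: int = 0
    inversion_length: tuple[int, int] = (2, 20)  # uniform, inclusive
    n_translocations: int = 0
    n_fusions: int = 0
    n_fissions: int = 0


@dataclass
class EvolutionConfig:
    tree_newick: str
    seed: int
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES
    genes_per_chromosome: int = DEFAULT_GENES_PER_CHROMOSOME
    events: dict[str, BranchEvents] = field(default_factory=dict)
    ks_sigma: float = DEFAULT_KS_SIGMA
    max_pairs_per_family: int = 200

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for label, ev in self.events.items():
            if not 0.0 <= ev.fractionation <= 1.0:
                raise ValueError(f"{label}: fractionation outside [0,1]")
            if any(not 0.0 < t < 1.0 for t in ev.wgd_times):
                raise ValueError(f"{label}: WGD times must lie inside (0,1)")


class _LineageNode:
    """A divergence event in one gene's genealogy."""

    __slots__ = ("parent", "time", "kind")

    def __init__(self, parent, time: float, kind: str):
        self.parent = parent
        self.time = time
        self.kind = kind  # root | speciation | wgd


class _SimGene:
    __slots__ = ("family", "origin", "strand", "lineage")

    def __init__(self, family: str, origin: str, strand: str, lineage):
        self.family = family
        self.origin = origin  # root chromosome = protochromosome of origin
        self.strand = strand
        self.lineage = lineage


@dataclass
class GroundTruth:
    tree: dendropy.Tree
    #: node label -> true Genome (gene ids are node-prefixed; family_id set)
    ancestral_genomes: dict[str, Genome]
    #: gene_id -> family id, over all emitted genomes (leaves and ancestors)
    family_of: dict[str, str]
    #: gene_id -> root chromosome of origin (protochromosome label)
    origin_of: dict[str, str]
    #: per-leaf-pair true divergence Ks grid is implicit in the tree; the
    #: realized noisy values live in the emitted homolog pairs
    event_log: list[dict]
    node_depths: dict[str, float]


# ---------------------------------------------------------------------------
# event application (shared by simulation and replay)
# ---------------------------------------------------------------------------

def _apply_wgd(chroms: list[list[_SimGene]], time: float,
               new_copy_ids: set[int], indices: list[int] | None = None) -> None:
    for ci in indices if indices is not None else range(len(chroms)):
        original, copy = [], []
        for g in chroms[ci]:
            node = g.lineage
            a = _LineageNode(node, time, "wgd")
            b = _LineageNode(node, time, "wgd")
            g.lineage = a
            original.append(g)
            dup = _SimGene(g.family, g.origin, g.strand, b)
            copy.append(dup)
            new_copy_ids.add(id(dup))
        chroms[ci] = original
        chroms.append(copy)


def _apply_fractionation(chroms: list[list[_SimGene]],
                         deletions: list[tuple[int, int]]) -> None:
    # deletions are (chromosome index, position) sampled beforehand
    for ci, positions in itertools.groupby(sorted(deletions), key=lambda t: t[0]):
        idx = {p for _, p in positions}
        chroms[ci] = [g for p, g in enumerate(chroms[ci]) if p not in idx]


def _apply_inversion(chroms, ci: int, i: int, j: int) -> None:
    seg = chroms[ci][i:j][::-1]
    for g in seg:
        g.strand = "+" if g.strand == "-" else "-"
    chroms[ci][i:j] = seg


def _apply_translocation(chroms, ca: int, i: int, cb: int, j: int) -> None:
    a, b = chroms[ca], chroms[cb]
    chroms[ca], chroms[cb] = a[:i] + b[j:], b[:j] + a[i:]


def _apply_fusion(chroms, ca: int, cb: int) -> None:
    lo, hi = min(ca, cb), max(ca, cb)
    merged = chroms[lo] + chroms[hi]
    chroms[lo] = merged
    del chroms[hi]


def _apply_fission(chroms, ci: int, pos: int) -> None:
    chroms.append(chroms[ci][pos:])
    chroms[ci] = chroms[ci][:pos]


# ---------------------------------------------------------------------------
# branch evolution
# ---------------------------------------------------------------------------

def _clean_translocation_cuts(chroms, rng, max_tries: int = 200):
    """Sample cut points whose old junctions are origin-uniform and whose
    new junctions differ in origin, so each swap paints as exactly two new
    boundaries."""
    eligible = [ci for ci, c in enumerate(chroms) if len(c) >= 4]
    if len(eligible) < 2:
        return None
    for _ in range(max_tries):
        ca, cb = rng.choice(len(eligible), size=2, replace=False)
        ca, cb = eligible[ca], eligible[cb]
        i = int(rng.integers(1, len(chroms[ca])))
        j = int(rng.integers(1, len(chroms[cb])))
        a, b = chroms[ca], chroms[cb]
        old_ok = (a[i - 1].origin == a[i].origin
                  and b[j - 1].origin == b[j].origin)
        new_ok = (a[i - 1].origin != b[j].origin
                  and b[j - 1].origin != a[i].origin)
        if old_ok and new_ok:
            return ca, i, cb, j
    return None


def _evolve_branch(chroms, label: str, ev: BranchEvents,
                   t0: float, t1: float, rng,
                   log: list[dict]) -> None:
    new_copies: set[int] = set()
    modes = ev.wgd_modes or ("doubling",) * len(ev.wgd_times)
    if len(modes) != len(ev.wgd_times):
        raise ValueError(f"{label}: wgd_modes length mismatch")
    n_ancestral = len(chroms)  # chromosome count at branch start
    for frac, mode in zip(ev.wgd_times, modes):
        time = t0 + frac * (t1 - t0)
        indices = (list(range(n_ancestral)) if mode == "addition"
                   else list(range(len(chroms))))
        _apply_wgd(chroms, time, new_copies, indices)
        log.append({"kind": "wgd", "branch": label, "time": time,
                    "indices": indices})

    if new_copies and ev.fractionation > 0:
        deletions = []
        for ci, chrom in enumerate(chroms):
            for p, g in enumerate(chrom):
                if id(g) in new_copies and rng.random() < ev.fractionation:
                    deletions.append((ci, p))
        _apply_fractionation(chroms, deletions)
        log.append({"kind": "fractionation", "branch": label,
                    "deletions": deletions})

    for _ in range(ev.n_inversions):
        sizes = np.array([len(c) for c in chroms], dtype=float)
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        n = len(chroms[ci])
        if n < 2:
            continue
        length = int(rng.integers(ev.inversion_length[0],
                                  ev.inversion_length[1] + 1))
        length = min(length, n)
        i = int(rng.integers(0, n - length + 1))
        _apply_inversion(chroms, ci, i, i + length)
        log.append({"kind": "inversion", "branch": label, "chrom": ci,
                    "start": i, "end": i + length})

    for _ in range(ev.n_translocations):
        cuts = _clean_translocation_cuts(chroms, rng)
        if cuts is None:
            log.append({"kind": "translocation_skipped", "branch": label})
            continue
        ca, i, cb, j = cuts
        _apply_translocation(chroms, ca, i, cb, j)
        log.append({"kind": "translocation", "branch": label,
                    "chrom_a": ca, "cut_a": i, "chrom_b": cb, "cut_b": j})

    for _ in range(ev.n_fusions):
        if len(chroms) < 2:
            break
        ca, cb = (int(x) for x in rng.choice(len(chroms), size=2,
                                             replace=False))
        _apply_fusion(chroms, ca, cb)
        log.append({"kind": "fusion", "branch": label, "chrom_a": ca,
                    "chrom_b": cb})

    for _ in range(ev.n_fissions):
        sizes = np.array([len(c) for c in chroms], dtype=float)
        if sizes.sum() == 0:
            break
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        if len(chroms[ci]) < 2:
            continue
        pos = int(rng.integers(1, len(chroms[ci])))
        _apply_fission(chroms, ci, pos)
        log.append({"kind": "fission", "branch": label, "chrom": ci,
                    "pos": pos})


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _snapshot(label: str, chroms, truth_family: dict, truth_origin: dict
              ) -> Genome:
    genome = Genome(genome_id=label)
    for ci, chrom in enumerate(chroms):
        name = f"chr{ci + 1}"
        genes = []
        for pos, g in enumerate(chrom):
            gid = f"{label}_{name}_{pos:05d}"
            genes.append(Gene(gene_id=gid, genome_id=label,
                              chromosome_id=name, rank=pos, strand=g.strand,
                              family_id=g.family))
            truth_family[gid] = g.family
            truth_origin[gid] = g.origin
        if genes:
            genome.chromosomes[name] = genes
    return genome


def _copy_chroms(chroms, time: float):
    out = []
    for chrom in chroms:
        out.append([
            _SimGene(g.family, g.origin, g.strand,
                     _LineageNode(g.lineage, time, "speciation"))
            for g in chrom])
    return out


def _divergence(x: _SimGene, y: _SimGene) -> tuple[float, str]:
    path = {}
    node = x.lineage
    while node is not None:
        path[id(node)] = node
        node = node.parent
    node, child = y.lineage, None
    while node is not None and id(node) not in path:
        child = node
        node = node.parent
    if node is None or child is None:
        raise RuntimeError("disconnected genealogies")
    return child.time, child.kind


def simulate(config: EvolutionConfig
             ) -> tuple[dict[str, Genome], list[HomologPair], GroundTruth]:
    """Run the generator; returns leaf genomes, homolog pairs, ground truth."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    check_binary(tree)

    depths: dict[str, float] = {}
    root_label = node_label(tree.seed_node) or "root"

    width = len(str(config.n_chromosomes * config.genes_per_chromosome))
    root_chroms: list[list[_SimGene]] = []
    idx = 0
    for ci in range(config.n_chromosomes):
        chrom = []
        for _ in range(config.genes_per_chromosome):
            fam = f"fam{idx:0{width}d}"
            node = _LineageNode(None, 0.0, "root")
            chrom.append(_SimGene(fam, f"chr{ci + 1}", "+", node))
            idx += 1
        root_chroms.append(chrom)

    truth_family: dict[str, str] = {}
    truth_origin: dict[str, str] = {}
    ancestral: dict[str, Genome] = {}
    leaf_genomes: dict[str, Genome] = {}
    leaf_sim: dict[str, list[list[_SimGene]]] = {}
    event_log: list[dict] = []

    def recurse(node: dendropy.Node, chroms, depth: float) -> None:
        label = node_label(node) or root_label
        depths[label] = depth
        if node.is_leaf():
            leaf_genomes[label] = _snapshot(label, chroms, truth_family,
                                            truth_origin)
            leaf_sim[label] = chroms
            return
        ancestral[label] = _snapshot(label, chroms, truth_family,
                                     truth_origin)
        for child in node.child_nodes():
            clabel = node_label(child)
            if clabel is None:
                raise ValueError("every tree node needs a label")
            blen = child.edge.length or 0.0
            child_chroms = _copy_chroms(chroms, depth)
            ev = config.events.get(clabel, BranchEvents())
            _evolve_branch(child_chroms, clabel, ev, depth, depth + blen,
                           rng, event_log)
            recurse(child, child_chroms, depth + blen)

    recurse(tree.seed_node, root_chroms, 0.0)

    pairs = _emit_pairs(leaf_genomes, leaf_sim, depths, config, rng)
    truth = GroundTruth(tree=tree, ancestral_genomes=ancestral,
                        family_of=truth_family, origin_of=truth_origin,
                        event_log=event_log, node_depths=depths)
    return leaf_genomes, pairs, truth


def _emit_pairs(leaf_genomes, leaf_sim, depths, config, rng
                ) -> list[HomologPair]:
    by_family: dict[str, list[tuple[str, float, _SimGene]]] = {}
    for label, chroms in leaf_sim.items():
        genome = leaf_genomes[label]
        depth = depths[label]
        flat = [g for chrom in chroms for g in chrom]
        ids = [gn.gene_id for gn in genome.genes()]
        for gid, sg in zip(ids, flat):
            by_family.setdefault(sg.family, []).append((gid, depth, sg))

    pairs: list[HomologPair] = []
    for fam in sorted(by_family):
        members = by_family[fam]
        combos = itertools.combinations(members, 2)
        for k, ((ga, da, sa), (gb, db, sb)) in enumerate(combos):
            if k >= config.max_pairs_per_family:
                break
            t_div, kind = _divergence(sa, sb)
            ks_true = (da - t_div) + (db - t_div)
            ks = max(0.0, ks_true + rng.normal(0.0, config.ks_sigma))
            sim = float(np.clip(
                100.0 - SIMILARITY_SCALE * ks_true
                + rng.normal(0.0, SIMILARITY_SCALE * config.ks_sigma),
                0.0, 100.0))
            pairs.append(HomologPair(
                gene_a=ga, gene_b=gb, ks=ks, similarity=sim,
                pair_class="paralog" if kind == "wgd" else "ortholog"))
    return pairs


def replay(config: EvolutionConfig, event_log: list[dict]
           ) -> dict[str, Genome]:
    """Re-apply a recorded event log; returns the regenerated leaf genomes."""
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    log_by_branch: dict[str, list[dict]] = {}
    for entry in event_log:
        log_by_branch.setdefault(entry["branch"], []).append(entry)

    width = len(str(config.n_chromosomes * config.genes_per_chromosome))
    chroms0: list[list[_SimGene]] = []
    idx = 0
    for ci in range(config.n_chromosomes):
        chroms0.append([
            _SimGene(f"fam{idx + p:0{width}d}", f"chr{ci + 1}", "+",
                     _LineageNode(None, 0.0, "root"))
            for p in range(config.genes_per_chromosome)])
        idx += config.genes_per_chromosome

    out: dict[str, Genome] = {}

    def recurse(node, chroms):
        label = node_label(node)
        if node.is_leaf():
            out[label] = _snapshot(label, chroms, {}, {})
            return
        for child in node.child_nodes():
            clabel = node_label(child)
            child_chroms = _copy_chroms(chroms, 0.0)
            for entry in log_by_branch.get(clabel, ()):
                kind = entry["kind"]
                if kind == "wgd":
                    _apply_wgd(child_chroms, entry["time"], set(),
                               entry.get("indices"))
                elif kind == "fractionation":
                    _apply_fractionation(child_chroms,
                                         [tuple(d) for d in entry["deletions"]])
                elif kind == "inversion":
                    _apply_inversion(child_chroms, entry["chrom"],
                                     entry["start"], entry["end"])
                elif kind == "translocation":
                    _apply_translocation(child_chroms, entry["chrom_a"],
                                         entry["cut_a"], entry["chrom_b"],
                                         entry["cut_b"])
                elif kind == "fusion":
                    _apply_fusion(child_chroms, entry["chrom_a"],
                                  entry["chrom_b"])
                elif kind == "fission":
                    _apply_fission(child_chroms, entry["chrom"], entry["pos"])
            recurse(child, child_chroms)

    recurse(tree.seed_node, chroms0)
    return out


# ---------------------------------------------------------------------------
# synteny blocks from ground truth
# ---------------------------------------------------------------------------

def synteny_blocks(genomes: dict[str, Genome],
                   family_of: dict[str, str],
                   min_length: int = 5,
                   max_gap: int = 5) -> list[SyntenyBlock]:
    """Gap-tolerant co-linear homolog chains between every genome pair.

    Anchors are same-family gene placements; anchors on one chromosome pair
    chain greedily while consecutive anchors advance by at most ``max_gap``
    ranks on both sides (so post-WGD fractionation holes do not shatter a
    block); chains of at least ``min_length`` anchors are emitted as blocks,
    once per genome in the target role.
    """
    placements: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for label, genome in genomes.items():
        d: dict[str, list[tuple[str, int]]] = {}
        for g in genome.genes():
            fam = family_of.get(g.gene_id)
            if fam is not None:
                d.setdefault(fam, []).append((g.chromosome_id, g.rank))
        placements[label] = d

    blocks: list[SyntenyBlock] = []
    counter = itertools.count()
    labels = sorted(genomes)
    for qa, qb in itertools.combinations(labels, 2):
        by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for g in genomes[qa].genes():
            fam = family_of.get(g.gene_id)
            if fam is None:
                continue
            for chrom_b, rank_b in placements[qb].get(fam, ()):
                by_pair.setdefault((g.chromosome_id, chrom_b), []).append(
                    (g.rank, rank_b))
        for (c1, c2), anchors in sorted(by_pair.items()):
            anchors.sort()
            open_chains: list[list[tuple[int, int]]] = []
            done: list[list[tuple[int, int]]] = []
            for i, j in anchors:
                best = None
                for chain in open_chains:
                    i0, j0 = chain[-1]
                    if 0 <= i - i0 <= max_gap and abs(j - j0) <= max_gap:
                        if best is None or abs(j - best[-1][1]) > abs(j - j0):
                            best = chain
                if best is None:
                    done.extend(c for c in open_chains
                                if i - c[-1][0] > max_gap)
                    open_chains = [c for c in open_chains
                                   if i - c[-1][0] <= max_gap]
                    open_chains.append([(i, j)])
                else:
                    best.append((i, j))
            done.extend(open_chains)
            for chain in done:
                if len(chain) < min_length:
                    continue
                qi = [a[0] for a in chain]
                tj = [a[1] for a in chain]
                q_lo, q_hi = min(qi), max(qi) + 1
                t_lo, t_hi = min(tj), max(tj) + 1
                bid = f"blk{next(counter):06d}"
                blocks.append(SyntenyBlock(
                    block_id=bid, query_genome=qa, query_chromosome=c1,
                    query_start=q_lo, query_end=q_hi,
                    target_genome=qb, target_chromosome=c2,
                    target_start=t_lo, target_end=t_hi))
                blocks.append(SyntenyBlock(
                    block_id=bid + "r", query_genome=qb, query_chromosome=c2,
                    query_start=t_lo, query_end=t_hi,
                    target_genome=qa, target_chromosome=c1,
                    target_start=q_lo, target_end=q_hi))
    return blocks


# ---------------------------------------------------------------------------
# the eudicot-like preset
# ---------------------------------------------------------------------------

PRESET_TREE = ("(Ranu:1.4,(Prot:1.2,((Buxus:0.8,Tetra:0.8)n_bt:0.2,"
               "(coreA:0.6,coreB:0.6)n_core:0.4)n_cru:0.2)n_pro:0.2)root;")


def preset_eudicot(seed: int,
                   fractionation: float = 0.2,
                   core_fractionation: float = 0.3,
                   inversions_per_branch: int = 5,
                   translocations_per_branch: int = 1) -> EvolutionConfig:
    """A six-leaf eudicot-like history with lineage-specific WGDs.

    Shaped (Ranunculales-like,(Proteales-like,((Buxus-like,Tetracentron-like),
    (coreA,coreB)))): one WGD on the Buxus-like branch, two successive WGDs
    on the Tetracentron-like branch, and the two-step hexaploidy on the core
    stem (a doubling followed by the addition of a third genome copy).
    Post-WGD fractionation leaves modal copy numbers of 2 (Buxus-like),
    4 (Tetracentron-like) and 3 (core leaves).
    """
    base = dict(n_inversions=inversions_per_branch,
                n_translocations=translocations_per_branch)
    events = {
        "Ranu": BranchEvents(**base),
        "Prot": BranchEvents(**base),
        "n_pro": BranchEvents(**base),
        "n_cru": BranchEvents(**base),
        "n_bt": BranchEvents(**base),
        "Buxus": BranchEvents(wgd_times=(0.5,), fractionation=fractionation,
                              **base),
        "Tetra": BranchEvents(wgd_times=(0.35, 0.65),
                              fractionation=fractionation, **base),
        "n_core": BranchEvents(wgd_times=(0.35, 0.65),
                               wgd_modes=("doubling", "addition"),
                               fractionation=core_fractionation, **base),
        "coreA": BranchEvents(**base),
        "coreB": BranchEvents(**base),
    }
    return EvolutionConfig(tree_newick=PRESET_TREE, seed=seed, events=events)
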