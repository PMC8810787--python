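"""Ancestral contig inference by maximum-weight matching of protogene ends.

An internal, non-root node of the species tree has three incident branches
that partition the leaves into three subtrees: its two descendant clades and
everything reached through the incoming edge.  A family-pair adjacency
observed anywhere in at least two of the three subtrees is a candidate
ancestral adjacency, weighted 2 or 3 by the number of supporting subtrees.
A maximum-weight matching over protogene ends then selects the heaviest
compatible set: each end joins at most one end of another protogene, so the
selected adjacencies decompose into linear (occasionally circular) contigs.
Orientation is deliberately ignored when counting support — inversions with
breakpoints inside the extraction window preserve which genes are adjacent
but not their reading direction — but the matcher only offers the
end-to-end ports actually observed in some genome, so that a pair cannot
double-select itself into a spurious two-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import networkx as nx

from .datamodel import AncestralContig, CandidateAdjacency, ObservedAdjacency
from .families import FamilySet
from .io import node_label


@dataclass
class SubtreePartition:
    """Leaf sets of the subtrees incident to an ancestor node."""

    ancestor: str
    subtrees: list[frozenset[str]]  # 3 for internal non-root, 2 for root

    @property
    def max_weight(self) -> int:
        return len(self.subtrees)


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise KeyError(f"no node labeled {label!r} in tree")


def _leaf_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(node_label(lf) for lf in node.leaf_iter())


def partition_subtrees(tree: dendropy.Tree, ancestor: str) -> SubtreePartition:
    """Split the leaves into the three subtrees incident to ``ancestor``."""
    node = find_node(tree, ancestor)
    if node.is_leaf():
        raise ValueError(f"{ancestor!r} is a leaf, not an ancestor")
    if node.parent_node is None:
        raise ValueError(
            f"{ancestor!r} is the root: it has no incoming edge, so only its "
            "two child subtrees exist — use partition_root() for two-subtree "
            "mode")
    left, right = (_leaf_set(c) for c in node.child_nodes())
    all_leaves = _leaf_set(tree.seed_node)
    outside = all_leaves - left - right
    return SubtreePartition(ancestor=ancestor,
                            subtrees=[left, right, frozenset(outside)])


def partition_root(tree: dendropy.Tree) -> SubtreePartition:
    """Two-subtree fallback for the root (candidate weights all 2)."""
    root = tree.seed_node
    left, right = (_leaf_set(c) for c in root.child_nodes())
    return SubtreePartition(ancestor=node_label(root) or "root",
                            subtrees=[left, right])


def collect_candidates(
        observed: list[ObservedAdjacency],
        partition: SubtreePartition) -> list[CandidateAdjacency]:
    """Weight family-pair adjacencies by the number of supporting subtrees.

    Adjacency identity is the unordered family pair; end sides and window
    distance are ignored here, and repeated sightings within one subtree do
    not raise the weight.  Pairs seen in a single subtree are discarded.
    """
    subtree_of: dict[str, int] = {}
    for i, leaves in enumerate(partition.subtrees):
        for leaf in leaves:
            subtree_of[leaf] = i

    support: dict[frozenset[str], set[int]] = {}
    genomes: dict[frozenset[str], set[str]] = {}
    min_dist: dict[frozenset[str], int] = {}
    end_pairs: dict[frozenset[str], set[tuple[int, int]]] = {}
    for adj in observed:
        st = subtree_of.get(adj.genome_id)
        if st is None:
            continue
        key = adj.family_pair
        support.setdefault(key, set()).add(st)
        genomes.setdefault(key, set()).add(adj.genome_id)
        d = min_dist.get(key)
        if d is None or adj.distance < d:
            min_dist[key] = adj.distance
        # canonical end-pair: sides ordered by family id
        if adj.family_a <= adj.family_b:
            ep = (adj.side_a, adj.side_b)
        else:
            ep = (adj.side_b, adj.side_a)
        end_pairs.setdefault(key, set()).add(ep)

    out = []
    for key, subtrees in support.items():
        if len(subtrees) < 2:
            continue
        out.append(CandidateAdjacency(
            families=key, weight=len(subtrees),
            subtrees=frozenset(subtrees), genomes=frozenset(genomes[key]),
            min_distance=min_dist[key],
            end_pairs=frozenset(end_pairs[key])))
    # deterministic downstream processing
    out.sort(key=lambda c: (-c.weight, sorted(c.families)))
    return out


def eligible_families(family_set: FamilySet,
                      partition: SubtreePartition,
                      min_subtrees: int = 2) -> set[str]:
    """Families present in >= ``min_subtrees`` subtrees become protogenes.

    Mirrors the candidate-adjacency evidence rule: a family seen on only one
    side of the ancestor carries no cross-branch signal of ancestral
    presence.
    """
    out = set()
    for fid, fam in family_set.families.items():
        if fam.oversize:
            continue
        present = {i for i, leaves in enumerate(partition.subtrees)
                   if any(fam.copy_counts.get(g, 0) > 0 for g in leaves)}
        if len(present) >= min_subtrees:
            out.add(fid)
    return out


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

#: tie-break scale preferring shortest-distance candidates among matchings
#: of equal subtree-support weight; small enough that the integer-weight
#: optimum is never traded away (total perturbation < 1/2 for any matching
#: of < 10^4 edges with window distances < 50)
DISTANCE_EPS = 1e-6


def _port_graph(candidates: list[CandidateAdjacency],
                families: set[str],
                all_ports: bool = False) -> nx.Graph:
    g = nx.Graph()
    for fid in sorted(families):
        g.add_node((fid, 0))
        g.add_node((fid, 1))
    for cand in candidates:
        fams = sorted(cand.families)
        if len(fams) != 2:
            continue  # tandem self-pairs never reach matching
        f, h = fams
        if f not in families or h not in families:
            continue
        w = cand.weight - DISTANCE_EPS * (cand.min_distance - 1)
        if all_ports or not cand.end_pairs:
            ports = [(sa, sb) for sa in (0, 1) for sb in (0, 1)]
        else:
            ports = sorted(cand.end_pairs)
        for sa, sb in ports:
            g.add_edge((f, sa), (h, sb), weight=w)
    return g


def mwm_assemble(candidates: list[CandidateAdjacency],
                 families: set[str] | None = None,
                 all_ports: bool = False) -> list[AncestralContig]:
    """Assemble ancestral contigs from a maximum-weight matching of ends.

    Every protogene contributes two end nodes ``(family, 0)`` and
    ``(family, 1)``; a candidate pair {f, h} contributes one port edge per
    end-side combination observed in the data (or, with ``all_ports=True``
    or when no sides were recorded, all four), each at the candidate's
    weight.  Restricting ports to observed sides keeps reading-direction
    out of the support count while preventing a pair from trivially closing
    into a weight-doubling two-cycle.  Matched port edges
    plus the intrinsic edge joining the two ends of each protogene decompose
    into paths and cycles; paths become linear contigs, cycles are flagged
    for :func:`linearize`.  Families untouched by the matching become
    singleton contigs.

    The matching itself is delegated to the blossom algorithm
    (``networkx.max_weight_matching``); determinism comes from inserting
    nodes and edges in sorted order.
    """
    if families is None:
        families = set()
        for cand in candidates:
            families.update(cand.families)
    graph = _port_graph(candidates, families, all_ports=all_ports)

    weight_of: dict[frozenset[str], int] = {
        c.families: c.weight for c in candidates}

    matched: list[tuple[tuple[str, int], tuple[str, int]]] = []
    for comp in nx.connected_components(graph):
        # rebuild the component in sorted node order: subgraph views iterate
        # the component set, whose order is hash-dependent, and blossom tie
        # resolution follows node order
        nodes = sorted(comp)
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(
            (u, v, d) for u, v, d in graph.edges(nodes, data=True))
        if sub.number_of_edges() == 0:
            continue
        for a, b in nx.max_weight_matching(sub, maxcardinality=False):
            matched.append((a, b) if a <= b else (b, a))
    matched.sort()

    # union of matched port edges and intrinsic protogene edges: degree <= 2
    skel = nx.MultiGraph()
    for fid in families:
        skel.add_edge((fid, 0), (fid, 1), kind="gene")
    for a, b in matched:
        skel.add_edge(a, b, kind="match")

    contigs: list[AncestralContig] = []
    seen: set[tuple[str, int]] = set()
    for comp in sorted(nx.connected_components(skel), key=sorted):
        comp = set(comp)
        seen |= comp
        contigs.append(_trace_component(skel, comp, weight_of))
    contigs = [c for c in contigs if c is not None]
    _assign_contig_ids(contigs)
    return contigs


def _trace_component(skel: nx.MultiGraph, comp: set,
                     weight_of: dict) -> AncestralContig:
    degree = {n: skel.degree(n) for n in comp}
    endpoints = sorted(n for n in comp if degree[n] == 1)
    circular = not endpoints
    start = endpoints[0] if endpoints else min(comp)

    fams: list[str] = []
    joins: list[int] = []
    node = start
    prev_kind = "match"  # first traversed edge must be the intrinsic gene edge
    visited_fams: set[str] = set()
    while True:
        fid, side = node
        if prev_kind == "match":
            fams.append(fid)
            visited_fams.add(fid)
            node = (fid, 1 - side)  # cross the gene
            prev_kind = "gene"
        else:
            nbrs = [n for n in skel.neighbors(node)
                    if n[0] != fid and n[0] not in visited_fams]
            if not nbrs:
                # closing edge of a cycle back to start
                if circular:
                    joins.append(weight_of[frozenset((fid, start[0]))])
                break
            nxt = nbrs[0]
            joins.append(weight_of[frozenset((fid, nxt[0]))])
            node = nxt
            prev_kind = "match"
    return AncestralContig(contig_id="", families=fams, join_weights=joins,
                           circular=circular)


def _canonical(fams: list[str]) -> list[str]:
    rev = list(reversed(fams))
    return fams if fams <= rev else rev


def _assign_contig_ids(contigs: list[AncestralContig]) -> None:
    contigs.sort(key=lambda c: (-len(c), _canonical(c.families)))
    width = max(4, len(str(len(contigs))))
    for i, c in enumerate(contigs):
        c.contig_id = f"ctg{i:0{width}d}"


def linearize(contigs: list[AncestralContig]) -> list[AncestralContig]:
    """Break every circular contig at its minimum-weight join.

    Ties go to the lexicographically smallest family pair at that weight.
    Linear contigs pass through unchanged.
    """
    out: list[AncestralContig] = []
    for c in contigs:
        if not c.circular:
            out.append(c)
            continue
        n = len(c.families)
        # join i connects families[i] -- families[(i+1) % n]
        best = min(
            range(n),
            key=lambda i: (c.join_weights[i],
                           sorted((c.families[i], c.families[(i + 1) % n]))))
        fams = c.families[best + 1:] + c.families[:best + 1]
        joins = c.join_weights[best + 1:] + c.join_weights[:best]
        out.append(AncestralContig(
            contig_id=c.contig_id, families=fams, join_weights=joins,
            circular=False, linearized_from_cycle=True))
    return out


def matched_adjacencies(contigs: list[AncestralContig]) -> set[frozenset[str]]:
    """The family-pair joins realized in a contig set (reporting helper)."""
    out: set[frozenset[str]] = set()
    for c in contigs:
        fams = c.families
        for i in range(len(fams) - 1):
            out.add(frozenset((fams[i], fams[i + 1])))
        if c.circular and len(fams) > 1:
            out.add(frozenset((fams[-1], fams[0])))
    return out


def reconstruct_ancestor(observed: list[ObservedAdjacency],
                         family_set: FamilySet,
                         partition: SubtreePartition,
                         all_ports: bool = False) -> list[AncestralContig]:
    """candidates -> matching -> linearization, in one call."""
    cands = collect_candidates(observed, partition)
    fams = eligible_families(family_set, partition)
    return linearize(mwm_assemble(cands, fams, all_ports=all_ports))
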