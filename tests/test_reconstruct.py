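import itertools

import numpy as np
import pytest

from conftest import reconstruction_scores, run_reconstruction, truth_translation
from paleokaryo import reconstruct as rec
from paleokaryo import simulate as sim
from paleokaryo.datamodel import AncestralContig, CandidateAdjacency, ObservedAdjacency
from paleokaryo.io import parse_tree_string


def cand(f, g, w, end_pairs=((1, 0),), dist=1):
    return CandidateAdjacency(
        families=frozenset((f, g)), weight=w, subtrees=frozenset(range(w)),
        genomes=frozenset(), min_distance=dist,
        end_pairs=frozenset(end_pairs))


def obs(genome, f, g, side_a=1, side_b=0, distance=1):
    return ObservedAdjacency(
        genome_id=genome, chromosome_id="c1", gene_a=f + "x", gene_b=g + "x",
        family_a=f, family_b=g, side_a=side_a, side_b=side_b,
        distance=distance)


class TestPartition:
    def test_balanced_quartet(self):
        tree = parse_tree_string("((A,B)n1,(C,D)n2)root;")
        p1 = rec.partition_subtrees(tree, "n1")
        assert sorted(map(sorted, p1.subtrees)) == [["A"], ["B"], ["C", "D"]]
        p2 = rec.partition_subtrees(tree, "n2")
        assert sorted(map(sorted, p2.subtrees)) == [["A", "B"], ["C"], ["D"]]

    def test_caterpillar(self):
        tree = parse_tree_string("(((A,B)x,C)y,D)root;")
        p = rec.partition_subtrees(tree, "y")
        assert sorted(map(sorted, p.subtrees)) == [["A", "B"], ["C"], ["D"]]

    def test_root_is_rejected_with_two_subtree_hint(self):
        tree = parse_tree_string("((A,B)n1,(C,D)n2)root;")
        with pytest.raises(ValueError, match="two-subtree"):
            rec.partition_subtrees(tree, "root")
        p = rec.partition_root(tree)
        assert p.max_weight == 2
        assert sorted(map(sorted, p.subtrees)) == [["A", "B"], ["C", "D"]]


class TestCandidates:
    def partition(self):
        tree = parse_tree_string("((A,B)n1,(C,D)n2)root;")
        return rec.partition_subtrees(tree, "n1")

    def test_two_and_three_subtree_weights(self):
        part = self.partition()
        observed = [obs("A", "f", "g"), obs("C", "f", "g"),
                    obs("A", "p", "q"), obs("B", "p", "q"), obs("D", "p", "q")]
        cands = {tuple(sorted(c.families)): c.weight
                 for c in rec.collect_candidates(observed, part)}
        assert cands == {("f", "g"): 2, ("p", "q"): 3}

    def test_single_subtree_support_is_not_a_candidate(self):
        part = self.partition()
        observed = [obs("C", "f", "g"), obs("D", "f", "g")]  # same subtree
        assert rec.collect_candidates(observed, part) == []

    def test_repeats_within_a_subtree_do_not_raise_weight(self):
        part = self.partition()
        observed = [obs("A", "f", "g", distance=1),
                    obs("A", "f", "g", distance=2),
                    obs("C", "f", "g"), obs("D", "f", "g")]
        (c,) = rec.collect_candidates(observed, part)
        assert c.weight == 2 and c.min_distance == 1


def brute_force_optimum(graph) -> float:
    """Exhaustive maximum-weight matching over all edge subsets."""
    edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
    best = 0.0

    def recurse(i, used, total):
        nonlocal best
        best = max(best, total)
        for j in range(i, len(edges)):
            u, v, w = edges[j]
            if u not in used and v not in used:
                recurse(j + 1, used | {u, v}, total + w)

    recurse(0, frozenset(), 0.0)
    return best


def matched_weight(contigs) -> int:
    return sum(sum(c.join_weights) for c in contigs)


class TestMatching:
    def test_forced_chain(self):
        contigs = rec.mwm_assemble([cand("a", "b", 3), cand("b", "c", 3)])
        (c,) = contigs
        assert c.families in (["a", "b", "c"], ["c", "b", "a"])
        assert sorted(c.join_weights) == [3, 3]

    def test_triangle_picks_two_heaviest_compatible(self):
        cands = [cand("a", "b", 3), cand("a", "c", 2), cand("b", "c", 2)]
        contigs = rec.mwm_assemble(cands)
        assert matched_weight(contigs) == 5
        graph = rec._port_graph(cands, {"a", "b", "c"})
        assert brute_force_optimum(graph) == pytest.approx(5, abs=0.01)

    def test_singletons_become_length_one_contigs(self):
        contigs = rec.mwm_assemble([cand("a", "b", 3)], {"a", "b", "z"})
        lengths = sorted(len(c) for c in contigs)
        assert lengths == [1, 2]

    def test_each_end_matched_at_most_once(self):
        rng = np.random.default_rng(0)
        fams = [f"f{i}" for i in range(8)]
        for _ in range(20):
            cands = [cand(a, b, int(rng.integers(2, 4)))
                     for a, b in itertools.combinations(fams, 2)
                     if rng.random() < 0.4]
            contigs = rec.mwm_assemble(cands, set(fams))
            # ends appear at most once as an internal join per side
            for c in contigs:
                assert len(c.families) == len(set(c.families))

    def test_random_instances_match_exhaustive_optimum(self):
        """Seeded random candidate sets: blossom == brute force, 40/40."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            fams = [f"f{i}" for i in range(n)]
            cands = []
            for a, b in itertools.combinations(fams, 2):
                if rng.random() < 0.5:
                    eps = [(int(rng.integers(0, 2)), int(rng.integers(0, 2)))]
                    cands.append(cand(a, b, int(rng.integers(2, 4)),
                                      end_pairs=eps))
            if not cands:
                continue
            contigs = rec.mwm_assemble(cands, set(fams))
            graph = rec._port_graph(cands, set(fams))
            assert matched_weight(contigs) == pytest.approx(
                brute_force_optimum(graph), abs=0.01)

    def test_deterministic_for_fixed_input(self):
        cands = [cand("a", "b", 2), cand("b", "c", 2), cand("c", "d", 3),
                 cand("a", "d", 2)]
        runs = [rec.mwm_assemble(list(cands), {"a", "b", "c", "d"})
                for _ in range(3)]
        fingerprints = [[(c.contig_id, c.families, c.join_weights)
                         for c in contigs] for contigs in runs]
        assert fingerprints[0] == fingerprints[1] == fingerprints[2]


class TestLinearize:
    def cycle(self, weights):
        fams = ["a", "b", "c"]
        return AncestralContig("c0", fams, list(weights), circular=True)

    def test_cycle_breaks_at_minimum_weight_join(self):
        # joins: a-b w3, b-c w3, c-a w2 -> break {c,a}
        (out,) = rec.linearize([self.cycle([3, 3, 2])])
        assert out.families == ["a", "b", "c"]
        assert out.join_weights == [3, 3]
        assert out.linearized_from_cycle and not out.circular

    def test_all_equal_weights_break_smallest_pair(self):
        (out,) = rec.linearize([self.cycle([3, 3, 3])])
        # smallest pair lexicographically is {a, b}: order b, c, a
        assert out.families == ["b", "c", "a"]

    def test_linear_contig_unchanged(self):
        c = AncestralContig("c0", ["a", "b"], [2])
        assert rec.linearize([c]) == [c]

    def test_two_cycle_from_complementary_ports(self):
        cands = [cand("a", "b", 3, end_pairs=((0, 0), (1, 1)))]
        contigs = rec.mwm_assemble(cands)
        (c,) = contigs
        assert c.circular and len(c.join_weights) == 2
        (lin,) = rec.linearize(contigs)
        assert not lin.circular and lin.join_weights == [3]


class TestRecovery:
    def test_exact_recovery_without_events(self, three_leaf_clean):
        """No WGD / rearrangement / fractionation: the matched adjacency set
        contains every true neighbor adjacency and contigs reproduce the
        ancestral order up to whole-contig reversal."""
        genomes, fs, truth, contigs = three_leaf_clean[:4]
        precision, recall = reconstruction_scores(contigs, fs, truth, "n1")
        assert recall == 1.0 and precision == 1.0
        tr = truth_translation(fs, truth)
        recovered = {tuple(tr[f] for f in c.families) for c in contigs}
        for genes in truth.ancestral_genomes["n1"].chromosomes.values():
            order = tuple(g.family_id for g in genes)
            assert order in recovered or order[::-1] in recovered

    def test_fractionation_degrades_recall_monotonically(self):
        """More fractionation after a WGD never helps adjacency recall."""
        def mean_recall(p, seeds):
            vals = []
            for s in seeds:
                cfg = sim.EvolutionConfig(
                    tree_newick="(A:1.0,(B:0.6,C:0.6)n1:0.4)root;", seed=s,
                    n_chromosomes=3, genes_per_chromosome=80,
                    events={"B": sim.BranchEvents(wgd_times=(0.5,),
                                                  fractionation=p)})
                _, fs, truth, contigs = run_reconstruction(cfg, "n1")
                vals.append(reconstruction_scores(contigs, fs, truth, "n1")[1])
            return np.mean(vals)

        seeds = range(200, 208)
        assert mean_recall(0.4, seeds) <= mean_recall(0.1, seeds) + 0.01
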