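import pytest

from conftest import make_genome, origin_proto_map
from paleokaryo import painting as pnt
from paleokaryo import simulate as sim
from paleokaryo.datamodel import SyntenyBlock, UNPAINTED


def label_genome(labels, chrom="c1"):
    """Genome + maps where gene i carries protochromosome label labels[i]."""
    genes = [(f"g{i:03d}", "+") for i in range(len(labels))]
    genome = make_genome("G", {chrom: genes})
    family_of = {gid: f"f_{gid}" for gid, _ in genes}
    proto_of = {f"f_{gid}": lab for (gid, _), lab in zip(genes, labels)
                if lab is not None}
    return genome, proto_of, family_of


class TestPaint:
    def test_runs_become_segments(self):
        genome, proto_of, family_of = label_genome(list("111222"))
        p = pnt.paint(genome, proto_of, family_of, min_segment=1)
        assert p.segments["c1"] == [(0, 3, "1"), (3, 6, "2")]

    def test_short_runs_merge_into_flanking_majority(self):
        genome, proto_of, family_of = label_genome(list("11211"))
        p = pnt.paint(genome, proto_of, family_of, min_segment=2)
        assert p.segments["c1"] == [(0, 5, "1")]

    def test_genes_without_ancestral_family_are_unpainted(self):
        genome, proto_of, family_of = label_genome(["1", "1", None, None])
        p = pnt.paint(genome, proto_of, family_of, min_segment=1)
        assert p.segments["c1"] == [(0, 2, "1"), (2, 4, UNPAINTED)]

    def test_segments_tile_every_chromosome(self):
        genome, proto_of, family_of = label_genome(list("1122121121"))
        for ms in (1, 2, 3):
            p = pnt.paint(genome, proto_of, family_of, min_segment=ms)
            p.validate()
            assert p.segments["c1"][0][0] == 0
            assert p.segments["c1"][-1][1] == 10

    def test_majority_smoothing_removes_single_gene_noise(self):
        genome, proto_of, family_of = label_genome(list("1112111"))
        p = pnt.paint(genome, proto_of, family_of, min_segment=1,
                      smooth_window=3)
        assert p.segments["c1"] == [(0, 7, "1")]


class TestExchanges:
    def count(self, labels, min_segment=1):
        genome, proto_of, family_of = label_genome(labels)
        p = pnt.paint(genome, proto_of, family_of, min_segment=min_segment)
        return pnt.count_exchanges(p).total

    def test_uniform_chromosome_has_no_exchanges(self):
        assert self.count(list("11111")) == 0

    def test_1_2_1_counts_two_boundaries(self):
        assert self.count(list("112211")) == 2

    def test_unpainted_runs_are_transparent(self):
        genome, proto_of, family_of = label_genome(
            ["1", "1", None, None, "2", "2"])
        p = pnt.paint(genome, proto_of, family_of, min_segment=1)
        assert pnt.count_exchanges(p).total == 1
        genome, proto_of, family_of = label_genome(
            ["1", "1", None, None, "1", "1"])
        p = pnt.paint(genome, proto_of, family_of, min_segment=1)
        assert pnt.count_exchanges(p).total == 0

    def test_invariant_to_whole_chromosome_reversal(self):
        labels = list("1122133221")
        assert self.count(labels) == self.count(labels[::-1])

    def test_per_chromosome_breakdown_sums_to_total(self):
        genome = make_genome("G", {
            "c1": [(f"a{i}", "+") for i in range(4)],
            "c2": [(f"b{i}", "+") for i in range(4)]})
        family_of = {g.gene_id: g.gene_id for g in genome.genes()}
        proto_of = {"a0": "1", "a1": "1", "a2": "2", "a3": "2",
                    "b0": "3", "b1": "3", "b2": "3", "b3": "3"}
        rep = pnt.count_exchanges(
            pnt.paint(genome, proto_of, family_of, min_segment=1))
        assert rep.per_chromosome == {"c1": 1, "c2": 0}
        assert rep.total == 1


class TestPaintingIdentity:
    def test_no_events_paints_one_segment_per_chromosome(self):
        cfg = sim.EvolutionConfig(
            tree_newick="(O:0.5,L:0.5)top;", seed=9,
            n_chromosomes=4, genes_per_chromosome=60)
        genomes, _, truth = sim.simulate(cfg)
        proto_of = origin_proto_map(truth.ancestral_genomes["top"])
        p = pnt.paint(genomes["L"], proto_of, truth.family_of)
        assert all(len(segs) == 1 for segs in p.segments.values())
        assert pnt.count_exchanges(p).total == 0


class TestSyntenicDepth:
    def genomes(self):
        return {"T": make_genome("T", {"c1": [(f"t{i}", "+")
                                              for i in range(100)]}),
                "Q": make_genome("Q", {"c1": [(f"q{i}", "+")
                                              for i in range(100)]})}

    def block(self, bid, tstart, tend):
        return SyntenyBlock(bid, "Q", "c1", 0, tend - tstart, "T", "c1",
                            tstart, tend)

    def test_overlapping_blocks_stack(self):
        blocks = [self.block(f"b{i}", 0, 50) for i in range(3)]
        prof = pnt.syntenic_depth(blocks, "T", self.genomes(), bin_size=50)
        assert prof.modal_depth == {"Q": 3}

    def test_empty_block_list_gives_zero_depth(self):
        prof = pnt.syntenic_depth([], "T", self.genomes(), bin_size=50)
        assert prof.modal_depth == {}

    def test_bin_below_1_is_an_error(self):
        with pytest.raises(ValueError, match="bin"):
            pnt.syntenic_depth([], "T", self.genomes(), bin_size=0)

    def test_hexaploid_vs_diploid_reciprocal_depths(self):
        """Two-step hexaploidy (doubling + genome addition) against a
        diploid: modal depth 1 on the hexaploid side, 3 on the diploid."""
        cfg = sim.EvolutionConfig(
            tree_newick="(D:1.0,H:1.0)root;", seed=2, n_chromosomes=3,
            genes_per_chromosome=80,
            events={"H": sim.BranchEvents(wgd_times=(0.3, 0.6),
                                          wgd_modes=("doubling", "addition"))})
        genomes, _, truth = sim.simulate(cfg)
        blocks = sim.synteny_blocks(genomes, truth.family_of)
        assert pnt.syntenic_depth(blocks, "H", genomes).modal_depth == {"D": 1}
        assert pnt.syntenic_depth(blocks, "D", genomes).modal_depth == {"H": 3}
        assert pnt.depth_ratio(blocks, "D", "H", genomes) == "1:3"


class TestNearerAncestor:
    def test_exchanges_monotone_in_ancestor_distance(self):
        """Rearrangements split across two ancestral intervals: the nearer
        ancestor never explains more exchanges than the farther one."""
        ok = 0
        for seed in range(300, 310):
            ev = dict(n_translocations=3, n_inversions=5)
            cfg = sim.EvolutionConfig(
                tree_newick="(O1:1.0,(O2:0.7,L:0.7)anc2:0.3)anc1;", seed=seed,
                events={k: sim.BranchEvents(**ev)
                        for k in ("anc2", "L", "O2", "O1")})
            genomes, _, truth = sim.simulate(cfg)
            ex = {}
            for anc in ("anc1", "anc2"):
                proto_of = origin_proto_map(truth.ancestral_genomes[anc])
                p = pnt.paint(genomes["L"], proto_of, truth.family_of,
                              min_segment=1, ancestor_id=anc)
                ex[anc] = pnt.count_exchanges(p).total
            ok += ex["anc2"] <= ex["anc1"]
        assert ok >= 9
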