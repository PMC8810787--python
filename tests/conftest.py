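import pytest

from paleokaryo import families as fam
from paleokaryo import reconstruct as rec
from paleokaryo import simulate as sim
from paleokaryo.datamodel import Gene, Genome


def make_genome(genome_id: str, chromosomes: dict[str, list[tuple[str, str]]]
                ) -> Genome:
    """Build a Genome from {chrom: [(gene_id, strand), ...]}."""
    g = Genome(genome_id=genome_id)
    for chrom, genes in chromosomes.items():
        g.chromosomes[chrom] = [
            Gene(gene_id=gid, genome_id=genome_id, chromosome_id=chrom,
                 rank=i, strand=strand)
            for i, (gid, strand) in enumerate(genes)]
    g.validate()
    return g


def trivial_family_set(genomes: dict[str, Genome]) -> fam.FamilySet:
    """One family per distinct family_id annotation (or per gene_id prefix)."""
    families: dict[str, fam.GeneFamily] = {}
    family_of: dict[str, str] = {}
    for genome in genomes.values():
        for g in genome.genes():
            fid = g.family_id or g.gene_id
            f = families.setdefault(fid, fam.GeneFamily(family_id=fid))
            f.members.add(g.gene_id)
            f.copy_counts[g.genome_id] = f.copy_counts.get(g.genome_id, 0) + 1
            family_of[g.gene_id] = fid
    return fam.FamilySet(families=families, family_of=family_of)


def truth_translation(family_set: fam.FamilySet,
                      truth: sim.GroundTruth) -> dict[str, str]:
    """Map inferred family ids (smallest member gene id) to true family ids."""
    return {fid: truth.family_of[next(iter(f.members))]
            for fid, f in family_set.families.items()}


def reconstruction_scores(contigs, family_set, truth, ancestor: str
                          ) -> tuple[float, float]:
    """(precision, recall) of matched joins vs true neighbor adjacencies."""
    tr = truth_translation(family_set, truth)
    anc = truth.ancestral_genomes[ancestor]
    true_adj = set()
    for genes in anc.chromosomes.values():
        fams = [g.family_id for g in genes]
        true_adj.update(frozenset((a, b)) for a, b in zip(fams, fams[1:]))
    matched = {frozenset(tr[f] for f in pair)
               for pair in rec.matched_adjacencies(contigs)}
    hit = len(matched & true_adj)
    return hit / len(matched), hit / len(true_adj)


def run_reconstruction(config: sim.EvolutionConfig, ancestor: str, w: int = 7):
    """simulate -> families -> adjacencies -> contigs at one ancestor."""
    genomes, pairs, truth = sim.simulate(config)
    fs = fam.build_families(pairs, genomes)
    obs = [a for g in sorted(genomes.values(), key=lambda g: g.genome_id)
           for a in fam.extract_generalized_adjacencies(g, fs, w)]
    part = rec.partition_subtrees(truth.tree, ancestor)
    contigs = rec.reconstruct_ancestor(obs, fs, part)
    return genomes, fs, truth, contigs


def origin_proto_map(ancestral_genome: Genome) -> dict[str, str]:
    """family -> ancestor chromosome, for single-copy families only."""
    out: dict[str, str] = {}
    dup = set()
    for g in ancestral_genome.genes():
        if g.family_id in out:
            dup.add(g.family_id)
        out[g.family_id] = g.chromosome_id
    return {f: c for f, c in out.items() if f not in dup}


@pytest.fixture(scope="session")
def three_leaf_clean():
    """3-leaf simulation with no WGD, rearrangement or fractionation."""
    cfg = sim.EvolutionConfig(
        tree_newick="(A:1.0,(B:0.6,C:0.6)n1:0.4)root;", seed=101)
    return run_reconstruction(cfg, "n1") + (cfg,)
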