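import numpy as np
import pytest

from ctsirna import study
from ctsirna.gene_features import gc_content
from ctsirna.synthetic import (
    SIZES,
    ConfigurationError,
    GenotypeSpec,
    SimulationConfig,
    simulate_genome,
    simulate_tags,
)
from ctsirna.io_formats import CATEGORIES


def _spec(**kw):
    base = dict(
        name="test",
        category_mixture=(0.5, 0.3, 0.1, 0.05, 0.05),
        size_mixture=(0.05, 0.25, 0.55, 0.05, 0.10),
        antisense_fraction=0.6,
    )
    base.update(kw)
    return GenotypeSpec(**base)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ConfigurationError, match="category_mixture"):
            _spec(category_mixture=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_hotspot_share_without_genes(self):
        with pytest.raises(ConfigurationError, match="hotspot_genes"):
            _spec(hotspot_share=0.5)

    def test_incompatible_gene_length(self):
        with pytest.raises(ConfigurationError, match="gene_length_range"):
            SimulationConfig(gene_length_range=(400, 500))

    def test_gc_levels_out_of_range(self):
        with pytest.raises(ConfigurationError, match="gc_levels"):
            SimulationConfig(gc_levels=(0.3, 1.0))


class TestGenomeConstruction:
    def test_category_counts_and_attributes(self):
        cfg = SimulationConfig(
            seed=5,
            genes_per_category={"structural RNA": 3},
            n_chromosomes=1,
        )
        genome, truth = simulate_genome(cfg)
        assert len(genome) == 3
        assert all(g.category == "structural RNA" for g in genome.genes.values())
        assert (truth["category"] == "structural RNA").all()

    def test_gc_targets_realized(self, sim_genome):
        genome, truth = sim_genome
        for row in truth.itertuples():
            gene = genome.genes[row.gene]
            seq = genome.sequence(gene.chrom, gene.start, gene.end)
            assert abs(gc_content(seq) - row.gc_target) <= 0.02
            if gene.category == "protein-coding":
                cds = genome.spliced_sequence(row.gene, kind="CDS")
                assert abs(gc_content(cds) - row.gc_target) <= 0.02

    def test_protein_coding_structure(self, sim_genome):
        genome, truth = sim_genome
        pc = truth[truth["category"] == "protein-coding"]
        for gid in pc["gene"]:
            gene = genome.genes[gid]
            kinds = {c.kind for c in gene.children}
            assert {"five_prime_UTR", "CDS", "three_prime_UTR", "exon"} <= kinds
            # gene length decomposes into UTRs + CDS + introns
            segs = sum(
                c.length
                for c in gene.children
                if c.kind in ("five_prime_UTR", "CDS", "three_prime_UTR", "intron")
            )
            assert segs == gene.span

    def test_intergenic_separation(self, sim_genome):
        genome, _ = sim_genome
        by_chrom = {}
        for g in genome.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end >= 2000

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert t1.equals(t2)


class TestTagSimulation:
    @pytest.fixture(scope="class")
    @staticmethod
    def genome_truth():
        return simulate_genome(study.default_config(seed=3))

    def test_copy_counts_sum_to_library_size(self, genome_truth):
        genome, _ = genome_truth
        tags, _ = simulate_tags(genome, _spec(), "single", 20_000, seed=1)
        assert sum(t.count for t in tags) == 20_000

    def test_tags_contained_in_source_features(self, genome_truth):
        genome, _ = genome_truth
        tags, _ = simulate_tags(genome, _spec(), "single", 5_000, seed=2)
        for tag in tags:
            hits = [
                g
                for g in genome.overlapping(tag.chrom, tag.start, tag.end)
                if g.start <= tag.start and tag.end <= g.end
            ]
            assert len(hits) == 1

    def test_zero_antisense_fraction(self, genome_truth):
        genome, _ = genome_truth
        tags, _ = simulate_tags(
            genome, _spec(antisense_fraction=0.0), "single", 10_000, seed=3
        )
        for tag in tags:
            gene = genome.overlapping(tag.chrom, tag.start, tag.end)[0]
            if gene.category == "protein-coding":
                assert tag.strand == gene.strand

    def test_pure_22nt_mixture(self, genome_truth):
        genome, _ = genome_truth
        tags, _ = simulate_tags(
            genome, _spec(size_mixture=(0, 0, 1, 0, 0)), "single", 5_000, seed=4
        )
        assert all(t.length == 22 for t in tags)

    def test_category_proportions_multinomial(self, genome_truth):
        """Realized category counts stay within 3 exact-multinomial SDs."""
        genome, _ = genome_truth
        n = 100_000
        spec = _spec()
        tags, _ = simulate_tags(genome, spec, "single", n, seed=5)
        counts = dict.fromkeys(CATEGORIES, 0)
        for tag in tags:
            gene = genome.overlapping(tag.chrom, tag.start, tag.end)[0]
            counts[gene.category] += tag.count
        for p, category in zip(spec.category_mixture, CATEGORIES):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[category] - n * p) <= 3 * sd

    def test_hotspot_share_recovery(self, genome_truth):
        genome, truth = genome_truth
        hot = tuple(study.high_gc_pc_genes(truth)[:20])
        spec = _spec(hotspot_genes=hot, hotspot_share=0.8)
        tags, _ = simulate_tags(genome, spec, "single", 50_000, seed=6)
        hot_set = set(hot)
        from_hot = total = 0
        for tag in tags:
            gene = genome.overlapping(tag.chrom, tag.start, tag.end)[0]
            if gene.category != "protein-coding" or tag.strand == gene.strand:
                continue
            if tag.length != 22:
                continue
            total += tag.count
            if gene.gene_id in hot_set:
                from_hot += tag.count
        sd = np.sqrt(total * 0.8 * 0.2)
        assert abs(from_hot - 0.8 * total) <= 3 * sd

    def test_truth_table_category_expectations(self, genome_truth):
        genome, _ = genome_truth
        spec = _spec()
        _, truth = simulate_tags(genome, spec, "single", 1_000, seed=7)
        cat = truth[truth["gene"] == "*"]
        assert np.isclose(cat["expected_fraction"].sum(), 1.0)
        gene_rows = truth[truth["gene"] != "*"]
        expected_as = spec.category_mixture[0] * spec.antisense_fraction
        assert np.isclose(gene_rows["expected_fraction"].sum(), expected_as)

    def test_determinism_same_seed(self, genome_truth):
        genome, _ = genome_truth
        t1, _ = simulate_tags(genome, _spec(), "single", 5_000, seed=11)
        t2, _ = simulate_tags(genome, _spec(), "single", 5_000, seed=11)
        assert [
            (t.chrom, t.start, t.end, t.strand, t.count) for t in t1
        ] == [(t.chrom, t.start, t.end, t.strand, t.count) for t in t2]

    def test_mass_on_empty_category_rejected(self):
        cfg = SimulationConfig(seed=1, genes_per_category={"protein-coding": 3})
        genome, _ = simulate_genome(cfg)
        with pytest.raises(ConfigurationError, match="empty category"):
            simulate_tags(genome, _spec(), "single", 100, seed=1)
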