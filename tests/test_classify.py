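"""Classifier tests, including the brute-force overlap oracle.

The oracle enumerates every gene, applies the 50%-overlap rule and the
documented category priority by exhaustive comparison — no interval index,
no shared code with the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from ctsirna import classify, study, synthetic
from ctsirna.classify import (
    CATEGORY_PRIORITY,
    UNASSIGNED,
    assign_tag,
    ct_sirna_counts,
    per_gene_coverage,
    size_percentages,
    tally_categories,
)
from ctsirna.io_formats import AnnotatedGenome, Gene, TagAlignment


def oracle_assign(tag, genome):
    """Naive per-tag scan with the documented priority and tie rules."""
    best = None
    for gene in genome.genes.values():
        if gene.chrom != tag.chrom:
            continue
        overlap = min(tag.end, gene.end) - max(tag.start, gene.start)
        if overlap < 0.5 * tag.length:
            continue
        if gene.category not in CATEGORY_PRIORITY:
            continue
        key = (CATEGORY_PRIORITY.index(gene.category), -overlap, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, gene)
    if best is None:
        return (UNASSIGNED, None, None)
    gene = best[1]
    return (
        gene.category,
        gene.gene_id,
        "antisense" if tag.strand != gene.strand else "sense",
    )


def random_instance(rng, n_features=30, n_tags=300, chrom_len=20_000):
    """A random annotation (overlaps allowed) plus random tags."""
    cats = list(CATEGORY_PRIORITY)
    genes = []
    for i in range(n_features):
        start = int(rng.integers(0, chrom_len - 600))
        end = start + int(rng.integers(200, 600))
        genes.append(
            Gene(
                f"g{i:03d}",
                "chr1",
                start,
                end,
                "+" if rng.random() < 0.5 else "-",
                cats[int(rng.integers(0, len(cats)))],
            )
        )
    genome = AnnotatedGenome({"chr1": "A" * chrom_len}, genes)
    tags = []
    for _ in range(n_tags):
        size = int(rng.integers(20, 25))
        start = int(rng.integers(0, chrom_len - size))
        tags.append(
            TagAlignment(
                "chr1",
                start,
                start + size,
                "+" if rng.random() < 0.5 else "-",
                count=int(rng.integers(1, 5)),
                n_hits=int(rng.integers(1, 3)),
            )
        )
    return genome, tags


def test_assign_matches_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(25):
        genome, tags = random_instance(rng)
        for tag in tags:
            assert assign_tag(tag, genome) == oracle_assign(tag, genome)


def test_priority_structural_rna_wins(toy_genome):
    # tag in the geneA/rrna1 overlap zone: fully inside both
    tag = TagAlignment("chr1", 310, 332, "+")
    category, gid, _ = assign_tag(tag, toy_genome)
    assert (category, gid) == ("structural RNA", "rrna1")


def test_antisense_definition_and_antisymmetry(toy_genome):
    minus_tag = TagAlignment("chr1", 150, 172, "-")
    assert assign_tag(minus_tag, toy_genome) == ("protein-coding", "geneA", "antisense")
    # geneB is on '-': a '-' tag is sense there
    assert assign_tag(TagAlignment("chr1", 800, 822, "-"), toy_genome)[2] == "sense"
    assert assign_tag(TagAlignment("chr1", 800, 822, "+"), toy_genome)[2] == "antisense"


def test_no_overlap_unassigned(toy_genome):
    assert assign_tag(TagAlignment("chr1", 550, 572, "+"), toy_genome) == (
        UNASSIGNED,
        None,
        None,
    )


def test_unknown_chromosome_rejected(toy_genome):
    from ctsirna.io_formats import ValidationError

    with pytest.raises(ValidationError, match="chr9"):
        assign_tag(TagAlignment("chr9", 0, 22, "+"), toy_genome)


class TestTally:
    def test_two_tag_arithmetic(self, toy_genome):
        tags = [
            TagAlignment("chr1", 160, 182, "+", count=3),  # geneA protein-coding
            TagAlignment("chr1", 1210, 1232, "+", count=1),  # mir1 pri-miRNA
        ]
        table = tally_categories(tags, toy_genome)
        assert table.loc["protein-coding", "percent"] == pytest.approx(75.0)
        assert table.loc["pri-miRNA", "percent"] == pytest.approx(25.0)

    def test_percentages_sum_to_100(self, toy_genome):
        rng = np.random.default_rng(1)
        genome, tags = random_instance(rng)
        table = tally_categories(tags, genome)
        assigned = table.drop(index=UNASSIGNED)
        assert assigned["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_conservation_of_weight(self):
        rng = np.random.default_rng(2)
        genome, tags = random_instance(rng)
        table = tally_categories(tags, genome)
        total_weight = sum(t.weight for t in tags if 20 <= t.length <= 24)
        assert table["weight"].sum() == pytest.approx(total_weight)

    def test_empty_library_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="no tags"):
            tally_categories([], toy_genome)


class TestCtSirnaCounts:
    def test_single_antisense_tag(self, toy_genome):
        tags = [TagAlignment("chr1", 160, 182, "-", count=5)]
        mat = ct_sirna_counts(tags, toy_genome)
        row = mat[
            (mat["gene"] == "geneA") & (mat["size"] == 22) & (mat["orientation"] == "antisense")
        ]
        assert row["count"].iloc[0] == pytest.approx(5.0)
        assert mat[mat["gene"] != "geneA"]["count"].sum() == 0

    def test_totals_match_bruteforce_recount(self):
        rng = np.random.default_rng(3)
        genome, tags = random_instance(rng)
        mat = ct_sirna_counts(tags, genome)
        expected = {}
        for tag in tags:
            if not 20 <= tag.length <= 24:
                continue
            cat, gid, ori = oracle_assign(tag, genome)
            if cat != "protein-coding":
                continue
            expected[(gid, tag.length, ori)] = (
                expected.get((gid, tag.length, ori), 0.0) + tag.weight
            )
        got = {
            (r.gene, r.size, r.orientation): r.count
            for r in mat.itertuples()
            if r.count > 0
        }
        assert got == pytest.approx(expected)

    def test_zero_antisense_simulation(self, sim_genome):
        genome, _ = sim_genome
        spec = synthetic.GenotypeSpec(
            name="s",
            category_mixture=(1.0, 0, 0, 0, 0),
            size_mixture=(0.2, 0.2, 0.2, 0.2, 0.2),
            antisense_fraction=0.0,
        )
        tags, _ = synthetic.simulate_tags(genome, spec, "single", 3_000, seed=5)
        mat = ct_sirna_counts(tags, genome)
        assert mat[mat["orientation"] == "antisense"]["count"].sum() == 0


class TestSizePercentages:
    def test_all_22(self, toy_genome):
        tags = [TagAlignment("chr1", 160, 182, "-", count=7)]
        mat = ct_sirna_counts(tags, toy_genome)
        pct = size_percentages(mat)
        assert pct[22] == pytest.approx(100.0)
        assert pct.sum() == pytest.approx(100.0)

    def test_equal_counts_each_size(self, toy_genome):
        tags = [
            TagAlignment("chr1", 160, 160 + size, "-", count=2) for size in range(20, 25)
        ]
        pct = size_percentages(ct_sirna_counts(tags, toy_genome))
        assert list(pct) == pytest.approx([20.0] * 5)

    def test_zero_antisense_returns_empty(self, toy_genome):
        tags = [TagAlignment("chr1", 160, 182, "+", count=2)]  # sense only
        pct = size_percentages(ct_sirna_counts(tags, toy_genome))
        assert pct.empty


class TestCoverage:
    def test_single_tag_geometry(self, toy_genome):
        # geneA spans [100,400); tag at gene-relative offset 10
        tag = TagAlignment("chr1", 110, 132, "-")
        cov = per_gene_coverage([tag], toy_genome, "geneA", size=22)
        assert cov.shape == (300,)
        assert cov[10:32].tolist() == [1.0] * 22
        assert cov.sum() == 22.0

    def test_no_matching_tags(self, toy_genome):
        cov = per_gene_coverage([], toy_genome, "geneA")
        assert not cov.any()

    def test_matches_naive_accumulation(self):
        rng = np.random.default_rng(4)
        genome, tags = random_instance(rng, n_features=10, n_tags=500)
        gid = sorted(
            g.gene_id for g in genome.genes.values() if g.category == "protein-coding"
        )[0]
        gene = genome.genes[gid]
        cov = per_gene_coverage(tags, genome, gid, size=None, orientation=None)
        naive = np.zeros(gene.span)
        for tag in tags:
            cat, g, _ = oracle_assign(tag, genome)
            if g != gid:
                continue
            lo = max(tag.start, gene.start) - gene.start
            hi = min(tag.end, gene.end) - gene.start
            naive[lo:hi] += tag.weight
        assert np.allclose(cov, naive)
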