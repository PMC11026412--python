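import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctsirna import study, synthetic
from ctsirna.gene_features import (
    compare_features,
    gc_class,
    gc_content,
    gene_metrics,
    genome_gc_bins,
    metagene_profile,
)
from ctsirna.io_formats import TagAlignment, write_fasta, write_gff3


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCCAT", 4 / 6), ("AAAA", 0.0), ("GCGC", 1.0), ("GGCCATNN", 4 / 6)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError, match="unambiguous"):
            gc_content("NNNN")


class TestGCClass:
    @pytest.mark.parametrize(
        "gc,expected",
        [(0.30, "low"), (0.299, "low"), (0.301, "medium"), (0.44, "medium"),
         (0.499, "medium"), (0.50, "high"), (1.0, "high"), (0.0, "low")],
    )
    def test_boundaries(self, gc, expected):
        assert gc_class(gc) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_partitions_unit_interval(self, gc):
        assert gc_class(gc) in {"low", "medium", "high"}


class TestGenomeGCBins:
    def test_bin_lengths_and_partial_flag(self):
        bins = genome_gc_bins({"g": "A" * 250})
        assert bins["length"].tolist() == [100, 100, 50]
        assert bins["partial"].tolist() == [False, False, True]

    def test_homopolymer_g(self):
        bins = genome_gc_bins({"g": "G" * 300})
        assert (bins["gc"] == 1.0).all()


class TestGeneMetrics:
    def test_matches_independent_reparse(self, sim_genome, tmp_path):
        """All fields equal a naive recomputation from the raw GFF3 + FASTA."""
        genome, _ = sim_genome
        fasta_path = tmp_path / "g.fa"
        gff_path = tmp_path / "g.gff3"
        write_fasta(genome.sequences, fasta_path)
        write_gff3(genome.genes.values(), gff_path)

        # independent minimal parsers
        seqs = {}
        name = None
        for line in fasta_path.read_text().splitlines():
            if line.startswith(">"):
                name = line[1:]
                seqs[name] = []
            else:
                seqs[name].append(line)
        seqs = {k: "".join(v) for k, v in seqs.items()}

        info: dict[str, dict] = {}
        for line in gff_path.read_text().splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(kv.split("=") for kv in f[8].split(";"))
            if f[2] == "gene" and "category=protein-coding" in line:
                info[attrs["ID"]] = {
                    "chrom": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
                    "strand": f[6], "utr5": 0, "utr3": 0, "exons": 0,
                }
            elif f[2] in ("five_prime_UTR", "three_prime_UTR", "exon"):
                gid = attrs["Parent"].rsplit(".", 1)[0]
                if gid in info:
                    span = int(f[4]) - int(f[3]) + 1
                    if f[2] == "five_prime_UTR":
                        info[gid]["utr5"] += span
                    elif f[2] == "three_prime_UTR":
                        info[gid]["utr3"] += span
                    else:
                        info[gid]["exons"] += 1

        table, clips = gene_metrics(genome)
        assert set(table.index) == set(info)
        def naive_gc(s):
            return sum(1 for b in s if b in "GC") / len(s)
        for gid, row in table.iterrows():
            exp = info[gid]
            assert row["length"] == exp["end"] - exp["start"]
            assert row["utr5_length"] == exp["utr5"]
            assert row["utr3_length"] == exp["utr3"]
            assert row["intron_count"] == exp["exons"] - 1
            seq = seqs[exp["chrom"]]
            if exp["strand"] == "+":
                up = seq[max(exp["start"] - 1000, 0) : exp["start"]]
            else:
                up = seq[exp["end"] : exp["end"] + 1000]
            if up:
                assert row["gc_upstream"] == pytest.approx(naive_gc(up))

    def test_single_exon_gene_zero_introns(self, toy_genome):
        table, _ = gene_metrics(toy_genome)
        assert table.loc["geneA", "intron_count"] == 0
        assert table.loc["geneA", "utr5_length"] == 50

    def test_simulated_utr_truth_recovery(self, sim_genome):
        genome, _ = sim_genome
        table, _ = gene_metrics(genome)
        for gid, row in table.iterrows():
            gene = genome.genes[gid]
            utr5 = sum(c.length for c in gene.sub("five_prime_UTR"))
            assert row["utr5_length"] == utr5

    def test_gc_class_consistency(self, sim_genome):
        genome, _ = sim_genome
        table, _ = gene_metrics(genome)
        for _, row in table.iterrows():
            assert row["gc_class"] == gc_class(row["gc_body"])


class TestCompareFeatures:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 40)
        table = pd.DataFrame({"f": np.concatenate([vals, vals])},
                             index=[f"g{i}" for i in range(80)])
        res = compare_features(table, [f"g{i}" for i in range(40)], "f")
        assert abs(res["t"]) < 1e-9
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        """Matches the textbook Welch formula on a tiny printed example."""
        a, b = np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 40.0])
        table = pd.DataFrame(
            {"f": np.concatenate([a, b])}, index=[f"g{i}" for i in range(8)]
        )
        res = compare_features(table, [f"g{i}" for i in range(4)], "f")
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        assert res["t"] == pytest.approx(t_hand)
        assert res["p"] == pytest.approx(p_hand)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 200)
            b = rng.normal(3, 1, 200)
            table = pd.DataFrame(
                {"f": np.concatenate([a, b])},
                index=[f"g{i}" for i in range(400)],
            )
            res = compare_features(table, [f"g{i}" for i in range(200)], "f")
            if res["p"] < 1e-10:
                hits += 1
        assert hits == 10

    def test_small_group_rejected(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2"):
            compare_features(table, ["a"], "f")


class TestMetagene:
    def test_flank_bins_zero_without_flank_tags(self, sim_genome):
        genome, truth = sim_genome
        gid = truth.loc[truth["category"] == "protein-coding", "gene"].iloc[0]
        gene = genome.genes[gid]
        anti = "-" if gene.strand == "+" else "+"
        tags = [TagAlignment(gene.chrom, gene.start + 50, gene.start + 72, anti)]
        prof = metagene_profile(tags, genome, [gid], size=22)
        assert not prof[:50].any() and not prof[150:].any()
        assert prof[50:150].sum() > 0

    def test_uniform_coverage_flat_body(self, sim_genome):
        """Uniform antisense sampling yields a flat body profile."""
        genome, truth = sim_genome
        pc = truth[truth["category"] == "protein-coding"]
        spec = synthetic.GenotypeSpec(
            name="u",
            category_mixture=(1.0, 0, 0, 0, 0),
            size_mixture=(0, 0, 1.0, 0, 0),
            antisense_fraction=1.0,
        )
        tags, _ = synthetic.simulate_tags(genome, spec, "single", 100_000, seed=8)
        gene_ids = sorted(pc["gene"])
        prof = metagene_profile(tags, genome, gene_ids, size=22)
        body = prof[55:145]  # clip edge bins where tag-start geometry tapers
        assert body.max() / body.min() < 1.2

    def test_empty_gene_set_warns_nan(self, sim_genome):
        genome, _ = sim_genome
        with pytest.warns(UserWarning, match="empty gene set"):
            prof = metagene_profile([], genome, [], size=22)
        assert np.isnan(prof).all()

    def test_gc_ordering_recovery(self, sim_genome):
        """GC-weighted production yields high > medium > low profile means."""
        genome, truth = sim_genome
        spec = synthetic.GenotypeSpec(
            name="gc",
            category_mixture=(1.0, 0, 0, 0, 0),
            size_mixture=(0, 0, 1.0, 0, 0),
            antisense_fraction=1.0,
            gc_effect=lambda gc: math.exp(6.0 * (gc - 0.44)),
        )
        tags, _ = synthetic.simulate_tags(genome, spec, "single", 50_000, seed=9)
        pc = truth[truth["category"] == "protein-coding"]
        means = {}
        for level, genes in pc.groupby("gc_target")["gene"]:
            prof = metagene_profile(tags, genome, sorted(genes), size=22)
            means[float(level)] = np.nanmean(prof[50:150])
        assert means[0.55] > means[0.40] > means[0.30]
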