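"""Associate ct-siRNA production with source-gene features.

Computes the per-gene feature table (lengths, UTRs, introns, body/flank GC,
GC class), the 100-bp CDS GC distribution, Welch t-tests of each feature
between differential 22-nt producers and the remaining protein-coding
genes, and GC-stratified metagene profiles of 22-nt antisense coverage.
Outputs under results/features/.

Usage: python analysis/05_features.py
"""

import sys
from pathlib import Path

import pandas as pd

from ctsirna.gene_features import compare_features, gene_metrics, genome_gc_bins, metagene_profile
from ctsirna.io_formats import read_annotation, read_tags

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    outdir = ROOT / "results" / "features"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_annotation(data / "genome.gff3", data / "genome.fa")

    table, clips = gene_metrics(genome)
    table.to_csv(outdir / "gene_features.tsv", sep="\t", float_format="%.6g")
    if clips:
        print(f"note: {len(clips)} flank windows clipped at contig edges")

    cds = {gid: genome.spliced_sequence(gid, kind="CDS")
           for gid, g in genome.genes.items() if g.category == "protein-coding"}
    bins = genome_gc_bins(cds, bin_size=100)
    bins.to_csv(outdir / "gc_bins.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"CDS 100-bp bins: {len(bins)}, mean GC {100 * bins['gc'].mean():.2f}%")

    producers = pd.read_csv(
        ROOT / "results" / "differential" / "differential_union_22nt.tsv", sep="\t"
    )["gene"].tolist()
    print(f"producer set: {len(producers)} genes with differential 22-nt ct-siRNAs")
    stats_rows = []
    for feature in ("length", "utr5_length", "utr3_length", "intron_count",
                    "gc_body", "gc_upstream", "gc_downstream"):
        res = compare_features(table, producers, feature)
        stats_rows.append({
            "feature": feature, "t": res["t"], "p": res["p"],
            "producer_mean": res["producers"]["mean"], "other_mean": res["others"]["mean"],
        })
        print(f"  {feature:13s} producers {res['producers']['mean']:10.3f} "
              f"vs others {res['others']['mean']:10.3f}  (Welch p={res['p']:.3g})")
    pd.DataFrame(stats_rows).to_csv(outdir / "feature_tests.tsv", sep="\t",
                                    index=False, float_format="%.6g")

    meta = pd.read_csv(data / "samples.tsv", sep="\t", index_col="sample")
    sample = meta.index[meta["genotype"] == "ed4"][0]
    tags, _ = read_tags(data / f"tags_{sample}.tsv")
    total = sum(t.weight for t in tags)
    for size in (21, 22):
        prof_rows = {}
        for cls in ("low", "medium", "high"):
            genes = sorted(table.index[table["gc_class"] == cls])
            prof_rows[cls] = metagene_profile(tags, genome, genes, size=size,
                                              library_total=total)
        prof = pd.DataFrame(prof_rows)
        prof.index.name = "bin"
        prof.to_csv(outdir / f"metagene_{size}nt.tsv", sep="\t", float_format="%.6g")
        means = prof.mean().round(3).to_dict()
        print(f"{size}-nt metagene mean abundance by GC class ({sample}): {means}")


if __name__ == "__main__":
    sys.exit(main())
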