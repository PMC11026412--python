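"""Classify tags by locus category and count ct-siRNAs per gene.

Reads the simulated libraries from results/data/, assigns every tag to a
locus category, and writes per-sample category percentages, the antisense
size profile (the ct-siRNA size-class fingerprint), and the per-gene
size x strand count matrices under results/classify/.

Usage: python analysis/02_classify.py
"""

import sys
from pathlib import Path

import pandas as pd

from ctsirna import classify
from ctsirna.io_formats import read_annotation, read_tags

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    outdir = ROOT / "results" / "classify"
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_annotation(data / "genome.gff3", data / "genome.fa")
    meta = pd.read_csv(data / "samples.tsv", sep="\t", index_col="sample")

    cat_rows, size_rows, totals = [], [], {}
    for sample in meta.index:
        tags, _ = read_tags(data / f"tags_{sample}.tsv")
        table = classify.tally_categories(tags, genome)
        totals[sample] = float(table["weight"].sum())
        row = table["percent"].rename(sample)
        cat_rows.append(row)
        matrix = classify.ct_sirna_counts(tags, genome)
        matrix.insert(0, "sample", sample)
        matrix.to_csv(outdir / f"gene_size_strand_{sample}.tsv", sep="\t", index=False)
        pct = classify.size_percentages(matrix).rename(sample)
        size_rows.append(pct)

    cats = pd.DataFrame(cat_rows)
    cats.index.name = "sample"
    cats.to_csv(outdir / "category_counts.tsv", sep="\t", float_format="%.6g")
    sizes = pd.DataFrame(size_rows)
    sizes.index.name = "sample"
    sizes.to_csv(outdir / "ct_sirna_size_percent.tsv", sep="\t", float_format="%.6g")
    pd.Series(totals, name="library_total").rename_axis("sample").to_csv(
        outdir / "library_totals.tsv", sep="\t"
    )

    by_geno = cats.join(meta["genotype"]).groupby("genotype").mean(numeric_only=True)
    print("mean category % by genotype:")
    print(by_geno.round(2).to_string())
    print("\nmean ct-siRNA size % by genotype:")
    print(sizes.join(meta["genotype"]).groupby("genotype").mean().round(2).to_string())


if __name__ == "__main__":
    sys.exit(main())
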