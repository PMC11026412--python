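"""Rank hotspot source genes, form the cross-mutant union, cluster samples.

Ranks 22-nt antisense source genes by replicate-mean TPM per mutant, reports
top-20 cumulative shares, writes the cross-genotype hotspot union with its
membership matrix, and clusters all mutant samples on per-gene log2 ratios
to the Col-0 mean (Newick export). Outputs under results/hotspots/.

Usage: python analysis/04_hotspots.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ctsirna.hotspots import cluster_samples, hotspot_union, linkage_to_newick, rank_sources, top_n_share
from ctsirna.quantify import tpm_normalize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cdir = ROOT / "results" / "classify"
    outdir = ROOT / "results" / "hotspots"
    outdir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(ROOT / "results" / "data" / "samples.tsv", sep="\t", index_col="sample")
    totals = pd.read_csv(cdir / "library_totals.tsv", sep="\t", index_col="sample")["library_total"]

    cols = {}
    for sample in meta.index:
        mat = pd.read_csv(cdir / f"gene_size_strand_{sample}.tsv", sep="\t")
        sub = mat[(mat["size"] == 22) & (mat["orientation"] == "antisense")]
        cols[sample] = sub.set_index("gene")["count"]
    counts = pd.DataFrame(cols).fillna(0.0).sort_index()
    tpm = tpm_normalize(counts, totals)

    reports = {}
    for genotype in ("ed4", "sd4"):
        reps = list(meta.index[meta["genotype"] == genotype])
        report = rank_sources(tpm, reps)
        report.to_csv(outdir / f"hotspots_{genotype}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        reports[genotype] = report
        print(f"{genotype}: top-20 cumulative 22-nt ct-siRNA share = "
              f"{100 * top_n_share(report, 20):.1f}%")

    union, membership = hotspot_union(reports, n=20)
    membership.T.rename_axis("gene").to_csv(outdir / "hotspot_union_membership.tsv", sep="\t")
    print(f"hotspot union across mutants: {len(union)} genes")

    col0 = list(meta.index[meta["genotype"] == "Col-0"])
    mut = list(meta.index[meta["genotype"] != "Col-0"])
    ref = tpm[col0].mean(axis=1)
    rel = np.log2((tpm[mut] + 1.0).div(ref + 1.0, axis=0))
    Z, leaves = cluster_samples(rel)
    (outdir / "sample_dendrogram.nwk").write_text(linkage_to_newick(Z, mut) + "\n")
    print("sample clustering leaf order:", " ".join(leaves))


if __name__ == "__main__":
    sys.exit(main())
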