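"""Call differential 21-/22-nt ct-siRNA accumulation, mutant vs Col-0.

Rebuilds genes x samples antisense count matrices from the classification
output, runs the negative-binomial Wald test per contrast and size class,
and writes per-gene results plus the significant gene sets (padj < 0.05 and
|log2FC| > 1) under results/differential/.

Usage: python analysis/03_differential.py
"""

import sys
from pathlib import Path

import pandas as pd

from ctsirna.quantify import call_differential, nb_test

ROOT = Path(__file__).resolve().parents[1]


def load_matrices(size: int) -> pd.DataFrame:
    cdir = ROOT / "results" / "classify"
    meta = pd.read_csv(ROOT / "results" / "data" / "samples.tsv", sep="\t", index_col="sample")
    cols = {}
    for sample in meta.index:
        mat = pd.read_csv(cdir / f"gene_size_strand_{sample}.tsv", sep="\t")
        sub = mat[(mat["size"] == size) & (mat["orientation"] == "antisense")]
        cols[sample] = sub.set_index("gene")["count"]
    return pd.DataFrame(cols).fillna(0.0).sort_index(), meta


def main() -> None:
    outdir = ROOT / "results" / "differential"
    outdir.mkdir(parents=True, exist_ok=True)

    union: dict[int, set] = {21: set(), 22: set()}
    for size in (21, 22):
        counts, meta = load_matrices(size)
        controls = list(meta.index[meta["genotype"] == "Col-0"])
        for mutant in ("ed4", "sd4"):
            mutants = list(meta.index[meta["genotype"] == mutant])
            res = nb_test(counts.round().astype(int), mutants, controls)
            res.to_csv(outdir / f"diff_{size}nt_{mutant}_vs_Col-0.tsv", sep="\t",
                       float_format="%.6g")
            hits = call_differential(res)
            union[size] |= set(hits)
            up = sum(res.loc[g, "log2FC"] > 0 for g in hits)
            print(f"{size}-nt {mutant} vs Col-0: {len(hits)} differential genes "
                  f"({up} up in mutant)")
    for size in (21, 22):
        pd.Series(sorted(union[size]), name="gene").to_csv(
            outdir / f"differential_union_{size}nt.tsv", sep="\t", index=False
        )
        print(f"{size}-nt union across mutants: {len(union[size])} genes")


if __name__ == "__main__":
    sys.exit(main())
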