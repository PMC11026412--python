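"""Simulate the synthetic comparative study: genome, annotation, libraries.

Builds the default annotated genome (92 genes, five locus categories, GC
levels 30/40/55%) and nine sRNA libraries (Col-0, ed4, sd4 x 3 replicates,
100k tags each), and writes FASTA/GFF3/tag TSVs plus truth tables under
results/data/.

Usage: python analysis/01_simulate.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

from ctsirna import study, synthetic
from ctsirna.io_formats import RunManifest, write_fasta, write_gff3, write_tags_tsv

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    outdir = ROOT / "results" / "data"
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = study.default_config(seed=seed)
    genome, truth = synthetic.simulate_genome(cfg)
    write_fasta(genome.sequences, outdir / "genome.fa")
    write_gff3(genome.genes.values(), outdir / "genome.gff3")
    truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)

    genotypes = study.default_genotypes(truth)
    samples, meta = study.simulate_samples(
        genome, genotypes, seed=seed, library_size=cfg.library_size,
        replicates=cfg.replicates,
    )
    for name, tags in samples.items():
        write_tags_tsv(tags, outdir / f"tags_{name}.tsv")
    meta.to_csv(outdir / "samples.tsv", sep="\t")

    manifest = RunManifest.create(
        config={"seed": seed, "library_size": cfg.library_size, "replicates": cfg.replicates},
        inputs=[outdir / "genome.fa", outdir / "genome.gff3"],
        seeds=[seed],
    )
    manifest.write(outdir / "manifest.json")

    n_pc = (truth["category"] == "protein-coding").sum()
    print(f"genome: {len(genome)} genes ({n_pc} protein-coding) on {len(genome.sequences)} chromosomes")
    print(f"libraries: {len(samples)} samples x {cfg.library_size} tags -> {outdir}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    sys.exit(main(args.seed))
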