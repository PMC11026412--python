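"""Default study conditions and end-to-end pipeline drivers.

The default synthetic study emulates the design of a comparative sRNA-seq
experiment in RNA-decay/PTGS-deficient Arabidopsis: a wild-type control
(``Col-0``) whose sRNA pool is dominated by structural-RNA fragments with
few antisense protein-coding tags, and double-mutant genotypes (``ed4``,
``sd4``, for ein5 dcl4- and ski2 dcl4-like backgrounds) in which 22-nt
antisense tags from protein-coding genes surge, concentrated on a small set
of hotspot genes with high-GC bias. A separate time-series design gives each
mutant one library per growth stage with per-gene multiplicative trends.

These defaults are the conditions all analyses and acceptance checks run
under; they are chosen once, not tuned per run.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify
from .io_formats import AnnotatedGenome, TagAlignment
from .synthetic import (
    SIZES,
    GenotypeSpec,
    SimulationConfig,
    sample_seed,
    simulate_genome,
    simulate_tags,
)

#: gene GC targets cycle over these levels in gene order (see synthetic)
GC_LEVELS = (0.30, 0.40, 0.55)

#: mutants concentrate ~85% of antisense PC tags on 20 hotspot genes
HOTSPOT_SHARE = 0.85
N_HOTSPOTS = 20


def _gc_effect(gc: float) -> float:
    """Monotone production weight: high-GC transcripts feed PTGS more readily."""
    return math.exp(6.0 * (gc - 0.44))


def high_gc_pc_genes(truth: pd.DataFrame) -> list[str]:
    pc = truth[truth["category"] == "protein-coding"]
    return sorted(pc.loc[pc["gc_target"] >= 0.50, "gene"])


def medium_gc_pc_genes(truth: pd.DataFrame) -> list[str]:
    pc = truth[truth["category"] == "protein-coding"]
    return sorted(pc.loc[(pc["gc_target"] > 0.30) & (pc["gc_target"] < 0.50), "gene"])


def default_config(seed: int = 0) -> SimulationConfig:
    """Genome-level defaults: 92 genes over five categories, GC levels 30/40/55%."""
    return SimulationConfig(seed=seed)


def default_genotypes(truth: pd.DataFrame) -> list[GenotypeSpec]:
    """The comparative design: Col-0 control plus two ct-siRNA mutants.

    ``ed4`` hotspots are the 20 high-GC protein-coding genes; ``sd4`` shares
    12 of them and adds 8 private medium-GC hotspots, so the expected top-20
    union across the two mutants is 28 genes.
    """
    high = high_gc_pc_genes(truth)
    medium = medium_gc_pc_genes(truth)
    ed4_hot = tuple(high[:N_HOTSPOTS])
    sd4_hot = tuple(high[:12] + medium[:8])
    col0 = GenotypeSpec(
        name="Col-0",
        category_mixture=(0.08, 0.55, 0.17, 0.15, 0.05),
        size_mixture=(0.15, 0.30, 0.20, 0.12, 0.23),
        antisense_fraction=0.10,
    )
    ed4 = GenotypeSpec(
        name="ed4",
        category_mixture=(0.45, 0.30, 0.10, 0.10, 0.05),
        size_mixture=(0.03, 0.12, 0.70, 0.05, 0.10),
        antisense_fraction=0.80,
        hotspot_genes=ed4_hot,
        hotspot_share=HOTSPOT_SHARE,
        gc_effect=_gc_effect,
    )
    sd4 = GenotypeSpec(
        name="sd4",
        category_mixture=(0.40, 0.33, 0.12, 0.10, 0.05),
        size_mixture=(0.04, 0.18, 0.62, 0.06, 0.10),
        antisense_fraction=0.75,
        hotspot_genes=sd4_hot,
        hotspot_share=HOTSPOT_SHARE,
        gc_effect=_gc_effect,
    )
    return [col0, ed4, sd4]


STAGES = ("d07", "d10", "d13", "d16", "d19")


def stage_trend_factory(truth: pd.DataFrame, stages: Sequence[str] = STAGES):
    """Deterministic per-gene multiplicative trajectories over stages.

    Protein-coding genes cycle through four archetypes in gene order:
    increasing (4-fold up over the series), decreasing (4-fold down), peaked
    (up then down), and flat.
    """
    pc = sorted(truth.loc[truth["category"] == "protein-coding", "gene"])
    n = len(stages)
    up = np.geomspace(0.5, 2.0, n)
    down = up[::-1]
    mid = (n - 1) / 2.0
    peak = np.exp(-((np.arange(n) - mid) ** 2) / 2.0) * 2.0
    flat = np.ones(n)
    archetypes = [up, down, peak, flat]
    table = {
        gid: dict(zip(stages, archetypes[i % 4])) for i, gid in enumerate(pc)
    }

    def trend(gene_id: str, stage: str) -> float:
        return table.get(gene_id, {}).get(stage, 1.0)

    trend.archetype = {gid: ["increasing", "decreasing", "peaked", "flat"][i % 4] for i, gid in enumerate(pc)}
    return trend


def timeseries_genotype(truth: pd.DataFrame, name: str = "ed4") -> GenotypeSpec:
    high = high_gc_pc_genes(truth)
    return GenotypeSpec(
        name=name,
        category_mixture=(0.45, 0.30, 0.10, 0.10, 0.05),
        size_mixture=(0.03, 0.12, 0.70, 0.05, 0.10),
        antisense_fraction=0.80,
        hotspot_genes=tuple(high[:N_HOTSPOTS]),
        hotspot_share=HOTSPOT_SHARE,
        gc_effect=_gc_effect,
        stage_trend=stage_trend_factory(truth),
    )


# ---------------------------------------------------------------------------
# Pipeline helpers shared by the analysis scripts and the acceptance script
# ---------------------------------------------------------------------------

def simulate_samples(
    genome: AnnotatedGenome,
    genotypes: Sequence[GenotypeSpec],
    seed: int,
    library_size: int = 100_000,
    replicates: int = 3,
    stage: str = "single",
) -> tuple[dict[str, list[TagAlignment]], pd.DataFrame]:
    """Simulate ``replicates`` libraries per genotype at one stage.

    Returns (sample -> tags, metadata table). Per-sample seeds are derived
    from the base seed and the sample name, so adding a sample never
    perturbs existing ones.
    """
    samples: dict[str, list[TagAlignment]] = {}
    meta = []
    for spec in genotypes:
        for rep in range(1, replicates + 1):
            name = f"{spec.name}_{stage}_r{rep}"
            s = sample_seed(seed, name)
            tags, _truth = simulate_tags(genome, spec, stage, library_size, s)
            samples[name] = tags
            meta.append(
                {"sample": name, "genotype": spec.name, "stage": stage, "replicate": rep}
            )
    return samples, pd.DataFrame(meta).set_index("sample")


def classify_samples(
    genome: AnnotatedGenome, samples: Mapping[str, Sequence[TagAlignment]]
) -> tuple[dict[str, pd.DataFrame], pd.Series, pd.DataFrame]:
    """Run the classifier on every sample.

    Returns (per-sample gene/size/orientation matrices, per-sample in-range
    library totals, stacked category percentage table).
    """
    matrices: dict[str, pd.DataFrame] = {}
    totals = {}
    cat_rows = []
    for name, tags in samples.items():
        matrices[name] = classify.ct_sirna_counts(tags, genome)
        table = classify.tally_categories(tags, genome)
        totals[name] = float(table["weight"].sum())
        row = table["percent"].to_dict()
        row["sample"] = name
        cat_rows.append(row)
    category_table = pd.DataFrame(cat_rows).set_index("sample")
    return matrices, pd.Series(totals, name="library_total"), category_table


def antisense_tpm(
    matrices: Mapping[str, pd.DataFrame],
    library_totals: pd.Series,
    size: int = 22,
) -> pd.DataFrame:
    """Genes x samples antisense TPM for one size class."""
    from .quantify import tpm_normalize

    counts = classify.assemble_count_matrix(dict(matrices), size=size)
    return tpm_normalize(counts, library_totals)
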