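"""Synthetic annotated genomes and aligned sRNA-tag libraries.

The generator emulates the statistical structure the downstream analysis
assumes: a genome whose genes fall into the five sRNA-producing locus
categories (protein-coding, structural RNA, non-coding RNA, pseudogene&TE,
pri-miRNA), and per-sample tag libraries that are mixtures over categories,
strands and lengths 20-24 nt, with optional "hotspot" genes concentrating a
configured share of the antisense protein-coding signal, GC-dependent
per-gene production rates, and per-stage multiplicative trends.

Tags are emitted pre-aligned (no read sequences, no aligner): the analysis
pipeline starts from mapped sRNA reads, and alignment is out of scope. Every
tag has a single placement (n_hits = 1), which keeps truth tables exact.

Each segment of a simulated gene carries an exact count of G+C bases equal to
``round(gc_target * segment_length)``, so realized GC matches its target to
rounding error at every granularity (gene body, CDS, individual exons).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CATEGORIES,
    AnnotatedGenome,
    Gene,
    SubFeature,
    TagAlignment,
)

SIZES = (20, 21, 22, 23, 24)


class ConfigurationError(ValueError):
    """A simulation parameter is out of range or internally inconsistent."""


def _check_probvec(name: str, vec: Sequence[float], length: int | None = None) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if length is not None and arr.size != length:
        raise ConfigurationError(f"{name} must have length {length}, got {arr.size}")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be a probability vector summing to 1")
    return arr


@dataclass
class GenotypeSpec:
    """Per-genotype sampling law for tag libraries.

    ``category_mixture`` follows the order of :data:`ctsirna.io_formats.CATEGORIES`;
    ``size_mixture`` the order 20..24 nt. ``hotspot_share`` is the fraction of
    antisense protein-coding tags drawn from ``hotspot_genes``. ``gc_effect``
    maps a gene's GC fraction to a relative production weight (monotone by
    convention; not enforced). ``stage_trend`` maps (gene_id, stage) to a
    multiplicative abundance factor.
    """

    name: str
    category_mixture: Sequence[float]
    size_mixture: Sequence[float]
    antisense_fraction: float
    hotspot_genes: tuple[str, ...] = ()
    hotspot_share: float = 0.0
    gc_effect: Callable[[float], float] | None = None
    stage_trend: Callable[[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.category_mixture = _check_probvec(
            f"{self.name}.category_mixture", self.category_mixture, len(CATEGORIES)
        )
        self.size_mixture = _check_probvec(
            f"{self.name}.size_mixture", self.size_mixture, len(SIZES)
        )
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ConfigurationError(f"{self.name}.antisense_fraction must be in [0,1]")
        if not 0.0 <= self.hotspot_share <= 1.0:
            raise ConfigurationError(f"{self.name}.hotspot_share must be in [0,1]")
        if self.hotspot_share > 0 and not self.hotspot_genes:
            raise ConfigurationError(
                f"{self.name}: hotspot_share > 0 requires non-empty hotspot_genes"
            )
        self.hotspot_genes = tuple(self.hotspot_genes)


@dataclass
class SimulationConfig:
    """Genome-level simulation parameters.

    ``genes_per_category`` maps each locus category to a gene count;
    ``gc_levels`` are the target GC fractions assigned to genes (cyclically,
    in gene order). Genes are separated by at least ``min_intergenic`` nt so
    1-kb flanks never overlap a neighbouring gene.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_category: Mapping[str, int] = field(
        default_factory=lambda: {
            "protein-coding": 60,
            "structural RNA": 8,
            "non-coding RNA": 8,
            "pseudogene&TE": 10,
            "pri-miRNA": 6,
        }
    )
    gene_length_range: tuple[int, int] = (1400, 3000)
    utr5_length_range: tuple[int, int] = (50, 300)
    utr3_length_range: tuple[int, int] = (100, 300)
    intron_count_range: tuple[int, int] = (0, 3)
    intron_length_range: tuple[int, int] = (80, 200)
    gc_levels: Sequence[float] = (0.30, 0.40, 0.55)
    min_intergenic: int = 2100
    intergenic_gc: float = 0.32
    genotypes: Sequence[GenotypeSpec] = ()
    stages: Sequence[str] = ("single",)
    library_size: int = 100_000
    replicates: int = 3

    def __post_init__(self) -> None:
        for name, count in self.genes_per_category.items():
            if name not in CATEGORIES:
                raise ConfigurationError(f"unknown category {name!r} in genes_per_category")
            if count < 0:
                raise ConfigurationError("genes_per_category counts must be >= 0")
        for gc in self.gc_levels:
            if not 0.0 < gc < 1.0:
                raise ConfigurationError("gc_levels must lie strictly in (0,1)")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be > 0")
        if self.min_intergenic < 2000:
            raise ConfigurationError("min_intergenic must be >= 2000 (1-kb flank isolation)")
        overhead = (
            self.utr5_length_range[1]
            + self.utr3_length_range[1]
            + self.intron_count_range[1] * self.intron_length_range[1]
        )
        if self.gene_length_range[0] < overhead + 60:
            raise ConfigurationError(
                "gene_length_range too short for utr5_length_range + utr3_length_range "
                f"+ intron ranges (need at least {overhead + 60} nt)"
            )


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

_BASES_GC = np.array(list("GC"))
_BASES_AT = np.array(list("AT"))


def _segment(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence of given length with exactly round(gc*length) G+C."""
    n_gc = int(round(gc * length))
    bases = np.concatenate(
        [
            _BASES_GC[rng.integers(0, 2, n_gc)],
            _BASES_AT[rng.integers(0, 2, length - n_gc)],
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def _gene_structure(
    rng: np.random.Generator, config: SimulationConfig, length: int
) -> list[tuple[str, int]]:
    """Transcript-order segments (kind, length) for a protein-coding gene."""
    u5 = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
    u3 = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
    n_introns = int(
        rng.integers(config.intron_count_range[0], config.intron_count_range[1] + 1)
    )
    intron_lens = [
        int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
        for _ in range(n_introns)
    ]
    cds_total = length - u5 - u3 - sum(intron_lens)
    if cds_total < 30:
        raise ConfigurationError(
            "gene_length_range incompatible with sampled UTR/intron lengths"
        )
    # split CDS into n_introns+1 near-equal exonic chunks
    n_chunks = n_introns + 1
    chunk_lens = [cds_total // n_chunks] * n_chunks
    chunk_lens[-1] += cds_total - sum(chunk_lens)
    segments: list[tuple[str, int]] = [("five_prime_UTR", u5)]
    for i, c in enumerate(chunk_lens):
        segments.append(("CDS", c))
        if i < n_introns:
            segments.append(("intron", intron_lens[i]))
    segments.append(("three_prime_UTR", u3))
    return segments


def simulate_genome(config: SimulationConfig) -> tuple[AnnotatedGenome, pd.DataFrame]:
    """Build an annotated genome plus a per-gene truth table.

    Returns the genome and a DataFrame with one row per gene: ``gene``,
    ``category``, ``chrom``, ``strand``, ``gc_target``, ``length``. Identical
    config (including seed) yields byte-identical FASTA/GFF3 on write.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    gene_specs: list[tuple[str, str, float]] = []  # (gene_id, category, gc)
    idx = 0
    for category in CATEGORIES:
        for i in range(config.genes_per_category.get(category, 0)):
            gc = float(config.gc_levels[idx % len(config.gc_levels)])
            prefix = {
                "protein-coding": "PC",
                "structural RNA": "SR",
                "non-coding RNA": "NC",
                "pseudogene&TE": "TE",
                "pri-miRNA": "MI",
            }[category]
            gene_specs.append((f"{prefix}G{i + 1:03d}", category, gc))
            idx += 1

    chrom_parts: dict[str, list[str]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_parts}
    genes: list[Gene] = []
    truth_rows = []

    for j, (gene_id, category, gc) in enumerate(gene_specs):
        chrom = f"chr{(j % config.n_chromosomes) + 1}"
        gap = int(rng.integers(config.min_intergenic, config.min_intergenic + 500))
        chrom_parts[chrom].append(_segment(rng, gap, config.intergenic_gc))
        chrom_pos[chrom] += gap
        start = chrom_pos[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(
            rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1)
        )
        children: list[SubFeature] = []
        if category == "protein-coding":
            segments = _gene_structure(rng, config, length)
            # genomic order: transcript order on '+', reversed on '-'
            genomic = segments if strand == "+" else segments[::-1]
            pos = start
            seq_parts = []
            for kind, seg_len in genomic:
                seq_parts.append(_segment(rng, seg_len, gc))
                children.append(SubFeature(kind, pos, pos + seg_len))
                pos += seg_len
            # exons = maximal non-intron runs
            exon_start = None
            for kind, seg_start, seg_end in [
                (c.kind, c.start, c.end) for c in sorted(children, key=lambda c: c.start)
            ]:
                if kind == "intron":
                    if exon_start is not None:
                        children.append(SubFeature("exon", exon_start, seg_start))
                        exon_start = None
                elif exon_start is None:
                    exon_start = seg_start
            if exon_start is not None:
                children.append(SubFeature("exon", exon_start, start + length))
            children = [c for c in children if c.kind != "intron"] + [
                c for c in children if c.kind == "intron"
            ]
            chrom_parts[chrom].append("".join(seq_parts))
        else:
            chrom_parts[chrom].append(_segment(rng, length, gc))
        end = start + length
        chrom_pos[chrom] = end
        genes.append(Gene(gene_id, chrom, start, end, strand, category, children))
        truth_rows.append(
            {
                "gene": gene_id,
                "category": category,
                "chrom": chrom,
                "strand": strand,
                "gc_target": gc,
                "length": length,
            }
        )

    for chrom in chrom_parts:
        tail = int(rng.integers(config.min_intergenic, config.min_intergenic + 500))
        chrom_parts[chrom].append(_segment(rng, tail, config.intergenic_gc))

    sequences = {c: "".join(parts) for c, parts in chrom_parts.items()}
    genome = AnnotatedGenome(sequences, genes)
    return genome, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def sample_seed(base_seed: int, name: str) -> int:
    """Stable per-sample seed below 2^31; adding samples never shifts others."""
    return (int(base_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31)


def _gene_weights(
    genome: AnnotatedGenome,
    gene_ids: Sequence[str],
    spec: GenotypeSpec,
    stage: str,
    gc_of: Mapping[str, float],
) -> np.ndarray:
    w = np.ones(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if spec.gc_effect is not None:
            w[i] *= spec.gc_effect(gc_of[gid])
        if spec.stage_trend is not None:
            w[i] *= spec.stage_trend(gid, stage)
    if w.sum() <= 0:
        raise ConfigurationError("gene production weights sum to zero")
    return w / w.sum()


def simulate_tags(
    genome: AnnotatedGenome,
    spec: GenotypeSpec,
    stage: str,
    library_size: int,
    seed: int,
) -> tuple[list[TagAlignment], pd.DataFrame]:
    """Draw one library of aligned, collapsed tags plus its truth table.

    Reads are drawn hierarchically -- category, then gene, strand and length,
    then a uniform placement inside the gene span -- and identical placements
    are collapsed into tags whose copy counts sum exactly to ``library_size``.

    The truth table has columns ``gene size strand expected_fraction`` giving
    the expected fraction of the library at each (gene, size, orientation)
    cell, plus per-category expectations under gene ``*`` (size 0).
    """
    rng = np.random.default_rng(int(seed))
    by_category: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for gid, gene in genome.genes.items():
        if gene.category in by_category:
            by_category[gene.category].append(gid)
    for gid in spec.hotspot_genes:
        if gid not in genome.genes:
            raise ConfigurationError(f"hotspot gene {gid} absent from annotation")

    gc_of = {}
    if spec.gc_effect is not None:
        from .gene_features import gc_content

        gc_of = {
            gid: gc_content(genome.spliced_sequence(gid)) for gid in genome.genes
        }
    else:
        gc_of = {gid: 0.0 for gid in genome.genes}

    cat_probs = np.asarray(spec.category_mixture, dtype=float)
    for ci, category in enumerate(CATEGORIES):
        if cat_probs[ci] > 0 and not by_category[category]:
            raise ConfigurationError(
                f"{spec.name}: category_mixture places mass on empty category {category!r}"
            )

    # per-read draws, fully vectorized
    cat_idx = rng.choice(len(CATEGORIES), size=library_size, p=cat_probs)
    sizes = np.asarray(SIZES)[rng.choice(len(SIZES), size=library_size, p=np.asarray(spec.size_mixture))]

    gene_arr = np.empty(library_size, dtype=object)
    antisense = np.zeros(library_size, dtype=bool)

    pc_ids = by_category["protein-coding"]
    hot = [g for g in spec.hotspot_genes]
    non_hot = [g for g in pc_ids if g not in set(hot)]

    # expected per-gene antisense split of the protein-coding antisense pool
    pc_mask = cat_idx == CATEGORIES.index("protein-coding")
    n_pc = int(pc_mask.sum())
    exp_gene_as: dict[str, float] = {}
    if pc_ids:
        antisense[pc_mask] = rng.random(n_pc) < spec.antisense_fraction
        as_mask = pc_mask & antisense
        n_as = int(as_mask.sum())
        if hot:
            w_hot = _gene_weights(genome, hot, spec, stage, gc_of)
            from_hot = rng.random(n_as) < spec.hotspot_share
        else:
            w_hot = np.array([])
            from_hot = np.zeros(n_as, dtype=bool)
        if non_hot:
            w_non = _gene_weights(genome, non_hot, spec, stage, gc_of)
        else:
            w_non = np.array([])
            from_hot[:] = True
        as_pos = np.flatnonzero(as_mask)
        if hot:
            picks = rng.choice(len(hot), size=int(from_hot.sum()), p=w_hot)
            gene_arr[as_pos[from_hot]] = np.asarray(hot, dtype=object)[picks]
        if non_hot:
            picks = rng.choice(len(non_hot), size=int((~from_hot).sum()), p=w_non)
            gene_arr[as_pos[~from_hot]] = np.asarray(non_hot, dtype=object)[picks]
        # sense protein-coding reads: drawn from all PC genes by weight
        sense_pos = np.flatnonzero(pc_mask & ~antisense)
        w_all = _gene_weights(genome, pc_ids, spec, stage, gc_of)
        picks = rng.choice(len(pc_ids), size=sense_pos.size, p=w_all)
        gene_arr[sense_pos] = np.asarray(pc_ids, dtype=object)[picks]

        s = spec.hotspot_share if hot else 0.0
        for i, gid in enumerate(hot):
            exp_gene_as[gid] = s * w_hot[i]
        for i, gid in enumerate(non_hot):
            exp_gene_as[gid] = exp_gene_as.get(gid, 0.0) + (1 - s) * w_non[i]

    for category in CATEGORIES:
        if category == "protein-coding":
            continue
        mask = cat_idx == CATEGORIES.index(category)
        pos = np.flatnonzero(mask)
        if pos.size == 0:
            continue
        ids = by_category[category]
        picks = rng.integers(0, len(ids), size=pos.size)
        gene_arr[pos] = np.asarray(ids, dtype=object)[picks]
        # non-coding loci shed fragments from both strands equally
        antisense[pos] = rng.random(pos.size) < 0.5

    # placements: uniform inside the source gene span
    starts = np.empty(library_size, dtype=np.int64)
    chroms = np.empty(library_size, dtype=object)
    strands = np.empty(library_size, dtype=object)
    for gid in set(gene_arr.tolist()):
        gene = genome.genes[gid]
        pos = np.flatnonzero(gene_arr == gid)
        max_start = gene.end - sizes[pos]
        starts[pos] = gene.start + (rng.random(pos.size) * (max_start - gene.start + 1)).astype(np.int64)
        chroms[pos] = gene.chrom
        gene_strand = gene.strand
        anti_strand = "-" if gene_strand == "+" else "+"
        strands[pos] = np.where(antisense[pos], anti_strand, gene_strand)

    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + sizes,
            "strand": strands,
        }
    )
    collapsed = (
        frame.groupby(["chrom", "start", "end", "strand"], sort=True)
        .size()
        .reset_index(name="count")
    )
    tags = [
        TagAlignment(r.chrom, int(r.start), int(r.end), r.strand, int(r.count), 1)
        for r in collapsed.itertuples()
    ]

    # truth table
    p_pc = float(cat_probs[CATEGORIES.index("protein-coding")])
    size_p = dict(zip(SIZES, np.asarray(spec.size_mixture, dtype=float)))
    rows = []
    for ci, category in enumerate(CATEGORIES):
        rows.append(
            {
                "gene": "*",
                "category": category,
                "size": 0,
                "strand": "any",
                "expected_fraction": float(cat_probs[ci]),
            }
        )
    for gid, p_gene in exp_gene_as.items():
        for size in SIZES:
            rows.append(
                {
                    "gene": gid,
                    "category": "protein-coding",
                    "size": size,
                    "strand": "antisense",
                    "expected_fraction": p_pc * spec.antisense_fraction * p_gene * size_p[size],
                }
            )
    truth = pd.DataFrame(rows)
    return tags, truth
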