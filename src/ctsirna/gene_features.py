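"""Source-gene features: lengths, UTRs, GC content, metagene profiles.

GC content is the fraction (G+C) / (A+C+G+T); IUPAC ambiguity codes are
excluded from both numerator and denominator. Genome-wide GC context comes
from splitting all coding sequences into 100-bp bins. Regions are classed as
low (GC <= 30%), medium (30% < GC < 50%) or high (GC >= 50%).

Metagene profiles average antisense ct-siRNA coverage over a fixed grid of
50 upstream-flank bins + 100 gene-body bins (each body linearly rescaled)
+ 50 downstream-flank bins, oriented 5' to 3' on the gene strand; flank
coverage counts both strands (flanks have no mRNA orientation), the body
antisense only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotatedGenome, TagAlignment
from . import classify

_GC = frozenset("GCgc")
_AT = frozenset("ATat")

#: metagene grid: flank bins / body bins / flank bins
N_FLANK_BINS = 50
N_BODY_BINS = 100


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); ambiguity codes ignored."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(1 for b in sequence if b in _GC)
    at = sum(1 for b in sequence if b in _AT)
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def gc_class(gc: float, low: float = 0.30, high: float = 0.50) -> str:
    """Classify a GC fraction: low iff gc <= 0.30, high iff gc >= 0.50."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction out of range: {gc}")
    if gc <= low:
        return "low"
    if gc >= high:
        return "high"
    return "medium"


def genome_gc_bins(
    cds_sequences: Mapping[str, str], bin_size: int = 100
) -> pd.DataFrame:
    """Split every CDS into fixed-size bins and compute per-bin GC.

    Returns a DataFrame ``gene bin_index start gc length partial`` where a
    trailing bin shorter than ``bin_size`` is retained and flagged partial.
    """
    rows = []
    for gene, seq in cds_sequences.items():
        for i, off in enumerate(range(0, len(seq), bin_size)):
            chunk = seq[off : off + bin_size]
            rows.append(
                {
                    "gene": gene,
                    "bin_index": i,
                    "start": off,
                    "gc": gc_content(chunk),
                    "length": len(chunk),
                    "partial": len(chunk) < bin_size,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FlankClip:
    """Record of a flank window clipped at a contig edge."""

    gene: str
    side: str
    requested: int
    obtained: int


def gene_metrics(
    genome: AnnotatedGenome,
    flank: int = 1000,
    body_gc_on: str = "exon",
) -> tuple[pd.DataFrame, list[FlankClip]]:
    """Per-gene feature table for protein-coding genes.

    Columns: ``length utr5_length utr3_length intron_count gc_body
    gc_upstream gc_downstream gc_class``. ``body_gc_on`` selects the mature
    (exonic) sequence or the full genomic ``span`` for the body GC. Upstream/
    downstream are relative to the gene's 5' end on its own strand; windows
    clipped at contig edges are recorded and returned.
    """
    rows = []
    clips: list[FlankClip] = []
    for gid in sorted(genome.genes):
        gene = genome.genes[gid]
        if gene.category != "protein-coding":
            continue
        utr5 = sum(c.length for c in gene.sub("five_prime_UTR"))
        utr3 = sum(c.length for c in gene.sub("three_prime_UTR"))
        exons = gene.sub("exon")
        intron_count: float
        if exons:
            intron_count = len(exons) - 1
        else:
            import warnings

            warnings.warn(f"gene {gid}: no exon children; intron count undefined")
            intron_count = np.nan
        if body_gc_on == "exon":
            body_seq = genome.spliced_sequence(gid)
        elif body_gc_on == "span":
            body_seq = genome.sequence(gene.chrom, gene.start, gene.end)
        else:
            raise ValueError("body_gc_on must be 'exon' or 'span'")
        chrom_len = len(genome.sequences[gene.chrom])
        if gene.strand == "+":
            up_iv = (max(gene.start - flank, 0), gene.start)
            down_iv = (gene.end, min(gene.end + flank, chrom_len))
        else:
            up_iv = (gene.end, min(gene.end + flank, chrom_len))
            down_iv = (max(gene.start - flank, 0), gene.start)
        for side, (lo, hi) in (("upstream", up_iv), ("downstream", down_iv)):
            if hi - lo < flank:
                clips.append(FlankClip(gid, side, flank, hi - lo))
        gc_up = gc_content(genome.sequence(gene.chrom, *up_iv)) if up_iv[1] > up_iv[0] else np.nan
        gc_down = (
            gc_content(genome.sequence(gene.chrom, *down_iv)) if down_iv[1] > down_iv[0] else np.nan
        )
        gc_body = gc_content(body_seq)
        rows.append(
            {
                "gene": gid,
                "length": gene.span,
                "utr5_length": utr5,
                "utr3_length": utr3,
                "intron_count": intron_count,
                "gc_body": gc_body,
                "gc_upstream": gc_up,
                "gc_downstream": gc_down,
                "gc_class": gc_class(gc_body),
            }
        )
    return pd.DataFrame(rows).set_index("gene"), clips


def compare_features(
    table: pd.DataFrame,
    producers: Iterable[str],
    feature: str,
) -> dict:
    """Welch two-tailed t-test of one feature, producers vs the rest.

    Returns a dict with the t statistic, p-value and per-group (n, mean, sd).
    Producer genes absent from the table are ignored; both groups must have
    at least two members.
    """
    producers = set(producers)
    in_prod = table.index.isin(producers)
    a = table.loc[in_prod, feature].dropna().to_numpy(dtype=float)
    b = table.loc[~in_prod, feature].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 genes with defined feature values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "feature": feature,
        "t": float(t),
        "p": float(p),
        "producers": {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "others": {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
    }


def _rescale_to_bins(cov: np.ndarray, n_bins: int) -> np.ndarray:
    """Average per-base coverage onto a fixed number of bins (linear grid)."""
    L = cov.size
    if L == 0:
        return np.zeros(n_bins)
    edges = np.linspace(0, L, n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
        out[i] = cov[lo:hi].mean() if hi > lo else 0.0
    return out


def metagene_profile(
    tags: Sequence[TagAlignment],
    genome: AnnotatedGenome,
    gene_ids: Sequence[str],
    size: int = 22,
    flank: int = 1000,
    library_total: float | None = None,
) -> np.ndarray:
    """Mean per-bin abundance over flank/body/flank grid for a gene set.

    Body coverage is antisense-assigned tag coverage (the ct-siRNA signal)
    rescaled to ``N_BODY_BINS``; each 1-kb flank is binned at fixed width and
    counts coverage from both strands. Profiles are oriented 5'->3' on the
    gene strand and averaged over genes; if ``library_total`` is given the
    result is per-million normalized. Returns an array of 200 bin means, or
    NaNs for an empty gene set (with a warning).
    """
    n_total = 2 * N_FLANK_BINS + N_BODY_BINS
    if not gene_ids:
        import warnings

        warnings.warn("empty gene set for metagene profile")
        return np.full(n_total, np.nan)
    acc = np.zeros(n_total)
    for gid in gene_ids:
        gene = genome.genes[gid]
        body_cov = classify.per_gene_coverage(tags, genome, gid, size=size, orientation="antisense")
        chrom_len = len(genome.sequences[gene.chrom])
        left_iv = (max(gene.start - flank, 0), gene.start)
        right_iv = (gene.end, min(gene.end + flank, chrom_len))
        left = np.zeros(flank)
        right = np.zeros(flank)
        # clipped left windows align to their gene-adjacent (right) edge;
        # right windows to their (left) gene-adjacent edge
        left_off = flank - (left_iv[1] - left_iv[0])
        for tag in tags:
            if tag.length != size or tag.chrom != gene.chrom:
                continue
            lo, hi = max(tag.start, left_iv[0]), min(tag.end, left_iv[1])
            if hi > lo:
                left[lo - left_iv[0] + left_off : hi - left_iv[0] + left_off] += tag.weight
            lo, hi = max(tag.start, right_iv[0]), min(tag.end, right_iv[1])
            if hi > lo:
                right[lo - right_iv[0] : hi - right_iv[0]] += tag.weight
        if gene.strand == "+":
            up, body, down = left, body_cov, right
        else:
            up, body, down = right[::-1], body_cov[::-1], left[::-1]
        prof = np.concatenate(
            [
                _rescale_to_bins(up, N_FLANK_BINS),
                _rescale_to_bins(body, N_BODY_BINS),
                _rescale_to_bins(down, N_FLANK_BINS),
            ]
        )
        acc += prof
    mean_profile = acc / len(gene_ids)
    if library_total is not None and library_total > 0:
        mean_profile = mean_profile / library_total * 1e6
    return mean_profile
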