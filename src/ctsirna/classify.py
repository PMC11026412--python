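"""Locus-category assignment and ct-siRNA counting.

A ct-siRNA is operationally a 20-24 nt tag mapping antisense to a
protein-coding gene. This module assigns each aligned tag to a locus
category, tallies per-sample category percentages, and builds the
gene x size x orientation count matrix that every downstream stage
(differential accumulation, hotspot ranking, metagene profiles) consumes.

Assignment rules (documented because the figures depend on them):

* a tag belongs to a feature when at least half of the tag's length overlaps
  the feature's full genomic span (exons and introns alike) -- gene bodies
  show signal wall to wall, and a containment-only rule would drop boundary
  tags;
* when features of different categories overlap, the category priority is
  structural RNA > pri-miRNA > protein-coding > pseudogene&TE >
  non-coding RNA, so that rRNA/tRNA fragments, which dominate sRNA
  libraries, never leak into ct-siRNA counts;
* within a category, ties go to the larger overlap, then the
  lexicographically smaller gene id (stable and permutation-invariant);
* a multi-hit tag contributes count / n_hits at each reported placement.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CATEGORIES, AnnotatedGenome, Gene, TagAlignment

#: Resolution order when overlapping features compete for a tag.
CATEGORY_PRIORITY = (
    "structural RNA",
    "pri-miRNA",
    "protein-coding",
    "pseudogene&TE",
    "non-coding RNA",
)

UNASSIGNED = "unassigned"

#: Tag lengths tabulated as potential siRNAs.
DEFAULT_SIZE_RANGE = (20, 24)

MIN_OVERLAP_FRACTION = 0.5


def assign_tag(
    tag: TagAlignment, annotation: AnnotatedGenome
) -> tuple[str, str | None, str | None]:
    """Assign one tag to (category, gene_id, orientation).

    Orientation is ``antisense`` iff the tag strand differs from the gene
    strand. Returns ``(UNASSIGNED, None, None)`` when no feature overlaps at
    least half of the tag.
    """
    candidates = annotation.overlapping(tag.chrom, tag.start, tag.end)
    min_overlap = MIN_OVERLAP_FRACTION * tag.length
    best: tuple[int, float, str] | None = None  # (priority, -overlap, gene_id)
    best_gene: Gene | None = None
    for gene in candidates:
        overlap = min(tag.end, gene.end) - max(tag.start, gene.start)
        if overlap < min_overlap:
            continue
        try:
            prio = CATEGORY_PRIORITY.index(gene.category)
        except ValueError:
            continue  # unknown category: not a siRNA-generating locus
        key = (prio, -overlap, gene.gene_id)
        if best is None or key < best:
            best, best_gene = key, gene
    if best_gene is None:
        return UNASSIGNED, None, None
    orientation = "antisense" if tag.strand != best_gene.strand else "sense"
    return best_gene.category, best_gene.gene_id, orientation


def tally_categories(
    tags: Iterable[TagAlignment],
    annotation: AnnotatedGenome,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> pd.DataFrame:
    """Weighted category tally over tags in the size window.

    Returns a DataFrame indexed by category with columns ``weight`` and
    ``percent``; percentages are computed over assigned categories only, and
    the unassigned weight is reported in its own row with percent NaN.
    """
    lo, hi = size_range
    if not (18 <= lo <= hi <= 30):
        raise ValueError("size_range must lie within [18, 30]")
    weights = {c: 0.0 for c in CATEGORIES}
    unassigned = 0.0
    n_in_range = 0
    for tag in tags:
        if not lo <= tag.length <= hi:
            continue
        n_in_range += 1
        category, _gid, _ori = assign_tag(tag, annotation)
        if category == UNASSIGNED:
            unassigned += tag.weight
        else:
            weights[category] += tag.weight
    if n_in_range == 0:
        raise ValueError("no tags in size range")
    assigned_total = sum(weights.values())
    rows = []
    for category in CATEGORIES:
        pct = 100.0 * weights[category] / assigned_total if assigned_total else np.nan
        rows.append({"category": category, "weight": weights[category], "percent": pct})
    rows.append({"category": UNASSIGNED, "weight": unassigned, "percent": np.nan})
    return pd.DataFrame(rows).set_index("category")


def ct_sirna_counts(
    tags: Iterable[TagAlignment],
    annotation: AnnotatedGenome,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> pd.DataFrame:
    """Per-gene size x orientation count matrix for one library.

    Long-format DataFrame with columns ``gene size orientation count``
    covering every protein-coding gene and every (size, orientation) cell in
    the window (zeros included). The ``antisense`` slice is the ct-siRNA
    signal used by all downstream modules.
    """
    lo, hi = size_range
    pc_genes = sorted(
        g.gene_id for g in annotation.genes.values() if g.category == "protein-coding"
    )
    if not pc_genes:
        raise ValueError("annotation has no protein-coding genes")
    sizes = list(range(lo, hi + 1))
    acc: dict[tuple[str, int, str], float] = {}
    for tag in tags:
        if not lo <= tag.length <= hi:
            continue
        category, gid, orientation = assign_tag(tag, annotation)
        if category != "protein-coding":
            continue
        key = (gid, tag.length, orientation)
        acc[key] = acc.get(key, 0.0) + tag.weight
    index = pd.MultiIndex.from_product(
        [pc_genes, sizes, ["sense", "antisense"]], names=["gene", "size", "orientation"]
    )
    counts = pd.Series(
        [acc.get(key, 0.0) for key in index], index=index, name="count"
    )
    return counts.reset_index()


def size_percentages(matrix: pd.DataFrame, orientation: str = "antisense") -> pd.Series:
    """Percentage of ct-siRNAs per size class (20-24 nt).

    ``matrix`` is the long-format output of :func:`ct_sirna_counts`. Returns a
    Series indexed by size summing to 100; an all-zero antisense slice yields
    an empty Series rather than a division error.
    """
    sub = matrix[matrix["orientation"] == orientation]
    totals = sub.groupby("size")["count"].sum()
    grand = totals.sum()
    if grand <= 0:
        return pd.Series(dtype=float, name="percent")
    return (100.0 * totals / grand).rename("percent")


def per_gene_coverage(
    tags: Iterable[TagAlignment],
    annotation: AnnotatedGenome,
    gene_id: str,
    size: int | None = None,
    orientation: str | None = "antisense",
) -> np.ndarray:
    """Per-nucleotide weighted coverage over the gene's genomic span.

    Only tags assigned to ``gene_id`` (by the standard 50%-overlap rule) with
    the requested length and orientation contribute; each adds its weight at
    every covered position clipped to the gene span. Coordinates are genomic
    (left to right), regardless of gene strand.
    """
    gene = annotation.genes[gene_id]
    cov = np.zeros(gene.span, dtype=float)
    for tag in tags:
        if size is not None and tag.length != size:
            continue
        if tag.chrom != gene.chrom or tag.start >= gene.end or tag.end <= gene.start:
            continue
        category, gid, ori = assign_tag(tag, annotation)
        if gid != gene_id:
            continue
        if orientation is not None and ori != orientation:
            continue
        lo = max(tag.start, gene.start) - gene.start
        hi = min(tag.end, gene.end) - gene.start
        cov[lo:hi] += tag.weight
    return cov


def assemble_count_matrix(
    per_sample: dict[str, pd.DataFrame],
    size: int,
    orientation: str = "antisense",
) -> pd.DataFrame:
    """Stack per-sample long matrices into a genes x samples table for one size."""
    cols = {}
    for sample, matrix in per_sample.items():
        sub = matrix[(matrix["size"] == size) & (matrix["orientation"] == orientation)]
        cols[sample] = sub.set_index("gene")["count"]
    return pd.DataFrame(cols).fillna(0.0).sort_index()
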