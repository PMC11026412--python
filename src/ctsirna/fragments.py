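"""Truncated-CDS transgene fragment analysis.

A CDS is cut into consecutive fixed-length fragments (default 600 nt) named
``GENE-1 .. GENE-k`` from the 5' end; a trailing remainder shorter than the
fragment size is kept as a flagged partial fragment but excluded from GC
ranking by default. Per-fragment GC feeds a silencing-risk flag (fragments
at or above 55% GC frequently trigger silencing when used as transgenes).

Sequence homology between fragments is measured two ways: shared exact
k-mers on both strands, and best local alignment identity under an explicit
scoring scheme (match +1, mismatch -2, gap -2.5). Spreading of siRNA signal
relative to a fragment's cognate CDS interval is partitioned into inside /
5'-ward / 3'-ward fractions, and trans spread to a homologous gene as the
homolog's share of the combined antisense signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import revcomp
from .gene_features import gc_content

GC_RISK_THRESHOLD = 0.55


@dataclass(frozen=True)
class Fragment:
    name: str
    start: int  # 0-based offset into the CDS
    end: int
    sequence: str
    partial: bool

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class FragmentSet:
    gene: str
    size: int
    fragments: list[Fragment]

    def full(self) -> list[Fragment]:
        return [f for f in self.fragments if not f.partial]


def fragment_cds(gene: str, cds: str, size: int = 600) -> FragmentSet:
    """Cut a CDS into consecutive ``size``-nt fragments from the 5' end.

    ``floor(L/size)`` full fragments plus, when L is not a multiple of
    ``size``, one flagged partial remainder. A CDS shorter than ``size``
    yields a single partial fragment with a warning. Concatenating all
    fragments in order reproduces the input exactly.
    """
    if not cds:
        raise ValueError("empty CDS")
    if len(cds) < size:
        import warnings

        warnings.warn(f"{gene}: CDS shorter than fragment size {size}; single partial fragment")
    fragments = []
    i = 0
    for start in range(0, len(cds), size):
        chunk = cds[start : start + size]
        i += 1
        fragments.append(
            Fragment(f"{gene}-{i}", start, start + len(chunk), chunk, len(chunk) < size)
        )
    return FragmentSet(gene, size, fragments)


def fragment_gc(
    fset: FragmentSet,
    full_length_seq: str | None = None,
    include_partial: bool = False,
    gc_flag: float = GC_RISK_THRESHOLD,
) -> pd.DataFrame:
    """GC per fragment with descending rank and a high-GC silencing flag.

    The full-length sequence, when given, is included as ``GENE-full``.
    Partial fragments are excluded from ranking unless requested.
    """
    rows = []
    for frag in fset.fragments:
        if frag.partial and not include_partial:
            continue
        rows.append({"name": frag.name, "length": len(frag.sequence), "gc": frag.gc})
    if full_length_seq:
        rows.append(
            {"name": f"{fset.gene}-full", "length": len(full_length_seq), "gc": gc_content(full_length_seq)}
        )
    if not rows:
        raise ValueError("no fragments to rank")
    table = pd.DataFrame(rows).sort_values(["gc", "name"], ascending=[False, True])
    table["rank"] = np.arange(1, len(table) + 1)
    table["high_gc_risk"] = table["gc"] >= gc_flag
    return table.reset_index(drop=True)


def shared_kmers(seq_a: str, seq_b: str, k: int = 20) -> int:
    """Number of positions in ``seq_a`` whose k-mer occurs in ``seq_b`` on
    either strand."""
    if len(seq_a) < k or len(seq_b) < k:
        return 0
    b_kmers = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    rc = revcomp(seq_b)
    b_kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return sum(1 for i in range(len(seq_a) - k + 1) if seq_a[i : i + k] in b_kmers)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.5
    return aligner


def pairwise_similarity(seq_a: str, seq_b: str, k: int = 20) -> dict:
    """Similarity record between two fragments.

    Returns shared k-mer count (both strands), best local-alignment identity
    percentage and aligned length (forward strand), and a ``homologous``
    verdict (shared k-mers > 0 or identity >= 80% over >= 100 aligned
    columns).
    """
    if not seq_a or not seq_b:
        raise ValueError("fragments must be non-empty")
    kmer_count = shared_kmers(seq_a, seq_b, k=k)
    aligner = _aligner()
    best = None
    if aligner.score(seq_a, seq_b) > 0:
        best = next(iter(aligner.align(seq_a, seq_b)))
    identity = 0.0
    aligned_length = 0
    if best is not None:
        a_idx, b_idx = best.aligned
        matches = 0
        cols = 0
        for (a0, a1), (b0, b1) in zip(a_idx, b_idx):
            cols += a1 - a0
            matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
        # count gap columns between aligned blocks
        for j in range(1, len(a_idx)):
            cols += max(a_idx[j][0] - a_idx[j - 1][1], b_idx[j][0] - b_idx[j - 1][1])
        aligned_length = cols
        identity = 100.0 * matches / cols if cols else 0.0
    return {
        "shared_kmers": kmer_count,
        "identity_pct": identity,
        "aligned_length": aligned_length,
        "homologous": kmer_count > 0 or (identity >= 80.0 and aligned_length >= 100),
    }


def spread_metrics(
    coverage: np.ndarray,
    fragment_interval: tuple[int, int],
    homolog_tpm: float | None = None,
    source_tpm: float | None = None,
) -> dict:
    """Partition antisense signal around a fragment's cognate interval.

    ``coverage`` is per-base antisense coverage over the source CDS (5'->3');
    ``fragment_interval`` the fragment's 0-based offsets in the same
    coordinates. Returns inside / 5'-ward / 3'-ward fractions (summing to 1
    when total > 0; NaN when the gene has no signal) and, when homolog and
    source TPM are supplied, the trans fraction
    ``homolog / (source + homolog)``. Fractions are invariant to uniform
    coverage scaling.
    """
    cov = np.asarray(coverage, dtype=float)
    lo, hi = fragment_interval
    if not (0 <= lo < hi <= cov.size):
        raise ValueError(f"fragment interval [{lo},{hi}) outside CDS of length {cov.size}")
    total = float(cov.sum())
    if total > 0:
        inside = float(cov[lo:hi].sum()) / total
        five = float(cov[:lo].sum()) / total
        three = float(cov[hi:].sum()) / total
    else:
        inside = five = three = float("nan")
    out = {"inside": inside, "spread_5p": five, "spread_3p": three}
    if homolog_tpm is not None and source_tpm is not None:
        denom = homolog_tpm + source_tpm
        out["trans_fraction"] = homolog_tpm / denom if denom > 0 else float("nan")
    return out
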