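"""Shared readers, writers and the annotated-genome data model.

All internal coordinates are 0-based half-open. Conversion to the 1-based
closed convention of GFF3 happens only at parse/serialize boundaries, so a
feature written as ``start+1 .. end`` on disk round-trips exactly.

Strand is mandatory on tags: orientation relative to the source gene is the
operational definition of a ct-siRNA, so unstranded records are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

CATEGORIES = (
    "protein-coding",
    "structural RNA",
    "non-coding RNA",
    "pseudogene&TE",
    "pri-miRNA",
)

GENE_BEARING = frozenset(CATEGORIES)


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class SubFeature:
    """Exon/CDS/UTR child of a gene (0-based half-open)."""

    kind: str  # exon | CDS | five_prime_UTR | three_prime_UTR | intron
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.kind} has empty span [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    """A locus with a category label; protein-coding loci carry children."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    children: list[SubFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: empty span")
        for child in self.children:
            if child.start < self.start or child.end > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: child {child.kind} "
                    f"[{child.start},{child.end}) outside gene span [{self.start},{self.end})"
                )

    @property
    def span(self) -> int:
        return self.end - self.start

    def sub(self, kind: str) -> list[SubFeature]:
        out = [c for c in self.children if c.kind == kind]
        return sorted(out, key=lambda c: c.start)

    @property
    def exons(self) -> list[SubFeature]:
        return self.sub("exon")


@dataclass
class TagAlignment:
    """A collapsed sRNA tag: the atomic evidence unit of the pipeline.

    ``count`` is the number of identical reads collapsed into this tag and
    ``n_hits`` the number of genome-wide placements; downstream tallies weight
    each placement by ``count / n_hits``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"tag at {self.chrom}:{self.start} has end <= start")
        if self.strand not in "+-":
            raise ValidationError(
                f"tag at {self.chrom}:{self.start}-{self.end} is unstranded"
            )
        if self.count < 1 or self.n_hits < 1:
            raise ValidationError("tag count and n_hits must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def weight(self) -> float:
        return self.count / self.n_hits


class AnnotatedGenome:
    """Chromosome sequences plus a category-labelled gene set.

    The coordinate authority for tag assignment and GC computation. Interval
    queries go through a per-chromosome interval tree; `overlapping` returns
    exactly what a naive scan over all genes would.
    """

    def __init__(self, sequences: Mapping[str, str], genes: Sequence[Gene]):
        self.sequences = dict(sequences)
        self.genes: dict[str, Gene] = {}
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in self.sequences}
        for gene in genes:
            if gene.chrom not in self.sequences:
                raise ValidationError(
                    f"gene {gene.gene_id} on unknown chromosome {gene.chrom}"
                )
            if gene.end > len(self.sequences[gene.chrom]):
                raise ValidationError(
                    f"gene {gene.gene_id} exceeds chromosome {gene.chrom} length"
                )
            if gene.gene_id in self.genes:
                raise ValidationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            self._trees[gene.chrom].addi(gene.start, gene.end, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes overlapping [start, end) on chrom, sorted by (start, id)."""
        if chrom not in self._trees:
            raise ValidationError(f"unknown chromosome {chrom!r} in query")
        hits = [self.genes[iv.data] for iv in self._trees[chrom].overlap(start, end)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.sequences[chrom][max(start, 0) : end]
        return revcomp(seq) if strand == "-" else seq

    def spliced_sequence(self, gene_id: str, kind: str = "exon") -> str:
        """Mature (spliced) sequence of a gene, 5'->3' on the gene strand."""
        gene = self.genes[gene_id]
        parts = gene.sub(kind)
        if not parts:
            parts = [SubFeature("exon", gene.start, gene.end)]
        seq = "".join(self.sequences[gene.chrom][p.start : p.end] for p in parts)
        return revcomp(seq) if gene.strand == "-" else seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_KIND_TO_GFF = {
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "intron": "intron",
}


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    """Serialize genes (and one mRNA + children for protein-coding loci)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={gene.gene_id};category={gene.category}"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "ctsirna",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            if not gene.children:
                continue
            mrna_id = f"{gene.gene_id}.1"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "ctsirna",
                        "mRNA",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={mrna_id};Parent={gene.gene_id}",
                    ]
                )
                + "\n"
            )
            for child in sorted(gene.children, key=lambda c: (c.start, c.kind)):
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "ctsirna",
                            _KIND_TO_GFF[child.kind],
                            str(child.start + 1),
                            str(child.end),
                            ".",
                            gene.strand,
                            ".",
                            f"Parent={mrna_id}",
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(gff3_path: str | Path, fasta_path: str | Path) -> AnnotatedGenome:
    """Load and validate a genome: sequences + category-labelled genes.

    Genes missing a ``category`` attribute default to their GFF3 type column
    with a warning. A child feature outside its parent span is a validation
    error naming the offending IDs.
    """
    sequences = read_fasta(fasta_path)
    genes: dict[str, Gene] = {}
    raw_children: dict[str, list[tuple[str, int, int]]] = {}
    mrna_parent: dict[str, str] = {}

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{gff3_path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs9 = fields
            start, end = int(start1) - 1, int(end1)
            attrs = _parse_attrs(attrs9)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValidationError(f"{gff3_path}:{lineno}: gene without ID")
                category = attrs.get("category")
                if category is None:
                    warnings.warn(
                        f"gene {gid}: no category attribute, defaulting to type 'gene'"
                    )
                    category = "gene"
                genes[gid] = Gene(gid, chrom, start, end, strand, category)
            elif ftype == "mRNA":
                mrna_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR", "intron"):
                parent = attrs["Parent"]
                raw_children.setdefault(parent, []).append((ftype, start, end))

    for mrna_id, kids in raw_children.items():
        gid = mrna_parent.get(mrna_id, mrna_id)
        if gid not in genes:
            raise ValidationError(f"child features reference unknown parent {mrna_id}")
        gene = genes[gid]
        for kind, start, end in kids:
            if start < gene.start or end > gene.end:
                raise ValidationError(
                    f"feature {kind} [{start},{end}) of {mrna_id} lies outside "
                    f"gene {gid} span [{gene.start},{gene.end})"
                )
            gene.children.append(SubFeature(kind, start, end))

    for gene in genes.values():
        if gene.chrom not in sequences:
            raise ValidationError(
                f"gene {gene.gene_id}: chromosome {gene.chrom} absent from FASTA"
            )
    return AnnotatedGenome(sequences, list(genes.values()))


# ---------------------------------------------------------------------------
# Tags: TSV and SAM
# ---------------------------------------------------------------------------

TAG_TSV_HEADER = ["chrom", "start", "end", "strand", "length", "count", "n_hits"]


def write_tags_tsv(tags: Iterable[TagAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAG_TSV_HEADER) + "\n")
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t{t.length}\t{t.count}\t{t.n_hits}\n"
            )


def write_tags_sam(
    tags: Sequence[TagAlignment], genome: AnnotatedGenome, path: str | Path
) -> None:
    """Write tags as a SAM file, fabricating read sequences from the reference.

    Count is carried in the read name (``tagN_xCOUNT``, the collapsed-read
    convention) and the placement multiplicity in the NH tag.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in sorted(genome.sequences.items())
        ],
    }
    ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    ordered = sorted(tags, key=lambda t: (t.chrom, t.start, t.end, t.strand))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, tag in enumerate(ordered):
            aln = pysam.AlignedSegment()
            aln.query_name = f"tag{i}_x{tag.count}"
            aln.reference_id = ref_ids[tag.chrom]
            aln.reference_start = tag.start
            aln.mapping_quality = 255
            aln.cigarstring = f"{tag.length}M"
            aln.flag = 16 if tag.strand == "-" else 0
            seq = genome.sequence(tag.chrom, tag.start, tag.end)
            aln.query_sequence = seq if tag.strand == "+" else revcomp(seq)
            aln.set_tag("NH", tag.n_hits)
            out.write(aln)


def read_tags(
    path: str | Path, size_range: tuple[int, int] | None = None
) -> tuple[list[TagAlignment], int]:
    """Read tags from TSV or SAM/BAM; returns (tags, n_dropped_out_of_range).

    NH is honoured when present (SAM), else n_hits defaults to the TSV column
    or 1. Tags outside ``size_range`` (inclusive) are dropped and counted.
    """
    path = Path(path)
    if path.suffix in (".sam", ".bam"):
        tags = list(_iter_sam(path))
    else:
        tags = list(_iter_tsv(path))
    if size_range is None:
        return tags, 0
    lo, hi = size_range
    kept = [t for t in tags if lo <= t.length <= hi]
    dropped = len(tags) - len(kept)
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} tags outside length range {lo}-{hi}")
    return kept, dropped


def _iter_tsv(path: Path) -> Iterator[TagAlignment]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != TAG_TSV_HEADER[:4]:
            raise ValidationError(f"{path}: unexpected tag TSV header {header}")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: malformed record")
            try:
                yield TagAlignment(
                    chrom=fields[col["chrom"]],
                    start=int(fields[col["start"]]),
                    end=int(fields[col["end"]]),
                    strand=fields[col["strand"]],
                    count=int(fields[col["count"]]) if "count" in col else 1,
                    n_hits=int(fields[col["n_hits"]]) if "n_hits" in col else 1,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def _iter_sam(path: Path) -> Iterator[TagAlignment]:
    import pysam

    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec_no, aln in enumerate(fh.fetch(until_eof=True), 1):
            if aln.is_unmapped:
                continue
            count = 1
            name = aln.query_name or ""
            if "_x" in name:
                try:
                    count = int(name.rsplit("_x", 1)[1])
                except ValueError:
                    pass
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            try:
                yield TagAlignment(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    count=count,
                    n_hits=int(n_hits),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: record {rec_no}: {exc}") from exc


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance stamp: identical manifest implies identical outputs."""

    tool_version: str
    config: dict
    input_checksums: dict[str, str]
    seeds: list[int]
    timestamp: str = ""

    @classmethod
    def create(
        cls, config: dict, inputs: Sequence[str | Path], seeds: Sequence[int]
    ) -> "RunManifest":
        from ctsirna import __version__

        return cls(
            tool_version=__version__,
            config=config,
            input_checksums={str(p): _sha256(Path(p)) for p in inputs},
            seeds=list(seeds),
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
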