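"""Gene annotation intervals and SNP-to-gene coverage.

Intervals are stored 1-based inclusive internally. BED input (0-based,
half-open) is converted on read; GFF3 gene features (1-based, inclusive) are
used as-is. Coverage queries use per-chromosome interval trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote

from intervaltree import IntervalTree

from .genotype_data import SnpRecord

__all__ = [
    "GeneInterval",
    "GeneAnnotation",
    "read_bed",
    "read_gff3",
    "read_annotation",
    "genes_covered",
    "gene_difference_trace",
]


@dataclass(frozen=True)
class GeneInterval:
    """One gene span: id, chromosome, and 1-based inclusive start/end."""

    gene_id: str
    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )


class GeneAnnotation:
    """Set of gene intervals indexed by chromosome for containment queries."""

    def __init__(self, genes: Iterable[GeneInterval]):
        self.genes = list(genes)
        self._trees: dict[int, IntervalTree] = {}
        for g in self.genes:
            # IntervalTree is half-open; widen the inclusive end by one
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(
                g.start, g.end + 1, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def genes_at(self, chromosome: int, position: int) -> set[str]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(position)}


def _parse_chrom(token: str) -> int | None:
    token = token.removeprefix("chr")
    return int(token) if token.isdigit() else None


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read gene intervals from BED (>= 4 columns; name column = gene id).

    BED's 0-based half-open [start, end) becomes 1-based inclusive
    [start+1, end]. Non-numeric chromosomes (sex chromosomes, scaffolds) are
    skipped, matching the autosome-only analysis.
    """
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{ln}: BED gene line needs >= 4 columns (name required)")
        chrom = _parse_chrom(fields[0])
        if chrom is None:
            continue
        start0, end0 = int(fields[1]), int(fields[2])
        genes.append(GeneInterval(fields[3], chrom, start0 + 1, end0))
    return GeneAnnotation(genes)


def read_gff3(path: str | Path, feature: str = "gene") -> GeneAnnotation:
    """Read gene features from GFF3 (1-based inclusive, used as-is).

    Gene id comes from the ``ID`` or ``gene_id`` attribute, falling back to
    ``Name``. Non-numeric chromosomes are skipped.
    """
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{ln}: GFF3 line has {len(fields)} columns, expected 9")
        if fields[2] != feature:
            continue
        chrom = _parse_chrom(fields[0])
        if chrom is None:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"{path}:{ln}: {feature} feature lacks ID/gene_id/Name")
        genes.append(GeneInterval(unquote(gene_id), chrom, int(fields[3]), int(fields[4])))
    return GeneAnnotation(genes)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Dispatch on extension: .bed -> BED, .gff/.gff3 -> GFF3 gene features."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed(path)
    if suffix in {".gff", ".gff3"}:
        return read_gff3(path)
    raise ValueError(f"unrecognised annotation format: {path} (expected .bed/.gff/.gff3)")


def genes_covered(
    snp_ids: Sequence[str],
    snp_map: Sequence[SnpRecord],
    annotation: GeneAnnotation,
) -> set[str]:
    """Gene ids whose interval contains >= 1 of the given SNPs (inclusive bounds)."""
    by_id = {s.id: s for s in snp_map}
    covered: set[str] = set()
    for sid in snp_ids:
        s = by_id[sid]
        covered |= annotation.genes_at(s.chromosome, s.position)
    return covered


def gene_difference_trace(
    subsets: Sequence[Sequence[str]],
    snp_map: Sequence[SnpRecord],
    annotation: GeneAnnotation,
) -> list[int]:
    """Newly covered gene count per step over nested SNP subsets.

    ``count_i = |genes(S_i) \\ genes(S_{i-1})|`` with ``genes(S_0)`` empty;
    subsets must be nested.
    """
    counts = []
    prev: set[str] = set()
    prev_ids: set[str] = set()
    for subset in subsets:
        ids = set(subset)
        if not prev_ids <= ids:
            raise ValueError("subsets are not nested")
        cur = genes_covered(list(subset), snp_map, annotation)
        counts.append(len(cur - prev))
        prev |= cur
        prev_ids = ids
    return counts
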