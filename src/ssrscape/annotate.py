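"""Assignment of SSR loci to genomic regions and gene association.

Each locus is placed, by its midpoint, into exactly one of four categories:
promoter (TSS - 1 kb .. TSS + 100 bp, strand-aware), TTS (TES - 100 bp ..
TES + 1 kb, strand-aware), exon, or intron+intergenic — with priority in
exactly that order. Intron and intergenic are deliberately merged into one
category. On the minus strand "upstream" means larger coordinates, so the
windows mirror accordingly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .flanks import locus_identifier
from .mining import SSRLocus

__all__ = [
    "PROMOTER",
    "TTS",
    "EXON",
    "INTRON_INTERGENIC",
    "REGION_ORDER",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "TTS_UPSTREAM",
    "TTS_DOWNSTREAM",
    "GeneModel",
    "GeneModelError",
    "RegionAssignment",
    "assign_region",
    "assign_regions",
    "region_counts",
    "associate_genes",
]

PROMOTER = "promoter"
TTS = "tts"
EXON = "exon"
INTRON_INTERGENIC = "intron_intergenic"
REGION_ORDER = (PROMOTER, TTS, EXON, INTRON_INTERGENIC)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


class GeneModelError(ValueError):
    """Raised for malformed gene models; message names the gene."""


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with TSS/TES and exon intervals.

    ``start``/``end`` are the genomic span (start <= end, 1-based
    inclusive); the TSS is the 5' end on the gene's strand and the TES the
    3' end. Exons are genomic (start, end) pairs. A gene without annotated
    transcripts is modelled as a single exon covering its whole span.
    """

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.start > self.end:
            raise GeneModelError(f"gene {self.gene_id!r}: start > end")
        last_end = 0
        for s, e in sorted(self.exons):
            if s > e or s < self.start or e > self.end:
                raise GeneModelError(
                    f"gene {self.gene_id!r}: exon ({s}, {e}) outside gene span"
                )
            if s <= last_end:
                raise GeneModelError(f"gene {self.gene_id!r}: overlapping exons")
            last_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def promoter_window(self) -> tuple[int, int]:
        """Genomic interval of the promoter (lo, hi), 1-based inclusive."""
        if self.strand == "+":
            return (self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM)
        return (self.tss - PROMOTER_DOWNSTREAM, self.tss + PROMOTER_UPSTREAM)

    def tts_window(self) -> tuple[int, int]:
        """Genomic interval of the termination-site window (lo, hi)."""
        if self.strand == "+":
            return (self.tes - TTS_UPSTREAM, self.tes + TTS_DOWNSTREAM)
        return (self.tes - TTS_DOWNSTREAM, self.tes + TTS_UPSTREAM)


@dataclass(frozen=True)
class RegionAssignment:
    locus_id: str
    category: str
    gene_id: str | None = None


def _midpoint(locus: SSRLocus) -> int:
    return (locus.start + locus.end) // 2


def assign_region(
    locus: SSRLocus, genes: Sequence[GeneModel]
) -> RegionAssignment:
    """Assign one locus to its region by midpoint.

    Priority: promoter > TTS > exon > intron+intergenic. When several
    genes' windows contain the midpoint, the gene with the nearest TSS
    wins.
    """
    mid = _midpoint(locus)
    on_seq = [g for g in genes if g.seq_id == locus.seq_id]

    def nearest(cands: list[GeneModel]) -> GeneModel:
        return min(cands, key=lambda g: (abs(g.tss - mid), g.gene_id))

    hits = [g for g in on_seq if g.promoter_window()[0] <= mid <= g.promoter_window()[1]]
    if hits:
        return RegionAssignment(locus_identifier(locus), PROMOTER, nearest(hits).gene_id)
    hits = [g for g in on_seq if g.tts_window()[0] <= mid <= g.tts_window()[1]]
    if hits:
        return RegionAssignment(locus_identifier(locus), TTS, nearest(hits).gene_id)
    hits = [g for g in on_seq if any(s <= mid <= e for s, e in g.exons)]
    if hits:
        return RegionAssignment(locus_identifier(locus), EXON, nearest(hits).gene_id)
    return RegionAssignment(locus_identifier(locus), INTRON_INTERGENIC, None)


def assign_regions(
    loci: Iterable[SSRLocus], genes: Sequence[GeneModel]
) -> list[RegionAssignment]:
    return [assign_region(locus, genes) for locus in loci]


def region_counts(assignments: Iterable[RegionAssignment]) -> dict[str, int]:
    """Category -> count; categories partition the assignment set."""
    tally = Counter(a.category for a in assignments)
    return {cat: tally.get(cat, 0) for cat in REGION_ORDER}


def associate_genes(
    assignments: Iterable[RegionAssignment],
) -> tuple[list[tuple[str, str]], list[str]]:
    """Locus -> gene association table plus the deduplicated gene list.

    Only assignments that carry a gene (promoter/TTS/exon) associate.
    """
    table = [(a.locus_id, a.gene_id) for a in assignments if a.gene_id is not None]
    distinct = sorted({gene_id for _, gene_id in table})
    return table, distinct
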