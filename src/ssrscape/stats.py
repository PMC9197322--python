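"""Summary statistics over SSR catalogs.

Per-class and per-chromosome counts, motif frequency tables, densities per
Mb, mean inter-SSR spacing, and sequencing-library panel means.

Density and spacing are reciprocal by construction::

    per_mb = count / (span_bp / 1e6)
    spacing_kb = (span_bp / 1e3) / count = 1000 / per_mb

"Average distance between two SSRs" is span/count, not the mean gap between
consecutive loci. All rates are rounded half-up to two decimals; Mb and Kb
are decimal (1e6 / 1e3 bp).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .mining import SSRLocus

__all__ = [
    "CLASS_ORDER",
    "round_half_up",
    "spacing_from_per_mb",
    "per_mb_from_spacing",
    "DensityStats",
    "density",
    "ClassSummary",
    "summarize_by_class",
    "summarize_by_sequence",
    "motif_frequency_table",
    "LibraryRow",
    "LibrarySummary",
    "library_summary",
]

#: Reporting order for repeat classes.
CLASS_ORDER = ("p1", "p2", "p3", "p4", "p5", "p6", "compound")

CLASS_LABELS = {
    "p1": "Mono",
    "p2": "Di",
    "p3": "Tri",
    "p4": "Tetra",
    "p5": "Penta",
    "p6": "Hexa",
    "compound": "Compound",
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (5 rounds away from zero), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def spacing_from_per_mb(per_mb: float) -> float:
    """Mean inter-locus spacing in Kb implied by a per-Mb density."""
    if per_mb <= 0:
        raise ValueError("per_mb must be positive")
    return round_half_up(1000.0 / per_mb)


def per_mb_from_spacing(spacing_kb: float) -> float:
    if spacing_kb <= 0:
        raise ValueError("spacing_kb must be positive")
    return round_half_up(1000.0 / spacing_kb)


@dataclass(frozen=True)
class DensityStats:
    """Locus density over a span: count, per-Mb rate, mean spacing in Kb."""

    count: int
    span_bp: int
    per_mb: float
    spacing_kb: float


def density(count: int, span_bp: int) -> DensityStats:
    """Density statistics for ``count`` loci over ``span_bp`` bases.

    Raises ValueError for zero counts (spacing would be undefined).
    """
    if count < 1:
        raise ValueError("count must be >= 1 (spacing undefined for 0 loci)")
    if span_bp < 1:
        raise ValueError("span_bp must be >= 1")
    per_mb = round_half_up(count / (span_bp / 1e6))
    spacing_kb = round_half_up((span_bp / 1e3) / count)
    return DensityStats(count=count, span_bp=span_bp, per_mb=per_mb, spacing_kb=spacing_kb)


def _locus_class(locus: SSRLocus) -> str:
    return "compound" if locus.is_compound else locus.ssr_class


@dataclass
class ClassSummary:
    """Per-repeat-class counts, motif diversity and proportions.

    ``counts`` maps class code (p1..p6, compound) to locus count;
    ``motif_types`` maps class code to the number of distinct motif strings.
    """

    counts: dict[str, int] = field(default_factory=dict)
    motif_types: dict[str, int] = field(default_factory=dict)
    span_bp: int | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, ssr_class: str) -> float:
        """Class share of the total, %, two decimals."""
        if self.total == 0:
            return 0.0
        return round_half_up(100.0 * self.counts.get(ssr_class, 0) / self.total)

    def per_mb(self, ssr_class: str) -> float | None:
        if self.span_bp is None or self.span_bp < 1:
            return None
        return round_half_up(self.counts.get(ssr_class, 0) / (self.span_bp / 1e6))

    def rows(self) -> list[dict]:
        out = []
        for cls in CLASS_ORDER:
            out.append(
                {
                    "class": CLASS_LABELS[cls],
                    "count": self.counts.get(cls, 0),
                    "motif_types": self.motif_types.get(cls, 0),
                    "proportion_pct": self.proportion(cls),
                    "per_mb": self.per_mb(cls),
                }
            )
        return out


def summarize_by_class(
    loci: Sequence[SSRLocus], span_bp: int | None = None
) -> ClassSummary:
    """Tally loci per repeat class; distinct motifs counted within class."""
    counts: Counter[str] = Counter()
    motifs: dict[str, set[str]] = {}
    for locus in loci:
        cls = _locus_class(locus)
        counts[cls] += 1
        motifs.setdefault(cls, set()).add(locus.motif)
    return ClassSummary(
        counts={cls: counts.get(cls, 0) for cls in CLASS_ORDER},
        motif_types={cls: len(motifs.get(cls, ())) for cls in CLASS_ORDER},
        span_bp=span_bp,
    )


def summarize_by_sequence(
    loci: Sequence[SSRLocus], sequence_lengths: Mapping[str, int]
) -> list[dict]:
    """Per-chromosome count / per-Mb / spacing table, sorted by seq_id.

    Sequences with zero loci get a row with null rate fields.
    """
    by_seq: Counter[str] = Counter(locus.seq_id for locus in loci)
    unknown = set(by_seq) - set(sequence_lengths)
    if unknown:
        raise ValueError(f"loci reference unknown sequences: {sorted(unknown)}")
    rows = []
    for seq_id in sorted(sequence_lengths):
        count = by_seq.get(seq_id, 0)
        span = sequence_lengths[seq_id]
        if count:
            d = density(count, span)
            rows.append(
                {
                    "seq_id": seq_id,
                    "count": count,
                    "span_bp": span,
                    "per_mb": d.per_mb,
                    "spacing_kb": d.spacing_kb,
                }
            )
        else:
            rows.append(
                {
                    "seq_id": seq_id,
                    "count": 0,
                    "span_bp": span,
                    "per_mb": None,
                    "spacing_kb": None,
                }
            )
    return rows


def motif_frequency_table(
    loci: Sequence[SSRLocus], unit_length: int, min_frequency: int = 1
) -> list[tuple[str, int]]:
    """(motif, frequency) pairs for simple loci of one unit length.

    Sorted descending by frequency, ties lexicographic; entries below
    ``min_frequency`` are dropped.
    """
    if not 1 <= unit_length <= 6:
        raise ValueError("unit_length must be 1..6")
    tally: Counter[str] = Counter(
        locus.motif
        for locus in loci
        if not locus.is_compound and locus.unit_length == unit_length
    )
    items = [(m, c) for m, c in tally.items() if c >= min_frequency]
    return sorted(items, key=lambda mc: (-mc[1], mc[0]))


@dataclass(frozen=True)
class LibraryRow:
    """One sequencing library: read count, GC%, scaffold and SSR counts."""

    genotype: str
    pe_reads: int
    gc_pct: float
    scaffolds: int
    ssr_count: int


@dataclass(frozen=True)
class LibrarySummary:
    n_libraries: int
    mean_reads: int
    mean_gc_pct: float
    mean_scaffolds: int
    mean_ssr_count: int


def library_summary(rows: Iterable[LibraryRow]) -> LibrarySummary:
    """Panel means: read/scaffold/SSR means to nearest integer, GC to 2 dp."""
    rows = list(rows)
    if not rows:
        raise ValueError("library_summary requires at least one row")
    n = len(rows)
    return LibrarySummary(
        n_libraries=n,
        mean_reads=int(round_half_up(sum(r.pe_reads for r in rows) / n, 0)),
        mean_gc_pct=round_half_up(sum(r.gc_pct for r in rows) / n),
        mean_scaffolds=int(round_half_up(sum(r.scaffolds for r in rows) / n, 0)),
        mean_ssr_count=int(round_half_up(sum(r.ssr_count for r in rows) / n, 0)),
    )
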