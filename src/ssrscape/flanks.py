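"""Flanking-sequence extraction and constrained primer-candidate design.

A FlankSignature (the 20-nt sequences immediately 5' and 3' of a tract plus
the motif and repeat count) is the identity key used to match one locus
across genomes. Primer candidates are picked from the flanking sequence
under fixed length / melting-temperature / GC / product-size windows and
ranked by Tm balance, then by product size closest to 200 bp.

The melting temperature model is the Wallace rule, Tm = 2(A+T) + 4(G+C);
nearest-neighbour thermodynamics are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .mining import SSRLocus, SequenceRecord
from .stats import round_half_up

__all__ = [
    "SIGNATURE_FLANK_LEN",
    "EPCR_FLANK_LEN",
    "FlankSignature",
    "PrimerConstraints",
    "PrimerPair",
    "revcomp",
    "gc_percent",
    "wallace_tm",
    "extract_flanks",
    "design_primers",
]

SIGNATURE_FLANK_LEN = 20
EPCR_FLANK_LEN = 200

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage, two decimals."""
    if not seq:
        raise ValueError("gc_percent requires a non-empty sequence")
    gc = sum(1 for b in seq if b in "GC")
    return round_half_up(100.0 * gc / len(seq))


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C) degrees C."""
    at = sum(1 for b in seq if b in "AT")
    gc = sum(1 for b in seq if b in "GC")
    return float(2 * at + 4 * gc)


@dataclass(frozen=True)
class FlankSignature:
    """Locus identity key: exact flanks + motif + repeat count.

    ``valid`` is False when either flank is truncated by a sequence end or
    contains N; invalid signatures never participate in matching.
    """

    locus_id: str
    left_flank: str
    right_flank: str
    motif: str
    repeat_count: int | None
    tract_length: int
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.left_flank, self.right_flank)


@dataclass(frozen=True)
class PrimerConstraints:
    """Primer picking windows (inclusive bounds)."""

    min_len: int = 18
    max_len: int = 27
    min_tm: float = 57.0
    max_tm: float = 63.0
    min_gc: float = 30.0
    max_gc: float = 70.0
    min_product: int = 100
    max_product: int = 300


@dataclass(frozen=True)
class PrimerPair:
    """One candidate or published primer pair.

    ``forward`` is a sense-strand substring 5'->3'; ``reverse`` is given
    5'->3' in its own reading direction (i.e. the reverse complement of the
    sense-strand site it binds). ``product_size`` is the distance between
    the two outer 5' ends, inclusive.
    """

    forward: str
    reverse: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int
    fwd_start: int | None = None  # 1-based, sense strand
    rev_end: int | None = None  # 1-based, sense-strand 3' end of the rev site
    pair_id: str | None = None


def locus_identifier(locus: SSRLocus) -> str:
    return f"{locus.seq_id}:{locus.start}-{locus.end}"


def extract_flanks(
    locus: SSRLocus,
    genome: Mapping[str, SequenceRecord],
    flank_len: int = SIGNATURE_FLANK_LEN,
) -> FlankSignature:
    """Flanking sequences immediately adjacent to the tract.

    A locus closer than ``flank_len`` to a sequence end yields a truncated
    signature flagged invalid; so does any flank containing N.
    """
    if locus.seq_id not in genome:
        raise KeyError(f"unknown sequence id {locus.seq_id!r}")
    seq = genome[locus.seq_id].seq
    left_start = locus.start - 1 - flank_len  # 0-based
    right_end = locus.end + flank_len  # 0-based exclusive
    left = seq[max(left_start, 0) : locus.start - 1]
    right = seq[locus.end : right_end]
    reason = None
    if len(left) < flank_len or len(right) < flank_len:
        reason = "truncated"
    elif "N" in left or "N" in right:
        reason = "ambiguous_base"
    return FlankSignature(
        locus_id=locus_identifier(locus),
        left_flank=left,
        right_flank=right,
        motif=locus.motif,
        repeat_count=locus.repeat_count,
        tract_length=locus.tract_length,
        valid=reason is None,
        invalid_reason=reason,
    )


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    return (
        c.min_len <= len(seq) <= c.max_len
        and "N" not in seq
        and c.min_tm <= wallace_tm(seq) <= c.max_tm
        and c.min_gc <= gc_percent(seq) <= c.max_gc
    )


def design_primers(
    locus: SSRLocus,
    genome: Mapping[str, SequenceRecord],
    constraints: PrimerConstraints | None = None,
    max_pairs: int = 5,
    search_window: int = EPCR_FLANK_LEN,
) -> list[PrimerPair]:
    """Enumerate primer pairs flanking the tract that satisfy all windows.

    Forward candidates end strictly before the tract; reverse candidates
    start strictly after it. The product must span the tract. Pairs are
    ranked by |Tm_f - Tm_r|, then by product size closest to 200 bp; at
    most ``max_pairs`` are returned (empty list when nothing qualifies).
    """
    c = constraints or PrimerConstraints()
    seq = genome[locus.seq_id].seq
    # 0-based half-open search regions either side of the tract
    left_lo = max(locus.start - 1 - search_window, 0)
    left_hi = locus.start - 1
    right_lo = locus.end
    right_hi = min(locus.end + search_window, len(seq))

    fwd: list[tuple[int, str]] = []  # (0-based start, sequence)
    for length in range(c.min_len, c.max_len + 1):
        for s in range(left_lo, left_hi - length + 1):
            cand = seq[s : s + length]
            if _primer_ok(cand, c):
                fwd.append((s, cand))

    rev: list[tuple[int, str]] = []  # (0-based inclusive sense-strand end, primer)
    for length in range(c.min_len, c.max_len + 1):
        for s in range(right_lo, right_hi - length + 1):
            site = seq[s : s + length]
            primer = revcomp(site)
            if _primer_ok(primer, c):
                rev.append((s + length - 1, primer))

    pairs: list[PrimerPair] = []
    for fs, fseq in fwd:
        for re_, rseq in rev:
            product = re_ - fs + 1
            if not c.min_product <= product <= c.max_product:
                continue
            pairs.append(
                PrimerPair(
                    forward=fseq,
                    reverse=rseq,
                    tm_f=wallace_tm(fseq),
                    tm_r=wallace_tm(rseq),
                    gc_f=gc_percent(fseq),
                    gc_r=gc_percent(rseq),
                    product_size=product,
                    fwd_start=fs + 1,
                    rev_end=re_ + 1,
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.tm_f - p.tm_r),
            abs(p.product_size - 200),
            p.fwd_start,
            p.rev_end,
        )
    )
    return pairs[:max_pairs]
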