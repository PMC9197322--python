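"""In-silico PCR placement of primer pairs near catalogued SSR loci.

Primer pairs are matched exactly (full length, ungapped, zero mismatches by
default) inside a window extending 200 bp beyond each side of an SSR
tract: the forward primer on the sense strand, the reverse complement of
the reverse primer downstream of it, in convergent orientation. Because
published primer orientation relative to the assembly is arbitrary, the
pair is also tried with roles swapped. A placement validates a locus only
when the product overlaps the SSR tract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .flanks import EPCR_FLANK_LEN, PrimerPair, revcomp
from .mining import SSRLocus, SequenceRecord

__all__ = ["EPCRMatch", "epcr_scan", "validate_panel"]


@dataclass(frozen=True)
class EPCRMatch:
    primer_pair_id: str | None
    locus_id: str
    seq_id: str
    fwd_start: int  # 1-based 5' end of the sense-strand primer site
    rev_start: int  # 1-based sense-strand start of the reverse-primer site
    product_size: int
    swapped: bool  # True when roles were exchanged to obtain the placement


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence starts (overlapping allowed)."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _mismatch_find_all(haystack: str, needle: str, max_mismatches: int) -> list[int]:
    n, m = len(haystack), len(needle)
    hits = []
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


def epcr_scan(
    pair: PrimerPair,
    locus: SSRLocus,
    genome: Mapping[str, SequenceRecord],
    window: int = EPCR_FLANK_LEN,
    max_mismatches: int = 0,
) -> list[EPCRMatch]:
    """All convergent exact placements of a primer pair around one locus.

    The search window is [locus.start - window, locus.end + window],
    clipped to sequence bounds. ``max_mismatches`` > 0 enables tolerant
    matching (off by default and excluded from validation guarantees).
    """
    seq = genome[locus.seq_id].seq
    w_lo = max(locus.start - 1 - window, 0)  # 0-based
    w_hi = min(locus.end + window, len(seq))  # 0-based exclusive
    win = seq[w_lo:w_hi]
    locus_id = f"{locus.seq_id}:{locus.start}-{locus.end}"

    find = (
        _find_all
        if max_mismatches == 0
        else lambda h, n: _mismatch_find_all(h, n, max_mismatches)
    )

    matches: list[EPCRMatch] = []
    seen: set[tuple[int, int, int]] = set()
    for swapped, (fwd, rev) in (
        (False, (pair.forward, pair.reverse)),
        (True, (pair.reverse, pair.forward)),
    ):
        rev_site = revcomp(rev)
        fwd_hits = find(win, fwd)
        rev_hits = find(win, rev_site)
        for f0 in fwd_hits:
            for r0 in rev_hits:
                # convergent: reverse site strictly downstream, no overlap
                if r0 < f0 + len(fwd):
                    continue
                prod_start = w_lo + f0 + 1  # 1-based genomic
                prod_end = w_lo + r0 + len(rev_site)  # 1-based genomic
                if prod_end < locus.start or prod_start > locus.end:
                    continue  # product must overlap the tract
                sig = (prod_start, prod_end, w_lo + r0)
                if sig in seen:
                    continue  # palindromic pairs re-place under the swap
                seen.add(sig)
                matches.append(
                    EPCRMatch(
                        primer_pair_id=pair.pair_id,
                        locus_id=locus_id,
                        seq_id=locus.seq_id,
                        fwd_start=prod_start,
                        rev_start=w_lo + r0 + 1,
                        product_size=prod_end - prod_start + 1,
                        swapped=swapped,
                    )
                )
    matches.sort(key=lambda m: (m.fwd_start, m.rev_start))
    return matches


def validate_panel(
    primers: Sequence[PrimerPair],
    catalog: Sequence[SSRLocus],
    genome: Mapping[str, SequenceRecord],
    window: int = EPCR_FLANK_LEN,
) -> list[dict]:
    """One row per primer pair: located loci, multi-mapped flag, or unplaced."""
    rows = []
    for i, pair in enumerate(primers):
        pair_id = pair.pair_id or f"pair{i + 1}"
        hits: list[EPCRMatch] = []
        for locus in catalog:
            hits.extend(epcr_scan(pair, locus, genome, window=window))
        located = sorted({h.locus_id for h in hits})
        rows.append(
            {
                "primer_pair_id": pair_id,
                "status": (
                    "unplaced"
                    if not located
                    else ("multi_mapped" if len(located) > 1 else "located")
                ),
                "loci": located,
                "n_placements": len(hits),
                "product_sizes": sorted({h.product_size for h in hits}),
            }
        )
    return rows
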