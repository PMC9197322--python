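"""Flank-anchored polymorphism calling between a reference SSR catalog and
per-genotype de-novo contig sets.

Each reference locus carries a signature: its 20-nt 5' and 3' flanks plus
motif and repeat count. Genotype contigs are mined for SSRs on both
orientations and indexed by the same signature key. A reference locus whose
flanks match exactly in a genotype is called monomorphic (same repeat
count / tract length) or polymorphic (different); no flank hit means
absent; conflicting or cross-motif hits are ambiguous.

Matching rules
--------------
* Flank comparison is exact identity, both sides, full 20 nt.
* The motif must be identical after strand normalisation (reverse-strand
  hits are re-expressed in reference orientation by mining the reverse
  complement of the contig); flank-identical hits with a different motif
  are ambiguous, never polymorphic.
* Compound loci are compared by component-motif sequence and total tract
  length; differing total length with identical flanks is polymorphic.
* A genotype locus may satisfy at most one reference locus; many-to-one
  collisions mark every involved call ambiguous.
* In the panel aggregation a locus polymorphic in at least one genotype is
  polymorphic in the union, regardless of monomorphic calls elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .flanks import FlankSignature, SIGNATURE_FLANK_LEN, extract_flanks, revcomp
from .mining import (
    HYPERVARIABLE_MIN_TRACT,
    MiningThresholds,
    SequenceRecord,
    mine_record,
)

__all__ = [
    "MONOMORPHIC",
    "POLYMORPHIC",
    "ABSENT",
    "AMBIGUOUS",
    "PolymorphismCall",
    "GenotypeIndex",
    "index_genotype",
    "call_locus",
    "call_genotype",
    "PanelSummary",
    "aggregate",
    "hypervariable_calls",
]

MONOMORPHIC = "monomorphic"
POLYMORPHIC = "polymorphic"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class _IndexEntry:
    """One genotype SSR locus as seen in one orientation."""

    contig_id: str
    strand: str  # orientation in which the flanks/motif are expressed
    motif: str
    repeat_count: int | None
    tract_length: int
    phys_start: int  # contig forward-strand coordinates (1-based)
    phys_end: int

    @property
    def physical_id(self) -> tuple[str, int, int]:
        return (self.contig_id, self.phys_start, self.phys_end)


@dataclass
class GenotypeIndex:
    """Signature-key lookup over every SSR minable from a contig set."""

    genotype_id: str
    by_key: dict[tuple[str, str], list[_IndexEntry]] = field(default_factory=dict)

    def lookup(self, key: tuple[str, str]) -> list[_IndexEntry]:
        return self.by_key.get(key, [])


@dataclass(frozen=True)
class PolymorphismCall:
    ref_locus_id: str
    genotype_id: str
    status: str
    ref_repeat_count: int | None = None
    ref_tract_length: int | None = None
    genotype_repeat_count: int | None = None
    genotype_tract_length: int | None = None
    matched_strand: str | None = None
    reason: str | None = None


def index_genotype(
    contigs: Iterable[SequenceRecord],
    thresholds: MiningThresholds | None = None,
    genotype_id: str = "",
    flank_len: int = SIGNATURE_FLANK_LEN,
) -> GenotypeIndex:
    """Mine every contig on both orientations and index loci by flank key.

    Only loci with two intact ``flank_len`` flanks are indexed; an SSR too
    close to a contig end is silently skipped.
    """
    thresholds = thresholds or MiningThresholds()
    index = GenotypeIndex(genotype_id=genotype_id)
    for contig in contigs:
        n = len(contig.seq)
        for strand, record in (
            ("+", contig),
            ("-", SequenceRecord(contig.id, revcomp(contig.seq))),
        ):
            lookup = {record.id: record}
            for locus in mine_record(record, thresholds):
                sig = extract_flanks(locus, lookup, flank_len)
                if not sig.valid:
                    continue
                if strand == "+":
                    phys_start, phys_end = locus.start, locus.end
                else:
                    phys_start = n - locus.end + 1
                    phys_end = n - locus.start + 1
                entry = _IndexEntry(
                    contig_id=contig.id,
                    strand=strand,
                    motif=locus.motif,
                    repeat_count=locus.repeat_count,
                    tract_length=locus.tract_length,
                    phys_start=phys_start,
                    phys_end=phys_end,
                )
                index.by_key.setdefault(sig.key, []).append(entry)
    return index


def _resolve_hits(
    ref_sig: FlankSignature, hits: Sequence[_IndexEntry], genotype_id: str
) -> tuple[PolymorphismCall, list[_IndexEntry]]:
    """Classify one reference signature against its flank-key hits."""
    # A palindromic signature can hit the same physical tract on both
    # orientations; collapse those, preferring the forward entry.
    distinct: dict[tuple[str, int, int], _IndexEntry] = {}
    for hit in sorted(hits, key=lambda h: h.strand):
        distinct.setdefault(hit.physical_id, hit)
    resolved = list(distinct.values())

    base = dict(
        ref_locus_id=ref_sig.locus_id,
        genotype_id=genotype_id,
        ref_repeat_count=ref_sig.repeat_count,
        ref_tract_length=ref_sig.tract_length,
    )
    motifs = {h.motif for h in resolved}
    tracts = {h.tract_length for h in resolved}
    if motifs != {ref_sig.motif}:
        return (
            PolymorphismCall(status=AMBIGUOUS, reason="motif_mismatch", **base),
            resolved,
        )
    if len(tracts) > 1:
        return (
            PolymorphismCall(status=AMBIGUOUS, reason="conflicting_counts", **base),
            resolved,
        )
    hit = resolved[0]
    same = (
        hit.tract_length == ref_sig.tract_length
        and hit.repeat_count == ref_sig.repeat_count
    )
    return (
        PolymorphismCall(
            status=MONOMORPHIC if same else POLYMORPHIC,
            genotype_repeat_count=hit.repeat_count,
            genotype_tract_length=hit.tract_length,
            matched_strand=hit.strand,
            **base,
        ),
        resolved,
    )


def call_locus(ref_sig: FlankSignature, index: GenotypeIndex) -> PolymorphismCall:
    """Call a single reference locus against one genotype index."""
    if not ref_sig.valid:
        return PolymorphismCall(
            ref_locus_id=ref_sig.locus_id,
            genotype_id=index.genotype_id,
            status=ABSENT,
            reason=f"invalid_signature:{ref_sig.invalid_reason}",
        )
    hits = index.lookup(ref_sig.key)
    if not hits:
        return PolymorphismCall(
            ref_locus_id=ref_sig.locus_id,
            genotype_id=index.genotype_id,
            status=ABSENT,
            ref_repeat_count=ref_sig.repeat_count,
            ref_tract_length=ref_sig.tract_length,
        )
    call, _ = _resolve_hits(ref_sig, hits, index.genotype_id)
    return call


def call_genotype(
    ref_signatures: Sequence[FlankSignature], index: GenotypeIndex
) -> list[PolymorphismCall]:
    """Call every reference locus, enforcing one-genotype-locus-per-ref-locus.

    When one physical genotype locus satisfies two or more reference
    signatures, every involved call is downgraded to ambiguous.
    """
    calls: list[PolymorphismCall] = []
    used_by: dict[tuple[str, int, int], list[int]] = {}
    for ref_sig in ref_signatures:
        if not ref_sig.valid or not index.lookup(ref_sig.key):
            calls.append(call_locus(ref_sig, index))
            continue
        call, resolved = _resolve_hits(ref_sig, index.lookup(ref_sig.key), index.genotype_id)
        pos = len(calls)
        calls.append(call)
        if call.status in (MONOMORPHIC, POLYMORPHIC):
            for hit in resolved:
                used_by.setdefault(hit.physical_id, []).append(pos)
    collided = {i for positions in used_by.values() if len(positions) > 1 for i in positions}
    for i in collided:
        old = calls[i]
        calls[i] = PolymorphismCall(
            ref_locus_id=old.ref_locus_id,
            genotype_id=old.genotype_id,
            status=AMBIGUOUS,
            ref_repeat_count=old.ref_repeat_count,
            ref_tract_length=old.ref_tract_length,
            reason="shared_genotype_locus",
        )
    return calls


@dataclass
class PanelSummary:
    """Cross-genotype aggregation of polymorphism calls."""

    per_genotype: dict[str, dict[str, int]]
    polymorphic_union: set[str]
    monomorphic_union: set[str]

    @property
    def common_loci(self) -> set[str]:
        return self.polymorphic_union | self.monomorphic_union

    @property
    def n_polymorphic(self) -> int:
        return len(self.polymorphic_union)

    @property
    def n_monomorphic(self) -> int:
        return len(self.monomorphic_union)

    @property
    def n_common(self) -> int:
        return self.n_polymorphic + self.n_monomorphic


def aggregate(calls_by_genotype: Mapping[str, Sequence[PolymorphismCall]]) -> PanelSummary:
    """Panel summary: per-genotype counts and the disjoint mono/poly unions.

    A reference locus polymorphic in any genotype lands in the polymorphic
    union; the monomorphic union holds loci matched somewhere but never
    polymorphic. The two unions partition the common-locus set.
    """
    per_genotype: dict[str, dict[str, int]] = {}
    poly: set[str] = set()
    mono_seen: set[str] = set()
    for genotype_id, calls in calls_by_genotype.items():
        mono_loci = {c.ref_locus_id for c in calls if c.status == MONOMORPHIC}
        poly_loci = {c.ref_locus_id for c in calls if c.status == POLYMORPHIC}
        per_genotype[genotype_id] = {
            "monomorphic": len(mono_loci),
            "polymorphic": len(poly_loci),
            "absent": sum(1 for c in calls if c.status == ABSENT),
            "ambiguous": sum(1 for c in calls if c.status == AMBIGUOUS),
        }
        poly |= poly_loci
        mono_seen |= mono_loci
    return PanelSummary(
        per_genotype=per_genotype,
        polymorphic_union=poly,
        monomorphic_union=mono_seen - poly,
    )


def hypervariable_calls(
    calls: Iterable[PolymorphismCall],
    min_tract: int = HYPERVARIABLE_MIN_TRACT,
) -> list[PolymorphismCall]:
    """Polymorphic calls whose reference or genotype tract spans >= 20 nt."""
    kept = []
    for call in calls:
        if call.status != POLYMORPHIC:
            continue
        ref_len = call.ref_tract_length or 0
        geno_len = call.genotype_tract_length or 0
        if ref_len >= min_tract or geno_len >= min_tract:
            kept.append(call)
    return kept
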