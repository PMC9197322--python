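"""Perfect microsatellite (SSR) detection and compound-locus merging.

Finds maximal perfect tandem repeats of unit length 1-6 under per-unit-length
minimum repeat counts, then merges neighbouring tracts separated by at most a
configurable interval into compound loci.

Conventions
-----------
* Coordinates are 1-based inclusive throughout.
* The motif is reported in the phase at which the tract begins (``TA`` and
  ``AT`` are distinct motifs); no cyclic or reverse-complement
  canonicalisation is applied.
* Motifs are always primitive: a tract with period 4 that is really an
  ``AT``-dimer repeat is reported with unit ``AT``.
* ``N`` terminates any tract; tracts never contain ``N``.
* Tracts cover whole repeat units only; a trailing partial unit is excluded
  (``(TA)6T`` reports count 6, tract length 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SequenceRecord",
    "MiningThresholds",
    "SSRLocus",
    "InputError",
    "ContractError",
    "find_perfect_ssrs",
    "merge_compound",
    "is_hypervariable",
    "mine_record",
    "mine_records",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Minimum repeat counts per unit length (mono..hexa) and the maximum
#: interval (bp) between neighbouring tracts of one compound locus.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_MAX_COMPOUND_INTERVAL = 100

HYPERVARIABLE_MIN_TRACT = 20


class InputError(ValueError):
    """Raised for invalid sequence input (non-DNA characters, bad ids)."""


class ContractError(ValueError):
    """Raised when an operation precondition is violated by the caller."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        """Check residues; reports the first offending position (1-based)."""
        for i, base in enumerate(self.seq):
            if base not in DNA_ALPHABET:
                raise InputError(
                    f"non-DNA character {base!r} at position {i + 1} "
                    f"of sequence {self.id!r}"
                )


@dataclass(frozen=True)
class MiningThresholds:
    """Detection thresholds: unit length -> minimum repeat count."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_compound_interval: int = DEFAULT_MAX_COMPOUND_INTERVAL

    def __post_init__(self) -> None:
        if set(self.min_repeats) - set(range(1, 7)):
            raise ValueError("min_repeats keys must be unit lengths 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("all minimum repeat counts must be >= 2")
        if self.max_compound_interval < 0:
            raise ValueError("max_compound_interval must be >= 0")

    @property
    def unit_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.min_repeats))


@dataclass
class SSRLocus:
    """One detected microsatellite locus (simple or compound).

    For simple loci ``tract_length == unit_length * repeat_count``. Compound
    loci carry their position-ordered simple components and have
    ``unit_length``/``repeat_count`` unset.
    """

    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str
    ssr_class: str  # p1..p6, c, c*
    unit_length: int | None = None
    repeat_count: int | None = None
    components: list["SSRLocus"] = field(default_factory=list)

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_compound(self) -> bool:
        return self.ssr_class in ("c", "c*")

    @property
    def ssr_string(self) -> str:
        """MISA-style rendering, e.g. ``(TA)6`` or ``(TA)6n50(ATC)5``."""
        if not self.is_compound:
            return f"({self.motif}){self.repeat_count}"
        parts = [self.components[0].ssr_string]
        for prev, cur in zip(self.components, self.components[1:]):
            gap = cur.start - prev.end - 1
            parts.append("*" if gap == 0 else f"n{gap}")
            parts.append(cur.ssr_string)
        return "".join(parts)


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _candidate_tracts(seq: str, thresholds: MiningThresholds) -> list[tuple]:
    """All maximal perfect tracts meeting their threshold, pre-resolution.

    Returns tuples (start0, end0, unit_length, count, motif) with 0-based
    inclusive coordinates.
    """
    n = len(seq)
    out = []
    for k in thresholds.unit_lengths:
        min_count = thresholds.min_repeats[k]
        i = 0
        limit = n - k
        while i < limit:
            # seek start of a period-k run
            if seq[i] != seq[i + k] or seq[i] == "N":
                i += 1
                continue
            j = i
            while j < limit and seq[j] == seq[j + k] and seq[j] != "N":
                j += 1
            # periodic region covers seq[i : j + k]; whole units only
            region_len = (j - i) + k
            count = region_len // k
            motif = seq[i : i + k]
            if count >= min_count and "N" not in motif and _is_primitive(motif):
                out.append((i, i + count * k - 1, k, count, motif))
            i = j + 1
    return out


def resolve_overlaps(candidates: Iterable[tuple]) -> list[tuple]:
    """Greedy overlap resolution: longer tract wins; ties prefer the smaller
    unit length, then the leftmost start."""
    ranked = sorted(
        candidates,
        key=lambda c: (-(c[1] - c[0] + 1), c[2], c[0]),
    )
    chosen: list[tuple] = []
    occupied: list[tuple[int, int]] = []
    for cand in ranked:
        s, e = cand[0], cand[1]
        if any(s <= oe and e >= os_ for os_, oe in occupied):
            continue
        chosen.append(cand)
        occupied.append((s, e))
    return sorted(chosen, key=lambda c: c[0])


def find_perfect_ssrs(
    record: SequenceRecord, thresholds: MiningThresholds | None = None
) -> list[SSRLocus]:
    """Detect all maximal perfect SSRs in one sequence.

    Returns simple loci sorted by start position, 1-based inclusive
    coordinates, non-overlapping after longest-wins resolution.
    """
    thresholds = thresholds or MiningThresholds()
    record.validate()
    loci = []
    for s0, e0, k, count, motif in resolve_overlaps(
        _candidate_tracts(record.seq, thresholds)
    ):
        loci.append(
            SSRLocus(
                seq_id=record.id,
                start=s0 + 1,
                end=e0 + 1,
                motif=motif,
                ssr_class=f"p{k}",
                unit_length=k,
                repeat_count=count,
            )
        )
    return loci


def merge_compound(
    loci: Sequence[SSRLocus], max_interval: int = DEFAULT_MAX_COMPOUND_INTERVAL
) -> list[SSRLocus]:
    """Merge runs of neighbouring simple loci into compound loci.

    Maximal runs of two or more simple loci whose consecutive gaps are all
    <= ``max_interval`` bp become one compound locus (class ``c``; ``c*``
    when any gap is zero). Isolated loci pass through unchanged.
    """
    for prev, cur in zip(loci, loci[1:]):
        if cur.seq_id != prev.seq_id:
            raise ContractError("merge_compound requires a single seq_id")
        if cur.start <= prev.end:
            raise ContractError("merge_compound requires sorted, non-overlapping loci")

    out: list[SSRLocus] = []
    run: list[SSRLocus] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            zero_gap = any(
                b.start - a.end - 1 == 0 for a, b in zip(run, run[1:])
            )
            compound = SSRLocus(
                seq_id=run[0].seq_id,
                start=run[0].start,
                end=run[-1].end,
                motif="+".join(c.motif for c in run),
                ssr_class="c*" if zero_gap else "c",
                components=list(run),
            )
            out.append(compound)
        run.clear()

    for locus in loci:
        if run and locus.start - run[-1].end - 1 <= max_interval:
            run.append(locus)
        else:
            flush()
            run.append(locus)
    flush()
    return out


def is_hypervariable(locus: SSRLocus) -> bool:
    """A locus is hypervariable when its total tract spans >= 20 nt."""
    return locus.tract_length >= HYPERVARIABLE_MIN_TRACT


def mine_record(
    record: SequenceRecord, thresholds: MiningThresholds | None = None
) -> list[SSRLocus]:
    """find_perfect_ssrs followed by compound merging for one record."""
    thresholds = thresholds or MiningThresholds()
    simple = find_perfect_ssrs(record, thresholds)
    return merge_compound(simple, thresholds.max_compound_interval)


def mine_records(
    records: Iterable[SequenceRecord], thresholds: MiningThresholds | None = None
) -> list[SSRLocus]:
    """Mine every record; loci are grouped by record in input order."""
    thresholds = thresholds or MiningThresholds()
    out: list[SSRLocus] = []
    for record in records:
        out.extend(mine_record(record, thresholds))
    return out
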