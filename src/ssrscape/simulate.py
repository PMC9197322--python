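"""Deterministic synthetic data: reference genomes with planted SSR
landscapes and annotations, plus genotype contig sets with planted
repeat-number variants emulating de-novo-assembled GBS fragments.

Background sequence is rejection-sampled with the miner itself as the
filter: a chromosome is accepted only when mining it returns exactly the
planted loci, so spurious repeats and junction artefacts are impossible by
construction. Each genotype contig carries one planted locus copied from
the reference together with its real flanking sequence, optionally with a
repeat-count variant, a signature-flank mutation, or a strand flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import (
    EXON,
    INTRON_INTERGENIC,
    PROMOTER,
    REGION_ORDER,
    TTS,
    GeneModel,
)
from .flanks import SIGNATURE_FLANK_LEN, revcomp
from .mining import MiningThresholds, SequenceRecord, mine_record

__all__ = [
    "SimConfig",
    "PlantedLocus",
    "TruthCall",
    "ReferenceBundle",
    "GenotypeBundle",
    "simulate_reference",
    "simulate_genotypes",
]

_BASES = np.array(list("ACGT"))

#: Motif pool for planting; phases deliberately varied.
DEFAULT_MOTIFS = ("A", "T", "TA", "AG", "CT", "ATC", "AAG", "GAT", "AATC", "AACTG", "AACGTC")

#: Minimum spacing so that annotation windows (reach 2,500 bp) and e-PCR
#: windows (200 bp) of neighbouring loci never collide.
_MIN_SPACING = 2700


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 60_000
    loci_per_chrom: int = 12
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    extra_repeats: int = 10  # counts drawn from [threshold, threshold+extra]
    compound_fraction: float = 0.0
    n_genotypes: int = 3
    variant_rate: float = 0.3
    max_delta: int = 3  # repeat-count deltas drawn from +/-1..max_delta, never 0
    allow_subthreshold: bool = False  # permit deltas pushing below threshold
    flank_mutation_rate: float = 0.0
    coverage: float = 1.0
    contig_pad: int = 40  # reference sequence copied either side of a tract
    strand_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("variant_rate", "flank_mutation_rate", "coverage",
                     "strand_flip_prob", "compound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contig_pad < SIGNATURE_FLANK_LEN:
            raise ValueError("contig_pad must be >= the 20 bp signature flank")
        spacing = self.chrom_length // (self.loci_per_chrom + 1)
        if spacing < _MIN_SPACING:
            raise ValueError(
                f"infeasible packing: {self.loci_per_chrom} loci in "
                f"{self.chrom_length} bp gives spacing {spacing} < {_MIN_SPACING}"
            )


@dataclass(frozen=True)
class PlantedLocus:
    locus_id: str
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # "+"-joined component motifs for compounds
    repeat_count: int | None  # None for compounds
    is_compound: bool
    region: str
    gene_id: str | None
    # compound bookkeeping: (motif, count) per component and the gap
    components: tuple[tuple[str, int], ...] = ()
    gap: int = 0

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TruthCall:
    locus_id: str
    genotype_id: str
    status: str  # monomorphic | polymorphic | absent
    genotype_repeat_count: int | None = None
    genotype_tract_length: int | None = None
    strand: str | None = None
    reason: str | None = None


@dataclass
class ReferenceBundle:
    records: list[SequenceRecord]
    genes: list[GeneModel]
    truth: list[PlantedLocus]


@dataclass
class GenotypeBundle:
    genotype_id: str
    contigs: list[SequenceRecord]
    truth_calls: list[TruthCall]


def _random_dna(
    rng: np.random.Generator,
    length: int,
    first_not: str | None = None,
    last_not: str | None = None,
) -> str:
    """Random DNA; optionally constrain the terminal bases so an adjacent
    tandem tract cannot extend or phase-shift across the junction."""
    if length == 0:
        return ""
    chars = list(rng.choice(_BASES, size=length))
    if first_not is not None and chars[0] == first_not:
        chars[0] = str(rng.choice([b for b in "ACGT" if b != first_not]))
    if last_not is not None and chars[-1] == last_not:
        alt = [b for b in "ACGT" if b != last_not]
        if length == 1 and first_not is not None:
            alt = [b for b in alt if b != first_not] or alt
        chars[-1] = str(rng.choice(alt))
    return "".join(chars)


def _tract(motif: str, count: int) -> str:
    return motif * count


def _draw_simple(rng, cfg: SimConfig, thresholds: MiningThresholds) -> tuple[str, int]:
    motif = str(rng.choice(np.array(cfg.motifs, dtype=object)))
    lo = thresholds.min_repeats[len(motif)]
    count = int(rng.integers(lo, lo + cfg.extra_repeats + 1))
    return motif, count


def _plan_chromosome(rng, cfg: SimConfig, thresholds: MiningThresholds) -> list[dict]:
    """Decide motif/count/region/gene geometry for each slot on one chromosome."""
    spacing = cfg.chrom_length // (cfg.loci_per_chrom + 1)
    plans = []
    for i in range(cfg.loci_per_chrom):
        anchor = spacing * (i + 1)
        compound = rng.random() < cfg.compound_fraction
        if compound:
            m1, c1 = _draw_simple(rng, cfg, thresholds)
            m2, c2 = _draw_simple(rng, cfg, thresholds)
            while m2 == m1:
                m2, c2 = _draw_simple(rng, cfg, thresholds)
            gap = int(rng.integers(5, 41))
            plans.append(
                {
                    "anchor": anchor,
                    "compound": True,
                    "components": ((m1, c1), (m2, c2)),
                    "gap": gap,
                    "region": REGION_ORDER[i % 4],
                    "strand": "+" if i % 2 == 0 else "-",
                }
            )
        else:
            motif, count = _draw_simple(rng, cfg, thresholds)
            plans.append(
                {
                    "anchor": anchor,
                    "compound": False,
                    "components": ((motif, count),),
                    "gap": 0,
                    "region": REGION_ORDER[i % 4],
                    "strand": "+" if i % 2 == 0 else "-",
                }
            )
    return plans


def _tract_seq(plan: dict, rng, gap_seq: str | None = None) -> tuple[str, str | None]:
    if not plan["compound"]:
        (m, c), = plan["components"]
        return _tract(m, c), None
    (m1, c1), (m2, c2) = plan["components"]
    if gap_seq is None:
        gap_seq = _random_dna(rng, plan["gap"], first_not=m1[0], last_not=m2[-1])
    return _tract(m1, c1) + gap_seq + _tract(m2, c2), gap_seq


def _gene_for(plan: dict, mid: int, chrom: str, gene_id: str) -> GeneModel | None:
    """A local gene model whose windows place ``mid`` in the intended region."""
    region, strand = plan["region"], plan["strand"]
    if region == INTRON_INTERGENIC:
        return None
    if region == PROMOTER:
        if strand == "+":
            start, end = mid + 400, mid + 1200
        else:
            start, end = mid - 1200, mid - 400
    elif region == TTS:
        if strand == "+":
            start, end = mid - 1200, mid - 400
        else:
            start, end = mid + 400, mid + 1200
    else:  # EXON: gene spans the locus, exon covers the midpoint
        start, end = mid - 1500, mid + 1500
    exons = ((mid - 200, mid + 200),) if region == EXON else ((start, end),)
    return GeneModel(
        gene_id=gene_id, seq_id=chrom, strand=strand, start=start, end=end, exons=exons
    )


def _expected_mined(planted: Sequence[PlantedLocus], mined) -> bool:
    """Exact agreement between planted truth and mined loci on one record."""
    if len(mined) != len(planted):
        return False
    for truth, locus in zip(sorted(planted, key=lambda p: p.start), mined):
        if (locus.start, locus.end, locus.motif) != (truth.start, truth.end, truth.motif):
            return False
        if truth.is_compound != locus.is_compound:
            return False
        if not truth.is_compound and locus.repeat_count != truth.repeat_count:
            return False
    return True


def simulate_reference(
    config: SimConfig, thresholds: MiningThresholds | None = None
) -> ReferenceBundle:
    """Build the reference genome, its annotation, and the planted truth.

    Deterministic for a fixed seed; independent of the genotype-level
    configuration fields (variant_rate etc.).
    """
    thresholds = thresholds or MiningThresholds()
    rng = np.random.default_rng([config.seed, 0])
    records: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    truth: list[PlantedLocus] = []

    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        plans = _plan_chromosome(rng, config, thresholds)
        tracts = []
        for plan in plans:
            seq, gap_seq = _tract_seq(plan, rng)
            plan["gap_seq"] = gap_seq
            tracts.append(seq)

        for attempt in range(200):
            # assemble: background between anchored tracts
            parts = []
            cursor = 0
            prev_guard: str | None = None
            planted: list[PlantedLocus] = []
            for li, (plan, tract) in enumerate(zip(plans, tracts)):
                start0 = plan["anchor"]  # 0-based tract start
                parts.append(
                    _random_dna(
                        rng,
                        start0 - cursor,
                        first_not=prev_guard,
                        last_not=plan["components"][0][0][-1],
                    )
                )
                parts.append(tract)
                prev_guard = plan["components"][-1][0][0]
                cursor = start0 + len(tract)
                locus_id = f"{chrom}:{start0 + 1}-{cursor}"
                planted.append(
                    PlantedLocus(
                        locus_id=locus_id,
                        seq_id=chrom,
                        start=start0 + 1,
                        end=cursor,
                        motif="+".join(m for m, _ in plan["components"]),
                        repeat_count=(
                            None if plan["compound"] else plan["components"][0][1]
                        ),
                        is_compound=plan["compound"],
                        region=plan["region"],
                        gene_id=(
                            f"{chrom}.g{li + 1}"
                            if plan["region"] != INTRON_INTERGENIC
                            else None
                        ),
                        components=plan["components"],
                        gap=plan["gap"],
                    )
                )
            parts.append(
                _random_dna(rng, config.chrom_length - cursor, first_not=prev_guard)
            )
            seq = "".join(parts)
            record = SequenceRecord(chrom, seq)
            if _expected_mined(planted, mine_record(record, thresholds)):
                break
        else:
            raise RuntimeError(f"could not build a clean background for {chrom}")

        records.append(record)
        truth.extend(planted)
        for li, (plan, p) in enumerate(zip(plans, planted)):
            gene = _gene_for(plan, (p.start + p.end) // 2, chrom, f"{chrom}.g{li + 1}")
            if gene is not None:
                genes.append(gene)
    return ReferenceBundle(records=records, genes=genes, truth=truth)


def _variant_components(
    rng, planted: PlantedLocus, cfg: SimConfig, thresholds: MiningThresholds
) -> tuple[tuple[tuple[str, int], ...], bool]:
    """Apply a repeat-count delta to one component; returns (components,
    below_threshold)."""
    comps = list(planted.components)
    idx = int(rng.integers(0, len(comps))) if len(comps) > 1 else 0
    motif, count = comps[idx]
    lo = thresholds.min_repeats[len(motif)]
    deltas = [d for d in range(-cfg.max_delta, cfg.max_delta + 1) if d != 0]
    if not cfg.allow_subthreshold:
        deltas = [d for d in deltas if count + d >= lo]
    delta = int(rng.choice(deltas))
    comps[idx] = (motif, count + delta)
    return tuple(comps), (count + delta) < lo


def simulate_genotypes(
    reference: ReferenceBundle,
    config: SimConfig,
    thresholds: MiningThresholds | None = None,
) -> list[GenotypeBundle]:
    """Emit per-genotype contig sets plus the intended truth calls.

    Each covered locus yields one contig: the reference sequence
    ``contig_pad`` bp either side of the tract, with the tract possibly
    rebuilt at a varied repeat count. Optionally a signature flank receives
    one substitution (truth becomes absent) or the contig is emitted
    reverse-complemented (truth unchanged, strand '-').
    """
    thresholds = thresholds or MiningThresholds()
    genome = {r.id: r for r in reference.records}
    bundles = []
    for gi in range(config.n_genotypes):
        genotype_id = f"G{gi + 1:02d}"
        rng = np.random.default_rng([config.seed, 1, gi])
        contigs: list[SequenceRecord] = []
        calls: list[TruthCall] = []
        for li, planted in enumerate(reference.truth):
            if rng.random() >= config.coverage:
                calls.append(
                    TruthCall(planted.locus_id, genotype_id, "absent", reason="uncovered")
                )
                continue
            ref_seq = genome[planted.seq_id].seq
            left = ref_seq[planted.start - 1 - config.contig_pad : planted.start - 1]
            right = ref_seq[planted.end : planted.end + config.contig_pad]

            status = "monomorphic"
            comps = planted.components
            below = False
            if rng.random() < config.variant_rate:
                comps, below = _variant_components(rng, planted, config, thresholds)
                status = "polymorphic"
            if planted.is_compound:
                (m1, _), (m2, _) = planted.components
                ref_gap_start = planted.start - 1 + len(
                    _tract(m1, planted.components[0][1])
                )
                gap_seq = ref_seq[ref_gap_start : ref_gap_start + planted.gap]
                tract = _tract(*comps[0]) + gap_seq + _tract(*comps[1])
            else:
                tract = _tract(*comps[0])

            contig_seq = left + tract + right
            geno_count = None if planted.is_compound else comps[0][1]
            geno_tract = len(tract)

            reason = None
            if below:
                status, reason = "absent", "below_threshold"
            elif config.flank_mutation_rate > 0 and rng.random() < config.flank_mutation_rate:
                # one substitution mid-flank (positions 5..15 from the tract)
                side_left = rng.random() < 0.5
                offset = int(rng.integers(5, 16))
                pos = (
                    len(left) - offset
                    if side_left
                    else len(left) + len(tract) + offset - 1
                )
                old = contig_seq[pos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                contig_seq = contig_seq[:pos] + new + contig_seq[pos + 1 :]
                status, reason = "absent", "flank_mutation"

            strand = "+"
            if rng.random() < config.strand_flip_prob:
                contig_seq = revcomp(contig_seq)
                strand = "-"

            contigs.append(SequenceRecord(f"{genotype_id}_c{li + 1}", contig_seq))
            if status == "absent":
                calls.append(
                    TruthCall(planted.locus_id, genotype_id, "absent", reason=reason)
                )
            else:
                calls.append(
                    TruthCall(
                        planted.locus_id,
                        genotype_id,
                        status,
                        genotype_repeat_count=geno_count,
                        genotype_tract_length=geno_tract,
                        strand=strand,
                    )
                )
        bundles.append(GenotypeBundle(genotype_id, contigs, calls))
    return bundles
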