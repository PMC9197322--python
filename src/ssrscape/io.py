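"""Readers and writers for FASTA, GFF3 and the tab-separated report tables.

All emitted tables are UTF-8 TSV with a single header row; coordinates in
every emitted file are 1-based inclusive (noted in a leading comment line).
FASTA output is wrapped at 60 columns; gzip-compressed FASTA input is
accepted transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel, GeneModelError, RegionAssignment
from .flanks import PrimerPair
from .mining import SSRLocus, SequenceRecord
from .polymorphism import PolymorphismCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_misa_tsv",
    "read_misa_tsv",
    "write_primer_tsv",
    "read_primer_panel",
    "write_calls_tsv",
    "write_assignments_tsv",
    "write_validation_tsv",
]

COORD_COMMENT = "# coordinates: 1-based inclusive\n"


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzip-compressed) multi-FASTA; residues upper-cased."""
    with _open_text(path) as handle:
        return [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write 60-column-wrapped FASTA (byte-stable round trip)."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into strand-aware gene models.

    The ID/Parent hierarchy is resolved with gffutils. Exons without a
    resolvable parent raise GeneModelError. A gene without transcript
    children is modelled as one exon spanning the gene.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_parents = {f.id for f in db.all_features() if f.featuretype in ("gene", "mRNA")}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not set(parents) & known_parents:
            raise GeneModelError(f"exon at {exon.seqid}:{exon.start} has no known parent")

    models = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for exon in db.children(mrna, featuretype="exon"):
                exons.append((exon.start, exon.end))
        if not exons:  # direct exon children, or none at all
            exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=tuple(sorted(set(exons))),
            )
        )
    models.sort(key=lambda g: (g.seq_id, g.start, g.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.start, g.gene_id)):
            fh.write(
                f"{g.seq_id}\tssrscape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.seq_id}\tssrscape\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\tssrscape\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.e{i};Parent={mrna_id}\n"
                )


MISA_COLUMNS = ("ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end")


def write_misa_tsv(loci: Sequence[SSRLocus], path: str | Path) -> None:
    """MISA-style locus table: ID, SSR nr., SSR type, SSR, size, start, end."""
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("\t".join(MISA_COLUMNS) + "\n")
        counters: dict[str, int] = {}
        for locus in loci:
            counters[locus.seq_id] = counters.get(locus.seq_id, 0) + 1
            fh.write(
                "\t".join(
                    [
                        locus.seq_id,
                        str(counters[locus.seq_id]),
                        locus.ssr_class,
                        locus.ssr_string,
                        str(locus.tract_length),
                        str(locus.start),
                        str(locus.end),
                    ]
                )
                + "\n"
            )


def read_misa_tsv(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                continue
            rows.append(dict(zip(header, fields)))
    return rows


def write_primer_tsv(
    rows: Sequence[tuple[str, PrimerPair]], path: str | Path
) -> None:
    cols = (
        "locus_id, forward, reverse, tm_f, tm_r, gc_f, gc_r, "
        "product_size, start, end"
    ).split(", ")
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("\t".join(cols) + "\n")
        for locus_id, p in rows:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            locus_id,
                            p.forward,
                            p.reverse,
                            p.tm_f,
                            p.tm_r,
                            p.gc_f,
                            p.gc_r,
                            p.product_size,
                            p.fwd_start or "",
                            p.rev_end or "",
                        ],
                    )
                )
                + "\n"
            )


def read_primer_panel(path: str | Path) -> list[PrimerPair]:
    """Read an (id, forward, reverse) TSV panel; header row optional."""
    from .flanks import gc_percent, wallace_tm

    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, fwd, rev = line.split("\t")[:3]
            if pid.lower() in ("id", "pair_id", "primer_pair_id"):
                continue
            fwd, rev = fwd.upper(), rev.upper()
            pairs.append(
                PrimerPair(
                    forward=fwd,
                    reverse=rev,
                    tm_f=wallace_tm(fwd),
                    tm_r=wallace_tm(rev),
                    gc_f=gc_percent(fwd),
                    gc_r=gc_percent(rev),
                    product_size=0,
                    pair_id=pid,
                )
            )
    return pairs


def write_calls_tsv(
    calls: Sequence[PolymorphismCall],
    path: str | Path,
    hypervariable_ids: set[str] | None = None,
) -> None:
    cols = (
        "ref_locus_id, genotype, status, ref_count, geno_count, "
        "strand, hypervariable"
    ).split(", ")
    hv = hypervariable_ids or set()
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.ref_locus_id,
                        c.genotype_id,
                        c.status,
                        "" if c.ref_repeat_count is None else str(c.ref_repeat_count),
                        ""
                        if c.genotype_repeat_count is None
                        else str(c.genotype_repeat_count),
                        c.matched_strand or "",
                        "1" if (c.ref_locus_id, c.genotype_id) in hv else "0",
                    ]
                )
                + "\n"
            )


def write_assignments_tsv(
    assignments: Sequence[RegionAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("locus_id\tcategory\tgene_id\n")
        for a in assignments:
            fh.write(f"{a.locus_id}\t{a.category}\t{a.gene_id or ''}\n")


def write_validation_tsv(rows: Sequence[Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("primer_pair_id\tstatus\tloci\tn_placements\tproduct_sizes\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        str(r["primer_pair_id"]),
                        str(r["status"]),
                        ",".join(r["loci"]),
                        str(r["n_placements"]),
                        ",".join(map(str, r["product_sizes"])),
                    ]
                )
                + "\n"
            )
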