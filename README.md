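# ssrscape

Genome-wide microsatellite (SSR) discovery and GBS-based polymorphic SSR
calling, as a tested Python library and CLI:

* **Mining** — maximal perfect SSRs of unit length 1–6 under per-unit minimum
  repeat counts (defaults: mono ≥10, di ≥6, tri/tetra/penta/hexa ≥5), with
  merging of neighbouring tracts ≤100 bp apart into compound loci (MISA-style
  `p1..p6 / c / c*` classes and TSV output).
* **Statistics** — per-class and per-chromosome counts, motif frequency
  tables, densities per Mb and mean inter-SSR spacing in Kb (reciprocal by
  construction), and sequencing-library panel means.
* **Polymorphism calling** — the core computation: reference loci are keyed
  by their exact 20-nt 5′/3′ flanking sequences plus motif; genotype contigs
  are mined on both orientations and matched by that key. Equal repeat count
  → monomorphic, different count → polymorphic, no hit → absent, conflicting
  hits → ambiguous; hypervariable = polymorphic with a ≥20 nt tract on either
  side. Panel aggregation counts distinct reference loci with
  polymorphic-precedence.
* **Genomic context** — midpoint assignment of loci to promoter
  (TSS −1 kb…+100 bp), TTS (TES −100 bp…+1 kb), exon, or intron+intergenic
  (strand-aware, priority in that order) from a GFF3 annotation, plus
  locus→gene association.
* **Primer design** — constrained picker (length 18–27 bp, Wallace-rule Tm
  57–63 °C, GC 30–70 %, product 100–300 bp) ranked by Tm balance then product
  size closest to 200 bp.
* **e-PCR** — exact, full-length, convergent placement of primer pairs
  within ±200 bp windows around catalogued SSRs, with role-swapped search and
  multi-mapping reported.
* **Simulation** — deterministic synthetic references with planted SSR
  landscapes and gene annotations, plus genotype contig sets with planted
  repeat-number variants, flank mutations and strand flips, emitted together
  with their truth tables.

## CLI

```sh
ssrscape simulate --seed 7 --out simdata/           # synthetic data + truth
ssrscape mine simdata/reference.fasta -o loci.tsv   # MISA-style locus table
ssrscape stats simdata/reference.fasta -o stats     # class + density tables
ssrscape annotate simdata/reference.fasta simdata/annotation.gff3 -o regions.tsv
ssrscape call simdata/reference.fasta simdata/G01.fasta simdata/G02.fasta -o calls
ssrscape epcr simdata/reference.fasta panel.tsv -o validation.tsv
ssrscape report simdata/reference.fasta --gff3 simdata/annotation.gff3 -o report.json
```

All emitted tables are UTF-8 TSV with 1-based inclusive coordinates; every
numeric default can be overridden through a YAML config passed with
`--config` (see `ssrscape.config.RunConfig`).

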