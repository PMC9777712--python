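# mitochar

Characterization toolkit for insect mitochondrial genomes.

A newly assembled mitogenome — a circular molecule of roughly 16 kb carrying
13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one AT-rich control
region (CR) — is routinely described by the same battery of analyses:
organization metrics from the gene coordinate table, nucleotide composition
and strand asymmetry, codon usage, CR repeat structure, and tRNA secondary
structure. `mitochar` implements that battery as a reusable, tested library
with a thin command-line interface, for researchers who want those numbers
recomputed reproducibly from a FASTA plus a coordinate table instead of
assembled by hand from assorted web tools. It ships the published gene table
of the *Galerita orientalis* mitogenome (GenBank ON920164.1, 16,137 bp) as a
reference layout, and a synthetic-genome generator that emulates that
genome's statistical structure so every stage is testable without any
download.

## What it computes

- **Organization metrics** (`annotation_metrics`) — per-gene sizes
  (end − start + 1 under 1-based inclusive coordinates), intergenic
  nucleotides between consecutive features (negative = overlap, positive =
  spacer, with the origin-wrapping pair included), overlap/spacer totals and
  extremes, and the strand partition of gene classes.
- **Composition and skews** (`composition`) — base counts, AT/GC content,
  and the Perna–Kocher strand-asymmetry statistics
  AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), for the whole
  genome or any feature on either strand. Both skews change sign exactly
  under reverse complement; undefined skews are NaN, never 0.
- **Codon usage and RSCU** (`codon_usage`) — CDS extraction honoring
  mitochondrial conventions (ATN/TTG starts; complete TAA/TAG stops or
  incomplete terminal T completed by mRNA polyadenylation), translation
  under NCBI genetic code 5 (invertebrate mitochondrial: ATA→Met, TGA→Trp,
  AGA/AGG→Ser), internal-codon counting (start and stop excluded), and
  relative synonymous codon usage RSCU(c) = count(c) · |family| / Σ family.
- **Control-region scanning** (`repeat_scan`) — a simplified Benson-style
  tandem-repeat detector (TRF-convention weights +2/−7/−7, minimum score 50,
  maximum period 500), leftmost-maximal homopolymer runs, and
  microsatellite arrays with ≤1 interruption.
- **tRNA cloverleaf checks** (`trna_fold`) — template-anchored folding that
  anchors the anticodon loop, extends the four stems (acceptor 6–8 bp,
  DHU 0–5, anticodon 3–8, TΨC 3–6) allowing G–U wobbles and one
  non-canonical apposition (U–U, A–G, other) per stem, and reports stem
  lengths, a missing DHU arm, and pair classes.
- **Phylogenetic data preparation** (`phylo_prep`) — concatenation of
  per-gene alignments into a partitioned supermatrix, Gblocks-style removal
  of ambiguously aligned columns, and a neighbor-joining sanity tree on
  p-distances (NJ exactly recovers additive distance matrices; it is a data
  sanity check, not a substitute for Bayesian/ML inference).
- **Synthetic data** (`synthetic_data`) — a deterministic generator that
  plants PCGs, tRNAs with known pairing, CR repeats, a poly-T stretch and a
  microsatellite into a genome with target composition, and returns a
  manifest predicting every downstream result.

## Worked example

Generate the default synthetic genome (which reproduces the reference gene
layout and composition targets) and run the pipeline on it:

```
$ mitochar synth --seed 1 --out-prefix s
wrote s.fasta / .tsv / .manifest.json

$ mitochar table --out table.tsv
# overlaps: 13 pairs, 45 bp (max (('trnY', 'cox1'), 8)); spacers: 9 regions, 55 bp (max (('trnW', 'trnC'), 26))

$ mitochar codon --genome s.fasta --annotation s.tsv --out rscu.tsv
# 3714 internal codons; starts {'ATA': 1, 'ATT': 5, 'ATG': 5, 'ATC': 1, 'TTG': 1}; stops {'TAA': 6, 'T': 4, 'TAG': 3}

$ mitochar cr --genome s.fasta --annotation s.tsv --out repeats.tsv
# CR 1327 bp, AT 88.09%; 7 repeats, 238 bp (17.94% of CR); poly-T 19 bp at 111
```

Reading the output: the 13 PCGs carry 3714 internal codons between their
start and stop codons, with one ATA start (nad2), one TTG (nad1) and four
genes ending on an incomplete T stop — the start/stop pattern of the
reference mitogenome. The 1327 bp control region carries seven tandem
repeats totaling 238 bp (17.94% of the CR), a conserved 19 bp poly-T
stretch and a (TA)24 microsatellite. The organization summary reports 13
overlapping gene pairs totaling 45 bp (the largest, 8 bp, between trnY and
cox1). Note the 26 bp trnW–trnC spacer: the published table's location
column genuinely implies it, even though its intergenic column prints 2 —
`mitochar` reports what the coordinates say and exposes
`OrganizationSummary.compare_expected` to flag such disagreements.

## Layout

```
src/mitochar/
  genome_io.py           FASTA/GenBank/TSV I/O, circular region extraction
  annotation_metrics.py  sizes, overlaps/spacers, organization summary
  composition.py         base counts, AT/GC content, skews
  codon_usage.py         CDS extraction, code-5 translation, RSCU
  repeat_scan.py         tandem repeats, poly-T runs, microsatellites
  trna_fold.py           cloverleaf template folding and pair classes
  phylo_prep.py          supermatrix, column trimming, NJ tree
  synthetic_data.py      synthetic genome generator + manifest
  datasets.py            bundled reference gene table
  cli.py                 `mitochar` command-line interface
```

See `docs/methods.md` for the models, conventions and numerical choices.
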