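# Methods

This note documents the conventions, algorithms and design choices behind
each stage of the pipeline, what the synthetic generator does and does not
emulate, and the numerical edge cases.

## Coordinates, strands and the reference layout

All coordinates are 1-based and inclusive, the convention of GenBank
feature tables and published mitogenome organization tables. The genome is
stored linearized at the conventional origin (base 1 = first base of trnI);
the region extractor supports origin-wrapping coordinates (`start > end`)
on circular genomes, and `linearize()` rotates a genome whose deposited
sequence starts elsewhere, but no feature wraps the origin in the bundled
reference layout. The majority ("J") strand is identified with the sequence
as deposited; minority ("N") strand features are analyzed on their reverse
complement.

The bundled reference table is the published gene organization of the
*Galerita orientalis* mitogenome (GenBank ON920164.1): 13 PCGs, 22 tRNAs,
2 rRNAs and one control region over 16,137 bp. One caveat a user should
know: the published table is internally inconsistent at trnW→trnC — its
location column implies a 26 bp spacer while its intergenic column prints
2. The location column is the self-consistent side (printed sizes minus
overlaps plus coordinate-derived spacers tile the 16,137 bp circle
exactly), so all derived quantities here follow coordinates. The
organization summary deliberately never "corrects" toward published prose;
`compare_expected()` surfaces disagreements instead.

## Organization metrics

Intergenic nucleotides are computed on consecutive table-order pairs only
(start(downstream) − end(upstream) − 1; negative = overlap), matching how
organization tables are printed, not by all-vs-all interval intersection;
pairs on opposite strands are treated identically. For circular genomes the
wrap pair (last feature, first feature) is included with value
start(first) + L − end(last) − 1. Ties for the maximum overlap or spacer
break to the earliest genome position. The tiling identity
Σ sizes + Σ spacings = L holds exactly for a complete table and is asserted
in the tests.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C). N bases are excluded
from every denominator; a zero denominator yields NaN (never 0, which would
wrongly suggest perfect symmetry). Both skews are exactly antisymmetric
under reverse complement — a property test, not an approximation. Reports
round percentages to 2 decimals and skews to 3 (the precision such tables
are printed at) while retaining full precision in machine-readable columns.
Per-feature statistics default to the feature's own sense strand — the
convention under which rRNA "AU-skews" are reported — with a `strand_mode`
switch to stay on the deposited strand.

## Codon usage

CDS extraction takes the sense-strand sequence at the annotated
coordinates. Stops are classified from length mod 3 and the terminal bases:
a complete TAA/TAG at length ≡ 0, or an incomplete terminal T (length ≡ 1)
or TA (≡ 2) completed to TAA by polyadenylation of the mRNA; incomplete
stops are never padded for counting. An unusual first triplet warns rather
than fails, since rarer starts (CGA, TAT) occur in related mitogenomes.

Codon counting is over *internal* codons: the start codon and the
(complete or incomplete) stop are both excluded, so a complete-stop gene of
size s contributes s/3 − 2 codons and a T-stop gene ⌊s/3⌋ − 1. This
accounting was chosen because it reproduces published internal-codon totals
exactly from table sizes alone (the bundled layout yields 3714). Synonymous
families follow NCBI genetic code 5 via Biopython's codon table: Met is
{ATG, ATA} (internal ATA counts toward Met), Leu has 6 codons, Ser 8
(including AGA/AGG). RSCU(c) = count(c) × family size / family total;
within any used family the values sum to the family size, and an unused
family is NaN. Display uses the RNA alphabet (UUA), computation the DNA
alphabet.

## Tandem repeats, homopolymers and microsatellites

The tandem-repeat detector is a simplified Benson-style scanner, not a
bit-exact Tandem Repeats Finder reimplementation. For each period p up to
`max_period`, self-alignment at lag p is segmented by a Kadane scan
(+match_weight per match, −mismatch_penalty per mismatch); each candidate
is refined against its majority-vote consensus by repeatedly taking the
maximum-scoring subarray in a window one period beyond the current
boundaries (this both trims spurious flanks and extends into adjacent
copies, and cleanly separates abutting structures such as a poly-T run next
to a (TA)n array). Candidates below `min_alignment_score`, above
`max_period`, or under `min_copies` copies are discarded. The alignment is
gap-free: the indel penalty is accepted for interface parity with
TRF-convention parameter strings ("2 7 7 80 10 50 500") but no indels are
modeled, and TRF's probabilistic match/indel criteria (80/10) are replaced
by the deterministic score threshold. Consequently repeat sets on real
control regions may differ from TRF's; the supported accuracy contract is
recovery of arrays with known coordinates, which the tests exercise via the
generator. Overlapping reports with genuinely different periods are all
retained; a report is dropped only when a containing report whose period
divides its own explains it (a period-p array trivially re-seeds at lag
2p). With the default score threshold of 50 and match weight 2, an array
needs ~25 matching bases to be reportable at all — short perfect arrays
such as (TA)10 are below threshold by design.

Homopolymer runs are leftmost-maximal (verified against a brute-force
oracle). Microsatellites are maximal perfect motif arrays, with two perfect
runs separated by at most motif-length bases merged into one near-perfect
array (≤1 interruption); up to 25 bp of left-flanking context is attached,
which is how the conserved poly-T stretch upstream of the (TA)n element is
reported.

## tRNA cloverleaf checking

Folding is template-anchored, not thermodynamic: the testable claims about
mitochondrial tRNAs are stem lengths, a present/absent DHU arm, the
anticodon position and the classes of non-canonical pairs, all of which a
template matcher recovers deterministically. The anticodon loop is fixed at
7 nt with the annotated anticodon central (the occurrence nearest the
sequence midpoint anchors the fold if it occurs twice). The anticodon stem
extends greedily outward from the loop; the acceptor stem pairs inward from
the termini, trying 0–4 unpaired 3′ tail bases and keeping the
most-paired, least-mismatched, shortest-tail variant; the DHU and TΨC arms
are the maximal hairpins in the regions between (ranked by stem length,
then fewest mismatches, then leftmost). G–U wobbles count as pairs; one
non-pairing apposition per stem is tolerated and classified (U–U, A–G,
other), never at a hairpin terminus. Stem-length search ranges reflect
observed mitochondrial variation: acceptor 6–8, DHU 0–5 (0 = arm replaced
by a loop, as in many metazoan trnS1 genes), anticodon 3–8, TΨC 3–6. A
sequence with no template-consistent arrangement returns an explicit
fold-failure result with the reason.

## Supermatrix preparation and the NJ sanity tree

Gene alignments are concatenated over the union taxon set (missing taxa
gap-padded with a warning) with a partition map. Trimming is
Gblocks-inspired, not bit-compatible: columns above `max_gap_fraction`
(default 0.5) are dropped; remaining columns are "conserved" when the most
frequent residue reaches `min_conserved_fraction` (0.5) of the rows; and
conserved columns are kept only in runs of at least `min_block_length` (10)
— with runs measured within each gene partition, which makes trimming
independent of gene concatenation order and idempotent. The tree is
Saitou–Nei neighbor joining on p-distances with pairwise deletion of gapped
sites, chosen for determinism and zero model burden; negative branch-length
estimates are clipped to zero. NJ exactly recovers additive distance
matrices (tested against patristic distances of random trees, with dendropy
as the independent oracle) and recovers the generating topology (RF = 0) on
low-divergence simulated alignments. It is a data sanity check: model
selection, Bayesian and maximum-likelihood inference, and bootstrap support
belong to dedicated phylogenetics software.

## The synthetic generator

The generator's defaults emulate the reference mitogenome's study
conditions: the published gene layout verbatim (so the annotation fixture
and the synthetic genome share one source of truth), 78.79% AT with skews
0.037/−0.202 genome-wide, an 88.62% AT control region carrying a 19 bp
poly-T stretch, a (TA)24 microsatellite, and seven planted tandem repeats
with (period, copies) = (10,3), (2,24), (16,2.5), (7,4), (9,3), (6,4.5),
(19,2) — 238 bp in total, with the (TA)24 array second and the poly-T
immediately left of it, mirroring the published control-region
organization. The reference's TR3–TR6 overlap one another; their
coordinates were published only graphically, so the defaults plant
non-overlapping arrays and overlapping detection is exercised separately by
the period-multiple retention rule.

Construction details that make the manifest exact ground truth:

- Background (intergenic, rRNA, CR) is drawn from the factorized per-base
  distribution p_A = at·(1 + skew_AT)/2 etc. The non-CR AT target is
  analytically lowered so that the genome-wide expectation, CR included,
  equals the requested content; genome-wide values are targets in
  expectation with binomial noise, and the tests use binomial tolerances
  (3·√(p(1−p)/L)).
- PCG internal codons are drawn from the non-stop codons of code 5 with a
  fixed-point-adjusted base distribution whose conditional per-base
  marginal matches the target (naively excluding the AT-rich stop codons
  would depress AT content). The no-internal-stop property is therefore
  exact by construction. Declared start/stop codons are written first;
  codons overlapping them or other genes are drawn conditioned on the
  already-planted bases, which reconciles every overlap in the layout
  (e.g. atp8/atp6, nad4/nad4l) without violating any declared codon.
- tRNAs are assembled arm-by-arm with exact complementary stems; loops and
  spacers are then adjusted by check-driven surgical repair until the
  planted structure is the unique template optimum (no spurious anticodon
  anchor, no over-extendable stem, no competing hairpin). Bases at guard
  positions are chosen from the non-pairing alternatives weighted by the
  target distribution so the repairs do not drift composition. A tRNA
  overlapped at both ends by neighbors can have a stem pair pinned to
  non-pairing bases; that conflict is absorbed as the stem's single
  tolerated mismatch when positionally legal, or the neighboring gene's
  codon is redrawn.
- Planted repeat arrays get mismatching guard bases at their flanks so
  detected boundaries equal planted boundaries, and chance background
  structure that would compete with the planted features (arrays above the
  score threshold, stray motif copies adjacent to the microsatellite,
  near-threshold T runs) is broken by single-base edits.

Everything is deterministic given the spec's seed. What the generator does
*not* emulate: real codon-usage bias beyond composition (per-codon counts
are draws, so e.g. the exact Leu/Ile/Phe counts of the deposited genome are
not reproduced, only the totals fixed by the layout), sequencing error,
heteroplasmy, rRNA secondary structure, and overlapping repeat arrays.
Passing tests on synthetic genomes therefore validate the pipeline's
bookkeeping and detection contracts, not its agreement with any particular
deposited sequence.

`simulate_alignment` evolves gapless sequences by Jukes–Cantor site
substitution along a newick tree (per-edge change probability
¾(1 − e^(−4d/3))), sufficient for testing concatenation, trimming and NJ
recovery; it models no indels, rate heterogeneity or compositional bias.

## Problem sizes

The default test suite and the acceptance script run on one 16,137 bp
synthetic genome, control-region scans of ~1.3 kb, and 13 simulated gene
alignments of 300 columns over 8 taxa — sizes at which every stage is
exact or statistically stable while the whole suite completes in seconds.

## Known limitations

- The repeat detector is substitution-only; arrays whose copies differ by
  indels are found only as shorter sub-arrays.
- The cloverleaf matcher trusts the annotated anticodon; it does not do
  de-novo tRNA detection or covariance-model scoring.
- Gblocks compatibility is approximate by design; published
  position-count reductions from specific Gblocks runs are not
  reproduced.
- The NJ tree is unrooted, unsupported (no bootstrap) and intended purely
  as a preparation sanity check.
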