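# Methods

This note documents the models, conventions and numerical choices behind
`mitokit`, in the order a typical analysis runs.

## Coordinates and circular topology

All public coordinates are 1-based inclusive. A circular genome is stored as
a linear string cut at its deposited origin; extraction across the origin is
expressed as `start > end` and implemented on the doubled string. Repeat and
recombination machinery treats the genome as linear at that origin —
origin-spanning repeats can be sought by re-running on a rotated copy — and
conformation identity uses a canonical circular form: the lexicographically
least rotation (Booth's algorithm) of the lesser of the sequence and its
reverse complement. This makes "same molecule up to rotation and strand"
decidable and cheap to test.

## Codon usage

Codon counting pools all supplied coding sequences (by default every
annotated PCG copy, including duplicated genes). Counts are reported in the
RNA alphabet. RSCU for codon *c* in family *F* is
`count(c) · |F| / Σ_{F} count`; families with zero total get 0 throughout,
single-codon families (AUG, UGG) are exactly 1 when observed. The standard
genetic code is the default — plant mitochondria translate with it — and the
three stop codons form one 3-member family by default (`include_stops=True`)
so stop-codon preference is a defined quantity. Codons containing N are
skipped with a warning rather than guessed. Non-AUG starts (ACG, TTG occur
in edited plant mitochondrial genes) are accepted; a coding length not
divisible by three is trimmed with a warning, never a hard failure. Tabular
output rounds RSCU to 2 decimals; internal values keep full precision.

## SSRs

Maximal perfect runs of a 1–6 bp unit meeting the per-class minimum copies
(10, 5, 4, 3, 3, 3). A run whose unit is a whole-number repetition of a
shorter unit is reported only under the shortest unit; a trailing partial
copy is trimmed so `end − start + 1 = unit · copies`. Compound-SSR merging
(joining runs within 100 bp, as MISA does) is deliberately not applied: each
maximal run is one record, which slightly inflates counts relative to
merged reports.

## Tandem repeats

A deterministic lag-correlation scan: for each period *p* (default 2–100),
maximal stretches where the sequence matches itself at lag *p* with
≥ 85 % identity and span ≥ max(9, 2p) are candidates; overlapping candidates
resolve to highest identity, then smallest period. This reproduces the
output contract of tandem finders, not the stochastic alignment model of
TRF — TRF's score thresholds suppress marginal short-period hits that this
scan reports, so absolute tandem counts are not comparable across engines
(and are not treated as a reproduction surface). The span floor of 9 bp
admits the shortest arrays reported for real mitogenomes.

## Dispersed repeats

The maximal-pair finder reproduces the REPuter output contract: pairs of the
four orientation classes — for copies (A, B): forward `B = A`, reverse
`B = reverse(A)`, complement `B = complement(A)`, palindromic
`B = revcomp(A)` — with ≤ 3 mismatches (Hamming, ungapped) and length
≥ 30 bp, top 5000 by length.

Engine: exact k-mer seeding with `k = ⌈(min_len − mm) / (mm + 1)⌉` (the
pigeonhole bound: any qualifying pair contains an exact run of that length;
note the `−mm` in the numerator, without which evenly spread mismatches can
evade seeding), then ungapped extension on the pair's diagonal
(forward/complement) or anti-diagonal (reverse/palindromic). From each seed,
all maximal ≤ mm-mismatch windows are enumerated by splitting the budget
between the two ends. Conventions:

- **Core trimming.** Each maximal window is reported by its matching core
  (mismatching boundary columns trimmed). Overlapping maximal windows of the
  same physical repeat then collapse to one record, and coordinates are
  independent of how the budget happened to be split.
- **Half-domain arms.** For reverse/palindromic pairs the scan runs on the
  half of the anti-diagonal where arm A lies left of the mirror centre, so
  arms can touch but never self-overlap; centre-crossing hairpins appear as
  touching arms.
- **Dedup and filters.** Each unordered pair is reported once (copy1 is the
  lexicographically earlier interval); pairs whose copies overlap by more
  than half their length are dropped as tandem-like; ties under the report
  cap break by length desc, start1, start2.

The test suite holds this engine equal to an independent all-diagonal
brute-force oracle on kilobase genomes for budgets 0–4.

## Recombination

Candidate selection takes forward (→ direct) and palindromic (→ inverted)
pairs ≥ 200 bp, labels them R1, R2, … by descending length, and attaches
1000 bp flanks (the CRS). Overlapping copies disqualify a pair.

**Events.** The crossover point inside a repeat copy is its midpoint; for
non-identical copies the recombinant repeat takes copyA's left half and
copyB's right half. On the current conformation the pair's copies are
re-located by exact search over the possible repeat variants (originals and
midpoint hybrids, both strands) rather than by coordinate arithmetic, so
events compose correctly after earlier inversions have moved or flipped a
copy. Same molecule + opposite strands → inversion of the inter-midpoint
segment; same strand → fission at the midpoints; copies on two molecules →
fusion (rotate each to its midpoint, concatenate). Total length is conserved
by construction, and inversion (and fission/fusion) are involutions —
both are asserted in tests.

**Enumeration.** One conformation per subset of pairs, events applied in
label order (2^k subsets, capped at 12 pairs). C1 is the empty subset — the
major conformation, identical to the master. Subsets whose chain becomes
inapplicable are flagged unreachable; canonically identical results of
different subsets are flagged duplicates. Both the subset count and the
single-event count are available from the output.

**Junctions and read support.** For each pair, refA/refB reproduce the
master across each copy with its flanks; recA/recB exchange flanks (B-side
flanks reverse-complemented for inverted pairs so all four junctions share
copyA's strand). Each recombinant junction occurs verbatim, up to strand, in
the molecules of the conformation its event creates (cross-checked in
tests). A read supports a junction when the probe — the repeat (or hybrid)
core plus `min_span` bases of both flanks — aligns within the read at
identity ≥ 0.95, where identity = matching columns / alignment columns of a
banded edit-distance alignment (edlib, both strands); "over 95 %" is
implemented as ≥ 0.95. `min_span` defaults to 100 bp: junction-crossing
evidence requires reaching well into both flanks, and 100 bp stays below
common PCR-validation flank lengths (200 bp). Each read is assigned only to
its best junction (ties resolve refA, refB, recA, recB).

**Type taxonomy.** Identical pairs take subtype 1 (direct) or 2 (inverted);
non-identical pairs one of six indices defined as orientation ×
recombinant-arrangement. The six-way indexing is a provisional convention of
this package.

## Transferred DNA and collinearity

Both modules use NCBI BLASTN (`-task blastn`, word size 11, +1/−2, dust and
soft-masking off for determinism) in query/subject mode — the canonical
engine for this step. Transfers: alignments with E ≤ 1e-5 and span ≥ 30 bp,
one fragment per alignment (no chaining or merging, so fragment counts and
per-fragment gene lists coexist), labelled MTPTn/NUMTn by descending length;
the trivial full-length self-alignment is excluded in self-comparison; a
multi-record donor (nuclear assembly) keeps per-record coordinates with
globally ordered labels. Totals are unions of recipient intervals, reported
to 2 decimals as percentages of either genome. Gapped extension can run a
few bases past a planted segment boundary and trims mismatching ends, so
planted-truth recovery is asserted as ≥ 98 % reciprocal coverage rather
than exact endpoints. Collinear blocks are the same alignments filtered to
≥ 500 bp (inverted when strands differ), without collinear chaining — block
order across genomes reveals rearrangement directly. Shared-PCG export takes
the intersection of PCG names (first copy by coordinate, logged), writes
per-gene FASTA, a concatenated supermatrix in alphabetical gene order, and a
RAxML-style partition table; alignment and tree inference are external by
design.

## Synthetic studies

The generator writes i.i.d. background at the configured GC (default 44.1 %,
the Rosaceae mitogenome range) on a default 50 kb circle — a deliberate
desk-scale stand-in for a ~439 kb genome that preserves every structural
property the methods exercise — then plants features at non-overlapping
positions with margins:

- **Divergence guards.** Planted repeats are bordered by 8 forced
  pair-mismatch columns (period-breaking bases around SSR/tandem runs,
  class-geometry mismatches around dispersed copies), so the planted
  coordinates are exactly the matching-core coordinates the finders report.
  Without guards, chance flank matches extend every maximal window a few
  bases past the planted interval and "exact recall" would be ill-posed.
- **Tandem units** are redrawn until primitive and free of internal
  sub-period structure, since the finder's overlap resolution would
  otherwise report the internal call.
- **Genes** are ATG + random sense codons + TAA, optionally drawn from a
  user codon-weight table (used to test amino-acid ranking).
- **Transfers** synthesise a donor genome and copy segments into the
  recipient at the configured identity.

Reads sample a conformation by mixture weight, a molecule
length-proportionally, a uniform circular start and strand, and a log-normal
length (default mean 8 kb, σ = 0.4 log-units — desk-scale Nanopore);
substitution/insertion/deletion errors at the configured rate split 2:1:1
(any split satisfies the tests; this one roughly resembles ONT error
structure). Each generator call consumes a single seeded stream
(`generate_genome` from `seed`, `simulate_reads` from `seed + 1`), so equal
configs give byte-identical FASTA/FASTQ.

What passing on synthetic data does **not** show: real mitogenomes have
non-i.i.d. composition (gene clusters, imported plastid DNA, homopolymer
tracts), reads have structured error profiles and chimeras, and real repeat
families are nested rather than isolated. The synthetic results validate the
algorithms' contracts, not field performance on any particular genome.

## Problem sizes and defaults

The shipped studies use a 50 kb recombination genome (three planted pairs:
400/300 bp inverted, 250 bp direct), a 60 kb recall genome with 12 SSRs,
3 tandems, 5 dispersed pairs and 3 transfers against a 30 kb donor, and
5,000 reads for mixture recovery — sizes at which every law the package
asserts (oracle equality, conservation, involution, exact recall, binomial
mixture recovery) is checked in minutes on one CPU. Thresholds default to
the standard organelle profile (SSR 10/5/4/3/3/3; dispersed 30 bp/3
mismatches/5000; CRS 200 bp with 1000 bp flanks; read support 0.95/100 bp;
transfers 1e-5/30 bp; blocks 500 bp) and are all overridable per call or in
the pipeline config.

## Known limitations

- Dispersed-repeat mismatches are substitutions only (no indels), matching
  the Hamming-distance contract; diverged repeats with indels surface via
  the BLAST-based modules instead.
- Tandem and dispersed counts are engine-definition-sensitive; compare
  counts across tools only with matched maximality and merging conventions.
- Conformation enumeration treats events as rare and independent; it
  enumerates reachable arrangements, not their equilibrium stoichiometry —
  junction read counts are the only abundance evidence reported.
- The NUMT path accepts multi-record assemblies but is designed for
  organelle-scale inputs; chromosome-scale nuclear scans are better run
  with a cluster BLAST and imported as fragments.
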