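# Methods

This note records the conventions, models and numerical choices behind each
analysis, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and strand conventions

All coordinates are 1-based inclusive on a circular genome. The "major"
strand is the deposited strand — the one encoding nine protein-coding genes
(ND2, COI, COII, COIII, ATP6, ATP8, ND3, ND6, CytB) in the ancestral insect
arrangement — written `+`; ND1, ND4, ND4L and ND5 sit on the minor strand
(`-`). Features spanning the replication origin are stored as two rows
sharing a name with a `part` tag, so `start ≤ end` holds row-wise; analyses
fuse the parts back into one circular span. Gene labels are normalized at
ingest (COX1→COI, s-rRNA→srRNA, trnL(taa)→trnL2, …) against a controlled
vocabulary of the 37 canonical genes plus the A+T-rich control region;
deviations from that complement are warnings, never errors.

The three bundled reference tables (M. pruinosa H1/H3, S. marginella) are
coordinate-only transcriptions of the published annotations. One printed
value is internally inconsistent in the source (the S. marginella lrRNA row
prints a size of 1205 while its coordinates give 1204, which is also the
size printed in the genome summary); the coordinates are taken as
authoritative.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed over non-N positions;
a zero denominator makes that component missing rather than zero. Skew for a
gene-class basis (all/major/minor protein-coding genes) concatenates the
genes in genome order and always counts **major-strand letters**, without
reverse-complementing minor-strand genes — the statistic describes strand
asymmetry of the genome as deposited, which is why the minor-strand protein
set reads strongly T-skewed on an A-skewed genome.

Codon counting follows one fixed convention: all complete in-frame codons,
minus a complete terminal stop; the 1–2 leftover nucleotides of a truncated
stop (completed by polyadenylation in vivo) are dropped. Applied to the
bundled coordinates this yields 3637 codons for S. marginella — exactly the
published total — and 3657 for M. pruinosa H1, one more than the published
3656. The two published totals are mutually inconsistent under any single
counting rule (the H1 discrepancy is one complete, non-stop codon in ATP6),
so the package applies one rule uniformly and documents the one-codon gap
rather than special-casing a genome. The genetic code is fixed to the
invertebrate mitochondrial code (NCBI table 5: ATA=Met, TGA=Trp,
AGA/AGG=Ser) everywhere.

## Spacers and overlaps

Features are sorted by start around the circle; for consecutive features the
signed gap is `start(next) − end(prev) − 1`: positive = intergenic spacer
(ISS), negative = overlap, zero = abutting (counted in neither total). The
A+T-rich region is not an ISS: its two flanking junctions are reported
separately and excluded from spacer totals — the accounting under which the
published totals (147 bp over 21 regions for H1; 68 bp over 11 for
S. marginella) are reproduced exactly. The book-keeping identity
Σ feature lengths + Σ signed gaps (including control flanks) = genome length
holds exactly on a circle and is tested for every fixture and simulation.
Ties for the longest spacer break by genome order.

## Gene order

A gene order is a signed circular permutation over the 37 genes (control
region excluded), canonically rotated to start at trnI. Tandemly duplicated
tRNAs collapse into a copy-count map: they are preserved for B′ detection
but dropped for breakpoint distance, which is defined on permutations. The
derived Delphacinae arrangements are expressed as edits of the ancestral
order: B = trnC/trnW transposed at the ND2–trnY junction plus the
trnT,trnP,ND6 block replaced by ND6(inverted),trnP,trnT between ND4L and
CytB; B′ = B with trnC triplicated; C = B with trnH moved from the ND5–ND4
junction to just before ND6. Because the published schematic is ambiguous
about the orientation of the translocated ND6, classification tolerates
either orientation (with a log note). Breakpoint distance counts signed
circular adjacencies of one order absent from the other, treating an
adjacency and its reverse-complement reading as identical; it is symmetric
and satisfies the triangle inequality (property-tested against a
brute-force adjacency oracle).

## Junction motif scan

The junction point is the midpoint between the facing boundaries of the two
named features; every offset within ±window (default 30 bp) is scored by
Hamming distance (substitutions only — the aligned figures across species
show substitution variants, not indels) on **both** strands, since the two
flanking genes typically lie on opposite strands. Hits are localized as
within-upstream / within-spacer / within-downstream / spanning from pure
coordinate containment. The default mismatch tolerance of 1 is a package
choice; the source describes "slight modification" without quantifying it.

## Control-region architecture

The tandem-repeat finder is self-contained and exactly specified so a
brute-force enumeration can verify it at test scale:

1. **Raw runs.** For each candidate period *u* (default 10–200 bp), scan the
   self-match profile `seq[i] == seq[i−u]`. A run starts at each left edge
   of a match stretch and extends greedily while the running identity since
   the start stays ≥ the threshold (default 0.85), giving up after a full
   period without improvement; the template copy is prepended.
2. **Refinement.** Rebuild the consensus from the full copies anchored at
   the current start; shed edge positions disagreeing with it; greedily trim
   a fractional tail, a contaminated last copy, or a contaminated first copy
   (re-extending leftward through clean content), to a fixed point. Finally,
   a maximal-scoring-window trim (match +1, mismatch −3) sheds edge noise
   that survives on chance matches.
3. **Qualification.** Copies ≥ min_copies (default 2.0), identity of full
   copies vs. consensus ≥ threshold, and the span must **not** self-match at
   any shorter period at the threshold — this removes harmonics (a 21-bp
   array also matches itself at 42, 63, … bp) and homopolymer/dinucleotide
   runs, which are reported as poly-runs instead.
4. **Selection.** Candidates from all periods are kept greedily by longer
   span, then higher identity, then smaller unit; survivors never overlap.

Fractional final copies are reported to one decimal and flagged truncated.
The `architecture` view segments the region (read left-to-right on the major
strand) into repeat/nonrepeat segments that tile it exactly, with per-segment
A+T content and poly-A/poly-T/poly-AT runs ≥ 8 bp (configurable; the
threshold is a package choice). `architecture` calls the finder with
`min_copies=2.3` and `min_span=60`: in a ~88% A+T core, chance period
matches routinely sustain two near-copies of a short unit, and requiring a
bit more than two copies over ≥ 60 bp suppresses that background without
touching the multi-copy arrays the region actually carries. Direct calls to
`find_tandem_repeats` keep the permissive defaults.

Repeat units are compared by global dynamic-programming alignment
(match +1, mismatch −1, gap open −4, extend −2); identity is aligned matches
over the shorter unit. Random 60-mers score ~0.35–0.5 under this scheme, so
the "alignable" verdict threshold of 0.6 separates shared ancestry from
background.

## Ka/Ks (NG86)

Synonymous/nonsynonymous sites per codon follow Nei–Gojobori (1986) under
table 5, with mutations to stop codons excluded from each position's
denominator (so S+N = 3 per codon after renormalization). Differences
between a codon pair are averaged with equal weight over all mutational
pathways avoiding stops; pairs with all pathways blocked are skipped and
counted. Proportions pS = Sd/S and pN = Nd/N are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined for p ≥ 3/4; Ka/Ks is
missing when Ks is zero or undefined. Note that the original study estimated
Ka/Ks with a 14-model averaging method; this package deliberately implements
the transparent NG86 counting estimator instead, so its claims are
calibrated by selection-regime recovery on simulations (ω of 0, 0.1 and 1
recovered within ±0.05 / [0.9, 1.1]) rather than by numeric reproduction of
the original model-averaged values, which depend on that method and on
external sequences.

## Intraspecies divergence

Distances are uncorrected p-distances with pairwise deletion of gap/N
columns — at intraspecies scales (≲1–2%) model corrections are negligible,
and this keeps the statistic assumption-free. The barcode region is the
5′ 658-bp prefix of COI in reading orientation (the standard animal barcode
fragment), configurable. Per-gene summaries (min/median/mean/max over all
pairs) sort by median; genes missing from any record, or not length-matched
across records, are skipped with a warning.

## tRNA evaluation

Cloverleaf structures are **evaluated, not predicted**: pairing comes from
dot-bracket annotations with arm spans (acceptor, DHU, anticodon, TΨC).
Each pair is Watson–Crick ({A:T, G:C} either orientation), G–U wobble, or a
mismatch; canonical dimensions are 7 bp acceptor stem, 5 bp anticodon stem,
7 nt anticodon loop; a DHU arm with zero pairs marks the truncated-DHU form
typical of trnS1. Structure prediction is out of scope — published
structures come from external predictors plus hand curation, and evaluating
a given annotation is the testable claim.

## Synthetic-data generator

The generator emulates a Flatidae-like mitogenome: 37 genes plus control
region at the reference gene lengths (so trnS1 at 61 bp is the shortest
tRNA and trnV at 73 bp the longest), 2-bp default intergenic spacers, the
requested arrangement type, default whole-genome composition targets
AT = 0.7662, AT skew = 0.25, GC skew = −0.26 (the study genomes' values),
H1-style start/stop codons including the truncated ATP6 stop "T", a TAGTA
motif planted at the ND1–trnS₂ junction, and a control region built as
[truncated composite repeat ~70 bp × 2.6] + [AT-rich nonrepeat core
(AT = 0.88) carrying a 23-bp poly-A, a poly-T and a poly-AT run] +
[21 bp × 20 array] + [short tail], mirroring the published architecture.

Composition targeting is analytic: per-base probabilities are solved from
(AT%, AT skew, GC skew). Coding regions sample sense codons from a codon
distribution obtained by a fixed-point inversion of the stop-codon
exclusion, so the conditional base marginal equals the target; minor-strand
genes are sampled in reading orientation from the complementary distribution
so their genome-strand letters also hit the target. Long stretches use quota
(largest-remainder) sampling — base counts are rounded expectations, then
shuffled — so realized whole-genome composition carries essentially no
multinomial noise (≤ ~0.01 absolute at 15 kb for a uniform-composition
configuration). When repeat arrays and an AT-rich core are planted, those
segments intentionally follow their own composition targets, so the
whole-genome mixture deviates from the global target by design. A single
base distribution cannot simultaneously satisfy whole-genome and
per-strand-class skew targets, so strand-class bias (e.g. T-rich
minor-strand gene spans) is an explicit override, not a default.

Motif planting never corrupts an open reading frame: after writing the motif
the affected genes are re-verified (start codon intact, no internal stop)
and the plant position is nudged or the generator fails loudly.

CDS pairs evolve by random single-nucleotide proposals (Poisson(t·3L) of
them), accepted with probability 1 if synonymous and ω if nonsynonymous,
stop proposals rejected; realized change counts are returned as truth.
Populations mutate each gene's sites independently at per-gene rates.
Everything is a deterministic function of the config and its mandatory seed.

**What the generator does not emulate:** indels and length variation,
transition/transversion bias, within-genome composition gradients, codon
usage preferences beyond base composition, rRNA/tRNA secondary-structure
constraints, and recombination. Passing tests therefore demonstrate correct
accounting, detection and estimation under idealized substitution-only
randomness — not robustness to alignment error or annotation noise in real
data.

## Problem sizes

The test suite and the acceptance script run simulations at the scale the
statistics need and no larger: dN/dS recovery uses 500-codon pairs
(200 replicates at ω = 0.1, 500 at ω = 1), gene-order classification uses
50 random rotations of each arrangement type, breakpoint distance is checked
on 100 random signed permutations, planted-repeat recovery on full 16.3-kb
genomes, and composition control on 15-kb genomes. The full suite runs in
well under a minute; the acceptance script in a few seconds.

## Known limitations

- Origin-spanning features are supported by the two-row convention, but none
  occur in the bundled genomes; the convention is exercised only via rotated
  synthetic records.
- The repeat finder reports one non-crossing set of arrays; biologically
  overlapping repeat structures (nested or interleaved families) are reduced
  to the dominant array per locus.
- `compare_repeat_units` uses a simple global alignment identity; it is a
  screen for shared ancestry, not a substitute for proper homology search.
- NG86 saturates quickly: for strongly diverged pairs pS can exceed 3/4 and
  Ks becomes undefined; such pairs are reported as missing rather than
  extrapolated.
- Ratios and distances are point estimates; no variance or significance
  machinery is provided (group summaries report mean/SD/n only).
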