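# Methods

## Model and scope

`irscan` treats "inverting" Type I restriction-modification loci as a search
problem anchored on an annotated specificity gene (*hsdS*): a locus can
switch specificity by recombination only if the gene shares a sufficiently
long, perfectly identical inverted segment with nearby DNA — in the
biologically interesting case, with a silent duplicate (*hsdS′*) carrying
alternative target recognition domains (TRDs). The pipeline therefore has
four stages: (1) locate the gene and extract its flanks, (2) enumerate all
maximal 100%-identity inverted repeats between gene and flanks, (3) interpret
the repeats (collation of identical genes, inverting/incidental/no-IR
classification, TRD segmentation, allele enumeration), and (4) report.

Sequence variation generated by repeat-mediated inversion is modeled purely
combinatorially: `n5` distinct 5'-TRDs and `n3` distinct 3'-TRDs give
`n5 x n3` hsdS alleles; `m` additional independently ON/OFF-switching mod
genes multiply the population state space by `2^m`. No switching dynamics
(rates, equilibria) are modeled.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_ir_len` | 20 | bp | shortest repeat reported; chosen above the shortest repeat length known to support homologous recombination between hsdS copies (repeats of 15, 85 and 33 bp occur in the SpnD39III locus, and 20 bp excludes only the smallest) |
| `window` | 30000 | bp | flank searched on each side; large enough to span one Type I locus, small enough to exclude partner repeats belonging to a different system |
| `tile_stagger` | 1 | bp | seed spacing; 1 guarantees completeness of the seed phase, larger values trade sensitivity for speed |
| `repeat_sense` | reverse-complement | — | biological inversions; a plain-reversal mode exists only for fidelity experiments |
| `max_report_len` | none | bp | optional ceiling reproducing bounded-scan behavior; hits longer than the cap are truncated at their 5' gene end |
| `include_gene_body` | false | — | when true, windows also cover the gene interval (self-palindrome searching) |

## Detector

Seeding hashes every `min_ir_len`-mer of the gene (tiles staggered by
`tile_stagger`); each seed that recurs in the reverse-complemented window is
extended left and right to maximality; runs are deduplicated per diagonal.
This finds exactly the maximal exact matches of length >= `min_ir_len` — the
staged fixed-length fragment rescans sometimes used for this task are a
bounded approximation of the same quantity, and maximal length is the
quantity of interest (repeat lengths are compared against recombination
thresholds). Redundancy filtering then removes any hit whose gene interval
and partner interval are both contained in those of a longer hit, leaving an
antichain; for degenerate (low-complexity) input, same-length shifted
diagonal runs are all genuine maximal matches and are retained.

Correctness is certified against an independent dynamic-programming oracle
(`brute_force_inverted_repeats`: maximal diagonal runs of the full match
matrix, refused above 16M cells) on a thousand seeded random instances per
test run, plus property suites for soundness (character-by-character
re-verification), maximality (every one-base extension fails), role symmetry
(swapping gene and window transposes coordinates), monotonicity in
`min_ir_len`, and an exact sensitivity floor (a planted repeat of
`min_ir_len` is always found; one base shorter never).

### Strand handling

Inversion is a genome-frame relation — region A is inverted relative to
region B iff A's plus-strand text is the reverse complement of B's — and is
symmetric under the anchor gene's reading direction. Matching therefore
always runs on the gene's plus-strand slice against the reverse-complemented
window; only the reported gene-local coordinates (and the upstream/downstream
labels) are mapped into coding orientation for minus-strand genes. Tiling
the coding sequence instead, as a naive reading of "normalize the gene first"
suggests, silently turns the search into a direct-repeat search for
minus-strand genes because the two orientation flips cancel; the test suite
pins this down. A `legacy_strand` mode treats minus-strand genes as if
plus-annotated (coordinates and sides stay in the plus frame); the matched
set is unchanged.

### Numerical and tie-break conventions

* Coordinates: 1-based inclusive everywhere user-facing (GFF convention),
  0-based half-open internally; BED exports convert.
* Ambiguity codes (N and friends) are preserved in sequences but can never
  participate in a match, so candidate repeats overlapping an N fail the
  100%-identity criterion by definition.
* Hits are sorted by (gene_start, partner_start); window clamping at contig
  boundaries is silent but logged; windows never span contigs.
* Percentages are truncated (floored) to one decimal — a survey of 875
  inverting genes among 22107 prints 3.9%, not 4.0% — with the raw float
  always emitted alongside. The floor uses a 1e-6 guard on the tenths scale
  so binary-float dust (2.0 + 7.9 + 3.9 = 13.799999...) cannot flip a
  decimal; mechanism percentages are additionally summed in decimal
  arithmetic. Sums above 100% warn (overlapping categories).
* Allele labels run A, B, C, ... in row-major order over the
  lexicographically sorted variant sets, so output is deterministic.
* TRD variant distinctness is exact sequence identity; no percent-identity
  clustering is applied.

## Classification

A gene with at least one repeat whose partner interval overlaps (>= 1 bp) a
second annotation labeled hsdS is `inverting`; with repeats but no such
partner, `incidental_ir`; with none, `no_ir`. The silent-copy check is
start-codon-only: the partner is flagged silent when its first codon in
annotated orientation is not ATG. Promoter presence is not assessed (reports
say so), and missing product labels degrade the call to `incidental_ir` with
a warning rather than failing.

## Synthetic data

The generator emulates the canonical locus architecture on one contig:
hsdR (900 bp) – hsdM (600 bp) – expressed hsdS – silent hsdS' copies on the
opposite strand – recombinase (600 bp), embedded in i.i.d. background at the
requested GC (default 0.40). Each hsdS copy is
`start codon + 9-bp spacer + leader IR + 5'-TRD + mid IR + 3'-TRD + TAA`;
defaults are 85- and 33-bp repeats (modeled on the SpnD39III locus) and
270/250-bp TRDs, a ~650-bp gene. The expressed copy starts ATG; silent
copies start GTG, encoding silence without promoter modeling. Single-base
breaks are enforced at every repeat junction (silent spacers differ from the
expressed spacer at their last base; TRD variants differ from the expressed
variant at their boundary bases), so each planted repeat's maximal-match
coordinates are exact by construction, and the truth table is computed by a
segment walk that also handles merged repeats when one TRD axis has a single
shared variant. The default contig is 40 kb with the locus anchored at
offset 2000: the full 30-kb downstream window and a beyond-window decoy fit,
while the upstream flank exercises contig-start clamping.

Decoys (all sized relative to `min_ir_len` k): an inverted copy of k-1 bp
(below threshold), an inverted copy of k+4 bp with one central mismatch
(violates 100% identity; each half stays below threshold), an inverted copy
planted 1 kb beyond the window, and a same-orientation copy of k+20 bp
(direct repeat, invisible to an inverted search). Decoy flanks are also
break-enforced so near-threshold decoys cannot extend past their intended
length by background coincidence.

What the generator does **not** emulate: real genomes have repeat families,
mobile elements, skewed composition, and assembly artifacts; background here
is i.i.d., so planted repeats are essentially the only signals and the
false-positive regime (~4^-20 per position pair) is far cleaner than in real
data. Passing the recovery suite therefore demonstrates correctness of the
detector and coordinate bookkeeping, not real-data specificity of the
inverting/incidental distinction, which on real genomes still warrants the
manual review step the classification mirrors.

## Problem sizes in the test suite

Oracle-equivalence runs use genes up to 1 kb against windows up to 2 kb at
GC 0.25–0.75 (1000 instances), and planted-repeat recovery uses 100 simulated
40-kb genomes alternating gene strand, all with full decoy sets. These sizes
exercise every code path (seeding, extension, dedup, clamping, strand
mapping, merging) while keeping a full run around a minute on one core.

## Known limitations

* Only exact (100%-identity) repeats are reported; no mismatch tolerance, by
  design.
* A repeat straddling a window boundary is truncated at the boundary — the
  windowed design forces this.
* Gene location by exact text match cannot place genes that differ from the
  assembly (SNPs, indels); ambiguous multi-copy genes are skipped with a
  warning and must be disambiguated by an explicit annotation.
* TRD segmentation requires exactly two repeats in the partner copy; loci
  with other architectures raise a structural error rather than guessing.
* Survey rollups count strains via a caller-provided gene-to-species map;
  no taxonomy inference is attempted.
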