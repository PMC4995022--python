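# Methods

This note documents the models and procedures implemented in bcrkit,
the defaults and numerical choices behind them, what the synthetic
generator does and does not emulate, and known limitations.

## Input model

The reader understands IMGT/HighV-QUEST-style output folders with
tab-separated tables (Summary, Nt-sequences, AA-sequences, V-REGION
mutation table) and flat TSVs carrying the union of the needed
columns. Table kinds are recognised first by the numbered-filename
convention (`1_Summary.txt`, ...) and, failing that, by header
sniffing, so renamed exports still load. Joining across table kinds is
by sequence ID, never by row order. The "no results" marker (a
sequence the annotator could not analyse) is matched case-insensitively
after trimming in the "D-GENE and allele" column because dialects vary
in capitalisation; filtering on it reports the number of dropped rows.
Encoding is fixed to UTF-8, the separator to tab, with no quoting —
matching what the annotator emits. All emitted coordinates (mutation
positions) are 1-based, the IMGT convention.

Functionality strings "productive (see comment)" and "unproductive
(see comment)" are kept as distinct categories in summaries but folded
into productive/unproductive by filters, which are binary decisions.
Sequences whose junction frame the annotator left blank form their own
`null` summary category and are excluded by `any_labeled` filters,
which keeps the reported proportions interpretable.

## Gene nomenclature and usage

IMGT names genes hierarchically — subgroup (IGHV1) → gene (IGHV1-69) →
allele (IGHV1-69*01) — and annotation strings may carry several
candidates joined by ", or ". Usage tables credit each of k candidates
a fractional weight 1/k by default, which conserves the per-sample
total regardless of the reporting level (allele-level usage aggregated
by gene prefix equals gene-level usage exactly); a `first` mode
reproduces tools that keep only the top hit. Relative columns are
normalised over sequences with at least one assignment in the queried
family. Gene–gene combination matrices place sequences lacking an
assignment in either family into an explicit NA row/column when
requested, else drop them from the denominator; with NA included, the
matrix marginals equal the single-family usage vectors. Output labels
are natural-sorted (numeric runs compared as integers) so tables are
stable and diffable.

## Mutation statistics

Mutation-table cells are parsed from the compact notation `a2>g`
(silent) / `a2>g,S1>T` (replacement); an event is a replacement
exactly when an amino-acid change with differing residues is attached.
The R/S ratio with zero silent mutations is reported as NaN rather
than infinity so that cohort means remain well-defined by exclusion.
The replacement matrix is the proportion of all replacement events per
(germline, mutated) residue pair; its physicochemical flags come from
the IMGT amino-acid classification (hydropathy in 3 classes, volume in
5, chemical characteristics in 7) embedded as a static table in
`_aa_classes.py`. Events involving placeholder residues ('*', 'X',
'#') are dropped from the matrix. Flags depend only on the residue
pair, are symmetric, and e.g. serine→threonine (both hydroxyl, both
hydropathy-neutral) carries no hydropathy flag while serine→asparagine
does.

Silent-mutation base context tallies, per from→to substitution type
and per offset −3..+3 (0 excluded), the base composition of the region
sequence around the mutated position; offsets truncated by a region
boundary drop out of that offset's denominator. Context is computed
per offset (the stricter reading) rather than pooled over offsets, and
on the V-gene strand only, since the annotator's output is already
V-oriented.

## Clonotype model

Two sequences belong to one clonotype when they use the same V gene at
gene level (optionally also the same J gene) and their CDR3s have
equal length and percent identity at or above a threshold
t ∈ (0, 100]. Identity is positional (Hamming) on the equal-length
strings: the threshold semantics are exact and indel handling is not
required; cross-length merging is deliberately impossible. Within a
candidate group, merging is single-linkage, which matches the
"chain of hypermutations" intuition and is independent of record
order; at t = 100 the procedure degenerates to hash-grouping on the
exact key, which is also the fast path used. Ambiguous gene
annotations match by their first candidate by default; an `intersect`
mode merges whenever candidate sets overlap. The default sequence kind
is the amino-acid CDR3. Clone IDs are content hashes of the key and
sorted member IDs, stable across runs. Lowering t can only coarsen the
partition (single linkage adds edges monotonically).

Shared ("public") clones across samples apply the identical criteria
to the clones' representative CDR3s (most frequent member CDR3, ties
to the lexicographically smallest); a merged group spanning ≥ 2
samples is one shared clone, and the summary counts them per sample
combination.

The Gini index of clone sizes is the standard normalised mean absolute
difference, computed via the sorted closed form (algebraically equal
to the double sum). For a single clone the formula gives 0 —
degenerate evenness — although one common informal description equates
"one clone holding everything" with an index of 1; that reading only
applies in the limit of one dominant clone among many, and the
standard formula is implemented as is.

## Diversity

Because indels make cross-length alignment of CDR3s ambiguous,
amino-acid distributions and diversity are computed per position
within groups of equal-length sequences. The Hill number
`D_q = (Σ pᵢ^q)^{1/(1−q)}` uses 0·ln 0 := 0 in the order-1 limit
(`exp` of Shannon entropy, taken when |q−1| < 1e-9), counts strictly
positive proportions at q = 0 with no epsilon, and accepts general
orders even though the interface advertises 0/1/2. Placeholder
symbols participate as ordinary observed types by default (they are
types actually observed), with an exclusion option. Per-length mean
and standard deviation are taken over positions; multi-sample
comparisons align on the union of lengths with NaN for absent lengths.
Conversions from classical indices (richness → identity, Shannon
entropy → exp, Simpson concentration → reciprocal) reproduce the
corresponding Hill numbers to machine precision.

## Distances and ordination

The edit-family string distances are dynamic programs authored here:
Levenshtein; restricted Damerau-Levenshtein (OSA, one transposition,
no substring edited twice); full Damerau-Levenshtein (Lowrance-Wagner
with last-occurrence bookkeeping); Hamming (equal lengths only); and
the indel-only distance |a|+|b| − 2·LCS(a,b). The last is sometimes
loosely called a "longest common substring" measure; its value on the
standard worked pair (AABBCC/ABBBBC → 4, common subsequence ABBC) is
that of the subsequence-based definition, which is what is
implemented. q-gram distances use count profiles with default q = 2
(q = 1 collapses amino-acid sequences to residue composition);
cosine, Jaccard and Jaro-Winkler are emitted as 1 − similarity so
larger always means more dissimilar; Jaro-Winkler uses the
conventional prefix weight 0.1 with cap 4. Pairwise-matrix routines
accept a `workers` argument for interface compatibility; computation
is serial and results are identical for every value.

Gene-usage profiles are compared with Bray-Curtis (abundance),
Jaccard on presence/absence, or cosine; proportions below a cutoff are
zeroed first, and cosine against an all-zero profile is NaN.
Transposing the table yields gene–gene distances across samples.

PCoA Gower-centers −½d², eigendecomposes the symmetrised form, and
scales eigenvectors by √λ over the positive axes. Eigenvalues within
1e-8·max|λ| of zero count as numerically zero when deciding whether a
correction is needed. Lingoes adds the minimal constant c (= −λ_min)
to all squared off-diagonal distances; Cailliez adds the minimal
constant to the distances themselves, obtained as the largest
eigenvalue of the standard 2n×2n companion problem. Explained
variance is reported relative to the sum of positive (corrected)
eigenvalues. Without correction, strongly negative eigenvalues set a
warning flag and coordinates use the positive part only.

## Synthetic generator

The generator plants a repertoire with full bookkeeping: clone sizes
partition `n_sequences` (uniform or power-law with α = 2 by default);
each clone draws a V/D/J assignment from a small built-in germline
catalog (10 V, 5 D, 6 J labels in IMGT syntax with codon-aligned
open-reading-frame sequences, fixed once) and a germline CDR3 of 8-16
amino acids; members copy the clone CDR3 with at most one nucleotide
substitution (probability 0.3), re-drawn if it would create a stop
codon. V-region mutations are Bernoulli per position (default 3 per
kilobase, light hypermutation) and classified silent/replacement by
translating the germline codon with that single substitution applied —
the same convention the mutation tables then carry, so recovery is
exact by construction. Clones sharing a (V gene, J gene, CDR3 length)
key are re-sampled until their germline CDR3s differ in at least two
thirds of positions, so with ≤ 1 substitution per member the planted
partition is unambiguous at thresholds around 70-85%. Functionality
defaults to 85% productive / 12% unproductive / 3% unknown, junction
frames correlate with functionality, 2% extra rows are emitted as
"No results", and 5% of rows carry a second V allele candidate to
exercise ambiguity handling. Identical seed and config give
byte-identical folders.

What the generator does **not** emulate: real VDJ recombination
mechanics (junctional insertions, trimming), hotspot-biased
hypermutation (WRC/GYW motifs), sequencing error, allele-level
germline variation, or realistic gene-usage frequencies. Passing
recovery tests therefore demonstrates correctness of the bookkeeping
and algorithms, not robustness to artefacts of real data.

## Problem sizes and tolerances in the test and acceptance suites

Analytic identities are asserted to 1e-12; recovery checks are exact
(integer equality or set equality); PCoA embedding exactness to 1e-9.
Synthetic recovery runs use 400-5000 sequences in 25-200 clones —
large enough that every code path (ambiguity, no-results rows, both
mutation kinds, multi-clone keys) is exercised, while the whole suite
and the acceptance script each complete in seconds.

## Known limitations

- No lineage trees, clone tracking over time, or repertoire-size
  (richness) extrapolation; no rarefaction or coverage-adjusted
  diversity estimators.
- No FASTA/FASTQ preprocessing; the toolkit starts from annotated
  tables.
- CDR3 identity is substitution-only; a clone whose members carry
  indels in the CDR3 will split by length.
- The per-sequence IMGT parameter file and individual-sequence files
  are not parsed.
- Gene labels are taken at face value; there is no validation against
  a germline database.
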