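# Methods

## Database representation

Proteins are concatenated into a single ASCII text; a sentinel `$`
(lexicographically below every residue letter) follows each protein,
including the last. Offsets are 0-based and half-open everywhere; only
output ranks are 1-based. `start[i]` is the offset of protein *i*'s first
residue and `start[n] = len(txt)`, so protein *i* is
`txt[start[i] : start[i+1] − 1]` and owns its trailing sentinel — this
makes the suffix-to-protein map total. Input FASTA is uppercased;
residues outside the 25-letter IUPAC amino-acid set, and the rare letters
U and O, are mapped to `X` (which compares as an ordinary letter, keeping
the lexicographic order total); `*`, `-` and `.` are removed; records
empty after cleaning are skipped with a warning rather than guessed at.
On disk the text costs one byte per character; the suffix-to-protein map
is stored at 4 bytes per rank and the query insertion ranks at 8 bytes
per offset.

## Suffix index

`build_suffix_array` uses prefix doubling (Manber–Myers) on numpy integer
rank pairs: each round sorts suffixes by (rank, rank *k* ahead) and
doubles *k* until all ranks are distinct. All suffixes of the
concatenated text are distinct strings (distinct lengths ending at the
final sentinel), so the order is strict. The contract is the output
invariant — `sa` is the permutation sorting all suffixes, `isa` its
inverse, `sap[l]` the protein owning suffix `sa[l]` — and the tests
verify it against a naive sort-all-suffixes oracle; the number of
doubling rounds is governed by the longest repeated prefix, not text
length, so measured work grows essentially linearly on protein-like
texts (checked by a step-count scaling test). Suffix comparison crosses
sentinels (a suffix runs to the end of the text); since the sentinel is
the smallest character and identical everywhere, within-window order is
driven by true sequence content. Sentinel-initial suffixes are indexed
(they cluster at the low ranks) and labelled with the preceding protein;
they are never used as query suffixes.

Query suffixes are mapped into the database order by a two-pointer merge
of the two sorted suffix arrays, comparing suffixes chunk-wise (32
characters at a time) so common prefixes are paid for only once per
comparison. A query suffix equal to a database suffix as a string maps to
that suffix's rank — the "≤" side of the bracket — so exact matches sit
inside the window on the left. This makes self-retrieval exact: querying
a database member places its own suffixes in their own windows.

## SANS scoring

For every unmasked query suffix with insertion rank `l`, the window is
the 2W ranks `l−W+1 … l` and `l+1 … l+W`, clipped by discarding
out-of-range ranks (windows shrink at the two ends of the suffix order
rather than wrapping or clamping). The window is two-sided because the
best-matching suffixes may sort on either side of the query suffix; with
`W = H` (the default coupling) at least H nearest suffixes are inside the
window regardless of side. Every occurrence of a protein's label in a
window counts — the score is a pure double sum with no per-window
deduplication — and self-hits are not excluded when the query set equals
the database; callers may filter. Ties in top-H selection break toward
the lower database protein index, and zero-score proteins are never
reported; threshold mode (`T`) reports all proteins scoring at least
`max(T, 1)`.

### Masking

A query suffix is masked when its leading residues look like a short
tandem repeat: the same character at suffix positions (1,2,3) or at
(1,3,5), 1-based from the suffix start. Positions are read only within
the suffix's own protein. A pattern applies when *every position of it
that exists* carries the same character; a consequence is that suffixes
with fewer than three in-protein residues are degenerate (the 1,3,5
pattern is vacuously satisfied) and are always masked, as are sentinel
offsets. The degenerate-suffix rule loses at most the last two residues
of each protein — windows seeded by one- or two-letter words are noise —
and makes a fully repetitive query (e.g. poly-A) score zero everywhere.

### Sectioned search

To bound memory, the database can be processed in contiguous runs of
whole proteins whose text fits a byte budget; each section gets its own
suffix array and query mapping, and window counts accumulate into global
per-protein scores before selection. Windows are computed per section and
never stitched across section boundaries. This is an approximation knob:
every query suffix contributes 2W counts *per section*, so the diffuse
background score of unrelated proteins grows with the section count while
genuine family scores (driven by long shared prefixes) are essentially
unchanged. Top-H membership is stable when family scores dominate the
background, which is the operating regime of the filter; a section budget
smaller than the largest single protein is an error.

## KSEARCH

The k-mer baseline scores a pair of proteins by the dot product of their
k-mer occurrence-count vectors (default `k = 6`, the selectivity/
sensitivity sweet spot for protein-scale databases; performance drops on
either side of it). It is implemented with an inverted k-mer table over
the database — the score contract is the dot product's value, and the
tests verify it against a dense 20^k-vector oracle for small k. The
tandem-repeat mask is applied on the query side with the minimal reading:
a masked suffix suppresses exactly the k-mer starting at its offset.
Database vectors are unmasked. Per-query cost grows with the number of
matched k-mer instances in the database, in contrast to the
constant-window SANS scan.

## Greedy ungapped rescoring

Hit lists can be reranked by a fast approximate alignment score:

* **Seeding.** The query is scanned left to right for exact 3-mer matches
  to the subject. The last hit on each diagonal is remembered; a new hit
  at start distance 3–40 from it forms a two-hit seed (closer hits
  overlap and count as the same hit; farther hits restart the diagonal).
  Seeds are exact 3-mer identities, not neighborhood words.
* **Extension.** Each seed is extended on its diagonal in both directions
  under an x-drop rule (default 20 raw BLOSUM62 units): extension stops
  once the running score falls more than `xdrop` below its running
  maximum, and the segment end is trimmed back to that maximum. HSPs with
  non-positive score are discarded; there is no further minimum-score
  acceptance bar. After an HSP is accepted the scan jumps past its end,
  so words inside an HSP are never retested.
* **Chaining.** Collected HSPs are taken in descending score order; an
  HSP joins the chain only if it is strictly before or strictly after
  every selected HSP in both coordinates. The alignment score is the plain
  sum of chained HSP scores — no gap penalties. Greedy selection is not
  guaranteed optimal; against an exhaustive dynamic-programming chain
  oracle it is exact on ≥ 90% (in practice 97–100%) of instances drawn
  from the scan stage on mutated sequence pairs, which is the instance
  distribution the chainer actually faces. Uniformly random overlapping
  HSP sets can be constructed where greedy falls short; they do not arise
  from the scan, whose accepted HSPs are already ordered in the query.
* **Rescoring.** Each (query, target) pair in a hit list gets the greedy
  alignment total; lists are re-sorted by that total, with the original
  retrieval score and then the database index as tie-breaks, and
  truncated to `keep`. Pairs with no seed score 0 and sink below every
  aligned hit.

BLOSUM62 is loaded through Biopython's substitution-matrix reader; any
NCBI-format matrix file can be substituted (`--matrix`). The aligner
exposes work counters (scan positions visited plus extension iterations);
near-identical pairs cost less than distant ones because one long HSP is
found and jumped over, which is why rescoring is cheap exactly where the
filter is strong.

## Evaluation

For a ranked hit list and a truth set of size T, precision = TP/P and
recall = TP/T at each rank P. The per-query AUC is computed as average
precision — the sum of precision at each rank where a new true hit
appears, divided by T — a step-function integral that is exact at rank
granularity, reaches 1 exactly when the ranking lists the truth set
first, is 0 with no true hit, and is invariant to false hits appended
after the last true one. (Trapezoidal integration of the PR polyline is
the other defensible convention; average precision was chosen as the
standard step form.) Method comparison uses the arithmetic mean of
per-query AUCs, and, at a fixed reporting depth, per-identity-bin
sensitivity (recovered true pairs / true pairs in bin) relative to a
reference method; empty bins and bins where the reference recovers
nothing are reported as missing. Default bins: <30, 30–50, 50–70, 70–90,
≥90 percent identity; default depth 1000 hits per query. Truth files are
external TSV inputs — this package never computes alignment e-values.

## Synthetic benchmarks

The generator plants families in a background of i.i.d.-random proteins:
family founders are database members, additional members and queries are
point-substituted copies (a substituted position always receives a
different residue, so expected identity is exactly 1 − rate). Lengths are
log-normal with mean 330, clipped to [50, 2000], echoing real protein
length spread; fixed lengths are available for controlled experiments.
An optional per-position indel rate (default 0) breaks diagonals for
aligner tests; identity control and the retrieval benchmarks use
substitutions only, since independent suffixes make the window filter
indel-tolerant by construction. All outputs are byte-deterministic under
a single integer seed.

What the generator does **not** emulate: real amino-acid composition
biases, BLOSUM-weighted substitution preferences, domain shuffling,
repeats and low-complexity regions beyond what random text produces, and
family size/identity distributions of curated databases. Passing
benchmarks here show the engines rank planted homologs correctly at
controlled identity under idealized mutation; they do not certify
sensitivity on real databases, where identity is concentrated near the
filter's failure regime (<50%) for many true pairs.

## Problem sizes and defaults

The retrieval benchmark used by the tests and the acceptance script is
1000 unrelated proteins of length 300, 50 of them queried with 20
replicate queries at a 30% substitution rate (1000 queries, ~70%
identity), scored with `W = H = 1` for top-hit mapping; the greedy arm
rescores the top 10 of a `W = H = 10` run. The ranked-list benchmark
plants 30 families of size 4 in a 300-protein background at substitution
rates {0.1, 0.3, 0.5} and evaluates mean AUC at depth 100. These sizes
exercise every code path (merge, windows, masking, sectioning is covered
separately) while keeping the full suite in the tens of seconds.

Defaults: `H = 100`, `W = H`, `k = 6`, x-drop 20, seed distance bound 40,
evaluation depth 1000. `W = H` and `k = 6` are the method's standard
couplings; the x-drop value and the positive-score HSP bar are this
package's choices (the stopping rule of the original greedy aligner is
not specified anywhere we could follow), as is average-precision AUC
integration.

## Known limitations

* Sectioned scores depend on the sectioning (see above); results are
  reported per run configuration, which the CLI echoes to a sidecar JSON.
* The suffix-array merge costs O(total common prefix length) character
  comparisons in the worst case (e.g. querying a database against
  itself); for diverged queries it is effectively linear.
* No e-values or score statistics: SANS scores are raw window counts and
  are comparable only within one database and parameter set.
* Greedy chaining and x-drop extension are heuristics; both are bounded
  above by their exhaustive counterparts in tests but can under-score
  adversarial repeat structures.
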