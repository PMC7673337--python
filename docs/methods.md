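# Methods

## Model of the artifact being detected

A CRISPR array is a sequence of near-identical DNA repeats r₁…rₙ
(20–60 bp) alternating with unique spacers of similar length. When a
gene finder annotates an ORF across an array, the database receives a
protein whose sequence is the in-frame translation of that region: the
same peptide (the repeat's frame translation) recurring with gaps of
7–20 aa (21–60 bp / 3). Two consequences drive the design:

* any reading frame of a repeat that contains a stop codon can never
  appear inside such a protein, so stop-containing frames are discarded
  at indexing time;
* all repeat copies in one ORF lie on one strand, so approach I only
  chains matches within one (repeat, strand) group — mixing frames of
  that strand is allowed (repeat-length jitter between copies can shift
  which frame peptide matches), mixing strands or repeats is not.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `spacer_min`/`spacer_max` | 7 / 20 | aa | inter-match gap; amino-acid image of a 21–60 bp spacer |
| `unit_min`/`unit_max` | 7 / 20 | aa | ab initio repeat-unit length; matches the repeat length range under ×3 scaling |
| `min_peptide_len` | 6 | aa | shortest indexed frame peptide: a 20 bp repeat in frame 2 translates to ⌊18/3⌋ = 6 aa; anything shorter matches promiscuously |
| `min_genome_len` | 500 000 | bp | genomes below this cannot be meaningfully searched for cas context (inclusive: 500 000 passes) |
| `window_bp` | 10 000 | bp | cas search window on each side of the candidate gene, boundary-anchored, inclusive at the bound |
| `max_evalue` | 1e−5 | — | cas-domain hit threshold (inclusive) |
| `min_identity` | 25 | % | idem |
| `min_coverage` | 0.70 | fraction of the domain model (subject coverage) | idem |

All three hit thresholds are treated as inclusive for symmetry; the
E-value bound is explicitly "equal or lower" in the protocol this
follows, and the other two are chosen to match. Candidate–cas distance
is measured boundary to boundary (0 on overlap); cas gene strand is
ignored; duplicate cas labels in a window (paralogs) count once for
cluster completeness.

## Chaining rule (approach I)

All exact occurrences of a group's peptides are collected, then the
maximal chain of non-overlapping occurrences with every consecutive gap
in [spacer_min, spacer_max] is found by dynamic programming (ties:
earlier start, longer peptide, lower frame). DP rather than a greedy
left-to-right pass guarantees that a protein is flagged whenever *any*
valid pair exists — a greedy pass can dead-end on an early occurrence
with no in-range partner while a later pair exists. Acceptance needs
one valid adjacent pair; the maximal chain is what gets reported. One
candidate per (protein, repeat, strand); sub-chains are not reported.

## Enumeration rule (approach II)

The scanner reports maximal perfect spaced repeats under this contract:

1. occurrences of a unit are *linked* only when consecutive in the
   unit's occurrence list and separated by a gap in [spacer_min,
   spacer_max]. A nearer copy — tandem or overlapping — breaks the
   chain. This single rule excludes tandem repeats and homopolymer runs
   (their nearest copies have gap ≤ 0) without a special case, and makes
   the report set symmetric under sequence reversal;
2. a report is a maximal linked run of ≥ 2 occurrences;
3. unit maximality: a run is suppressed when its unit can grow one
   residue left or right with all copies identical (and not `X`) and
   all internal gaps, which shrink by one, still ≥ spacer_min — this
   removes the cascade of sub-unit reports inside every longer repeat;
4. overlapping surviving reports are deduplicated leftmost-start-first,
   then longest-unit-first.

Correctness is defined by equivalence with a brute-force enumerator
that implements steps 1–4 literally from the definition (the test
suite's oracle), not by the seed-and-extend details of the scanner.
Note that the dedup tie-break in step 4 is directional, so *post-dedup*
output is mirror-symmetric only when nothing was suppressed; the
mirror-symmetry property is exact for the pre-dedup report set and is
tested there. `X` never matches anything, including `X`: two unknown
residues are not evidence of repetition.

Approach II cannot see arrays whose designated frame peptide is 6 aa
(20 bp repeats in frames 1–2): its unit floor is 7 aa, while approach I
indexes peptides down to 6 aa. The overlap between the approaches is
therefore complete only over candidates whose matched peptides are
≥ 7 aa, even on fixtures where all copies are exact.

## Classification

For a tested candidate, the windowed cas label set *L* decides:
`negative` if *L* = ∅; `pfp` if *L* ⊇ required(s) for some subtype *s*
(rule `cluster`, first match in subtype name order reported) or
{cas1, cas2} ⊆ *L* (rule `cas1cas2`); otherwise `cas_positive`.
Classification is a pure function of the label set — hit order never
matters. The shipped subtype catalog (`data/cas_subtypes.json`) carries
a minimal literature-style gene set per subtype and is deliberately
editable: the rule engine is the contribution, the catalog is
configuration, and users tracking a specific subtype classification
release should supply their own JSON. The same applies to the
domain-id → cas-label mapping (`data/cas_domain_labels.json`); hit
tables may instead carry a `cas_label` column directly. Strict set
containment is used for "complete cluster" — no accessory-gene
tolerance — because any looser rule belongs in the catalog, not the
engine.

Summary medians use the lower median (element ⌊(n−1)/2⌋ of the sorted
values): no interpolation, so integer inputs give integer medians and
reports are byte-reproducible.

## Synthetic data: what it emulates, and what it does not

Each locus is one genome (default 500 kb, uniform random DNA at 50 %
GC) carrying one planted protein:

* `spurious_with_cluster` — a complete cas subtype cluster (genes
  450–1050 bp, intergenic 50–200 bp, each with a hit passing all
  filters; the gap to the array is capped so the whole cluster stays
  inside the 10 kb window) followed by a translated array: 3–6 copies
  of a repeat's designated-frame codon block separated by 7–20 sense
  codons. Expected status `pfp`.
* `spurious_split_array` — same array, 12–20 kb downstream of the
  cluster: no cas gene within the window. Expected `negative`.
* `true_protein` — two copies of a 13 aa unit with one central
  mismatch (every exact common block ≤ 6 aa).
* `decoy_short_repeat` — two exact 6 aa copies, below the unit floor.
* `decoy_tandem` — a 7–10 aa unit repeated in tandem (spacer 0; units
  are kept ≤ 13 aa because a tandem unit of length L contains exact
  7-mers spaced L−7 apart, which re-enters the spacer range at L ≥ 14).

Decoy spacer boundary residues are forced to differ from the residues
flanking the planted copies; otherwise a 1-in-20 coincidence would
extend a decoy's exact block past the unit floor and the decoy would
(correctly, but unhelpfully) stop being a decoy. Half the clusters also
carry hit rows that each fail exactly one filter threshold (E = 1e−4,
identity 20, coverage 0.5), so fixtures exercise the hit filter.

Deliberate non-realism, and hence the limits of what passing tests
show: spacers inside the planted ORF are sense codons (a database
protein cannot contain a stop symbol) but no start/stop grammar is
imposed unless `enforce_orf_grammar` is set; cas gene intervals carry
no real coding sequence (the pipeline consumes hit tables and never
re-translates genes); the genome embeds the repeat's designated-frame
codon block rather than full repeat copies (re-scanning genomes for
arrays is out of scope); there is no codon-usage, GC-skew or
assembly-error model. Real databases additionally contain degenerate
arrays (copies with mismatches), which the exact-match scanners will
miss by design — perfect planted recall on fixtures therefore bounds
sensitivity on real data from above, not below.

All randomness flows from one `numpy` `default_rng(seed)`; a fixed seed
reproduces byte-identical files, recorded as SHA-256 checksums in
`manifest.json`.

## Numerical and I/O choices

Tables are tab-separated UTF-8 with a header, no quoting, floats at six
significant digits; output orders are fixed (input order then repeat
then strand for candidates; accession for classifications; leftmost
then longest for spaced repeats), so identical inputs reproduce
byte-identical outputs. GFF3 is 1-based inclusive on disk and 0-based
half-open in memory; genome lengths come from `##sequence-region` or a
lengths TSV (which takes priority). Degenerate inputs: an empty repeat
collection, duplicate protein accessions and duplicate gene ids are
errors; a repeat whose six frames all contain stops is dropped with a
warning; malformed hit rows are skipped and counted; an empty candidate
set summarizes to an all-zero report.

Problem sizes used by the shipped checks: scanner/oracle equivalence on
1000+ random and adversarial proteins of 20–300 aa; planted recovery on
a 200-locus fixture (one 500 kb genome per locus); translation laws on
10 000 random DNA strings of 3–100 nt. These sizes give every class
dozens-to-hundreds of instances while keeping the whole suite fast
enough to run on every change.

## Known limitations

Exact matching only — degenerate repeats, scoring matrices and fuzzy
units are out of scope. Approach II reports at most what its
consecutive-linkage contract defines; arrays interleaved with other
copies of the same unit at out-of-range gaps are split, mirroring the
one-peptide limitation discussed above. The subtype catalog and domain
mapping are minimal seeds, not authoritative releases. The tool screens
proteins; it does not detect CRISPR arrays in genomic DNA, does not
re-implement RPS-BLAST or any external spurious-protein predictor (their
outputs can be joined onto the report), and applies no rescue logic for
split arrays.
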