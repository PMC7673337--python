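# spurscan

Screen protein databases for spurious entries translated from CRISPR
repeat-spacer arrays.

## The problem

Prokaryotic CRISPR-Cas loci consist of a cluster of *cas* genes followed
by an array of short DNA repeats (20–60 bp) alternating with unique
spacers of similar length. CRISPR arrays do not encode proteins, but ORF-based
gene finders sometimes annotate an open reading frame across an array,
and the resulting "protein" — a short peptide repeated every 7–20
residues — ends up in public databases such as UniProtKB, from where it
can contaminate homology searches and downstream annotation. `spurscan`
is for database curators and annotation-pipeline developers who want to
detect (and remove or prevent) this class of contamination.

## The method

Two complementary scans produce *initial candidates*, which genomic
context then validates:

1. **Repeat-database scan (approach I).** Every repeat *r* in a CRISPR
   repeat database is translated in all six reading frames; frames
   containing a stop codon are discarded (a translated array cannot
   contain one). A protein *P* is flagged when ≥ 2 non-overlapping exact
   occurrences of the peptides from one strand of one repeat appear with
   every consecutive gap *g* satisfying 7 ≤ *g* ≤ 20 aa — the amino-acid
   image of a 21–60 bp DNA spacer.
2. **Ab initio scan (approach II).** Independently of any repeat
   database, *P* is flagged when it carries ≥ 2 exact copies of a unit
   *u* with 7 ≤ |*u*| ≤ 20 aa separated by spacers in the same range.
   Tandem repeats (spacer 0) are excluded. This can discover arrays
   absent from repeat databases, but only sees arrays whose copies
   translate identically.
3. **Genomic context.** Each candidate is mapped to its gene; genomes
   shorter than 500 kb are *untested*. Cas evidence (RPS-BLAST-style
   domain hits filtered at E ≤ 1e−5, identity ≥ 25 %, domain coverage
   ≥ 70 %) is windowed within 10 kb of the gene on both sides. A
   candidate with ≥ 1 windowed *cas* gene is **Cas(+)**; it is a
   **putative false protein (PFP)** when the windowed labels contain a
   complete *cas* subtype cluster or at least both *cas1* and *cas2*.

A synthetic fixture generator plants translated arrays (with complete
cas clusters or as cas-free "split arrays"), decoy proteins with tandem,
short, or approximate repeats, and ground truth for every emitted
protein, so the whole protocol is testable without any database
download.

## Worked example

Generate a 12-locus fixture and run the full protocol:

```sh
spurscan -q simulate --seed 42 --n-loci 12 --out fixture
spurscan run-all \
    --repeats fixture/repeats.fasta --proteins fixture/proteins.fasta \
    --gff fixture/genes.gff3 --cas-hits fixture/cas_hits.tsv \
    --meta fixture/proteins_meta.tsv --out-dir out
cat out/summary.txt
```

```
subset                       n  tested   neg  cas+   pfp   %cas+    %pfp
------------------------------------------------------------------------
approach I                   6       6     2     0     4    66.7    66.7
approach II                  6       6     2     0     4    66.7    66.7
I/tr/archaea                 1       1     1     0     0     0.0     0.0
I/tr/bacteria                5       5     1     0     4    80.0    80.0
II/tr/archaea                1       1     1     0     0     0.0     0.0
II/tr/bacteria               5       5     1     0     4    80.0    80.0
```

Both scans flag the six planted array translations (`n` = 6) and none
of the six decoys. All six genomes are 500 kb, so all candidates are
tested. The four candidates whose arrays sit next to a complete cas
cluster come out as PFP; the two "split arrays" (no *cas* gene within
10 kb) are negative, e.g.:

```
accession   status    rule     matched_subtype  n_cas_genes  distance_to_nearest_cas
SYNP00000   pfp       cluster  II-C             3            1452
SYNP00005   pfp       cluster  VI-B             1            2831
SYNP00006   negative  none                      0
```

`out/candidates.tsv` records the match evidence per protein, e.g.
`SYNP00000  I  SYNR0000  -  4 matches  spacers 10,10,20` — four copies
of a reverse-strand repeat peptide with in-range spacers. Compare
`fixture/truth.tsv` to verify every status against the planted class.

On real data, replace the fixture files with a repeat FASTA (e.g.
CRISPRCasdb evidence-4 repeats), a protein FASTA (UniProt-style headers
are parsed), a GFF3 annotation with `##sequence-region` lines (or a
lengths TSV), a cas-domain hit table, and a metadata TSV mapping each
accession to its genome and gene. `spurscan classify --help` lists the
threshold flags; every default can also be set in a JSON config file.

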