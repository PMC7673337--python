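"""Synthetic fixtures: genomes, annotations, cas-hit tables, proteins, truth.

Each locus emulates one of five planted classes:

* ``spurious_with_cluster`` — a complete cas subtype cluster followed,
  within the search window, by a repeat-spacer array whose designated
  reading frame is translated into a database protein (expected PFP);
* ``spurious_split_array`` — the same translated array placed far
  beyond the window from any cas gene (expected negative — the
  "split array" situation);
* ``true_protein`` — a decoy carrying two *approximate* copies
  (1 central mismatch) of a 13 aa unit;
* ``decoy_short_repeat`` — a decoy with perfect 6 aa copies, one below
  the unit-length floor;
* ``decoy_tandem`` — a decoy with a short unit repeated in tandem
  (spacer 0).

Decoys must never be flagged by either scanning approach.  The planted
ORF is defined by coordinates: its designated frame is stop-free (a
database protein cannot contain a stop symbol) but no start/stop-codon
grammar is imposed, matching how gene-finder artifacts actually arise.
cas evidence is planted directly as hit-table rows; alongside every
passing hit the generator can emit rows that must fail each filter
threshold, so fixtures exercise the hit filter too.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .context import load_domain_label_map, load_subtype_definitions
from .errors import ConfigError
from .io import write_cas_hits_tsv, write_fasta, write_gff3
from .model import (
    CasHit,
    FixtureTruth,
    GeneLocus,
    ProteinRecord,
    RepeatRecord,
    STATUS_NEGATIVE,
    STATUS_PFP,
)
from .translation import reverse_complement, translate_six_frames

log = logging.getLogger(__name__)

CLASSES = (
    "spurious_with_cluster",
    "spurious_split_array",
    "true_protein",
    "decoy_short_repeat",
    "decoy_tandem",
)

DEFAULT_FRACTIONS = {
    "spurious_with_cluster": 0.35,
    "spurious_split_array": 0.15,
    "true_protein": 0.20,
    "decoy_short_repeat": 0.15,
    "decoy_tandem": 0.15,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Generation parameters; a fixed seed reproduces byte-identical files."""

    seed: int
    n_loci: int = 200
    repeat_len_range: tuple[int, int] = (20, 60)  # bp
    spacer_len_range_bp: tuple[int, int] = (21, 60)  # bp (multiples of 3 used)
    n_units_range: tuple[int, int] = (3, 6)  # repeat copies per planted ORF
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    genome_length: int = 500_000  # bp per locus genome
    enforce_orf_grammar: bool = False  # prepend ATG / append stop in the genome

    def validate(self) -> "FixtureSpec":
        if self.n_loci < 0:
            raise ConfigError("n_loci must be >= 0")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("class fractions must sum to 1")
        if set(self.class_fractions) - set(CLASSES):
            raise ConfigError(
                f"unknown planted classes: {sorted(set(self.class_fractions) - set(CLASSES))}"
            )
        lo, hi = self.repeat_len_range
        if not 20 <= lo <= hi <= 60:
            raise ConfigError("repeat_len_range must lie within [20, 60] bp")
        if self.genome_length < 100_000:
            raise ConfigError(
                "genome_length below 100 kb cannot hold the locus layout"
            )
        return self


@dataclass
class LocusBundle:
    """Everything one locus contributes to the fixture files."""

    genome_accession: str
    genome_length: int
    planted_class: str
    gene_loci: list[GeneLocus]
    cas_hits: list[CasHit]
    protein: ProteinRecord
    truth: FixtureTruth
    repeat: Optional[RepeatRecord] = None
    inserts: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _sense_codon_dna(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_AA_ALPHABET), size=n)
    return "".join(_AA_ALPHABET[i] for i in idx)


def generate_repeat(
    rng: np.random.Generator,
    length: int,
    strand: str = "forward",
    frame: int = 0,
    repeat_id: str = "SYNR0000",
) -> RepeatRecord:
    """Random 20-60 bp repeat whose designated strand/frame is stop-free.

    Rejection sampling; the other five frames are unconstrained, as in
    real repeats.
    """
    if not 20 <= length <= 60:
        raise ConfigError(f"repeat length {length} outside [20, 60] bp")
    if frame not in (0, 1, 2) or strand not in ("forward", "reverse"):
        raise ConfigError(f"bad designated frame {strand}/{frame}")
    while True:
        dna = _random_dna(rng, length)
        frames = {
            (t.strand, t.frame): t.peptide
            for t in translate_six_frames(dna, repeat_id=repeat_id)
        }
        if (strand, frame) in frames:
            return RepeatRecord(repeat_id=repeat_id, dna=dna)


def designated_peptide(repeat: RepeatRecord, strand: str, frame: int) -> str:
    """The stop-free frame peptide the planted ORF exposes."""
    seq = repeat.dna if strand == "forward" else reverse_complement(repeat.dna)
    block = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
    return str(Seq(block).translate(table=1))


def _codon_block(repeat: RepeatRecord, strand: str, frame: int) -> str:
    seq = repeat.dna if strand == "forward" else reverse_complement(repeat.dna)
    return seq[frame : frame + 3 * ((len(seq) - frame) // 3)]


def _cluster_genes(
    rng: np.random.Generator,
    genome_accession: str,
    genome_length: int,
    subtype: str,
    required: list[str],
    domain_by_label: dict[str, str],
    gene_prefix: str,
    start: int,
    plant_failing: bool,
) -> tuple[list[GeneLocus], list[CasHit], int]:
    """A complete cas cluster with passing hits; returns (loci, hits, end)."""
    loci: list[GeneLocus] = []
    hits: list[CasHit] = []
    pos = start
    for k, label in enumerate(required):
        # 450-1050 bp keeps even an 8-gene cluster compact enough that the
        # whole cluster fits inside the 10 kb window of an adjacent array
        length = 3 * int(rng.integers(150, 350))
        locus = GeneLocus(
            genome_accession=genome_accession,
            genome_length=genome_length,
            gene_id=f"{gene_prefix}_cas{k:02d}",
            start=pos,
            end=pos + length,
            strand="+" if rng.integers(0, 2) == 0 else "-",
        )
        loci.append(locus)
        hits.append(
            CasHit(
                gene_id=locus.gene_id,
                domain_id=domain_by_label[label],
                cas_label=label,
                evalue=float(10.0 ** -rng.uniform(6.0, 30.0)),
                identity_pct=float(rng.uniform(30.0, 95.0)),
                coverage=float(rng.uniform(0.75, 1.0)),
            )
        )
        pos += length + int(rng.integers(50, 200))
    if plant_failing:
        # each row must fail exactly one threshold and be filtered out
        decoy_domain = domain_by_label["cas9"]
        for evalue, ident, cov in (
            (1e-4, 50.0, 0.9),
            (1e-9, 20.0, 0.9),
            (1e-9, 50.0, 0.5),
        ):
            hits.append(
                CasHit(
                    gene_id=loci[0].gene_id,
                    domain_id=decoy_domain,
                    cas_label="cas9",
                    evalue=evalue,
                    identity_pct=ident,
                    coverage=cov,
                )
            )
    return loci, hits, pos


def generate_locus(
    rng: np.random.Generator,
    locus_index: int,
    planted_class: str,
    spec: FixtureSpec,
    subtype_names: list[str],
    subtype_genes: dict[str, list[str]],
    domain_by_label: dict[str, str],
) -> LocusBundle:
    """One genome with its planted protein, annotation and cas evidence."""
    if planted_class not in CLASSES:
        raise ConfigError(f"unknown planted class {planted_class!r}")
    genome_accession = f"SYNG{locus_index:04d}.1"
    genome_length = spec.genome_length
    accession = f"SYNP{locus_index:05d}"
    gene_prefix = f"SYNG{locus_index:04d}"
    division = "archaea" if rng.uniform() < 0.3 else "bacteria"
    section = "sp" if rng.uniform() < 0.05 else "tr"
    year = int(rng.integers(2005, 2020))
    meta = {"section": section, "division": division, "year": year}

    gene_loci: list[GeneLocus] = []
    cas_hits: list[CasHit] = []
    inserts: list[tuple[int, str]] = []
    repeat: Optional[RepeatRecord] = None

    if planted_class in ("spurious_with_cluster", "spurious_split_array"):
        subtype = subtype_names[int(rng.integers(0, len(subtype_names)))]
        required = sorted(subtype_genes[subtype])
        cluster_loci, hits, cluster_end = _cluster_genes(
            rng,
            genome_accession,
            genome_length,
            subtype,
            required,
            domain_by_label,
            gene_prefix,
            start=20_000,
            plant_failing=bool(rng.integers(0, 2)),
        )
        gene_loci.extend(cluster_loci)
        cas_hits.extend(hits)

        strand = "forward" if rng.integers(0, 2) == 0 else "reverse"
        frame = int(rng.integers(0, 3))
        repeat = generate_repeat(
            rng,
            length=int(rng.integers(spec.repeat_len_range[0], spec.repeat_len_range[1] + 1)),
            strand=strand,
            frame=frame,
            repeat_id=f"SYNR{locus_index:04d}",
        )
        block = _codon_block(repeat, strand, frame)
        n_units = int(rng.integers(spec.n_units_range[0], spec.n_units_range[1] + 1))
        gap_lo = max(7, spec.spacer_len_range_bp[0] // 3)
        gap_hi = min(20, spec.spacer_len_range_bp[1] // 3)
        pieces = [_sense_codon_dna(rng, int(rng.integers(2, 10)))]  # N flank
        for u in range(n_units):
            if u:
                pieces.append(
                    _sense_codon_dna(rng, int(rng.integers(gap_lo, gap_hi + 1)))
                )
            pieces.append(block)
        pieces.append(_sense_codon_dna(rng, int(rng.integers(2, 10))))  # C flank
        orf_dna = "".join(pieces)
        if spec.enforce_orf_grammar:
            orf_dna = "ATG" + orf_dna
        protein_seq = str(Seq(orf_dna).translate(table=1))
        assert "*" not in protein_seq

        if planted_class == "spurious_with_cluster":
            # cap the gap so every cluster gene stays inside the window:
            # the farthest gene is the first one, at (cluster_end -
            # first_gene_end) + gap from the array
            first_gene_end = cluster_loci[0].end
            gap_cap = 10_000 - (cluster_end - first_gene_end)
            orf_start = cluster_end + int(rng.integers(500, min(3000, gap_cap)))
            expected = STATUS_PFP
        else:
            orf_start = cluster_end + int(rng.integers(12_000, 20_000))
            expected = STATUS_NEGATIVE
        orf_end = orf_start + len(orf_dna)
        if spec.enforce_orf_grammar:
            inserts.append((orf_end, _STOP_FOR(rng)))
        if orf_end + 3 > genome_length:
            raise ConfigError(
                f"locus {locus_index}: planted array [{orf_start},{orf_end}) "
                f"does not fit in a {genome_length} bp genome"
            )
        gene_strand = "+" if strand == "forward" else "-"
        genomic = orf_dna if strand == "forward" else reverse_complement(orf_dna)
        inserts.append((orf_start, genomic))
        orf_locus = GeneLocus(
            genome_accession=genome_accession,
            genome_length=genome_length,
            gene_id=f"{gene_prefix}_orf",
            start=orf_start,
            end=orf_end,
            strand=gene_strand,
        )
        gene_loci.append(orf_locus)
        truth = FixtureTruth(
            accession=accession,
            planted_class=planted_class,
            expected_status=expected,
            repeat_id=repeat.repeat_id,
            strand=strand,
            frame=frame,
            genome_accession=genome_accession,
            gene_id=orf_locus.gene_id,
            array_start=orf_start,
            array_end=orf_end,
        )
        meta["subtype"] = subtype
    else:
        flank_n = _random_peptide(rng, int(rng.integers(5, 15)))
        flank_c = _random_peptide(rng, int(rng.integers(5, 15)))
        gap = int(rng.integers(7, 21))
        if planted_class == "true_protein":
            unit = _random_peptide(rng, 13)
            pos = 6  # central mismatch keeps every exact common block < 7 aa
            alt = _other_residue(unit[pos])
            copy2 = unit[:pos] + alt + unit[pos + 1 :]
            spacer = _guarded_spacer(rng, gap, flank_n[-1], flank_c[0])
            core = unit + spacer + copy2
        elif planted_class == "decoy_short_repeat":
            unit = _random_peptide(rng, 6)
            spacer = _guarded_spacer(rng, gap, flank_n[-1], flank_c[0])
            core = unit + spacer + unit
        else:  # decoy_tandem
            unit = _random_peptide(rng, int(rng.integers(7, 11)))
            core = unit * int(rng.integers(3, 5))
        protein_seq = flank_n + core + flank_c
        gene_start = int(genome_length * 0.6) + int(rng.integers(0, 5_000))
        coding = _encode_peptide(rng, protein_seq)
        gene_end = gene_start + len(coding)
        inserts.append((gene_start, coding))
        locus = GeneLocus(
            genome_accession=genome_accession,
            genome_length=genome_length,
            gene_id=f"{gene_prefix}_orf",
            start=gene_start,
            end=gene_end,
            strand="+",
        )
        gene_loci.append(locus)
        truth = FixtureTruth(
            accession=accession,
            planted_class=planted_class,
            expected_status="not_candidate",
            genome_accession=genome_accession,
            gene_id=locus.gene_id,
        )

    protein = ProteinRecord(
        accession=accession,
        sequence=protein_seq,
        section=section,
        division=division,
        year=year,
        locus_ref=(genome_accession, f"{gene_prefix}_orf"),
    )
    return LocusBundle(
        genome_accession=genome_accession,
        genome_length=genome_length,
        planted_class=planted_class,
        gene_loci=gene_loci,
        cas_hits=cas_hits,
        protein=protein,
        truth=truth,
        repeat=repeat,
        inserts=inserts,
        meta=meta,
    )


def _STOP_FOR(rng: np.random.Generator) -> str:
    return sorted(_STOPS)[int(rng.integers(0, 3))]


_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in _SENSE_CODONS:
    _CODONS_BY_AA.setdefault(str(Seq(_codon).translate(table=1)), []).append(_codon)


def _other_residue(aa: str) -> str:
    return _AA_ALPHABET[(_AA_ALPHABET.index(aa) + 1) % len(_AA_ALPHABET)]


def _guarded_spacer(
    rng: np.random.Generator, gap: int, before_first: str, after_last: str
) -> str:
    """Random spacer whose boundary residues cannot extend the planted
    decoy copies into an in-range perfect unit.

    The residue preceding copy 2 (spacer end) must differ from the one
    preceding copy 1, and the residue following copy 1 (spacer start)
    must differ from the one following copy 2 — otherwise a chance
    coincidence would lengthen the exact block past the unit-length
    floor and the decoy would stop being a decoy.
    """
    spacer = list(_random_peptide(rng, gap))
    if spacer[0] == after_last:
        spacer[0] = _other_residue(spacer[0])
    if spacer[-1] == before_first:
        spacer[-1] = _other_residue(spacer[-1])
    return "".join(spacer)


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    """Reverse-translate with uniformly random synonymous codons."""
    return "".join(
        _CODONS_BY_AA[aa][int(rng.integers(0, len(_CODONS_BY_AA[aa])))]
        for aa in peptide
    )


def _class_counts(spec: FixtureSpec) -> list[str]:
    """Deterministic largest-remainder apportionment of loci to classes."""
    quotas = {c: spec.n_loci * spec.class_fractions.get(c, 0.0) for c in CLASSES}
    counts = {c: int(q) for c, q in quotas.items()}
    short = spec.n_loci - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: (-(quotas[c] - counts[c]), c))[:short]:
        counts[c] += 1
    out: list[str] = []
    for c in CLASSES:
        out.extend([c] * counts[c])
    return out


def generate_fixture(spec: FixtureSpec) -> list[LocusBundle]:
    """All locus bundles of a fixture, in deterministic order."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subtype_defs = load_subtype_definitions()
    subtype_names = sorted(d.subtype for d in subtype_defs)
    subtype_genes = {d.subtype: sorted(d.required_genes) for d in subtype_defs}
    label_map = load_domain_label_map()
    domain_by_label = {label: dom for dom, label in sorted(label_map.items())}
    classes = _class_counts(spec)
    rng.shuffle(classes)
    return [
        generate_locus(
            rng, i, cls, spec, subtype_names, subtype_genes, domain_by_label
        )
        for i, cls in enumerate(classes)
    ]


def _genome_sequence(
    rng: np.random.Generator, length: int, inserts: list[tuple[int, str]]
) -> str:
    arr = _BASES[rng.integers(0, 4, size=length)]
    for pos, dna in inserts:
        arr[pos : pos + len(dna)] = np.frombuffer(dna.encode(), dtype=np.uint8)
    return arr.tobytes().decode()


def write_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write the complete fixture and return its manifest.

    Files: genome.fasta, genes.gff3, cas_hits.tsv, proteins.fasta,
    proteins_meta.tsv, repeats.fasta, truth.tsv, manifest.json.  The
    manifest embeds the spec and a SHA-256 per file; rerunning with the
    same seed reproduces identical checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = generate_fixture(spec)
    genome_rng = np.random.default_rng(spec.seed + 1_000_003)

    with open(out_dir / "genome.fasta", "w") as fh:
        for b in bundles:
            seq = _genome_sequence(genome_rng, b.genome_length, b.inserts)
            fh.write(f">{b.genome_accession}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    all_loci = [locus for b in bundles for locus in b.gene_loci]
    lengths = {b.genome_accession: b.genome_length for b in bundles}
    write_gff3(all_loci, lengths, out_dir / "genes.gff3")
    write_cas_hits_tsv(
        [h for b in bundles for h in b.cas_hits], out_dir / "cas_hits.tsv"
    )
    write_fasta(
        out_dir / "proteins.fasta",
        [(b.protein.accession, b.protein.sequence) for b in bundles],
    )
    write_fasta(
        out_dir / "repeats.fasta",
        [(b.repeat.repeat_id, b.repeat.dna) for b in bundles if b.repeat is not None],
    )
    pd.DataFrame(
        [
            {
                "accession": b.protein.accession,
                "section": b.protein.section,
                "division": b.protein.division,
                "year": b.protein.year,
                "genome_accession": b.genome_accession,
                "gene_id": b.protein.locus_ref[1],
            }
            for b in bundles
        ],
        columns=["accession", "section", "division", "year", "genome_accession", "gene_id"],
    ).to_csv(out_dir / "proteins_meta.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(b.truth) for b in bundles],
        columns=[
            "accession",
            "planted_class",
            "expected_status",
            "repeat_id",
            "strand",
            "frame",
            "genome_accession",
            "gene_id",
            "array_start",
            "array_end",
        ],
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)

    files = [
        "genome.fasta",
        "genes.gff3",
        "cas_hits.tsv",
        "proteins.fasta",
        "proteins_meta.tsv",
        "repeats.fasta",
        "truth.tsv",
    ]
    manifest = {
        "spec": dataclasses.asdict(spec),
        "n_loci": spec.n_loci,
        "checksums": {
            name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("fixture with %d loci written to %s", spec.n_loci, out_dir)
    return manifest
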