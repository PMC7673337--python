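"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Bio.SeqIO, GFF3 through gffutils (in-memory sqlite),
tables through pandas.  All tables are tab-separated UTF-8 with a header
row, no quoting, '.' decimal, floats printed to 6 significant digits —
so identical inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .model import (
    Candidate,
    CasHit,
    ContextClassification,
    GeneLocus,
    ProteinRecord,
    RepeatRecord,
)
from .translation import PeptideIndex

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def _float(value: float) -> str:
    return FLOAT_FORMAT % value


# ---------------------------------------------------------------------------
# FASTA


def read_repeats_fasta(path) -> list[RepeatRecord]:
    """Repeat DNA FASTA; record id = repeat_id, description free text."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"repeat FASTA not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            RepeatRecord(
                repeat_id=rec.id,
                dna=str(rec.seq).upper(),
                source=rec.description if rec.description != rec.id else None,
            )
        )
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def parse_accession(header_id: str) -> str:
    """Accession from a UniProt-style ``db|ACCESSION|entry`` id, else the id."""
    if "|" in header_id:
        fields = header_id.split("|")
        if len(fields) >= 2 and fields[1]:
            return fields[1]
    return header_id


def read_proteins_fasta(
    path, metadata: Optional[Mapping[str, Mapping[str, object]]] = None
) -> Iterator[ProteinRecord]:
    """Stream a protein FASTA, attaching optional per-accession metadata."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"protein FASTA not found: {path}")
    metadata = metadata or {}
    position = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        position += 1
        accession = parse_accession(rec.id)
        sequence = str(rec.seq).upper()
        if not sequence:
            raise InputError(f"{path}: record {position} ({accession}) is empty")
        meta = metadata.get(accession, {})
        locus_ref = None
        if meta.get("genome_accession") and meta.get("gene_id"):
            locus_ref = (str(meta["genome_accession"]), str(meta["gene_id"]))
        year = meta.get("year")
        yield ProteinRecord(
            accession=accession,
            sequence=sequence,
            section=meta.get("section"),
            division=meta.get("division"),
            year=int(year) if year not in (None, "") and not pd.isna(year) else None,
            locus_ref=locus_ref,
        )


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write (identifier, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# metadata / tables


def read_protein_metadata(path) -> dict[str, dict[str, object]]:
    """Metadata TSV keyed by accession.

    Recognized columns: accession (required), section, division, year,
    genome_accession, gene_id; unknown columns pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise InputError(f"{path}: metadata TSV lacks an 'accession' column")
    out: dict[str, dict[str, object]] = {}
    for row in df.to_dict(orient="records"):
        out[str(row["accession"])] = {k: (v or None) for k, v in row.items()}
    return out


def write_peptide_index_tsv(index: PeptideIndex, path) -> None:
    rows = [
        {
            "repeat_id": t.repeat_id,
            "strand": "+" if t.strand == "forward" else "-",
            "frame": t.frame,
            "peptide": t.peptide,
        }
        for t in sorted(
            index.entries(), key=lambda t: (t.repeat_id, t.strand, t.frame)
        )
    ]
    pd.DataFrame(
        rows, columns=["repeat_id", "strand", "frame", "peptide"]
    ).to_csv(path, sep="\t", index=False)


CANDIDATE_COLUMNS = [
    "accession",
    "approach",
    "repeat_id",
    "strand",
    "unit",
    "unit_length",
    "n_matches",
    "match_starts",
    "spacer_lengths",
    "protein_length",
]


def write_candidates_tsv(candidates: Iterable[Candidate], path) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "accession": c.accession,
                "approach": c.approach,
                "repeat_id": c.repeat_id or "",
                "strand": {"forward": "+", "reverse": "-"}.get(c.strand or "", ""),
                "unit": c.unit or "",
                "unit_length": len(c.unit) if c.unit else "",
                "n_matches": len(c.matches),
                "match_starts": ",".join(str(m.start) for m in c.matches),
                "spacer_lengths": ",".join(str(g) for g in c.spacer_lengths),
                "protein_length": c.protein_length,
            }
        )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = {"accession", "approach", "protein_length"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: candidate TSV lacks columns {sorted(missing)}")
    return df


def write_classifications_tsv(
    classifications: Mapping[str, ContextClassification], path
) -> None:
    rows = []
    for acc in sorted(classifications):
        c = classifications[acc]
        rows.append(
            {
                "accession": c.accession,
                "status": c.status,
                "rule": c.rule,
                "matched_subtype": c.matched_subtype or "",
                "n_cas_genes": c.n_cas_genes,
                "distance_to_nearest_cas": (
                    c.distance_to_nearest_cas
                    if c.distance_to_nearest_cas is not None
                    else ""
                ),
                "genome_accession": c.genome_accession or "",
                "genome_length": c.genome_length if c.genome_length is not None else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "accession",
            "status",
            "rule",
            "matched_subtype",
            "n_cas_genes",
            "distance_to_nearest_cas",
            "genome_accession",
            "genome_length",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cas hits


def read_cas_hits_tsv(
    path, domain_label_map: Optional[Mapping[str, str]] = None
) -> list[CasHit]:
    """Hit table with columns gene_id, domain_id, evalue, identity_pct,
    coverage and optionally cas_label.

    Rows without a cas_label are labeled through ``domain_label_map``;
    unmappable or malformed rows are skipped with a warning and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "domain_id", "evalue", "identity_pct", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: cas hit TSV lacks columns {sorted(missing)}")
    domain_label_map = domain_label_map or {}
    hits: list[CasHit] = []
    n_skipped = 0
    for i, row in enumerate(df.to_dict(orient="records"), start=2):
        try:
            label = str(row.get("cas_label") or "") or domain_label_map.get(
                str(row["domain_id"]), ""
            )
            if not label:
                raise ValueError(f"domain {row['domain_id']!r} has no cas label")
            hit = CasHit(
                gene_id=str(row["gene_id"]),
                domain_id=str(row["domain_id"]),
                cas_label=label,
                evalue=float(row["evalue"]),
                identity_pct=float(row["identity_pct"]),
                coverage=float(row["coverage"]),
            )
            if hit.evalue < 0 or not 0 <= hit.identity_pct <= 100 or not 0 <= hit.coverage <= 1:
                raise ValueError("score out of range")
        except (ValueError, TypeError, KeyError) as exc:
            n_skipped += 1
            log.warning("%s line %d: skipping malformed hit row (%s)", path, i, exc)
            continue
        hits.append(hit)
    if n_skipped:
        log.warning("%s: %d malformed hit rows skipped", path, n_skipped)
    return hits


def write_cas_hits_tsv(hits: Iterable[CasHit], path) -> None:
    rows = [
        {
            "gene_id": h.gene_id,
            "domain_id": h.domain_id,
            "cas_label": h.cas_label,
            "evalue": _float(h.evalue),
            "identity_pct": _float(h.identity_pct),
            "coverage": _float(h.coverage),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "domain_id", "cas_label", "evalue", "identity_pct", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def parse_rpsblast_outfmt6(
    path, domain_label_map: Optional[Mapping[str, str]] = None
) -> list[CasHit]:
    """Parse RPS-BLAST tabular output.

    Expected column order: qseqid sseqid pident length qlen slen evalue
    (``-outfmt "6 qseqid sseqid pident length qlen slen evalue"``).
    Coverage is computed as aligned-length / subject (domain) length.
    """
    names = ["qseqid", "sseqid", "pident", "length", "qlen", "slen", "evalue"]
    df = pd.read_csv(path, sep="\t", names=names, comment="#", dtype=str)
    hits: list[CasHit] = []
    n_skipped = 0
    domain_label_map = domain_label_map or {}
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            domain_id = str(row["sseqid"]).split("|")[-1]
            label = domain_label_map.get(domain_id, "")
            if not label:
                raise ValueError(f"domain {domain_id!r} has no cas label")
            hits.append(
                CasHit(
                    gene_id=str(row["qseqid"]),
                    domain_id=domain_id,
                    cas_label=label,
                    evalue=float(row["evalue"]),
                    identity_pct=float(row["pident"]),
                    coverage=float(row["length"]) / float(row["slen"]),
                )
            )
        except (ValueError, TypeError, ZeroDivisionError) as exc:
            n_skipped += 1
            log.warning("%s line %d: skipping malformed row (%s)", path, i, exc)
    if n_skipped:
        log.warning("%s: %d malformed rows skipped", path, n_skipped)
    return hits


def run_rpsblast(
    query_fasta, cdd_db, out_path, rpsblast_exe: str = "rpsblast"
) -> Path:
    """Invoke an installed rpsblast and return the tabular output path.

    Optional convenience only — the pipeline's contract is the
    precomputed hit table, and nothing in the package requires the
    external tool to be present.
    """
    import subprocess

    out_path = Path(out_path)
    cmd = [
        rpsblast_exe,
        "-query",
        str(query_fasta),
        "-db",
        str(cdd_db),
        "-outfmt",
        "6 qseqid sseqid pident length qlen slen evalue",
        "-out",
        str(out_path),
    ]
    subprocess.run(cmd, check=True)
    return out_path


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path, lengths_tsv=None) -> tuple[dict[str, GeneLocus], dict[str, int]]:
    """Gene loci and genome lengths from a GFF3 annotation.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open.  Genome lengths come from ``##sequence-region`` directives
    or, with priority, from a two-column (genome_accession, length) TSV.
    Returns (gene_id -> locus, genome_accession -> length).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GFF3 not found: {path}")
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                fields = line.split()
                if len(fields) >= 4:
                    lengths[fields[1]] = int(fields[3])
            elif not line.startswith("#"):
                break
    if lengths_tsv is not None:
        df = pd.read_csv(
            lengths_tsv, sep="\t", names=["genome_accession", "length"], header=0
        )
        lengths.update(
            {str(r.genome_accession): int(r.length) for r in df.itertuples()}
        )
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    loci: dict[str, GeneLocus] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genome = feat.seqid
        if genome not in lengths:
            raise InputError(
                f"{path}: no genome length for {genome!r} "
                "(missing ##sequence-region and no lengths TSV)"
            )
        gene_id = feat.attributes.get("locus_tag", [feat.id])[0]
        locus = GeneLocus(
            genome_accession=genome,
            genome_length=lengths[genome],
            gene_id=gene_id,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
        )
        locus.validate()
        if gene_id in loci:
            raise InputError(f"{path}: duplicate gene id {gene_id!r}")
        loci[gene_id] = locus
    return loci, lengths


def write_gff3(loci: Iterable[GeneLocus], lengths: Mapping[str, int], path) -> None:
    """Write gene loci as GFF3 (1-based inclusive on disk)."""
    by_genome: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_genome.setdefault(locus.genome_accession, []).append(locus)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome in sorted(lengths):
            fh.write(f"##sequence-region {genome} 1 {lengths[genome]}\n")
        for genome in sorted(by_genome):
            for locus in sorted(by_genome[genome], key=lambda l: l.start):
                attrs = f"ID={locus.gene_id};locus_tag={locus.gene_id}"
                fh.write(
                    "\t".join(
                        [
                            genome,
                            "spurscan",
                            "gene",
                            str(locus.start + 1),
                            str(locus.end),
                            ".",
                            locus.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
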