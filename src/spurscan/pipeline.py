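"""End-to-end orchestration: repeats + proteins + annotation -> report.

The full protocol: translate the repeat database, scan proteins with
both approaches, map every flagged protein to its gene, test the genome
length, window cas evidence and classify, then summarize.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import context as ctx
from . import io as sio
from .config import ScanConfig
from .denovo_scan import scan_database_ab_initio
from .model import Candidate, ContextClassification, GeneLocus
from .repeat_scan import scan_database
from .report import merge_external_evidence, write_summary
from .translation import build_peptide_index

log = logging.getLogger(__name__)


def run_all(
    repeats_fasta,
    proteins_fasta,
    gff3,
    cas_hits_tsv,
    meta_tsv=None,
    lengths_tsv=None,
    out_dir=".",
    config: Optional[ScanConfig] = None,
    spurio_tsv=None,
    pfam_tsv=None,
) -> dict:
    """Run the whole protocol and write candidates/classifications/summary.

    Returns the summary dict.  Outputs are deterministic: identical
    inputs reproduce byte-identical files.
    """
    config = (config or ScanConfig()).validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metadata = sio.read_protein_metadata(meta_tsv) if meta_tsv else {}
    repeats = sio.read_repeats_fasta(repeats_fasta)
    index = build_peptide_index(repeats, min_peptide_len=config.min_peptide_len)

    log.info("stage scan1: %d repeats, %d indexed peptides", len(repeats), len(index))
    candidates_i = scan_database(
        sio.read_proteins_fasta(proteins_fasta, metadata),
        index,
        spacer_min=config.spacer_min,
        spacer_max=config.spacer_max,
    )
    log.info("stage scan2")
    candidates_ii = scan_database_ab_initio(
        sio.read_proteins_fasta(proteins_fasta, metadata),
        unit_min=config.unit_min,
        unit_max=config.unit_max,
        spacer_min=config.spacer_min,
        spacer_max=config.spacer_max,
    )
    candidates = list(candidates_i) + list(candidates_ii)
    sio.write_candidates_tsv(candidates, out_dir / "candidates.tsv")

    classifications = classify_from_files(
        candidates, gff3, cas_hits_tsv, metadata, lengths_tsv, config
    )
    sio.write_classifications_tsv(classifications, out_dir / "classifications.tsv")

    meta_by_acc = {
        acc: {"section": m.get("section", "?"), "division": m.get("division", "?")}
        for acc, m in metadata.items()
    }
    summary = ctx.summarize(classifications, candidates, meta_by_acc)

    if spurio_tsv or pfam_tsv:
        table = pd.read_csv(out_dir / "classifications.tsv", sep="\t", dtype=str)
        annotated, notes = merge_external_evidence(table, spurio_tsv, pfam_tsv)
        annotated.to_csv(out_dir / "classifications_annotated.tsv", sep="\t", index=False)
        summary["external_evidence"] = notes

    write_summary(summary, out_dir / "summary.json", out_dir / "summary.txt")
    return summary


def classify_from_files(
    candidates: list[Candidate],
    gff3,
    cas_hits_tsv,
    metadata: dict,
    lengths_tsv=None,
    config: Optional[ScanConfig] = None,
) -> dict[str, ContextClassification]:
    """Context stage from on-disk annotation and hit-table inputs."""
    config = (config or ScanConfig()).validate()
    gene_loci, _lengths = sio.read_gff3(gff3, lengths_tsv)
    label_map = ctx.load_domain_label_map(config.domain_map_json)
    hits = sio.read_cas_hits_tsv(cas_hits_tsv, label_map)
    subtypes = ctx.load_subtype_definitions(config.subtypes_json)

    protein_loci: dict[str, Optional[GeneLocus]] = {}
    for cand in candidates:
        if cand.accession in protein_loci:
            continue
        meta = metadata.get(cand.accession, {})
        gene_id = meta.get("gene_id")
        locus = gene_loci.get(str(gene_id)) if gene_id else None
        if locus is None and gene_id:
            log.warning(
                "candidate %s: gene %r absent from annotation", cand.accession, gene_id
            )
        protein_loci[cand.accession] = locus

    return ctx.classify_candidates(
        candidates,
        protein_loci,
        hits,
        subtypes,
        gene_loci,
        min_genome_len=config.min_genome_len,
        window_bp=config.window_bp,
        max_evalue=config.max_evalue,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
    )
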