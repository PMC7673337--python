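"""Report assembly and optional external-evidence joins.

External tools (a spurious-protein predictor such as Spurio, or a Pfam
domain scan) are never re-implemented here; their per-accession output
can be joined onto the classification table for side-by-side reading
and a PFP-overlap count.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import pandas as pd

from .errors import InputError
from .model import STATUS_PFP

log = logging.getLogger(__name__)

#: spurio_call values treated as "predicted spurious"
SPURIO_POSITIVE = {"spurious", "positive", "1", "true", "yes"}


def merge_external_evidence(
    classifications: pd.DataFrame,
    spurio_tsv: Optional[str] = None,
    pfam_tsv: Optional[str] = None,
) -> tuple[pd.DataFrame, dict]:
    """Join optional per-accession evidence tables onto classifications.

    ``spurio_tsv`` needs columns (accession, spurio_call); ``pfam_tsv``
    needs (accession, pfam_domains).  Accessions unknown to the
    classification table are ignored with a warning.  Returns the
    annotated table and a small report dict with the PFP overlap count.
    """
    if "accession" not in classifications.columns:
        raise InputError("classification table lacks an 'accession' column")
    out = classifications.copy()
    notes: dict = {}
    known = set(out["accession"])

    if spurio_tsv is not None:
        sp = pd.read_csv(spurio_tsv, sep="\t", dtype=str)
        if {"accession", "spurio_call"} - set(sp.columns):
            raise InputError(f"{spurio_tsv}: needs columns accession, spurio_call")
        unknown = set(sp["accession"]) - known
        if unknown:
            log.warning(
                "%d spurio accessions absent from classifications (ignored)",
                len(unknown),
            )
        sp = sp[sp["accession"].isin(known)][["accession", "spurio_call"]]
        out = out.merge(sp, on="accession", how="left")
        pfp = out[out["status"] == STATUS_PFP]
        overlap = int(
            pfp["spurio_call"].fillna("").str.lower().isin(SPURIO_POSITIVE).sum()
        )
        notes["spurio_pfp_overlap"] = overlap
        notes["n_pfp"] = int((out["status"] == STATUS_PFP).sum())
    else:
        notes["spurio"] = "not provided"

    if pfam_tsv is not None:
        pf = pd.read_csv(pfam_tsv, sep="\t", dtype=str)
        if {"accession", "pfam_domains"} - set(pf.columns):
            raise InputError(f"{pfam_tsv}: needs columns accession, pfam_domains")
        unknown = set(pf["accession"]) - known
        if unknown:
            log.warning(
                "%d pfam accessions absent from classifications (ignored)",
                len(unknown),
            )
        pf = pf[pf["accession"].isin(known)][["accession", "pfam_domains"]]
        out = out.merge(pf, on="accession", how="left")
        notes["n_with_pfam"] = int(out["pfam_domains"].notna().sum())
    else:
        notes["pfam"] = "not provided"

    return out, notes


def write_summary(summary: dict, json_path, text_path=None) -> None:
    """Summary as sorted JSON plus an optional human-readable table."""
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is None:
        return
    lines = []
    header = (
        f"{'subset':<24}{'n':>6}{'tested':>8}{'neg':>6}{'cas+':>6}{'pfp':>6}"
        f"{'%cas+':>8}{'%pfp':>8}"
    )
    lines.append(header)
    lines.append("-" * len(header))

    def row(name: str, block: dict) -> str:
        s = block["by_status"]
        return (
            f"{name:<24}{block['n_candidates']:>6}{block['tested']:>8}"
            f"{s['negative']:>6}{s['cas_positive']:>6}{s['pfp']:>6}"
            f"{block['pct_cas_positive_of_tested']:>8.1f}"
            f"{block['pct_pfp_of_tested']:>8.1f}"
        )

    for approach, block in sorted(summary.get("per_approach", {}).items()):
        lines.append(row(f"approach {approach}", block))
    for subset, block in sorted(summary.get("per_subset", {}).items()):
        lines.append(row(subset, block))
    with open(text_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
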