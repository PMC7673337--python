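"""Genomic cas-gene context: windowing, evidence filtering, classification.

A flagged protein is only believed to be a translated CRISPR array when
its gene sits in a genome of useful size (>= 500 kb) and cas genes are
found within 10 kb on either side.  Evidence comes as precomputed
cas-domain hit tables (RPS-BLAST style); a hit survives when
E-value <= 1e-5, identity >= 25% and domain coverage >= 70% (all
inclusive).  A candidate is a putative false protein (PFP) when the
windowed cas labels contain all genes of one CRISPR-Cas subtype
("complete cluster") or at least both cas1 and cas2 — the universal
adaptation module.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, InputError
from .model import (
    Candidate,
    CasHit,
    CasSubtypeDefinition,
    ContextClassification,
    GeneLocus,
    STATUS_CAS_POSITIVE,
    STATUS_NEGATIVE,
    STATUS_PFP,
    STATUS_UNTESTED,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_GENOME_LEN = 500_000  # bp, inclusive
DEFAULT_WINDOW_BP = 10_000  # bp up- and downstream, inclusive
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 25.0  # percent
DEFAULT_MIN_COVERAGE = 0.70  # fraction of the domain model


def load_subtype_definitions(path=None) -> list[CasSubtypeDefinition]:
    """Load the cas subtype catalog (name -> required gene labels).

    Without ``path`` the packaged catalog is used; it carries a minimal
    published gene set per subtype and is meant to be overridden by
    users tracking a specific classification release.
    """
    if path is None:
        text = resources.files("spurscan.data").joinpath("cas_subtypes.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)
    defs = [
        CasSubtypeDefinition(subtype=name, required_genes=frozenset(genes))
        for name, genes in raw.items()
    ]
    if not defs:
        raise ConfigError("subtype catalog is empty")
    for d in defs:
        if not d.required_genes:
            raise ConfigError(f"subtype {d.subtype!r} has an empty gene set")
    return defs


def load_domain_label_map(path=None) -> dict[str, str]:
    """Load the domain-model-id -> canonical cas label mapping."""
    if path is None:
        text = (
            resources.files("spurscan.data").joinpath("cas_domain_labels.json").read_text()
        )
    else:
        text = open(path).read()
    return dict(json.loads(text))


def filter_genome(
    locus: Optional[GeneLocus], min_genome_len: int = DEFAULT_MIN_GENOME_LEN
) -> str:
    """'tested' when the candidate maps to a genome of sufficient length.

    Unmapped candidates and genomes below ``min_genome_len`` (strict;
    500,000 bp itself passes) are 'untested' and excluded from the
    Cas(+)/PFP percentages.
    """
    if locus is None:
        return STATUS_UNTESTED
    return "tested" if locus.genome_length >= min_genome_len else STATUS_UNTESTED


def filter_cas_hits(
    raw_hits: Iterable[CasHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[CasHit]:
    """Threshold hits (all bounds inclusive), then keep the best per gene.

    Best = lowest E-value, ties broken by highest identity.
    """
    passing = [
        h
        for h in raw_hits
        if h.evalue <= max_evalue
        and h.identity_pct >= min_identity
        and h.coverage >= min_coverage
    ]
    best: dict[str, CasHit] = {}
    for h in passing:
        cur = best.get(h.gene_id)
        if cur is None or (h.evalue, -h.identity_pct) < (cur.evalue, -cur.identity_pct):
            best[h.gene_id] = h
    return [best[g] for g in sorted(best)]


def interval_distance(a: GeneLocus, b: GeneLocus) -> int:
    """Gap in bp between two gene intervals; 0 when they overlap."""
    if a.genome_accession != b.genome_accession:
        raise InputError(
            f"cannot measure distance across genomes "
            f"({a.genome_accession!r} vs {b.genome_accession!r})"
        )
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def window_cas_genes(
    candidate_locus: GeneLocus,
    cas_genes: Iterable[tuple[CasHit, GeneLocus]],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[tuple[CasHit, GeneLocus, int]]:
    """cas genes within ``window_bp`` of the candidate gene's boundaries.

    Distance is measured boundary-to-boundary (0 on overlap) and the
    bound is inclusive: a gene exactly 10,000 bp away counts, 10,001 bp
    does not.  cas gene strand is ignored.
    """
    out = []
    for hit, locus in cas_genes:
        dist = interval_distance(candidate_locus, locus)
        if dist <= window_bp:
            out.append((hit, locus, dist))
    out.sort(key=lambda t: (t[2], t[1].start, t[0].gene_id))
    return out


def classify(
    accession: str,
    windowed_cas: Sequence[tuple[CasHit, GeneLocus, int]],
    subtypes: Sequence[CasSubtypeDefinition],
    genome_accession: Optional[str] = None,
    genome_length: Optional[int] = None,
) -> ContextClassification:
    """Classify one tested candidate from its windowed cas evidence.

    negative: no cas gene in the window; cas_positive: at least one;
    pfp: the windowed label set covers a complete subtype cluster
    (rule=cluster, first matching subtype in name order) or contains
    both cas1 and cas2 (rule=cas1cas2).  Duplicate labels (paralogs)
    count once; the result depends only on the label set, never on hit
    order.
    """
    if not subtypes:
        raise ConfigError("no subtype definitions supplied for the cluster rule")
    if not windowed_cas:
        return ContextClassification(
            accession=accession,
            status=STATUS_NEGATIVE,
            n_cas_genes=0,
            genome_accession=genome_accession,
            genome_length=genome_length,
        )
    labels = {hit.cas_label for hit, _, _ in windowed_cas}
    distance = min(d for _, _, d in windowed_cas)
    n_genes = len({locus.gene_id for _, locus, _ in windowed_cas})
    matched = next(
        (
            d.subtype
            for d in sorted(subtypes, key=lambda d: d.subtype)
            if d.required_genes <= labels
        ),
        None,
    )
    if matched is not None:
        status, rule = STATUS_PFP, "cluster"
    elif {"cas1", "cas2"} <= labels:
        status, rule = STATUS_PFP, "cas1cas2"
    else:
        status, rule = STATUS_CAS_POSITIVE, "none"
    return ContextClassification(
        accession=accession,
        status=status,
        n_cas_genes=n_genes,
        distance_to_nearest_cas=distance,
        matched_subtype=matched,
        rule=rule,
        genome_accession=genome_accession,
        genome_length=genome_length,
    )


def classify_candidates(
    candidates: Sequence[Candidate],
    protein_loci: Mapping[str, Optional[GeneLocus]],
    cas_hits: Iterable[CasHit],
    subtypes: Sequence[CasSubtypeDefinition],
    gene_loci: Mapping[str, GeneLocus],
    min_genome_len: int = DEFAULT_MIN_GENOME_LEN,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, ContextClassification]:
    """Run the full context stage for every distinct candidate accession.

    ``protein_loci`` maps accession -> candidate gene locus (or None when
    unmapped); ``gene_loci`` maps gene_id -> locus for the genes named in
    the hit table.  Hits are filtered once, joined to their loci and
    grouped per genome before windowing.
    """
    kept = filter_cas_hits(
        cas_hits,
        max_evalue=max_evalue,
        min_identity=min_identity,
        min_coverage=min_coverage,
    )
    by_genome: dict[str, list[tuple[CasHit, GeneLocus]]] = defaultdict(list)
    n_unmapped_hits = 0
    for hit in kept:
        locus = gene_loci.get(hit.gene_id)
        if locus is None:
            n_unmapped_hits += 1
            continue
        by_genome[locus.genome_accession].append((hit, locus))
    if n_unmapped_hits:
        log.warning("%d cas hits reference genes absent from the annotation", n_unmapped_hits)

    out: dict[str, ContextClassification] = {}
    for cand in candidates:
        if cand.accession in out:
            continue
        locus = protein_loci.get(cand.accession)
        if filter_genome(locus, min_genome_len) == STATUS_UNTESTED:
            length = locus.genome_length if locus else None
            acc = locus.genome_accession if locus else None
            log.info(
                "candidate %s untested (%s)",
                cand.accession,
                f"genome {acc} is {length} bp" if locus else "no genome mapping",
            )
            out[cand.accession] = ContextClassification(
                accession=cand.accession,
                status=STATUS_UNTESTED,
                genome_accession=acc,
                genome_length=length,
            )
            continue
        assert locus is not None
        windowed = window_cas_genes(
            locus, by_genome.get(locus.genome_accession, []), window_bp
        )
        out[cand.accession] = classify(
            cand.accession,
            windowed,
            subtypes,
            genome_accession=locus.genome_accession,
            genome_length=locus.genome_length,
        )
    return out


def _median_lower(values: Sequence[float]) -> Optional[float]:
    """Lower median: element at index (n-1)//2 of the sorted values.

    No interpolation on even sizes, so integer inputs give integer
    medians and summary tables stay reproducible byte for byte.
    """
    if not values:
        return None
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def summarize(
    classifications: Mapping[str, ContextClassification],
    candidates: Sequence[Candidate],
    protein_meta: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> dict:
    """Per-approach (and per section x division subset) summary report.

    Reports counts by status, Cas(+)/PFP percentages of tested
    candidates, lower-median candidate lengths (Cas(+) and PFP
    separately), lower-median distance to the nearest cas gene, and the
    fraction of Cas(+) candidates with >= 3 cas genes in the window.
    """
    protein_meta = protein_meta or {}

    def subset_of(acc: str) -> tuple[str, str]:
        meta = protein_meta.get(acc, {})
        return (str(meta.get("section", "?")), str(meta.get("division", "?")))

    def block(accs: set[str], lengths: Mapping[str, int]) -> dict:
        cls = [classifications[a] for a in sorted(accs) if a in classifications]
        n = len(cls)
        by_status = {
            s: sum(1 for c in cls if c.status == s)
            for s in (STATUS_UNTESTED, STATUS_NEGATIVE, STATUS_CAS_POSITIVE, STATUS_PFP)
        }
        # pfp candidates also count as cas-positive evidence holders
        tested = n - by_status[STATUS_UNTESTED]
        cas_pos = [c for c in cls if c.status in (STATUS_CAS_POSITIVE, STATUS_PFP)]
        pfp = [c for c in cls if c.status == STATUS_PFP]
        return {
            "n_candidates": n,
            "tested": tested,
            "by_status": by_status,
            "pct_cas_positive_of_tested": (
                round(100.0 * len(cas_pos) / tested, 6) if tested else 0.0
            ),
            "pct_pfp_of_tested": (
                round(100.0 * len(pfp) / tested, 6) if tested else 0.0
            ),
            "median_length_cas_positive": _median_lower(
                [lengths[c.accession] for c in cas_pos]
            ),
            "median_length_pfp": _median_lower([lengths[c.accession] for c in pfp]),
            "median_distance_to_cas": _median_lower(
                [
                    c.distance_to_nearest_cas
                    for c in cas_pos
                    if c.distance_to_nearest_cas is not None
                ]
            ),
            "frac_cas_positive_ge3_cas_genes": (
                round(
                    sum(1 for c in cas_pos if c.n_cas_genes >= 3) / len(cas_pos), 6
                )
                if cas_pos
                else 0.0
            ),
        }

    report: dict = {"per_approach": {}, "per_subset": {}}
    for approach in ("I", "II"):
        of_approach = [c for c in candidates if c.approach == approach]
        accs = {c.accession for c in of_approach}
        lengths = {c.accession: c.protein_length for c in of_approach}
        report["per_approach"][approach] = block(accs, lengths)
        subsets: dict[tuple[str, str], set[str]] = defaultdict(set)
        for acc in accs:
            subsets[subset_of(acc)].add(acc)
        for (section, division), sub_accs in sorted(subsets.items()):
            report["per_subset"][f"{approach}/{section}/{division}"] = block(
                sub_accs, lengths
            )
    return report
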