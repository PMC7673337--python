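"""Approach I: scan proteins for regularly interspaced translated-repeat peptides.

A protein is flagged when >= 2 exact, non-overlapping occurrences of
peptides from one (repeat, strand) group appear with every consecutive
gap of 7-20 aa (the amino-acid equivalent of a 21-60 bp DNA spacer).
Matching is exact; 'X' in a protein never matches anything because the
indexed peptides are stop-free translations over the 20 standard
residues.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Iterator

from .errors import InputError
from .model import Candidate, ProteinRecord, RepeatMatch
from .translation import PeptideIndex

log = logging.getLogger(__name__)

DEFAULT_SPACER_MIN = 7  # aa; 21 bp of DNA
DEFAULT_SPACER_MAX = 20  # aa; 60 bp of DNA


def _occurrences(sequence: str, peptide: str) -> Iterator[int]:
    """All (possibly overlapping) start offsets of ``peptide``."""
    pos = sequence.find(peptide)
    while pos != -1:
        yield pos
        pos = sequence.find(peptide, pos + 1)


def _best_chain(
    matches: list[RepeatMatch], spacer_min: int, spacer_max: int
) -> list[RepeatMatch]:
    """Maximal chain of non-overlapping matches with all gaps in range.

    Dynamic programming over matches sorted by (start, -length, frame):
    the longest accepting chain is found even when a shorter greedy
    prefix would dead-end; ties prefer earlier starts, then longer
    peptides, then lower frame numbers.
    """
    order = sorted(matches, key=lambda m: (m.start, -(m.end - m.start), m.frame))
    best_len = [1] * len(order)
    prev = [-1] * len(order)
    for i, mi in enumerate(order):
        for j in range(i):
            mj = order[j]
            gap = mi.start - mj.end
            if spacer_min <= gap <= spacer_max and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not order:
        return []
    # pick the longest chain; earliest end index wins ties (stable order)
    top = max(best_len)
    i = best_len.index(top)
    chain: list[RepeatMatch] = []
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return chain


def scan_protein(
    protein: ProteinRecord,
    index: PeptideIndex,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> list[Candidate]:
    """Scan one protein against every (repeat, strand) peptide group.

    Returns at most one candidate per (repeat_id, strand): the maximal
    accepting chain.  A chain may mix the different frame peptides of
    one strand group but never peptides of different strands or repeats.
    """
    if spacer_min > spacer_max:
        raise InputError(f"spacer_min {spacer_min} > spacer_max {spacer_max}")
    seq = protein.sequence
    out: list[Candidate] = []
    for (repeat_id, strand), bucket in index.groups.items():
        matches = [
            RepeatMatch(
                peptide=tr.peptide,
                repeat_id=repeat_id,
                strand=strand,
                frame=tr.frame,
                start=pos,
                end=pos + len(tr.peptide),
            )
            for tr in bucket
            for pos in _occurrences(seq, tr.peptide)
        ]
        if len(matches) < 2:
            continue
        chain = _best_chain(matches, spacer_min, spacer_max)
        if len(chain) < 2:
            continue
        gaps = tuple(
            chain[k + 1].start - chain[k].end for k in range(len(chain) - 1)
        )
        out.append(
            Candidate(
                accession=protein.accession,
                approach="I",
                matches=tuple(chain),
                spacer_lengths=gaps,
                protein_length=len(seq),
                repeat_id=repeat_id,
                strand=strand,
            )
        )
    out.sort(key=lambda c: (c.repeat_id, c.strand))
    return out


def scan_database(
    proteins: Iterable[ProteinRecord],
    index: PeptideIndex,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> list[Candidate]:
    """Stream a protein database through :func:`scan_protein`.

    Memory per record is constant; candidates come out in input order,
    then repeat_id, then strand.  Duplicate accessions are an error.
    Per-subset (section x division) candidate counts go to the log.
    """
    if len(index) == 0:
        log.warning("empty peptide index: no protein can be flagged")
    seen: set[str] = set()
    subset_counts: Counter[tuple[str, str]] = Counter()
    candidates: list[Candidate] = []
    n_proteins = 0
    for protein in proteins:
        n_proteins += 1
        if protein.accession in seen:
            raise InputError(f"duplicate protein accession {protein.accession!r}")
        seen.add(protein.accession)
        found = scan_protein(protein, index, spacer_min, spacer_max)
        if found:
            subset_counts[(protein.section or "?", protein.division or "?")] += 1
        candidates.extend(found)
    for (section, division), n in sorted(subset_counts.items()):
        log.info("approach I: subset %s/%s -> %d flagged proteins", section, division, n)
    log.info(
        "approach I: %d proteins scanned, %d candidates from %d proteins",
        n_proteins,
        len(candidates),
        len({c.accession for c in candidates}),
    )
    return candidates
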