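"""Approach II: ab initio detection of perfect interspaced peptide repeats.

Finds proteins carrying >= 2 exact copies of a 7-20 aa unit separated by
7-20 aa spacers, with no repeat database required.  This mirrors the
amino-acid footprint of a translated CRISPR array but, unlike approach I,
can only see arrays whose copies translate to one identical peptide.

Enumeration rule (the scanners' contract, checked against a brute-force
oracle in the test suite):

* occurrences of a unit are *linked* only when consecutive in the
  unit's occurrence list and separated by an in-range gap — a nearer
  copy (tandem or overlapping) breaks the chain, which is what excludes
  tandem repeats and homopolymer runs;
* a report is a maximal linked run of >= 2 occurrences;
* a run is suppressed when its unit can be extended one residue left or
  right with all copies still identical and all gaps still >= spacer_min
  (unit maximality);
* overlapping reports that survive maximality are deduplicated
  leftmost-start-first, then longest-unit-first.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable

from .errors import InputError
from .model import Candidate, ProteinRecord, RepeatMatch, SpacedRepeat

log = logging.getLogger(__name__)

DEFAULT_UNIT_MIN = 7
DEFAULT_UNIT_MAX = 20


def _maximal_runs(
    positions: list[int], unit_len: int, spacer_min: int, spacer_max: int
) -> list[list[int]]:
    """Split an ascending occurrence list into maximal linked runs."""
    runs: list[list[int]] = []
    current = [positions[0]]
    for pos in positions[1:]:
        gap = pos - current[-1] - unit_len
        if spacer_min <= gap <= spacer_max:
            current.append(pos)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [pos]
    if len(current) >= 2:
        runs.append(current)
    return runs


def _extendable(
    seq: str, starts: list[int], unit_len: int, spacer_min: int
) -> bool:
    """True if the unit can grow one residue left or right.

    Growth requires every copy to stay identical (and not 'X') and every
    internal gap, which shrinks by one, to stay >= spacer_min.
    """
    gaps_ok = all(
        starts[k + 1] - starts[k] - unit_len - 1 >= spacer_min
        for k in range(len(starts) - 1)
    )
    if not gaps_ok:
        return False
    # right extension
    if all(p + unit_len < len(seq) for p in starts):
        chars = {seq[p + unit_len] for p in starts}
        if len(chars) == 1 and "X" not in chars:
            return True
    # left extension
    if all(p >= 1 for p in starts):
        chars = {seq[p - 1] for p in starts}
        if len(chars) == 1 and "X" not in chars:
            return True
    return False


def find_spaced_repeats(
    sequence: str,
    unit_min: int = DEFAULT_UNIT_MIN,
    unit_max: int = DEFAULT_UNIT_MAX,
    spacer_min: int = 7,
    spacer_max: int = 20,
    dedupe: bool = True,
) -> list[SpacedRepeat]:
    """All maximal perfect spaced repeats of ``sequence``.

    Output is ordered by leftmost occurrence start, then longest unit.
    Units containing 'X' are never reported (two unknown residues are
    not evidence of repetition).  Set ``dedupe=False`` to keep every
    maximal-unit run, including overlapping ones.
    """
    if not sequence:
        raise InputError("empty protein sequence")
    if unit_min > unit_max:
        raise InputError(f"unit_min {unit_min} > unit_max {unit_max}")
    if spacer_min > spacer_max:
        raise InputError(f"spacer_min {spacer_min} > spacer_max {spacer_max}")

    reports: list[SpacedRepeat] = []
    n = len(sequence)
    for unit_len in range(unit_min, min(unit_max, n) + 1):
        by_unit: dict[str, list[int]] = defaultdict(list)
        for i in range(n - unit_len + 1):
            unit = sequence[i : i + unit_len]
            if "X" not in unit:
                by_unit[unit].append(i)
        for unit, positions in by_unit.items():
            if len(positions) < 2:
                continue
            for run in _maximal_runs(positions, unit_len, spacer_min, spacer_max):
                if _extendable(sequence, run, unit_len, spacer_min):
                    continue
                reports.append(
                    SpacedRepeat(
                        unit=unit,
                        occurrence_starts=tuple(run),
                        spacer_lengths=tuple(
                            run[k + 1] - run[k] - unit_len
                            for k in range(len(run) - 1)
                        ),
                    )
                )
    reports.sort(key=lambda r: (r.occurrence_starts[0], -len(r.unit), r.unit))
    if not dedupe:
        return reports
    kept: list[SpacedRepeat] = []
    kept_intervals: list[tuple[int, int]] = []
    for rep in reports:
        intervals = [(p, p + len(rep.unit)) for p in rep.occurrence_starts]
        if any(
            a < e and s < b for (a, b) in intervals for (s, e) in kept_intervals
        ):
            continue
        kept.append(rep)
        kept_intervals.extend(intervals)
    return kept


def scan_database_ab_initio(
    proteins: Iterable[ProteinRecord],
    unit_min: int = DEFAULT_UNIT_MIN,
    unit_max: int = DEFAULT_UNIT_MAX,
    spacer_min: int = 7,
    spacer_max: int = 20,
) -> list[Candidate]:
    """Stream a protein database through :func:`find_spaced_repeats`.

    One candidate per reported spaced repeat; a protein with several
    distinct repeats yields several rows.  Duplicate accessions are an
    error; per-subset counts go to the log.
    """
    seen: set[str] = set()
    subset_counts: Counter[tuple[str, str]] = Counter()
    candidates: list[Candidate] = []
    n_proteins = 0
    for protein in proteins:
        n_proteins += 1
        if protein.accession in seen:
            raise InputError(f"duplicate protein accession {protein.accession!r}")
        seen.add(protein.accession)
        found = find_spaced_repeats(
            protein.sequence, unit_min, unit_max, spacer_min, spacer_max
        )
        if found:
            subset_counts[(protein.section or "?", protein.division or "?")] += 1
        for rep in found:
            matches = tuple(
                RepeatMatch(
                    peptide=rep.unit,
                    repeat_id="",
                    strand="",
                    frame=-1,
                    start=p,
                    end=p + len(rep.unit),
                )
                for p in rep.occurrence_starts
            )
            candidates.append(
                Candidate(
                    accession=protein.accession,
                    approach="II",
                    matches=matches,
                    spacer_lengths=rep.spacer_lengths,
                    protein_length=len(protein.sequence),
                    unit=rep.unit,
                )
            )
    for (section, division), n in sorted(subset_counts.items()):
        log.info("approach II: subset %s/%s -> %d flagged proteins", section, division, n)
    log.info(
        "approach II: %d proteins scanned, %d spaced repeats in %d proteins",
        n_proteins,
        len(candidates),
        len({c.accession for c in candidates}),
    )
    return candidates
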