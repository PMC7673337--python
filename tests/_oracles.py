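"""Independent brute-force oracles for the two scanning approaches.

Written directly from the definitions, with naive occurrence discovery
and no shared code with the package implementations; the test suite
checks the fast scanners against these on random and adversarial
inputs.
"""

from __future__ import annotations


def naive_occurrences(sequence: str, pattern: str) -> list[int]:
    """All (overlapping) start offsets of ``pattern`` in ``sequence``."""
    out = []
    start = 0
    while True:
        pos = sequence.find(pattern, start)
        if pos == -1:
            return out
        out.append(pos)
        start = pos + 1


def approach1_flagged(
    sequence: str, peptides: list[str], spacer_min: int, spacer_max: int
) -> bool:
    """True iff some pair of non-overlapping occurrences of the group's
    peptides is separated by an in-range gap (a chain of length >= 2
    exists iff such an adjacent pair exists)."""
    occs = [
        (pos, pos + len(pep))
        for pep in peptides
        for pos in naive_occurrences(sequence, pep)
    ]
    for a_start, a_end in occs:
        for b_start, b_end in occs:
            if b_start >= a_end and spacer_min <= b_start - a_end <= spacer_max:
                return True
    return False


def approach1_best_chain_len(
    sequence: str, peptides: list[str], spacer_min: int, spacer_max: int
) -> int:
    """Length of the longest accepting chain, by exhaustive recursion."""
    occs = sorted(
        {
            (pos, pos + len(pep))
            for pep in peptides
            for pos in naive_occurrences(sequence, pep)
        }
    )

    def extend(last_end: int) -> int:
        best = 0
        for start, end in occs:
            if start >= last_end and spacer_min <= start - last_end <= spacer_max:
                best = max(best, 1 + extend(end))
        return best

    best = 0
    for start, end in occs:
        best = max(best, 1 + extend(end))
    return best


def spaced_repeats_bruteforce(
    sequence: str,
    unit_min: int = 7,
    unit_max: int = 20,
    spacer_min: int = 7,
    spacer_max: int = 20,
    dedupe: bool = True,
) -> list[tuple[str, tuple[int, ...]]]:
    """All maximal perfect spaced repeats, straight from the definition.

    For every (start, unit length) the unit's full occurrence list is
    recomputed naively; maximal runs of consecutive occurrences with
    in-range gaps are collected, suppressed when the unit extends one
    residue left/right with copies identical and shrunken gaps still
    >= spacer_min, then optionally deduplicated leftmost-then-longest
    on occurrence-interval overlap.
    """
    n = len(sequence)
    seen: set[tuple[str, tuple[int, ...]]] = set()
    reports: list[tuple[str, tuple[int, ...]]] = []
    for length in range(unit_min, unit_max + 1):
        for i in range(n - length + 1):
            unit = sequence[i : i + length]
            if "X" in unit:
                continue
            occ = naive_occurrences(sequence, unit)
            # maximal consecutive runs with all gaps in range
            runs: list[list[int]] = []
            cur = [occ[0]]
            for pos in occ[1:]:
                if spacer_min <= pos - cur[-1] - length <= spacer_max:
                    cur.append(pos)
                else:
                    runs.append(cur)
                    cur = [pos]
            runs.append(cur)
            for run in runs:
                if len(run) < 2 or i not in run:
                    continue
                key = (unit, tuple(run))
                if key in seen:
                    continue
                seen.add(key)
                if _extendable_bf(sequence, run, length, spacer_min):
                    continue
                reports.append(key)
    reports.sort(key=lambda r: (r[1][0], -len(r[0]), r[0]))
    if not dedupe:
        return reports
    kept: list[tuple[str, tuple[int, ...]]] = []
    occupied: list[tuple[int, int]] = []
    for unit, starts in reports:
        ivals = [(p, p + len(unit)) for p in starts]
        if any(a < e and s < b for a, b in ivals for s, e in occupied):
            continue
        kept.append((unit, starts))
        occupied.extend(ivals)
    return kept


def _extendable_bf(sequence: str, run: list[int], length: int, spacer_min: int) -> bool:
    if any(
        run[k + 1] - run[k] - length - 1 < spacer_min for k in range(len(run) - 1)
    ):
        return False
    right = [sequence[p + length] for p in run if p + length < len(sequence)]
    if len(right) == len(run) and len(set(right)) == 1 and right[0] != "X":
        return True
    left = [sequence[p - 1] for p in run if p >= 1]
    if len(left) == len(run) and len(set(left)) == 1 and left[0] != "X":
        return True
    return False
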