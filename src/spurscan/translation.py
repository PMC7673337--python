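"""Six-frame translation of CRISPR repeats and the searchable peptide index.

A 20-60 bp repeat has six possible reading frames (three per strand).
Frames whose translation contains a stop codon cannot appear inside an
erroneously annotated ORF and are discarded; the surviving peptides are
grouped by (repeat, strand) because a translated array exposes the
peptides of exactly one strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .errors import InputError
from .model import FORWARD, REVERSE, RepeatRecord, TranslatedRepeat

log = logging.getLogger(__name__)

#: shortest stop-free frame peptide of a 20 bp repeat is floor((20-2)/3) = 6
DEFAULT_MIN_PEPTIDE_LEN = 6


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate_six_frames(dna: str, repeat_id: str = "?") -> list[TranslatedRepeat]:
    """Translate ``dna`` in all six frames, dropping frames with stops.

    Uses the standard genetic code (translation table 1); repeats are
    translated as internal peptides, so start-codon rules do not apply.
    Trailing partial codons are ignored, hence each frame-``f`` peptide
    has length ``(len(dna) - f) // 3``.

    Raises
    ------
    InputError
        If ``dna`` is shorter than 3 nt or contains non-ACGT characters.
    """
    RepeatRecord(repeat_id=repeat_id, dna=dna).validate()
    out: list[TranslatedRepeat] = []
    for strand, seq in ((FORWARD, dna), (REVERSE, reverse_complement(dna))):
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            if not sub:
                continue
            peptide = str(Seq(sub).translate(table=1))
            if "*" in peptide:
                continue
            out.append(
                TranslatedRepeat(
                    repeat_id=repeat_id, strand=strand, frame=frame, peptide=peptide
                )
            )
    return out


@dataclass
class PeptideIndex:
    """Stop-free repeat peptides grouped by (repeat_id, strand).

    Each group holds at most the three frame peptides of that strand;
    approach I requires >= 2 regularly spaced matches drawn from one
    group.
    """

    min_peptide_len: int = DEFAULT_MIN_PEPTIDE_LEN
    groups: dict[tuple[str, str], list[TranslatedRepeat]] = field(default_factory=dict)

    def add(self, tr: TranslatedRepeat) -> None:
        key = (tr.repeat_id, tr.strand)
        bucket = self.groups.setdefault(key, [])
        if tr not in bucket:
            bucket.append(tr)

    def entries(self) -> Iterable[TranslatedRepeat]:
        for bucket in self.groups.values():
            yield from bucket

    def __len__(self) -> int:
        return sum(len(b) for b in self.groups.values())

    def peptides(self, repeat_id: str, strand: str) -> list[str]:
        return [t.peptide for t in self.groups.get((repeat_id, strand), [])]


def build_peptide_index(
    repeats: Iterable[RepeatRecord],
    min_peptide_len: int = DEFAULT_MIN_PEPTIDE_LEN,
) -> PeptideIndex:
    """Translate every repeat and index the usable peptides.

    Repeats whose six frames all contain stops (or fall below
    ``min_peptide_len``) are absent from the index; a per-record warning
    and summary counts go to the log.  Records with ambiguous bases are
    rejected per record with a warning rather than silently altered.

    Raises
    ------
    InputError
        If the repeat collection is empty.
    """
    index = PeptideIndex(min_peptide_len=min_peptide_len)
    n_repeats = 0
    n_rejected = 0
    n_discarded_frames = 0
    for rec in repeats:
        n_repeats += 1
        try:
            frames = translate_six_frames(rec.dna, repeat_id=rec.repeat_id)
        except InputError as exc:
            n_rejected += 1
            log.warning("rejecting repeat: %s", exc)
            continue
        kept = 0
        for tr in frames:
            if len(tr.peptide) >= min_peptide_len:
                index.add(tr)
                kept += 1
        n_discarded_frames += 6 - kept
        if kept == 0:
            log.warning(
                "repeat %r: no stop-free frame peptide of length >= %d; "
                "repeat absent from index",
                rec.repeat_id,
                min_peptide_len,
            )
    if n_repeats == 0:
        raise InputError("empty repeat collection: nothing to index")
    log.info(
        "peptide index: %d repeats (%d rejected), %d peptides indexed, "
        "%d frames discarded (stop codon or < %d aa)",
        n_repeats,
        n_rejected,
        len(index),
        n_discarded_frames,
        min_peptide_len,
    )
    return index
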