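"""Domain records shared across the pipeline.

The pipeline screens protein sequences for translated CRISPR
repeat-spacer arrays.  A CRISPR array is a series of 20-60 bp DNA
repeats alternating with unique spacers of similar length; when a gene
finder erroneously annotates an ORF across such an array, the resulting
database protein shows the same repeat peptide every 7-20 residues.
These dataclasses carry the objects that flow between the stages:
repeat translations, flagged proteins (candidates), gene coordinates,
cas-domain hits, and the final per-candidate classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMBIGUOUS_FREE = frozenset("ACGT")

FORWARD = "forward"
REVERSE = "reverse"

#: classification states, in increasing rank of cas evidence
STATUS_UNTESTED = "untested"
STATUS_NEGATIVE = "negative"
STATUS_CAS_POSITIVE = "cas_positive"
STATUS_PFP = "pfp"

_STATUS_RANK = {STATUS_NEGATIVE: 0, STATUS_CAS_POSITIVE: 1, STATUS_PFP: 2}


def status_rank(status: str) -> int:
    """Ordering of tested statuses: negative < cas_positive < pfp."""
    return _STATUS_RANK[status]


@dataclass(frozen=True)
class RepeatRecord:
    """One CRISPR repeat DNA sequence (the unit translated in approach I)."""

    repeat_id: str
    dna: str
    source: Optional[str] = None

    def validate(self) -> None:
        from .errors import InputError

        if len(self.dna) < 3:
            raise InputError(
                f"repeat {self.repeat_id!r}: DNA shorter than 3 nt ({len(self.dna)})"
            )
        bad = set(self.dna) - AMBIGUOUS_FREE
        if bad:
            raise InputError(
                f"repeat {self.repeat_id!r}: non-ACGT characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class TranslatedRepeat:
    """A stop-free reading-frame peptide of one repeat."""

    repeat_id: str
    strand: str  # FORWARD | REVERSE
    frame: int  # 0, 1, 2
    peptide: str


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence to screen, with optional database metadata."""

    accession: str
    sequence: str
    section: Optional[str] = None  # sp | tr
    division: Optional[str] = None  # archaea | bacteria
    year: Optional[int] = None
    locus_ref: Optional[tuple[str, str]] = None  # (genome_accession, gene_id)


@dataclass(frozen=True)
class RepeatMatch:
    """One exact occurrence of a translated-repeat peptide in a protein."""

    peptide: str
    repeat_id: str
    strand: str
    frame: int
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


@dataclass(frozen=True)
class SpacedRepeat:
    """A perfect interspaced peptide repeat found ab initio (approach II)."""

    unit: str
    occurrence_starts: tuple[int, ...]
    spacer_lengths: tuple[int, ...]


@dataclass(frozen=True)
class Candidate:
    """A protein flagged by approach I or II."""

    accession: str
    approach: str  # "I" | "II"
    matches: tuple[RepeatMatch, ...]
    spacer_lengths: tuple[int, ...]
    protein_length: int
    repeat_id: Optional[str] = None  # approach I
    strand: Optional[str] = None  # approach I
    unit: Optional[str] = None  # approach II


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval on a genome; 0-based half-open internally."""

    genome_accession: str
    genome_length: int
    gene_id: str
    start: int
    end: int
    strand: str  # "+" | "-"

    def validate(self) -> None:
        from .errors import InputError

        if not (0 <= self.start < self.end <= self.genome_length):
            raise InputError(
                f"gene {self.gene_id!r} on {self.genome_accession!r}: "
                f"interval [{self.start},{self.end}) outside genome of "
                f"length {self.genome_length}"
            )


@dataclass(frozen=True)
class CasHit:
    """A filtered cas-domain hit on an annotated gene."""

    gene_id: str
    domain_id: str
    cas_label: str
    evalue: float
    identity_pct: float
    coverage: float


@dataclass(frozen=True)
class CasSubtypeDefinition:
    """Gene-set signature of one CRISPR-Cas subtype (e.g. I-E, III-B)."""

    subtype: str
    required_genes: frozenset[str]


@dataclass(frozen=True)
class ContextClassification:
    """Final genomic-context status of one candidate protein."""

    accession: str
    status: str
    n_cas_genes: int = 0
    distance_to_nearest_cas: Optional[int] = None
    matched_subtype: Optional[str] = None
    rule: str = "none"  # cluster | cas1cas2 | none
    genome_accession: Optional[str] = None
    genome_length: Optional[int] = None


@dataclass
class FixtureTruth:
    """Ground truth for one synthetic protein."""

    accession: str
    planted_class: str
    expected_status: str  # pfp | negative | not_candidate
    repeat_id: Optional[str] = None
    strand: Optional[str] = None
    frame: Optional[int] = None
    genome_accession: Optional[str] = None
    gene_id: Optional[str] = None
    array_start: Optional[int] = None
    array_end: Optional[int] = None
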