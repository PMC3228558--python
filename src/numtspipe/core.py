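"""Shared domain types and small sequence utilities.

Coordinate conventions used throughout the package:

* internal coordinates are 0-based, half-open, on the forward strand of
  each sequence;
* BLAST tabular input/output is 1-based inclusive;
* BED output is 0-based half-open.

Conversions happen only at the parse/write boundaries (:mod:`numtspipe.io`).
Minus-strand hits always store their nuclear interval with ``start < end``
plus a separate strand flag, and the mitochondrial interval is always
expressed on the mitochondrial plus strand, so interval arithmetic is
strand-agnostic everywhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

RCRS_LENGTH = 16569
"""Length in bp of the revised Cambridge Reference Sequence (NC_012920)."""

#: The control region (D-loop) is annotated on the linearised mitochondrial
#: reference as the tail of the sequence followed by its head, i.e. it spans
#: the circular origin (0-based: [16023, 16569) followed by [0, 576)).
DLOOP_TAIL_START = 16023
DLOOP_HEAD_END = 576

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y|M|MT)$", re.IGNORECASE)


def karyotype_key(chrom: str):
    """Sort key placing chromosomes in karyotype order 1..22, X, Y, M.

    Anything that is not a standard human chromosome name sorts after the
    karyotype, lexicographically.
    """
    m = _CHROM_RE.match(chrom)
    if m:
        token = m.group(2).upper()
        if token.isdigit():
            return (0, int(token), "")
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[token], "")
    return (1, 0, chrom)


class ValidationError(ValueError):
    """Raised when input data violates a documented contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence restricted to the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def validate(self) -> "SequenceRecord":
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}; "
                "alphabet is restricted to A,C,G,T,N"
            )
        return self

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoringScheme:
    """BLASTN-style scoring used for both local and global alignment.

    A gap of length ``g`` costs ``gap_open + g * gap_extend`` (the BLAST
    convention: the opening penalty is charged once per gap and the
    extension penalty for every gapped base, including the first).

    ``min_raw_score`` is the significance filter for the internal aligner:
    62 equals the score of a 31 bp exact match under the +2 match reward,
    and approximates E ~ 1e-3 under Karlin-Altschul statistics for a
    mitochondrial-genome query against a mammalian-genome-scale subject.
    Karlin-Altschul ``ka_lambda``/``ka_k`` are used only to annotate HSPs
    with approximate E-values; parsed BLAST tables keep their own column.
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    evalue_threshold: float = 1e-3
    min_raw_score: int = 62
    ka_lambda: float = 0.625
    ka_k: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValidationError("match_reward must be positive")
        if self.mismatch_penalty >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValidationError("penalties must be negative")
        if self.evalue_threshold <= 0:
            raise ValidationError("evalue_threshold must be positive")


@dataclass
class HSP:
    """One local alignment (high-scoring pair) between the mitochondrial
    genome and a nuclear locus.

    ``nuc_start``/``nuc_end`` are 0-based half-open on the chromosome
    forward strand; ``mito_start``/``mito_end`` are 0-based half-open on the
    mitochondrial plus strand regardless of ``strand``.
    """

    chrom: str
    nuc_start: int
    nuc_end: int
    strand: str
    mito_start: int
    mito_end: int
    percent_identity: float
    alignment_length: int
    raw_score: int = 0
    evalue: float = 0.0
    mismatches: int = 0
    gap_opens: int = 0
    hsp_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.nuc_start >= self.nuc_end:
            raise ValidationError("nuclear interval must satisfy start < end")
        if self.mito_start >= self.mito_end:
            raise ValidationError("mito interval must satisfy start < end")
        if not 0 < self.percent_identity <= 100:
            raise ValidationError("percent_identity must lie in (0, 100]")

    @property
    def nuc_length(self) -> int:
        return self.nuc_end - self.nuc_start

    @property
    def mito_length(self) -> int:
        return self.mito_end - self.mito_start

    def with_id(self, hsp_id: str) -> "HSP":
        return replace(self, hsp_id=hsp_id)


@dataclass
class AssemblyParams:
    """Merge thresholds for chaining HSPs into assembled NumtS.

    The nuclear bound is exclusive (fragments strictly less than
    ``nuclear_gap_max`` apart merge) while the mitochondrial bound is
    inclusive (gaps up to and including ``mito_gap_max`` merge); both are
    configurable for sensitivity analysis.  ``mito_length`` makes the
    mitochondrial gap circular, so chains spanning the control-region
    junction merge without special-casing the D-loop coordinates.
    """

    nuclear_gap_max: int = 2000
    mito_gap_max: int = 2000
    mito_length: int = RCRS_LENGTH
    require_same_orientation: bool = True

    def __post_init__(self) -> None:
        if self.nuclear_gap_max < 0 or self.mito_gap_max < 0:
            raise ValidationError("gap bounds must be non-negative")
        if self.mito_length <= 0:
            raise ValidationError("mito_length must be positive")


@dataclass
class AssembledNumts:
    """An ordered chain of HSPs merged into a single annotated NumtS."""

    chrom: str
    strand: str
    nuc_start: int
    nuc_end: int
    members: list  # list[HSP], sorted by nuclear start
    mito_start: int
    mito_end: int
    wraps_junction: bool
    aggregate_identity: float
    numts_id: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def nuc_length(self) -> int:
        return self.nuc_end - self.nuc_start

    @property
    def member_ids(self) -> list:
        return [h.hsp_id for h in self.members]


@dataclass
class AlignmentBlockList:
    """Gapless co-linear blocks of a pairwise global alignment.

    Each block pairs an interval on sequence *a* with an equal-length
    interval on sequence *b*; blocks are strictly increasing in both
    coordinates, with indels appearing as gaps between consecutive blocks.
    """

    blocks: list  # list[tuple[tuple[int, int], tuple[int, int]]]
    score: float

    def __post_init__(self) -> None:
        prev_a = prev_b = -1
        for (a0, a1), (b0, b1) in self.blocks:
            if a1 - a0 != b1 - b0:
                raise ValidationError("paired blocks must have equal lengths")
            if a0 < prev_a or b0 < prev_b or a0 >= a1:
                raise ValidationError("blocks must be strictly increasing")
            prev_a, prev_b = a1, b1
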