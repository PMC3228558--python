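"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing/writing is delegated to Biopython's ``SeqIO`` with a strict
validation layer on top; BLAST tabular tables are read with pandas.  BED,
bedGraph and TSV writers live here because they need UCSC ``track`` header
lines and deterministic ordering.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .core import (
    HSP,
    SequenceRecord,
    ValidationError,
    VALID_ALPHABET,
    karyotype_key,
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, n_mask_ambiguous: bool = False) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated :class:`SequenceRecord` s.

    Lowercase is folded to uppercase and multi-line sequences are
    concatenated.  Ambiguity codes other than ``N`` are rejected unless
    ``n_mask_ambiguous`` is set, in which case they are replaced by ``N``
    (aligner scoring is defined only on {A,C,G,T,N}).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first == "":
            return []
        if first != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(bio_rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {bio_rec.id!r}: empty sequence")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            if n_mask_ambiguous:
                seq = "".join(c if c in VALID_ALPHABET else "N" for c in seq)
            else:
                raise ParseError(
                    f"{path}: record {bio_rec.id!r}: ambiguity codes {sorted(bad)!r} "
                    "not allowed (pass n_mask_ambiguous=True to N-mask them)"
                )
        records.append(SequenceRecord(bio_rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns (default 60)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt-6 dialect)

BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


def parse_blast_tabular(path, evalue_threshold: float = 1e-3) -> list[HSP]:
    """Parse a 12-column BLAST tabular file into internal HSPs.

    The query is the mitochondrial genome, the subject a chromosome.
    1-based inclusive coordinates become 0-based half-open; rows whose
    subject coordinates descend become minus-strand HSPs with normalised
    (min < max) subject coordinates; only rows with E-value strictly below
    ``evalue_threshold`` are kept.
    """
    path = Path(path)
    hsps: list[HSP] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mism = int(fields[4])
                gaps = int(fields[5])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if not evalue < evalue_threshold:
                continue
            if s_start <= s_end:
                strand, nuc = "+", (s_start - 1, s_end)
            else:
                strand, nuc = "-", (s_end - 1, s_start)
            hsps.append(
                HSP(
                    chrom=fields[1],
                    nuc_start=nuc[0],
                    nuc_end=nuc[1],
                    strand=strand,
                    mito_start=q_start - 1,
                    mito_end=q_end,
                    percent_identity=pident,
                    alignment_length=length,
                    mismatches=mism,
                    gap_opens=gaps,
                    evalue=evalue,
                    raw_score=int(round(bit_score)),
                )
            )
    return hsps


def write_blast_tabular(hsps: Sequence[HSP], path, query_id: str = "chrM") -> None:
    """Write HSPs back out in the same 12-column dialect the parser reads.

    Minus-strand HSPs are emitted with descending subject coordinates, so a
    round trip through :func:`parse_blast_tabular` is lossless for the
    fields the format carries.  The score column holds the raw score (the
    internal aligner does not compute bit scores).
    """
    with Path(path).open("w") as handle:
        for h in hsps:
            if h.strand == "+":
                s_start, s_end = h.nuc_start + 1, h.nuc_end
            else:
                s_start, s_end = h.nuc_end, h.nuc_start + 1
            handle.write(
                "\t".join(
                    [
                        query_id,
                        h.chrom,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.mito_start + 1),
                        str(h.mito_end),
                        str(s_start),
                        str(s_end),
                        f"{h.evalue:.2g}",
                        str(h.raw_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED


class BedFeature:
    """A single BED6/BED9 feature (0-based half-open)."""

    __slots__ = ("chrom", "start", "end", "name", "score", "strand", "item_rgb")

    def __init__(self, chrom, start, end, name, score, strand, item_rgb=None):
        if start >= end:
            raise ValidationError(f"BED feature {name!r}: start >= end")
        if not 0 <= score <= 1000:
            raise ValidationError(f"BED feature {name!r}: score {score} not in [0, 1000]")
        if strand not in "+-.":
            raise ValidationError(f"BED feature {name!r}: bad strand {strand!r}")
        if item_rgb is not None:
            r, g, b = item_rgb
            if not all(0 <= c <= 255 for c in (r, g, b)):
                raise ValidationError(f"BED feature {name!r}: bad RGB {item_rgb!r}")
        self.chrom, self.start, self.end = chrom, int(start), int(end)
        self.name, self.score, self.strand = name, int(score), strand
        self.item_rgb = item_rgb

    def __eq__(self, other):
        return all(
            getattr(self, f) == getattr(other, f) for f in self.__slots__
        )

    def __repr__(self):
        return (
            f"BedFeature({self.chrom}:{self.start}-{self.end} {self.name} "
            f"{self.score} {self.strand})"
        )


def write_bed(
    features: Sequence[BedFeature],
    path,
    bed_type: str = "BED6",
    track_line: Optional[str] = None,
) -> None:
    """Write features as BED6 or BED9, sorted by (chrom, start).

    BED9 repeats start/end as thickStart/thickEnd and appends the itemRgb
    column; features missing a colour get 0,0,0.
    """
    if bed_type not in ("BED6", "BED9"):
        raise ValidationError(f"bed_type must be BED6 or BED9, got {bed_type!r}")
    ordered = sorted(features, key=lambda f: (karyotype_key(f.chrom), f.start, f.name))
    with Path(path).open("w") as handle:
        if track_line:
            handle.write(track_line.rstrip("\n") + "\n")
        for f in ordered:
            fields = [f.chrom, str(f.start), str(f.end), f.name, str(f.score), f.strand]
            if bed_type == "BED9":
                rgb = f.item_rgb or (0, 0, 0)
                fields += [str(f.start), str(f.end), ",".join(map(str, rgb))]
            handle.write("\t".join(fields) + "\n")


def read_bed(path) -> list[BedFeature]:
    """Parse BED6/BED9 lines (track/browser headers are skipped)."""
    feats = []
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 BED columns")
            rgb = None
            if len(fields) >= 9:
                rgb = tuple(int(c) for c in fields[8].split(","))
            try:
                feats.append(
                    BedFeature(
                        fields[0],
                        int(fields[1]),
                        int(fields[2]),
                        fields[3],
                        int(fields[4]),
                        fields[5],
                        rgb,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return feats


def write_bedgraph(counts, chrom: str, path, track_line: Optional[str] = None) -> None:
    """Write an integer per-position vector as run-length-encoded bedGraph."""
    with Path(path).open("w") as handle:
        if track_line:
            handle.write(track_line.rstrip("\n") + "\n")
        run_start = 0
        for pos in range(1, len(counts) + 1):
            if pos == len(counts) or counts[pos] != counts[run_start]:
                value = int(counts[run_start])
                if value != 0:
                    handle.write(f"{chrom}\t{run_start}\t{pos}\t{value}\n")
                run_start = pos


# ---------------------------------------------------------------------------
# TSV reports


def hsps_to_frame(hsps: Sequence[HSP]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hsp_id": [h.hsp_id for h in hsps],
            "chrom": [h.chrom for h in hsps],
            "strand": [h.strand for h in hsps],
            "nuc_start": [h.nuc_start for h in hsps],
            "nuc_end": [h.nuc_end for h in hsps],
            "mito_start": [h.mito_start for h in hsps],
            "mito_end": [h.mito_end for h in hsps],
            "percent_identity": [h.percent_identity for h in hsps],
            "alignment_length": [h.alignment_length for h in hsps],
            "raw_score": [h.raw_score for h in hsps],
            "evalue": [h.evalue for h in hsps],
        }
    )


def numts_to_frame(numts) -> pd.DataFrame:
    """Assembled-NumtS table: one row per member HSP, mirroring the layout
    of a per-fragment compilation spreadsheet (NumtS ID, HSP ID, location,
    strand, nuclear and mitochondrial positions, identity)."""
    rows = []
    for n in numts:
        for h in n.members:
            rows.append(
                {
                    "numts_id": n.numts_id,
                    "hsp_id": h.hsp_id,
                    "chrom": n.chrom,
                    "strand": n.strand,
                    "numts_nuc_start": n.nuc_start,
                    "numts_nuc_end": n.nuc_end,
                    "hsp_nuc_start": h.nuc_start,
                    "hsp_nuc_end": h.nuc_end,
                    "hsp_mito_start": h.mito_start,
                    "hsp_mito_end": h.mito_end,
                    "wraps_junction": n.wraps_junction,
                    "percent_identity": h.percent_identity,
                }
            )
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
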