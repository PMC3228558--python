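"""Genome-browser track generation.

Emits the four NumtS tracks as BED files in the UCSC style:

1. ``numts_hsp.bed`` — one BED6 item per HSP on the nuclear genome, score
   shading by percent identity, arrows by strand;
2. ``numts_assembled.bed`` — one BED6 item per assembled NumtS;
3. ``numts_on_mito.bed`` — the HSPs mapped back onto the mitochondrial
   genome, identity-shaded;
4. ``numts_on_mito_chrom_colors.bed`` — the same items as BED9 with
   itemRgb set to the colour conventionally assigned to the source
   chromosome.

A genome browser realises the reciprocal nuclear<->mitochondrial links as
hyperlinks; in flat BED the same information is carried by shared item
names plus the crosslink TSV from :func:`make_crosslink_table`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import HSP, AssembledNumts, ValidationError
from .io import BedFeature, write_bed


def load_chrom_colors(path=None) -> dict:
    """Chromosome -> RGB map; the packaged default follows the genome
    browser's conventional karyotype colours and is user-overridable by a
    TSV with columns chrom/red/green/blue."""
    if path is None:
        source = resources.files("numtspipe").joinpath("data/ucsc_chrom_colors.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    colors = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        colors[row["chrom"]] = (int(row["red"]), int(row["green"]), int(row["blue"]))
    return colors


@dataclass
class TrackConfig:
    hsp_track_name: str = "NumtS"
    assembled_track_name: str = "NumtS assembled"
    mito_track_name: str = "NumtS on mitochondrion"
    mito_color_track_name: str = "NumtS on mitochondrion with chromosome placement"
    chrom_colors: dict = field(default_factory=load_chrom_colors)
    score_scale: float = 10.0  # identity percent -> BED score
    mito_chrom_name: str = "chrM"

    def __post_init__(self) -> None:
        names = {
            self.hsp_track_name,
            self.assembled_track_name,
            self.mito_track_name,
            self.mito_color_track_name,
        }
        if len(names) != 4:
            raise ValidationError("the four track names must be distinct")


def identity_to_bed_score(percent_identity: float, scale: float = 10.0) -> int:
    """Map percent identity to the BED score column (item shading).

    Linear ``round(identity * 10)`` clipped to [0, 1000]; deliberately not
    rescaled to the observed identity range so shading is comparable
    across datasets.
    """
    if not 0 < percent_identity <= 100:
        raise ValidationError(
            f"percent identity {percent_identity} outside (0, 100]"
        )
    return min(1000, max(0, int(round(percent_identity * scale))))


def _track_line(name: str, description: str, *, use_score: bool = True, rgb: bool = False) -> str:
    attrs = [f'track name="{name}"', f'description="{description}"']
    if rgb:
        attrs.append("itemRgb=On")
    elif use_score:
        attrs.append("useScore=1")
    return " ".join(attrs)


def _require_ids(items, what: str) -> None:
    for item in items:
        item_id = item.hsp_id if isinstance(item, HSP) else item.numts_id
        if not item_id:
            raise ValidationError(f"unnamed {what}: assign IDs before track export")


def make_nuclear_tracks(
    hsps: Sequence[HSP],
    numts: Sequence[AssembledNumts],
    config: TrackConfig,
    out_dir,
) -> tuple[Path, Path]:
    """Write the per-HSP and per-assembled-NumtS nuclear BED6 tracks."""
    _require_ids(hsps, "HSP")
    _require_ids(numts, "assembled NumtS")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hsp_feats = [
        BedFeature(
            h.chrom,
            h.nuc_start,
            h.nuc_end,
            h.hsp_id,
            identity_to_bed_score(h.percent_identity, config.score_scale),
            h.strand,
        )
        for h in hsps
    ]
    numts_feats = [
        BedFeature(
            n.chrom,
            n.nuc_start,
            n.nuc_end,
            n.numts_id,
            identity_to_bed_score(n.aggregate_identity, config.score_scale),
            n.strand,
        )
        for n in numts
    ]
    hsp_path = out_dir / "numts_hsp.bed"
    assembled_path = out_dir / "numts_assembled.bed"
    write_bed(
        hsp_feats,
        hsp_path,
        "BED6",
        _track_line(config.hsp_track_name, "Mitochondrial fragments (HSPs) on the nuclear genome"),
    )
    write_bed(
        numts_feats,
        assembled_path,
        "BED6",
        _track_line(config.assembled_track_name, "Assembled NumtS"),
    )
    return hsp_path, assembled_path


def make_mito_tracks(
    hsps: Sequence[HSP], config: TrackConfig, out_dir
) -> tuple[Path, Path]:
    """Write the two mitochondrial tracks (BED6 shaded, BED9 coloured).

    Items are the individual HSPs (never junction-wrapping: a chain that
    spans the circular origin is represented by its constituent HSPs on
    either side of the junction, sharing the NumtS ID prefix).  The BED9
    itemRgb is the colour of the source chromosome; a chromosome missing
    from the colour table is an error naming it.
    """
    _require_ids(hsps, "HSP")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shaded = []
    colored = []
    for h in hsps:
        score = identity_to_bed_score(h.percent_identity, config.score_scale)
        shaded.append(
            BedFeature(config.mito_chrom_name, h.mito_start, h.mito_end, h.hsp_id, score, h.strand)
        )
        key = h.chrom if h.chrom in config.chrom_colors else f"chr{h.chrom}"
        if key not in config.chrom_colors:
            raise ValidationError(
                f"chromosome {h.chrom!r} missing from the colour table"
            )
        colored.append(
            BedFeature(
                config.mito_chrom_name,
                h.mito_start,
                h.mito_end,
                h.hsp_id,
                score,
                h.strand,
                config.chrom_colors[key],
            )
        )
    mito_path = out_dir / "numts_on_mito.bed"
    color_path = out_dir / "numts_on_mito_chrom_colors.bed"
    write_bed(
        shaded,
        mito_path,
        "BED6",
        _track_line(config.mito_track_name, "HSPs mapped on the mitochondrial genome"),
    )
    write_bed(
        colored,
        color_path,
        "BED9",
        _track_line(
            config.mito_color_track_name,
            "HSPs on the mitochondrial genome, coloured by source chromosome",
            rgb=True,
        ),
    )
    return mito_path, color_path


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


def format_locus(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def parse_locus(locus: str) -> tuple[str, int, int, str]:
    m = _LOCUS_RE.match(locus)
    if not m:
        raise ValidationError(f"malformed locus string {locus!r}")
    return (m["chrom"], int(m["start"]), int(m["end"]), m["strand"])


def make_crosslink_table(hsps: Sequence[HSP], mito_id: str = "chrM") -> pd.DataFrame:
    """One row per HSP linking its nuclear and mitochondrial loci by name —
    the flat-file stand-in for the browser's reciprocal hyperlinks."""
    _require_ids(hsps, "HSP")
    return pd.DataFrame(
        {
            "hsp_id": [h.hsp_id for h in hsps],
            "nuclear_locus": [
                format_locus(h.chrom, h.nuc_start, h.nuc_end, h.strand) for h in hsps
            ],
            "mito_locus": [
                format_locus(mito_id, h.mito_start, h.mito_end, h.strand) for h in hsps
            ],
        }
    )
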