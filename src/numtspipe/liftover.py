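"""Coordinate remapping between two mitochondrial reference sequences.

Different assemblies have historically shipped different mitochondrial
references (e.g. the revised Cambridge reference versus an African-lineage
sequence differing by a few insertions), so annotations computed against
one must be remapped before display on the other.  The map is always
computed from the two supplied sequences by global alignment — no indel
coordinates are hard-coded.

Lifting operates on interval endpoints, not per-base.  An endpoint falling
where the target carries an insertion, or inside a source-only segment,
snaps *outward* to the nearest mapped coordinate so that a lifted feature
never loses coverage; such results are flagged ``snapped``.  Intervals
wholly inside a source-only segment have no image and come back
``unmapped``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import global_align
from .core import AlignmentBlockList, ScoringScheme, SequenceRecord, ValidationError


@dataclass
class LiftoverMap:
    """Block-wise coordinate correspondence between two references."""

    source_id: str
    target_id: str
    blocks: list  # [((a0,a1),(b0,b1)), ...] monotone, equal-length pairs
    source_length: int
    target_length: int

    def inverted(self) -> "LiftoverMap":
        return LiftoverMap(
            source_id=self.target_id,
            target_id=self.source_id,
            blocks=[(b, a) for a, b in self.blocks],
            source_length=self.target_length,
            target_length=self.source_length,
        )


@dataclass
class LiftResult:
    start: int
    end: int
    snapped: bool
    unmapped: bool = False


def _alignment_identity(blocks, a: str, b: str) -> float:
    """Percent identity over all alignment columns (gap columns count)."""
    matches = 0
    aligned_cols = 0
    prev_a = prev_b = 0
    for (a0, a1), (b0, b1) in blocks:
        aligned_cols += max(a0 - prev_a, b0 - prev_b)  # indel columns
        for x, y in zip(a[a0:a1], b[b0:b1]):
            matches += x == y
        aligned_cols += a1 - a0
        prev_a, prev_b = a1, b1
    aligned_cols += max(len(a) - prev_a, len(b) - prev_b)
    return 100.0 * matches / aligned_cols if aligned_cols else 0.0


def build_liftover_map(
    source: SequenceRecord,
    target: SequenceRecord,
    scoring: Optional[ScoringScheme] = None,
    min_identity: float = 90.0,
) -> LiftoverMap:
    """Build a liftover map by globally aligning two reference sequences.

    Refuses pairs whose alignment identity falls below ``min_identity``
    percent, signalling that the sequences are not homologous references.
    """
    result: AlignmentBlockList = global_align(source, target, scoring)
    identity = _alignment_identity(result.blocks, source.sequence, target.sequence)
    if identity < min_identity:
        raise ValidationError(
            f"alignment identity {identity:.1f}% below the {min_identity:.0f}% "
            f"floor: {source.id!r} and {target.id!r} do not look like "
            "homologous references"
        )
    return LiftoverMap(
        source_id=source.id,
        target_id=target.id,
        blocks=list(result.blocks),
        source_length=len(source.sequence),
        target_length=len(target.sequence),
    )


def _lift_endpoint(pos: int, blocks, is_start: bool) -> tuple[int, bool]:
    """Map one boundary coordinate; returns (target position, snapped).

    A boundary ``pos`` maps exactly when it lies within a single block's
    closed span [a0, a1].  At a block junction both neighbours claim it;
    when their images differ (a target-only insertion) the start of an
    interval takes the smaller image and the end the larger one — outward
    snapping.  Inside a source-only segment the boundary snaps to the
    neighbouring block edge, likewise outward.
    """
    candidates = []
    prev_b_end = 0
    next_b_start = None
    for (a0, a1), (b0, b1) in blocks:
        if a0 <= pos <= a1:
            candidates.append(b0 + (pos - a0))
        if a1 <= pos:
            prev_b_end = b1
        if a0 > pos and next_b_start is None:
            next_b_start = b0
    if candidates:
        if len(set(candidates)) == 1:
            return candidates[0], False
        return (min(candidates), True) if is_start else (max(candidates), True)
    # source-only segment (no block covers pos)
    if is_start:
        return prev_b_end, True
    return (next_b_start if next_b_start is not None else prev_b_end), True


def lift_interval(interval: tuple[int, int], lift_map: LiftoverMap) -> LiftResult:
    """Lift a half-open source interval onto the target reference.

    Endpoints are lifted independently with outward snapping; intervals
    that intersect no aligned block are returned ``unmapped``.
    """
    start, end = interval
    if start < 0 or end > lift_map.source_length or start >= end:
        raise ValidationError(
            f"interval [{start}, {end}) outside source bounds "
            f"[0, {lift_map.source_length})"
        )
    overlaps = any(
        min(end, a1) - max(start, a0) > 0 for (a0, a1), _ in lift_map.blocks
    )
    if not overlaps:
        return LiftResult(0, 0, snapped=False, unmapped=True)
    t_start, snap_s = _lift_endpoint(start, lift_map.blocks, is_start=True)
    t_end, snap_e = _lift_endpoint(end, lift_map.blocks, is_start=False)
    return LiftResult(t_start, t_end, snapped=snap_s or snap_e)


def map_summary(lift_map: LiftoverMap):
    """Tabulate block boundaries and the indels between them.

    Returns a list of dict rows: one per aligned block plus one per indel
    (target insertions and source deletions), ready for a TSV report.
    """
    rows = []
    prev_a = prev_b = 0
    for (a0, a1), (b0, b1) in lift_map.blocks:
        if a0 > prev_a:
            rows.append(
                {
                    "kind": "source_only",
                    "source_start": prev_a,
                    "source_end": a0,
                    "target_start": prev_b,
                    "target_end": prev_b,
                    "length": a0 - prev_a,
                }
            )
        if b0 > prev_b:
            rows.append(
                {
                    "kind": "target_insertion",
                    "source_start": a0,
                    "source_end": a0,
                    "target_start": prev_b,
                    "target_end": b0,
                    "length": b0 - prev_b,
                }
            )
        rows.append(
            {
                "kind": "block",
                "source_start": a0,
                "source_end": a1,
                "target_start": b0,
                "target_end": b1,
                "length": a1 - a0,
            }
        )
        prev_a, prev_b = a1, b1
    return rows
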