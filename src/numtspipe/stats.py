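"""Summary statistics over HSPs and assembled NumtS.

Covers the per-position mitochondrial coverage profile, per-chromosome
count/span tables, Pearson correlation, five-number summaries of the HSP
length/similarity/distance distributions, and the repeat content of NumtS
flanking regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import HSP, AssembledNumts, ValidationError, karyotype_key


@dataclass
class CoverageProfile:
    """Occurrences per mitochondrial position across all HSPs."""

    mito_length: int
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def coverage_profile(hsps: Sequence[HSP], mito_length: int) -> CoverageProfile:
    """counts[p] = number of HSPs whose mitochondrial interval contains p.

    Computed with a difference array; conserves total coverage (the sum of
    counts equals the sum of interval lengths).
    """
    diff = np.zeros(mito_length + 1, dtype=np.int64)
    for h in hsps:
        if h.mito_start < 0 or h.mito_end > mito_length:
            raise ValidationError(
                f"HSP mito interval [{h.mito_start}, {h.mito_end}) exceeds "
                f"the mitochondrial length {mito_length}"
            )
        diff[h.mito_start] += 1
        diff[h.mito_end] -= 1
    return CoverageProfile(mito_length, np.cumsum(diff[:-1]))


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero (spreadsheet convention), e.g. for the
    3-decimal chromosome coverage percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def chromosome_stats(
    numts: Sequence[AssembledNumts],
    chrom_lengths: Mapping[str, int],
    span_mode: str = "envelope",
) -> pd.DataFrame:
    """Per-chromosome NumtS count, summed span, and percent of chromosome.

    ``span_mode='envelope'`` sums each NumtS's outer nuclear extent
    (inter-block gaps included); ``'members'`` sums member HSP lengths
    instead — the published table does not state which roll-up it used, so
    both are provided.  Percentages are rounded half-away-from-zero to 3
    decimals.  Returns one row per chromosome in ``chrom_lengths``
    (karyotype order) plus a ``total`` row carrying the grand-total span.
    """
    if span_mode not in ("envelope", "members"):
        raise ValidationError(f"unknown span_mode {span_mode!r}")
    spans: dict = {c: 0 for c in chrom_lengths}
    counts: dict = {c: 0 for c in chrom_lengths}
    for n in numts:
        if n.chrom not in chrom_lengths:
            raise ValidationError(f"chromosome {n.chrom!r} missing from chrom_lengths")
        counts[n.chrom] += 1
        if span_mode == "envelope":
            spans[n.chrom] += n.nuc_length
        else:
            spans[n.chrom] += sum(h.nuc_length for h in n.members)
    rows = []
    for chrom in sorted(chrom_lengths, key=karyotype_key):
        length = chrom_lengths[chrom]
        span = spans[chrom]
        if span > length:
            raise ValidationError(f"chromosome {chrom!r}: span {span} exceeds length")
        rows.append(
            {
                "chrom": chrom,
                "numts_count": counts[chrom],
                "chrom_length": length,
                "total_span": span,
                "span_percent": round_half_up(100.0 * span / length, 3),
            }
        )
    rows.append(
        {
            "chrom": "total",
            "numts_count": sum(counts.values()),
            "chrom_length": sum(chrom_lengths.values()),
            "total_span": sum(spans.values()),
            "span_percent": round_half_up(
                100.0 * sum(spans.values()) / sum(chrom_lengths.values()), 3
            ),
        }
    )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Product-moment correlation, implemented from the definition
    (covariance over the product of standard deviations)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r requires two equal-length vectors, n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum()) * np.sqrt((dy * dy).sum())
    if denom == 0:
        raise ValidationError("correlation undefined: an argument has zero variance")
    return float((dx * dy).sum() / denom)


@dataclass
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def as_tuple(self):
        return (self.min, self.q1, self.median, self.q3, self.max)


def five_number_summary(values) -> FiveNumberSummary:
    """Min, quartiles and max with quartiles by linear interpolation of
    order statistics (the (n-1)q convention used by most spreadsheets)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("five_number_summary requires non-empty input")
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumberSummary(*map(float, q))


def span_differences(hsps: Sequence[HSP]) -> np.ndarray:
    """|nuclear extent - mitochondrial extent| per HSP — the footprint
    difference caused by indels accumulated since insertion."""
    return np.array(
        [abs(h.nuc_length - h.mito_length) for h in hsps], dtype=float
    )


def concatenation_distances(numts: Sequence[AssembledNumts]) -> np.ndarray:
    """Signed nuclear gaps between adjacent members inside multi-member
    NumtS; negative values mean the merged fragments overlap."""
    out = []
    for n in numts:
        for h1, h2 in zip(n.members, n.members[1:]):
            out.append(h2.nuc_start - h1.nuc_end)
    return np.array(out, dtype=float)


def _union_coverage(intervals: list, lo: int, hi: int) -> int:
    """Total bases of [lo, hi) covered by the union of intervals."""
    clipped = sorted(
        (max(lo, s), min(hi, e)) for s, e in intervals if min(hi, e) > max(lo, s)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def flank_repeat_content(
    numts: Sequence[AssembledNumts],
    repeats: Mapping[str, list],
    flank: int = 1000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat content of the 5' and 3' flanking regions of each NumtS.

    ``repeats`` maps chromosome name to a list of (start, end) repeat
    intervals (e.g. repeat-masker or segmental-duplication annotations in
    the NumtS coordinate space).  For each NumtS the fraction of its up to
    ``2*flank`` flanking bases covered by the union of repeats is computed,
    flanks being truncated at chromosome ends when lengths are supplied.

    Returns ``(per_numts, cumulative)``: per-NumtS fractions, and the
    cumulative distribution over NumtS at 1% bins (fraction of NumtS whose
    repeat content is <= each threshold).
    """
    rows = []
    for n in numts:
        chrom_repeats = list(repeats.get(n.chrom, []))
        limit = chrom_lengths[n.chrom] if chrom_lengths else None
        left_lo = max(0, n.nuc_start - flank)
        left_hi = n.nuc_start
        right_lo = n.nuc_end
        right_hi = n.nuc_end + flank if limit is None else min(limit, n.nuc_end + flank)
        flank_bases = (left_hi - left_lo) + (right_hi - right_lo)
        covered = _union_coverage(chrom_repeats, left_lo, left_hi) + _union_coverage(
            chrom_repeats, right_lo, right_hi
        )
        rows.append(
            {
                "numts_id": n.numts_id,
                "chrom": n.chrom,
                "flank_bases": flank_bases,
                "repeat_bases": covered,
                "repeat_fraction": covered / flank_bases if flank_bases else 0.0,
            }
        )
    per_numts = pd.DataFrame(rows)
    bins = np.arange(0, 101) / 100.0
    if len(per_numts):
        fracs = per_numts["repeat_fraction"].to_numpy()
        cum = [(fracs <= b + 1e-12).mean() for b in bins]
    else:
        cum = [0.0] * len(bins)
    cumulative = pd.DataFrame(
        {"repeat_content_percent": np.arange(0, 101), "cumulative_fraction": cum}
    )
    return per_numts, cumulative


def plot_coverage(profile: CoverageProfile, path) -> None:
    """Coverage of mitochondrial sites across the nuclear genome, as a
    step plot along the mitochondrial coordinate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.fill_between(np.arange(profile.mito_length), profile.counts, step="post")
    ax.set_xlabel("mitochondrial position (bp)")
    ax.set_ylabel("occurrences in nuclear genome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_flank_cumulative(cumulative: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(
        cumulative["repeat_content_percent"], cumulative["cumulative_fraction"] * 100
    )
    ax.set_xlabel("repeat + segdup content of 1 kb flanks (%)")
    ax.set_ylabel("cumulative % of NumtS")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
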