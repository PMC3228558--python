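"""Merging HSPs into assembled NumtS.

Two mitochondrial fragments found on the same chromosome are merged when
they are less than 2 kb apart in the nucleus (strict bound), their
mitochondrial fragments are not more than 2 kb apart (inclusive bound) in
the orientation of the alignment, and they lie on the same strand.  The
mitochondrial gap is circular — the minimum of the linear gap and the gap
taken around the origin — so chains spanning the control-region junction
(the D-loop is annotated as the tail of the linearised reference followed
by its head) merge without any special case.

Assembly is the transitive closure of this pairwise relation: within each
(chromosome, strand) group a union-find over all mergeable pairs yields
the connected components, each of which becomes one assembled NumtS.  The
transitivity accommodates chains interrupted by long repetitive elements,
where consecutive blocks may individually fail a bound that a nearby block
bridges.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .core import (
    HSP,
    AssembledNumts,
    AssemblyParams,
    ValidationError,
    karyotype_key,
)


def _oriented_mito_gap(h1: HSP, h2: HSP, L: int) -> int:
    """Signed mitochondrial gap from h1 to h2 in alignment orientation.

    ``h1`` must precede ``h2`` in nuclear order.  On the plus strand
    successive nuclear blocks ascend along the mitochondrial coordinate, on
    the minus strand they descend, so the gap runs from h1's mito end to
    h2's mito start (plus) or from h2's mito end to h1's mito start
    (minus).  Returns the linear gap; the circular variant is this value
    modulo L.
    """
    if h1.strand == "+":
        return h2.mito_start - h1.mito_end
    return h1.mito_start - h2.mito_end


def mergeable(h1: HSP, h2: HSP, params: Optional[AssemblyParams] = None) -> bool:
    """True iff two HSPs belong in the same assembled NumtS.

    Requires ``h1.nuc_start <= h2.nuc_start`` (pass them in nuclear order)
    and both on the same chromosome.  Overlapping fragments (negative gaps)
    always pass the corresponding bound.
    """
    params = params or AssemblyParams()
    if h1.chrom != h2.chrom:
        raise ValidationError(
            f"mergeable() requires HSPs on one chromosome, got "
            f"{h1.chrom!r} and {h2.chrom!r}"
        )
    if h1.nuc_start > h2.nuc_start:
        raise ValidationError("mergeable() requires h1.nuc_start <= h2.nuc_start")
    if params.require_same_orientation and h1.strand != h2.strand:
        return False
    nuclear_gap = h2.nuc_start - h1.nuc_end
    if nuclear_gap >= params.nuclear_gap_max:
        return False
    linear = _oriented_mito_gap(h1, h2, params.mito_length)
    circular = linear % params.mito_length
    return min(linear, circular) <= params.mito_gap_max


def _chain_wraps_junction(members: Sequence[HSP], params: AssemblyParams) -> bool:
    """A chain wraps the circular origin when some adjacent pair merges
    only via the around-the-origin gap (large negative linear gap, small
    circular gap)."""
    L = params.mito_length
    for h1, h2 in zip(members, members[1:]):
        linear = _oriented_mito_gap(h1, h2, L)
        if linear <= -L // 2 and linear % L <= params.mito_gap_max:
            return True
    return False


def _mito_span(members: Sequence[HSP], strand: str, wraps: bool) -> tuple[int, int]:
    """Union span of the members on the mitochondrial plus strand.

    For a junction-wrapping chain the span is the circular interval running
    from the first fragment encountered (in alignment orientation) across
    the origin to the last, reported as (start, end) with start > end.
    """
    if not wraps:
        return min(h.mito_start for h in members), max(h.mito_end for h in members)
    if strand == "+":
        return members[0].mito_start, members[-1].mito_end
    return members[-1].mito_start, members[0].mito_end


def assemble_numts(
    hsps: Sequence[HSP], params: Optional[AssemblyParams] = None
) -> list[AssembledNumts]:
    """Partition HSPs into assembled NumtS.

    HSPs are grouped per (chromosome, strand); within a group the
    connected components of the pairwise :func:`mergeable` graph become
    chains.  Every HSP belongs to exactly one output NumtS (singletons
    allowed); output is sorted by karyotype order then nuclear start, and
    members inside each NumtS by nuclear start.
    """
    params = params or AssemblyParams()
    groups: dict = {}
    for h in hsps:
        groups.setdefault((h.chrom, h.strand), []).append(h)

    numts: list[AssembledNumts] = []
    for (chrom, strand), members in groups.items():
        members = sorted(members, key=lambda h: (h.nuc_start, h.nuc_end, h.mito_start))
        parent = list(range(len(members)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if mergeable(members[a], members[b], params):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        chains: dict = {}
        for idx in range(len(members)):
            chains.setdefault(find(idx), []).append(members[idx])
        for chain in chains.values():
            chain.sort(key=lambda h: (h.nuc_start, h.nuc_end, h.mito_start))
            wraps = _chain_wraps_junction(chain, params)
            mito_start, mito_end = _mito_span(chain, strand, wraps)
            total_len = sum(h.alignment_length for h in chain)
            agg = sum(h.percent_identity * h.alignment_length for h in chain) / total_len
            numts.append(
                AssembledNumts(
                    chrom=chrom,
                    strand=strand,
                    nuc_start=min(h.nuc_start for h in chain),
                    nuc_end=max(h.nuc_end for h in chain),
                    members=chain,
                    mito_start=mito_start,
                    mito_end=mito_end,
                    wraps_junction=wraps,
                    aggregate_identity=agg,
                )
            )
    numts.sort(key=lambda n: (karyotype_key(n.chrom), n.nuc_start, n.nuc_end, n.strand))
    return numts


def assign_ids(
    numts: Sequence[AssembledNumts], prefix: str = "HSA_NumtS"
) -> list[AssembledNumts]:
    """Assign sequential IDs like ``HSA_NumtS_014`` to sorted NumtS.

    Numbers are zero-padded to three digits, growing naturally to four
    beyond 999.  Member HSPs of multi-member NumtS get block suffixes
    ``_b1.._bN`` in nuclear order (e.g. ``HSA_NumtS_014_b5``); members of
    single-HSP NumtS carry the bare NumtS ID.  Modifies members in place
    and returns the list for chaining.
    """
    for rank, n in enumerate(numts, start=1):
        n.numts_id = f"{prefix}_{rank:03d}"
        if len(n.members) == 1:
            n.members[0] = n.members[0].with_id(n.numts_id)
        else:
            n.members = [
                h.with_id(f"{n.numts_id}_b{k}") for k, h in enumerate(n.members, start=1)
            ]
    return list(numts)
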