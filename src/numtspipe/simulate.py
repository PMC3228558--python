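"""Synthetic genomes with implanted mitochondrial fragments.

The generator emulates the situation the pipeline is built for: fragments
of a circular mitochondrial genome inserted into nuclear background at
various ages.  Divergence since insertion is modelled as i.i.d. per-base
substitutions plus rare short indels; implants may be reverse-complement
("minus strand"), split into 2-4 sub-blocks separated by short non-
mitochondrial spacers (mimicking repeat interruption of old insertions),
or sampled across the circular origin so that a linear aligner must report
them as two junction-flanking HSPs.

Every implant is described exactly by a :class:`TruthRecord` whose
realised identity is computed from the mutation log — not by re-aligning —
so ground truth never depends on the aligner under test.  Fragment
lengths default to 31 bp - 15 kb (log-uniform, matching the strongly
right-skewed length distribution of real NumtS) and target identities to
the 63-100% range observed in the human compilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import HSP, AssembledNumts, SequenceRecord, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, seed: Union[int, np.random.Generator]) -> str:
    """Uniform i.i.d. A/C/G/T string of the given length."""
    rng = _as_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic genome.

    Defaults mirror the observed human NumtS landscape: fragment lengths
    spanning 31 bp to 15 kb, similarity to the modern mitochondrial
    reference between 63% and 100%, both orientations equally likely, a
    fifth of implants split by short spacers (< 2 kb, so the assembler
    should rejoin them) and a small fraction crossing the circular origin.
    ``min_separation`` keeps distinct implants more than one merge radius
    apart so they remain distinguishable insertions.
    """

    nuclear_length: int = 300_000
    n_implants: int = 20
    fragment_length_range: tuple = (31, 15_000)
    target_identity_range: tuple = (63.0, 100.0)
    indel_rate: float = 5e-4
    p_minus_strand: float = 0.5
    p_split: float = 0.2
    p_junction_spanning: float = 0.05
    rng_seed: int = 0
    min_separation: int = 2500
    spacer_length_range: tuple = (200, 1900)
    chrom_name: str = "chr1"
    repeat_fraction: float = 0.0  # optional tandem-repeat background content
    junction_arm_min: int = 100  # both arms of an origin-crossing implant
    split_block_min: int = 150  # minimum length of each split sub-block

    def __post_init__(self) -> None:
        for p in (self.p_minus_strand, self.p_split, self.p_junction_spanning):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        lo, hi = self.fragment_length_range
        if lo <= 0 or hi < lo:
            raise ValidationError("fragment_length_range must be positive and ordered")
        lo, hi = self.target_identity_range
        if not (0 < lo <= hi <= 100):
            raise ValidationError("target_identity_range must lie in (0, 100]")


@dataclass
class TruthRecord:
    """Ground-truth descriptor of one implant."""

    implant_id: str
    chrom: str
    nuc_start: int
    nuc_end: int
    strand: str
    mito_start: int
    mito_end: int
    wraps_junction: bool
    realized_identity: float
    n_blocks: int

    @property
    def nuc_length(self) -> int:
        return self.nuc_end - self.nuc_start


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float,
    seed: Union[int, np.random.Generator],
    indel_extension_p: float = 0.7,
) -> tuple[str, float]:
    """Mutate a sequence and report the realised percent identity.

    Substitutions are i.i.d. per base to a uniformly chosen different
    base; indel events occur at ``indel_rate`` per base (insertion or
    deletion with equal probability) with geometric lengths dominated by
    length 1.  Identity is bookkept from the mutation log as
    matches / (matches + mismatches + inserted + deleted) x 100.
    """
    if not (0 <= substitution_rate < 1 and 0 <= indel_rate < 1):
        raise ValidationError("mutation rates must lie in [0, 1)")
    if not seq:
        raise ValidationError("cannot mutate an empty sequence")
    mean_indel_len = 1.0 / indel_extension_p
    expected_survivors = len(seq) * (1.0 - 0.5 * indel_rate * mean_indel_len)
    if expected_survivors < 10:
        raise ValidationError(
            "mutation rates would destroy the sequence "
            f"(expected surviving length {expected_survivors:.1f} < 10)"
        )
    rng = _as_rng(seed)
    out: list = []
    matches = mismatches = inserted = deleted = 0
    alphabet = "ACGT"
    i = 0
    n = len(seq)
    while i < n:
        if indel_rate and rng.random() < indel_rate:
            length = int(rng.geometric(indel_extension_p))
            if rng.random() < 0.5:
                for _ in range(length):
                    out.append(alphabet[rng.integers(4)])
                inserted += length
            else:
                skipped = min(length, n - i)
                deleted += skipped
                i += skipped
                continue
        base = seq[i]
        if substitution_rate and rng.random() < substitution_rate:
            choices = alphabet.replace(base, "") if base in alphabet else alphabet
            out.append(choices[rng.integers(len(choices))])
            mismatches += 1
        else:
            out.append(base)
            matches += 1
        i += 1
    columns = matches + mismatches + inserted + deleted
    identity = 100.0 * matches / columns if columns else 100.0
    return "".join(out), identity


def _sample_fragment(
    mito: str, length: int, junction: bool, rng: np.random.Generator, arm_min: int = 100
) -> tuple[str, int, int, bool]:
    """Sample a fragment from the circular mitochondrial genome.

    Returns (sequence, mito_start, mito_end, wraps); a wrapping fragment
    has start > end with the sequence running across the origin.  Each arm
    of a wrapping fragment spans at least ``arm_min`` bases (a fragment
    with a vestigial arm would not actually cross the junction in any
    observable way), falling back to a 1-base minimum for short fragments.
    """
    L = len(mito)
    length = min(length, L)
    if junction and length >= 2:
        lo = arm_min if length >= 2 * arm_min else 1
        tail = int(rng.integers(lo, length - lo + 1))  # bases before the origin
        start = L - tail
        end = length - tail
        return mito[start:] + mito[:end], start, end, True
    start = int(rng.integers(0, L - length + 1))
    return mito[start : start + length], start, start + length, False


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _inject_tandem_repeats(bg: list, rng: np.random.Generator, fraction: float) -> None:
    """Overwrite a fraction of the background with tandem repeats (an
    opt-in stress test emulating the repeat-rich neighbourhoods real NumtS
    inhabit)."""
    total = int(len(bg) * fraction)
    placed = 0
    while placed < total:
        motif = random_sequence(int(rng.integers(5, 51)), rng)
        span = int(rng.integers(200, 2001))
        start = int(rng.integers(0, len(bg) - span))
        rep = (motif * (span // len(motif) + 1))[:span]
        bg[start : start + span] = list(rep)
        placed += span


def simulate_genome(
    mito: SequenceRecord, params: SimulationParams
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Generate a nuclear chromosome with implanted mitochondrial
    fragments plus the exact truth table.

    Deterministic for a given (mito, params): identical inputs give
    byte-identical output.  Raises a placement error when the requested
    implants cannot be spaced ``min_separation`` apart on the requested
    background length.
    """
    rng = np.random.default_rng(params.rng_seed)
    lo_len, hi_len = params.fragment_length_range
    lo_id, hi_id = params.target_identity_range

    implants = []
    for k in range(params.n_implants):
        frag_len = _log_uniform(rng, lo_len, min(hi_len, len(mito.sequence)))
        junction = rng.random() < params.p_junction_spanning
        frag, m_start, m_end, wraps = _sample_fragment(
            mito.sequence, frag_len, junction, rng, params.junction_arm_min
        )
        target = rng.uniform(lo_id, hi_id)
        sub_rate = max(0.0, 1.0 - target / 100.0)
        mutated, identity = mutate_sequence(
            frag, sub_rate, params.indel_rate, rng
        )
        strand = "-" if rng.random() < params.p_minus_strand else "+"
        if strand == "-":
            from .core import revcomp

            mutated = revcomp(mutated)
        n_blocks = 1
        if params.p_split and rng.random() < params.p_split:
            # every sub-block spans at least split_block_min bases — a
            # shorter piece would not be an observable fragment of its own
            n_blocks = min(
                int(rng.integers(2, 5)), len(mutated) // params.split_block_min
            )
            n_blocks = max(n_blocks, 1)
        if n_blocks == 1:
            pieces = [mutated]
        else:
            extra = len(mutated) - n_blocks * params.split_block_min
            bounds = np.sort(rng.integers(0, extra + 1, size=n_blocks - 1))
            lengths = np.diff(
                np.concatenate([[0], bounds + params.split_block_min * np.arange(1, n_blocks), [len(mutated)]])
            )
            pieces = []
            prev = 0
            for ln in lengths:
                pieces.append(mutated[prev : prev + int(ln)])
                prev += int(ln)
        spacer_lo, spacer_hi = params.spacer_length_range
        parts = []
        for idx, piece in enumerate(pieces):
            if idx:
                parts.append(random_sequence(int(rng.integers(spacer_lo, spacer_hi + 1)), rng))
            parts.append(piece)
        implant_seq = "".join(parts)
        implants.append(
            {
                "seq": implant_seq,
                "strand": strand,
                "mito_start": m_start,
                "mito_end": m_end,
                "wraps": wraps,
                "identity": identity,
                "n_blocks": n_blocks,
            }
        )

    # spacing: place implants left to right with random slack in between
    lengths = [len(im["seq"]) for im in implants]
    sep = params.min_separation
    free = params.nuclear_length - sum(lengths) - (len(implants) + 1) * sep
    if free < 0:
        raise ValidationError(
            f"cannot place {params.n_implants} implants totalling {sum(lengths)} bp "
            f"with {sep} bp separation on a {params.nuclear_length} bp background; "
            "increase nuclear_length"
        )
    slack = np.sort(rng.integers(0, free + 1, size=len(implants))) if implants else []
    background = list(random_sequence(params.nuclear_length, rng))
    if params.repeat_fraction:
        _inject_tandem_repeats(background, rng, params.repeat_fraction)

    truth: list[TruthRecord] = []
    cursor = sep
    for k, im in enumerate(implants):
        gap = int(slack[k]) - (int(slack[k - 1]) if k else 0)
        start = cursor + gap
        background[start : start + len(im["seq"])] = list(im["seq"])
        truth.append(
            TruthRecord(
                implant_id=f"implant_{k + 1:03d}",
                chrom=params.chrom_name,
                nuc_start=start,
                nuc_end=start + len(im["seq"]),
                strand=im["strand"],
                mito_start=im["mito_start"],
                mito_end=im["mito_end"],
                wraps_junction=im["wraps"],
                realized_identity=im["identity"],
                n_blocks=im["n_blocks"],
            )
        )
        cursor = start + len(im["seq"]) + sep
    genome = SequenceRecord(params.chrom_name, "".join(background))
    return genome, truth


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "implant_id": [t.implant_id for t in truth],
            "chrom": [t.chrom for t in truth],
            "nuc_start": [t.nuc_start for t in truth],
            "nuc_end": [t.nuc_end for t in truth],
            "strand": [t.strand for t in truth],
            "mito_start": [t.mito_start for t in truth],
            "mito_end": [t.mito_end for t in truth],
            "wraps_junction": [t.wraps_junction for t in truth],
            "realized_identity": [t.realized_identity for t in truth],
            "n_blocks": [t.n_blocks for t in truth],
        }
    )


def evaluate_recovery(
    detected: Sequence[AssembledNumts],
    truth: Sequence[TruthRecord],
    min_overlap_frac: float = 0.5,
) -> dict:
    """Score detected assembled NumtS against the truth table.

    Matching uses reciprocal overlap: a (truth, detection) pair is a
    candidate when their nuclear intervals overlap by at least
    ``min_overlap_frac`` of *each*; candidates are assigned greedily by
    descending overlap, one-to-one.  Reports precision, recall and merge
    accuracy (the fraction of split implants recovered as exactly one
    assembled NumtS).  With no detections at all, precision is reported as
    1.0 by convention, flagged by ``zero_detection``.
    """
    candidates = []
    for ti, t in enumerate(truth):
        for di, d in enumerate(detected):
            if d.chrom != t.chrom:
                continue
            ov = min(d.nuc_end, t.nuc_end) - max(d.nuc_start, t.nuc_start)
            if ov <= 0:
                continue
            if ov >= min_overlap_frac * t.nuc_length and ov >= min_overlap_frac * d.nuc_length:
                candidates.append((ov, ti, di))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    matched_t: dict = {}
    matched_d: set = set()
    for ov, ti, di in candidates:
        if ti in matched_t or di in matched_d:
            continue
        matched_t[ti] = di
        matched_d.add(di)

    n_truth, n_detected = len(truth), len(detected)
    recall = len(matched_t) / n_truth if n_truth else 1.0
    precision = len(matched_d) / n_detected if n_detected else 1.0
    split_idx = [i for i, t in enumerate(truth) if t.n_blocks >= 2]
    merged_ok = 0
    for i in split_idx:
        if i not in matched_t:
            continue
        t = truth[i]
        # a split implant counts as merged only if exactly one detection
        # lies (mostly) within its footprint
        inside = sum(
            1
            for d in detected
            if d.chrom == t.chrom
            and min(d.nuc_end, t.nuc_end) - max(d.nuc_start, t.nuc_start)
            >= 0.5 * d.nuc_length
        )
        merged_ok += inside == 1
    return {
        "precision": precision,
        "recall": recall,
        "merge_accuracy": merged_ok / len(split_idx) if split_idx else 1.0,
        "n_truth": n_truth,
        "n_detected": n_detected,
        "n_matched": len(matched_t),
        "n_split_truth": len(split_idx),
        "zero_detection": n_detected == 0,
    }
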