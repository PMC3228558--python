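"""Local and global alignment between mitochondrial and nuclear sequences.

The HSP search is a self-contained seed-and-extend aligner in the BLASTN
mould: exact k-mer seeds (default word size 11) are clustered by diagonal,
clusters are triaged with a cheap ungapped X-drop extension, and surviving
clusters are resolved with a banded Smith-Waterman with affine gaps.  The
banded DP is exact within its band, so on well-seeded hits the reported
local alignment is the true optimum.

Scoring follows the BLAST convention: a gap of length ``g`` costs
``gap_open + g * gap_extend``.  Minus-strand hits are found by running the
identical plus-strand search against the reverse complement of the
chromosome and mapping subject coordinates back to the forward strand, so
the mitochondrial interval of every HSP is always reported on the
mitochondrial plus strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import HSP, AlignmentBlockList, ScoringScheme, SequenceRecord, ValidationError, revcomp

_NEG = -(1 << 30)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else (N) as 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int):
    """Rolling base-4 k-mer codes plus a validity mask (no N in window)."""
    m = len(codes)
    if m < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    x = codes.astype(np.int64)
    out = np.zeros(m - k + 1, dtype=np.int64)
    for t in range(k):
        out = out * 4 + x[t : m - k + 1 + t]
    bad = np.cumsum(np.concatenate([[0], (codes == 4).astype(np.int64)]))
    valid = (bad[k:] - bad[: m - k + 1]) == 0
    return out, valid


def _seed_index(qcodes: np.ndarray, k: int) -> dict:
    kc, valid = _kmer_codes(qcodes, k)
    index: dict = {}
    for pos in np.nonzero(valid)[0]:
        index.setdefault(int(kc[pos]), []).append(int(pos))
    return index


def _seed_hits(index: dict, scodes: np.ndarray, k: int) -> list:
    """All (query_pos, subject_pos) exact k-mer matches."""
    kc, valid = _kmer_codes(scodes, k)
    hits = []
    get = index.get
    for j in np.nonzero(valid)[0]:
        qpos = get(int(kc[j]))
        if qpos is not None:
            for i in qpos:
                hits.append((i, int(j)))
    return hits


def _cluster_hits(hits: list, diag_tol: int, max_seed_gap: int) -> list:
    """Group seed hits into diagonal clusters.

    Hits are first banded by diagonal (gaps > ``diag_tol`` start a new
    band), then split along the subject coordinate at jumps larger than
    ``max_seed_gap``.  Each cluster is a list of (i, j) hits.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[1]))
    clusters = []
    band: list = []
    for h in hits:
        d = h[1] - h[0]
        if band and d - (band[-1][1] - band[-1][0]) > diag_tol:
            clusters.extend(_split_by_subject(band, max_seed_gap))
            band = []
        band.append(h)
    clusters.extend(_split_by_subject(band, max_seed_gap))
    return clusters


def _split_by_subject(band: list, max_seed_gap: int) -> list:
    band = sorted(band, key=lambda h: h[1])
    out = []
    cur = [band[0]]
    for h in band[1:]:
        if h[1] - cur[-1][1] > max_seed_gap:
            out.append(cur)
            cur = []
        cur.append(h)
    out.append(cur)
    return out


def _ungapped_extend(q, s, i, j, k, scoring: ScoringScheme, xdrop: int = 40) -> int:
    """Best ungapped score through the seed at (i, j), X-drop bounded."""
    match, mismatch = scoring.match_reward, scoring.mismatch_penalty
    score = k * match
    # right of the seed
    cur = gain = 0
    qi, sj = i + k, j + k
    while qi < len(q) and sj < len(s):
        cur += match if (q[qi] == s[sj] and q[qi] != 4) else mismatch
        if cur > gain:
            gain = cur
        if cur < gain - xdrop:
            break
        qi += 1
        sj += 1
    score += gain
    # left of the seed
    cur = gain = 0
    qi, sj = i - 1, j - 1
    while qi >= 0 and sj >= 0:
        cur += match if (q[qi] == s[sj] and q[qi] != 4) else mismatch
        if cur > gain:
            gain = cur
        if cur < gain - xdrop:
            break
        qi -= 1
        sj -= 1
    return score + gain


@dataclass
class _LocalAlignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    mismatches: int
    gap_opens: int
    gap_columns: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns


def banded_local_align(
    q: np.ndarray, s: np.ndarray, scoring: ScoringScheme, dlo: int, dhi: int
) -> Optional[_LocalAlignment]:
    """Smith-Waterman with affine gaps, restricted to diagonals
    ``d = j - i`` in ``[dlo, dhi]``; exact within the band.

    The in-row gap recurrence (a gap in the query) is resolved in closed
    form with a max-plus prefix scan, so each DP row is a handful of
    vectorised operations: for row ``i``,
    ``E[b] = gap_open + gap_extend*b + max_{k<b}(H0[k] - gap_extend*k)``
    where ``H0`` is the row maximum over diagonal/subject-gap/zero moves.
    Opening a query gap from an E-derived cell would merely extend the same
    gap, so the scan over ``H0`` is exact.
    """
    n, m = len(q), len(s)
    W = dhi - dlo + 1
    if W <= 0 or n == 0 or m == 0:
        return None
    match, mismatch = scoring.match_reward, scoring.mismatch_penalty
    go, ge = scoring.gap_open, scoring.gap_extend
    oe = go + ge  # first gapped base

    H = np.full((n + 1, W), _NEG, dtype=np.int32)
    E = np.full((n + 1, W), _NEG, dtype=np.int32)
    F = np.full((n + 1, W), _NEG, dtype=np.int32)
    b_idx = np.arange(W, dtype=np.int32)
    j0 = dlo + b_idx
    H[0, (j0 >= 0) & (j0 <= m)] = 0  # zero-valued local-alignment anchors

    best_score, best_i, best_b = 0, 0, 0
    neg_tail = np.array([_NEG], dtype=np.int32)
    for i in range(1, n + 1):
        j = i + dlo + b_idx
        valid = (j >= 1) & (j <= m)  # cells with a subject character
        if not valid.any():
            H[i, j == 0] = 0
            continue
        jv = np.where(valid, j, 1)
        sub = np.where((s[jv - 1] == q[i - 1]) & (q[i - 1] != 4), match, mismatch).astype(np.int32)
        diag = H[i - 1] + sub
        h_up = np.concatenate([H[i - 1, 1:], neg_tail])
        f_up = np.concatenate([F[i - 1, 1:], neg_tail])
        f_row = np.maximum(h_up + oe, f_up + ge)
        h0 = np.maximum(np.maximum(diag, f_row), 0)
        h0 = np.where(valid, h0, _NEG)
        # max-plus prefix scan for the in-row (query) gap
        t = np.where(valid, h0 - ge * b_idx, _NEG)
        run = np.maximum.accumulate(t)
        e_row = np.concatenate([neg_tail, run[:-1]]) + go + ge * b_idx
        e_row = np.where(valid, e_row, _NEG).astype(np.int32)
        h1 = np.maximum(h0, e_row)
        h1 = np.where(j == 0, 0, h1)  # anchors at subject position 0
        H[i], E[i], F[i] = h1, e_row, f_row
        rb = int(np.argmax(h1))
        if h1[rb] > best_score:
            best_score, best_i, best_b = int(h1[rb]), i, rb

    if best_score <= 0:
        return None
    return _traceback(q, s, scoring, H, E, F, dlo, best_i, best_b)


def _traceback(q, s, scoring, H, E, F, dlo, i, b) -> _LocalAlignment:
    match, mismatch = scoring.match_reward, scoring.mismatch_penalty
    go, ge = scoring.gap_open, scoring.gap_extend
    oe = go + ge
    W = H.shape[1]
    q_end = i
    s_end = i + dlo + b
    matches = mismatches = gap_opens = gap_cols = 0
    score = int(H[i, b])
    while True:
        v = int(H[i, b])
        if v == 0:
            break
        j = i + dlo + b
        is_match = bool(q[i - 1] == s[j - 1] and q[i - 1] != 4)
        sub = match if is_match else mismatch
        if i >= 1 and H[i - 1, b] > _NEG // 2 and v == int(H[i - 1, b]) + sub:
            matches += is_match
            mismatches += not is_match
            i -= 1
            continue
        if v == int(F[i, b]):  # gap in the subject: consume query chars
            gap_opens += 1
            while True:
                fv = int(F[i, b])
                gap_cols += 1
                up_f = int(F[i - 1, b + 1]) if b + 1 < W else _NEG
                up_h = int(H[i - 1, b + 1]) if b + 1 < W else _NEG
                i, b = i - 1, b + 1
                if up_f > _NEG // 2 and fv == up_f + ge:
                    continue
                assert fv == up_h + oe, "traceback: inconsistent F state"
                break
            continue
        assert v == int(E[i, b]), "traceback: inconsistent H state"
        gap_opens += 1
        while True:  # gap in the query: consume subject chars
            ev = int(E[i, b])
            gap_cols += 1
            left_e = int(E[i, b - 1]) if b >= 1 else _NEG
            left_h = int(H[i, b - 1]) if b >= 1 else _NEG
            b -= 1
            if left_e > _NEG // 2 and ev == left_e + ge:
                continue
            assert ev == left_h + oe, "traceback: inconsistent E state"
            break
    return _LocalAlignment(
        score=score,
        q_start=i,
        q_end=q_end,
        s_start=i + dlo + b,
        s_end=s_end,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gap_columns=gap_cols,
    )


def _search_one_strand(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    scoring: ScoringScheme,
    *,
    word_size: int,
    diag_tol: int,
    max_seed_gap: int,
    band_pad: int,
    window_margin: int,
    ungapped_trigger: int,
    min_cluster_seeds: int,
) -> list[_LocalAlignment]:
    index = _seed_index(qcodes, word_size)
    hits = _seed_hits(index, scodes, word_size)
    alignments = []
    for cluster in _cluster_hits(hits, diag_tol, max_seed_gap):
        if len(cluster) < min_cluster_seeds:
            best_seed = max(
                _ungapped_extend(qcodes, scodes, i, j, word_size, scoring)
                for i, j in cluster
            )
            if best_seed < ungapped_trigger:
                continue
        qs = [h[0] for h in cluster]
        js = [h[1] for h in cluster]
        ds = [j - i for i, j in cluster]
        qlo = max(0, min(qs) - window_margin)
        qhi = min(len(qcodes), max(qs) + word_size + window_margin)
        jlo = max(0, min(js) - window_margin)
        jhi = min(len(scodes), max(js) + word_size + window_margin)
        shift = jlo - qlo
        dlo = min(ds) - band_pad - shift
        dhi = max(ds) + band_pad - shift
        aln = banded_local_align(qcodes[qlo:qhi], scodes[jlo:jhi], scoring, dlo, dhi)
        if aln is None:
            continue
        aln.q_start += qlo
        aln.q_end += qlo
        aln.s_start += jlo
        aln.s_end += jlo
        alignments.append(aln)
    return alignments


def _dedup(pairs: list) -> list:
    """Keep the highest-scoring HSP among mutually overlapping ones.

    Two HSPs conflict when, on the same strand, their nuclear intervals
    overlap by more than half of the shorter one and their mitochondrial
    intervals overlap at all.  Ties go to the leftmost nuclear start.
    """
    pairs = sorted(
        pairs, key=lambda p: (-p[0].raw_score, p[0].nuc_start, p[0].mito_start)
    )
    kept: list = []
    for hsp, stats in pairs:
        conflict = False
        for other, _ in kept:
            if other.strand != hsp.strand or other.chrom != hsp.chrom:
                continue
            nuc_ov = min(other.nuc_end, hsp.nuc_end) - max(other.nuc_start, hsp.nuc_start)
            mito_ov = min(other.mito_end, hsp.mito_end) - max(
                other.mito_start, hsp.mito_start
            )
            shorter = min(other.nuc_length, hsp.nuc_length)
            if nuc_ov > 0.5 * shorter and mito_ov > 0:
                conflict = True
                break
        if not conflict:
            kept.append((hsp, stats))
    kept.sort(key=lambda p: (p[0].nuc_start, p[0].mito_start, p[0].strand))
    return kept


def find_hsps_detailed(
    mito: SequenceRecord,
    chrom: SequenceRecord,
    scoring: Optional[ScoringScheme] = None,
    search_both_strands: bool = True,
    *,
    word_size: int = 11,
    diag_tol: int = 50,
    max_seed_gap: int = 2000,
    band_pad: int = 50,
    window_margin: int = 1000,
    ungapped_trigger: int = 40,
    min_cluster_seeds: int = 3,
) -> list[tuple[HSP, dict]]:
    """As :func:`find_hsps`, but pairs each HSP with its alignment counts
    (matches / mismatches / gap_opens / gap_columns) for self-consistency
    checks."""
    scoring = scoring or ScoringScheme()
    if len(mito.sequence) < word_size or len(chrom.sequence) < word_size:
        return []
    qcodes = encode(mito.sequence)
    kwargs = dict(
        word_size=word_size,
        diag_tol=diag_tol,
        max_seed_gap=max_seed_gap,
        band_pad=band_pad,
        window_margin=window_margin,
        ungapped_trigger=ungapped_trigger,
        min_cluster_seeds=min_cluster_seeds,
    )
    search_space = len(mito.sequence) * len(chrom.sequence)
    pairs: list = []
    strands = [("+", chrom.sequence)]
    if search_both_strands:
        strands.append(("-", revcomp(chrom.sequence)))
    m = len(chrom.sequence)
    for strand, subject_seq in strands:
        scodes = encode(subject_seq)
        for aln in _search_one_strand(qcodes, scodes, scoring, **kwargs):
            if aln.score < scoring.min_raw_score:
                continue
            if strand == "+":
                nuc_start, nuc_end = aln.s_start, aln.s_end
            else:
                nuc_start, nuc_end = m - aln.s_end, m - aln.s_start
            evalue = (
                scoring.ka_k
                * search_space
                * math.exp(-scoring.ka_lambda * aln.score)
            )
            hsp = HSP(
                chrom=chrom.id,
                nuc_start=nuc_start,
                nuc_end=nuc_end,
                strand=strand,
                mito_start=aln.q_start,
                mito_end=aln.q_end,
                percent_identity=100.0 * aln.matches / aln.columns,
                alignment_length=aln.columns,
                raw_score=aln.score,
                evalue=evalue,
                mismatches=aln.mismatches,
                gap_opens=aln.gap_opens,
            )
            stats = {
                "matches": aln.matches,
                "mismatches": aln.mismatches,
                "gap_opens": aln.gap_opens,
                "gap_columns": aln.gap_columns,
            }
            pairs.append((hsp, stats))
    return _dedup(pairs)


def find_hsps(
    mito: SequenceRecord,
    chrom: SequenceRecord,
    scoring: Optional[ScoringScheme] = None,
    search_both_strands: bool = True,
    **kwargs,
) -> list[HSP]:
    """Find all local alignments (HSPs) of the mitochondrial query against
    one chromosome, on both strands, with raw score >= ``min_raw_score``.

    Returns HSPs sorted by nuclear start, each reported once (overlapping
    same-diagonal hits are culled, keeping the best score).  Sequences
    shorter than the word size, or consisting only of N, yield an empty
    list rather than an error.
    """
    return [h for h, _ in find_hsps_detailed(mito, chrom, scoring, search_both_strands, **kwargs)]


# ---------------------------------------------------------------------------
# Global alignment (liftover substrate)


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: Optional[ScoringScheme] = None,
    max_combined_length: int = 100_000,
) -> AlignmentBlockList:
    """Needleman-Wunsch global alignment with affine gaps, decomposed into
    gapless blocks.

    Intended for near-identical mitochondrial references (<= ~17 kb); the
    DP is delegated to :class:`Bio.Align.PairwiseAligner` with this
    package's scoring convention (a gap of length g costs
    ``gap_open + g*gap_extend``).
    """
    from Bio import Align

    scoring = scoring or ScoringScheme()
    if not a.sequence or not b.sequence:
        raise ValidationError("global_align requires non-empty sequences")
    if len(a.sequence) + len(b.sequence) > max_combined_length:
        raise ValidationError(
            f"combined length {len(a.sequence) + len(b.sequence)} exceeds the "
            f"{max_combined_length} bp cap for global alignment"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match_reward
    aligner.mismatch_score = scoring.mismatch_penalty
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(a.sequence, b.sequence)[0]
    a_blocks, b_blocks = aln.aligned
    blocks = []
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        a0, a1, b0, b1 = int(a0), int(a1), int(b0), int(b1)
        if blocks and blocks[-1][0][1] == a0 and blocks[-1][1][1] == b0:
            blocks[-1] = ((blocks[-1][0][0], a1), (blocks[-1][1][0], b1))
        else:
            blocks.append(((a0, a1), (b0, b1)))
    return AlignmentBlockList(blocks=blocks, score=float(aln.score))
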