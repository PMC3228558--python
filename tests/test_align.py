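"""Aligner tests: trivial implants, invariances, and exact agreement with
an independent full-DP oracle (Biopython's PairwiseAligner)."""

import numpy as np
import pytest
from Bio import Align

from numtspipe import (
    ScoringScheme,
    SequenceRecord,
    ValidationError,
    find_hsps,
    find_hsps_detailed,
    global_align,
    mutate_sequence,
    random_sequence,
    revcomp,
)

SCORING = ScoringScheme()


def sw_oracle(query: str, subject: str):
    """Full Smith-Waterman with affine gaps under the package's scoring
    convention (gap of length g costs -5 - 2g)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = SCORING.match_reward
    a.mismatch_score = SCORING.mismatch_penalty
    a.open_gap_score = SCORING.gap_open + SCORING.gap_extend
    a.extend_gap_score = SCORING.gap_extend
    aln = a.align(query, subject)[0]
    qb, sb = aln.aligned
    return {
        "score": int(aln.score),
        "q": (int(qb[0][0]), int(qb[-1][1])),
        "s": (int(sb[0][0]), int(sb[-1][1])),
    }


def implant(background: str, fragment: str, pos: int) -> str:
    return background[:pos] + fragment + background[pos + len(fragment):]


class TestFindHsps:
    def test_exact_copy_scores_two_per_base(self, mito, rng):
        frag = mito.sequence[500:600]
        chrom = SequenceRecord("chr1", implant(random_sequence(30_000, rng), frag, 10_000))
        (h,) = find_hsps(mito, chrom)
        assert (h.mito_start, h.mito_end) == (500, 600)
        assert (h.nuc_start, h.nuc_end) == (10_000, 10_100)
        assert h.percent_identity == 100.0
        assert h.raw_score == 200
        assert h.strand == "+"

    def test_no_implant_no_hsps(self, mito, rng):
        chrom = SequenceRecord("chr1", random_sequence(20_000, rng))
        assert find_hsps(mito, chrom) == []

    def test_all_n_sequence_empty_result(self, mito):
        assert find_hsps(mito, SequenceRecord("chr1", "N" * 5000)) == []

    def test_sequence_shorter_than_word_empty_result(self, mito):
        assert find_hsps(mito, SequenceRecord("chr1", "ACGTACG")) == []

    def test_shift_invariance(self, mito, rng):
        # prepending a constant offset shifts coordinates by exactly that
        # offset and changes nothing else
        frag = mito.sequence[2000:2400]
        genome = implant(random_sequence(30_000, rng), frag, 5_000)
        prefix = random_sequence(1_377, rng)
        (h1,) = find_hsps(mito, SequenceRecord("chr1", genome))
        (h2,) = find_hsps(mito, SequenceRecord("chr1", prefix + genome))
        assert (h2.nuc_start - h1.nuc_start, h2.nuc_end - h1.nuc_end) == (1_377, 1_377)
        assert (h2.mito_start, h2.mito_end, h2.raw_score) == (
            h1.mito_start,
            h1.mito_end,
            h1.raw_score,
        )

    def test_reverse_complement_symmetry(self, mito, rng):
        # reverse-complementing the whole chromosome mirrors every HSP:
        # strand flips, the nuclear interval reflects, the mitochondrial
        # interval (always plus strand) and score are unchanged
        frag = mito.sequence[8_000:8_500]
        genome = implant(random_sequence(30_000, rng), frag, 12_000)
        L = len(genome)
        (plus,) = find_hsps(mito, SequenceRecord("chr1", genome))
        (minus,) = find_hsps(mito, SequenceRecord("chr1", revcomp(genome)))
        assert plus.strand == "+" and minus.strand == "-"
        assert (minus.mito_start, minus.mito_end) == (plus.mito_start, plus.mito_end)
        assert (minus.nuc_start, minus.nuc_end) == (L - plus.nuc_end, L - plus.nuc_start)
        assert minus.raw_score == plus.raw_score

    def test_raw_score_self_consistency(self, mito, rng):
        frag, _ = mutate_sequence(mito.sequence[1000:2500], 0.1, 1e-3, 7)
        chrom = SequenceRecord("chr1", implant(random_sequence(20_000, rng), frag, 6_000))
        for h, stats in find_hsps_detailed(mito, chrom):
            recomputed = (
                SCORING.match_reward * stats["matches"]
                + SCORING.mismatch_penalty * stats["mismatches"]
                + SCORING.gap_open * stats["gap_opens"]
                + SCORING.gap_extend * stats["gap_columns"]
            )
            assert recomputed == h.raw_score
            assert stats["matches"] + stats["mismatches"] + stats["gap_columns"] == h.alignment_length

    def test_dp_oracle_equivalence_across_divergence(self, mito):
        """Coordinates (within 5 bp of end trimming) and score of every
        detected HSP match a full SW-with-affine-gaps oracle run on the
        implant neighbourhood."""
        rng = np.random.default_rng(99)
        n_implants = 10
        frag_len = 800
        sep = 2_000
        chunk = frag_len + sep
        bg = random_sequence(n_implants * chunk + sep, rng)
        implants = []
        genome = bg
        for k in range(n_implants):
            m0 = int(rng.integers(0, len(mito.sequence) - frag_len))
            div = k * 0.02  # 0..18% substitution divergence
            frag, _ = mutate_sequence(mito.sequence[m0 : m0 + frag_len], div, 5e-4, int(rng.integers(2**31)))
            pos = sep + k * chunk
            genome = implant(genome, frag, pos)
            implants.append((m0, pos, len(frag)))
        hsps = find_hsps(mito, SequenceRecord("chr1", genome), search_both_strands=False)
        assert len(hsps) == n_implants
        for (m0, pos, flen), h in zip(implants, sorted(hsps, key=lambda h: h.nuc_start)):
            qwin = (max(0, m0 - 200), min(len(mito.sequence), m0 + frag_len + 200))
            swin = (max(0, pos - 200), pos + flen + 200)
            o = sw_oracle(mito.sequence[qwin[0] : qwin[1]], genome[swin[0] : swin[1]])
            assert h.raw_score == o["score"]
            assert abs(h.mito_start - (qwin[0] + o["q"][0])) <= 5
            assert abs(h.mito_end - (qwin[0] + o["q"][1])) <= 5
            assert abs(h.nuc_start - (swin[0] + o["s"][0])) <= 5
            assert abs(h.nuc_end - (swin[0] + o["s"][1])) <= 5


class TestGlobalAlign:
    def test_identity_single_block(self):
        a = SequenceRecord("a", "ACGTACGTACGT")
        result = global_align(a, a)
        assert result.blocks == [((0, 12), (0, 12))]
        assert result.score == 2 * 12

    def test_single_insertion_two_blocks(self, rng):
        seq = random_sequence(60, rng)
        a = SequenceRecord("a", seq)
        b = SequenceRecord("b", seq[:10] + "TT" + seq[10:])
        result = global_align(a, b)
        assert len(result.blocks) == 2
        (a0, b0), (a1, b1) = result.blocks
        assert a0 == (0, 10) and b0 == (0, 10)
        assert a1 == (10, 60) and b1 == (12, 62)

    def test_score_matches_tiny_dp_oracle(self, rng):
        """Hand-written quadratic affine-gap NW agrees on random mutated
        pairs at <= 2% divergence."""
        for trial in range(6):
            seq = random_sequence(120, rng)
            mut, _ = mutate_sequence(seq, 0.02, 0.01, trial)
            got = global_align(SequenceRecord("a", seq), SequenceRecord("b", mut))
            assert got.score == _nw_oracle(seq, mut)

    def test_size_cap(self):
        a = SequenceRecord("a", "A" * 60_000)
        with pytest.raises(ValidationError, match="cap"):
            global_align(a, a)


def _nw_oracle(a: str, b: str) -> int:
    """Plain O(nm) global affine-gap DP (gap of length g costs 5 + 2g)."""
    NEG = -(10**9)
    n, m = len(a), len(b)
    go, ge = -7, -2  # first gapped base, extension
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        E[0][j] = go + ge * (j - 1)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = go + ge * (i - 1)
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            sub = 2 if a[i - 1] == b[j - 1] else -3
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    return H[n][m]
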