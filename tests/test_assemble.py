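"""Assembly tests: the merge rule's exact boundary behaviour, circular
D-loop chaining, and equivalence with a brute-force connected-components
oracle on random instances."""

import random

import networkx as nx
import pytest

from numtspipe import AssemblyParams, HSP, ValidationError, assemble_numts, assign_ids, mergeable

L = 16569
PARAMS = AssemblyParams(mito_length=L)


def make_hsp(nuc, mito, strand="+", chrom="chr1", identity=95.0):
    return HSP(
        chrom=chrom,
        nuc_start=nuc[0],
        nuc_end=nuc[1],
        strand=strand,
        mito_start=mito[0],
        mito_end=mito[1],
        percent_identity=identity,
        alignment_length=nuc[1] - nuc[0],
    )


class TestMergeable:
    def test_identical_hsp_merges_with_itself(self):
        h = make_hsp((100, 200), (300, 400))
        assert mergeable(h, h, PARAMS)

    def test_dloop_junction_spanning_pair_merges(self):
        # control region annotated as the tail of the linearised reference
        # followed by its head: circular gap across the origin is 0
        h1 = make_hsp((10_000, 10_546), (16_023, L))
        h2 = make_hsp((10_646, 11_222), (0, 576))
        assert mergeable(h1, h2, PARAMS)

    @pytest.mark.parametrize(
        "nuclear_gap,expected",
        [(2000, False), (1999, True), (-8, True)],
    )
    def test_nuclear_gap_boundary_is_strict(self, nuclear_gap, expected):
        h1 = make_hsp((1000, 2000), (100, 1100))
        h2 = make_hsp((2000 + nuclear_gap, 4500 + nuclear_gap), (1105, 2105))
        assert mergeable(h1, h2, PARAMS) is expected

    @pytest.mark.parametrize("mito_gap,expected", [(2000, True), (2001, False)])
    def test_mito_gap_boundary_is_inclusive(self, mito_gap, expected):
        h1 = make_hsp((1000, 2000), (100, 1100))
        h2 = make_hsp((2100, 3100), (1100 + mito_gap, 2100 + mito_gap))
        assert mergeable(h1, h2, PARAMS) is expected

    def test_overlapping_hsps_always_pass_gaps(self):
        # nuclear gap -8 (overlap) and small mito overlap both pass
        h1 = make_hsp((1000, 2000), (100, 1100))
        h2 = make_hsp((1992, 3000), (1095, 2100))
        assert mergeable(h1, h2, PARAMS)

    def test_opposite_strands_never_merge(self):
        h1 = make_hsp((1000, 2000), (100, 1100), "+")
        h2 = make_hsp((2100, 3100), (1150, 2150), "-")
        assert not mergeable(h1, h2, PARAMS)

    def test_minus_strand_gap_is_oriented(self):
        # on the minus strand successive nuclear blocks descend along the
        # mitochondrial coordinate
        h1 = make_hsp((1000, 2000), (5000, 6000), "-")
        h2 = make_hsp((2100, 3100), (3900, 4995), "-")
        assert mergeable(h1, h2, PARAMS)  # gap = 5000 - 4995 = 5
        h3 = make_hsp((2100, 3100), (7000, 8000), "-")
        # gap = 5000 - 8000 < 0 -> overlap passes
        assert mergeable(h1, h3, PARAMS)

    def test_different_chromosomes_is_contract_violation(self):
        h1 = make_hsp((0, 10), (0, 10), chrom="chr1")
        h2 = make_hsp((0, 10), (0, 10), chrom="chr2")
        with pytest.raises(ValidationError):
            mergeable(h1, h2, PARAMS)


def random_hsps(rng: random.Random, n: int):
    hsps = []
    for _ in range(n):
        nuc_start = rng.randrange(0, 60_000)
        nuc_len = rng.randrange(50, 3_000)
        mito_start = rng.randrange(0, L - 3_000)
        mito_len = rng.randrange(50, 3_000)
        hsps.append(
            make_hsp(
                (nuc_start, nuc_start + nuc_len),
                (mito_start, mito_start + mito_len),
                strand=rng.choice("+-"),
                chrom=rng.choice(["chr1", "chr2"]),
            )
        )
    return hsps


def oracle_partition(hsps, params):
    """Brute force: connected components of the full pairwise mergeable
    graph, per (chrom, strand), via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(len(hsps)))
    for a in range(len(hsps)):
        for b in range(len(hsps)):
            if a >= b:
                continue
            ha, hb = hsps[a], hsps[b]
            if ha.chrom != hb.chrom or ha.strand != hb.strand:
                continue
            first, second = (ha, hb) if ha.nuc_start <= hb.nuc_start else (hb, ha)
            if mergeable(first, second, params):
                g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestAssembleNumts:
    def test_empty_input(self):
        assert assemble_numts([], PARAMS) == []

    def test_single_hsp_is_singleton(self):
        h = make_hsp((100, 200), (300, 400))
        (n,) = assemble_numts([h], PARAMS)
        assert (n.nuc_start, n.nuc_end) == (100, 200)
        assert n.members == [h]
        assert not n.wraps_junction

    def test_ten_block_chain_assembles_into_one(self):
        # ten consecutive fragments interleaved with ~1.5 kb nuclear gaps,
        # advancing along the mitochondrial genome: one NumtS of ten blocks
        hsps = []
        for k in range(10):
            nuc0 = 10_000 + k * 2_000
            mito0 = 1_000 + k * 600
            hsps.append(make_hsp((nuc0, nuc0 + 500), (mito0, mito0 + 500)))
        (n,) = assemble_numts(hsps, PARAMS)
        assert n.n_members == 10
        assign_ids([n])
        assert n.members[0].hsp_id == f"{n.numts_id}_b1"
        assert n.members[9].hsp_id == f"{n.numts_id}_b10"

    def test_junction_spanning_chain_wraps(self):
        h1 = make_hsp((10_000, 10_546), (16_023, L))
        h2 = make_hsp((10_646, 11_222), (0, 576))
        (n,) = assemble_numts([h1, h2], PARAMS)
        assert n.wraps_junction
        assert (n.mito_start, n.mito_end) == (16_023, 576)

    def test_conservation_of_members(self):
        rng = random.Random(5)
        hsps = random_hsps(rng, 80)
        numts = assemble_numts(hsps, PARAMS)
        assert sum(n.n_members for n in numts) == len(hsps)
        for n in numts:
            assert len({(h.chrom, h.strand) for h in n.members}) == 1
            assert n.nuc_start == min(h.nuc_start for h in n.members)
            assert n.nuc_end == max(h.nuc_end for h in n.members)

    def test_input_order_invariance(self):
        rng = random.Random(11)
        hsps = random_hsps(rng, 40)
        ref = [(n.chrom, n.strand, n.nuc_start, n.n_members) for n in assemble_numts(hsps, PARAMS)]
        for seed in range(5):
            shuffled = hsps[:]
            random.Random(seed).shuffle(shuffled)
            got = [(n.chrom, n.strand, n.nuc_start, n.n_members) for n in assemble_numts(shuffled, PARAMS)]
            assert got == ref

    def test_idempotent_on_singleton_projection(self):
        rng = random.Random(21)
        numts = assemble_numts(random_hsps(rng, 30), PARAMS)
        again = assemble_numts([h for n in numts for h in n.members], PARAMS)
        assert [(n.chrom, n.strand, n.nuc_start, n.nuc_end, n.n_members) for n in numts] == [
            (n.chrom, n.strand, n.nuc_start, n.nuc_end, n.n_members) for n in again
        ]

    def test_partition_equals_connected_components_oracle(self):
        rng = random.Random(2024)
        for _ in range(30):
            hsps = random_hsps(rng, rng.randrange(2, 50))
            expected = oracle_partition(hsps, PARAMS)
            index = {id(h): k for k, h in enumerate(hsps)}
            got = {
                frozenset(index[id(h)] for h in n.members)
                for n in assemble_numts(hsps, PARAMS)
            }
            assert got == expected


class TestAssignIds:
    def test_first_id(self):
        n = assemble_numts([make_hsp((0, 10), (0, 10))], PARAMS)
        assign_ids(n)
        assert n[0].numts_id == "HSA_NumtS_001"
        assert n[0].members[0].hsp_id == "HSA_NumtS_001"  # no block suffix

    def test_block_suffix_format(self):
        hsps = [make_hsp((k * 1000, k * 1000 + 500), (k * 600, k * 600 + 500)) for k in range(5)]
        numts = assemble_numts(hsps, PARAMS)
        # pad with singletons on later coordinates so the chain is 14th
        extra = [
            make_hsp((100_000 + k * 10_000, 100_000 + k * 10_000 + 50), (9_000, 9_050))
            for k in range(13)
        ]
        all_numts = assemble_numts(hsps + extra, PARAMS)
        assign_ids(all_numts)
        chain = next(n for n in all_numts if n.n_members == 5)
        rank = all_numts.index(chain) + 1
        assert chain.members[4].hsp_id == f"HSA_NumtS_{rank:03d}_b5"

    def test_width_grows_past_999(self):
        numts = assemble_numts(
            [
                make_hsp((k * 4000, k * 4000 + 100), (500, 600))
                for k in range(1000)
            ],
            PARAMS,
        )
        assign_ids(numts)
        assert numts[0].numts_id == "HSA_NumtS_001"
        assert numts[-1].numts_id == "HSA_NumtS_1000"
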