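"""Block partitioning: CIT pair classification and candidate rule against a
brute-force oracle, FGR, SSLD spine enumeration, and the pan-consensus
profile."""

import itertools

import numpy as np
import pytest

from haploblocks import (Block, PairwiseLD, Partition, classify_pair_cit,
                         pan_consensus, partition_cit, partition_fgr,
                         partition_ssld)

from util import make_gm


def fake_ld(i, j, ci=None, dprime=None):
    ld = PairwiseLD(i=i, j=j, informative=True)
    if ci is not None:
        ld.ci_low, ld.ci_high = ci
    if dprime is not None:
        ld.Dprime = dprime
    return ld


class TestClassifyPairCit:
    @pytest.mark.parametrize("ci,expected", [
        ((0.71, 0.99), "strong_LD"),
        ((0.30, 0.85), "recombination"),
        ((0.50, 0.95), "uninformative"),
    ])
    def test_threshold_application(self, ci, expected):
        assert classify_pair_cit(fake_ld(0, 1, ci=ci)) == expected

    def test_noninformative_pair(self):
        assert classify_pair_cit(PairwiseLD(0, 1)) == "uninformative"


def cit_candidates_oracle(cls, m, min_frac=0.95):
    """Brute force: every interval whose outer pair is strong and whose
    informative-pair strong fraction meets the cutoff."""
    cands = []
    for i, j in itertools.combinations(range(m), 2):
        if cls.get((i, j)) != "strong_LD":
            continue
        pairs = [cls.get(p) for p in itertools.combinations(range(i, j + 1), 2)]
        s = pairs.count("strong_LD")
        r = pairs.count("recombination")
        if s + r and s / (s + r) >= min_frac:
            cands.append((i, j))
    return cands


class TestPartitionCit:
    def _run(self, cls, m):
        gm = make_gm([("0" * m, "1" * m), ("0" * m, "0" * m),
                      ("1" * m, "1" * m)],
                     positions=[1000 * (k + 1) for k in range(m)])
        ld = {}
        for (i, j), c in cls.items():
            ci = {"strong_LD": (0.8, 0.99), "recombination": (0.1, 0.5),
                  "uninformative": (0.5, 0.95)}[c]
            ld[(i, j)] = fake_ld(i, j, ci=ci)
        return partition_cit(gm, ld)

    def test_all_strong_single_block(self):
        cls = {p: "strong_LD" for p in itertools.combinations(range(3), 2)}
        part = self._run(cls, 3)
        assert [(b.first_idx, b.last_idx) for b in part.blocks] == [(0, 2)]

    def test_outer_recombination_rejects_candidate(self):
        cls = {(0, 1): "strong_LD", (1, 2): "strong_LD",
               (0, 2): "recombination"}
        part = self._run(cls, 3)
        assert all(b.n_markers == 2 for b in part.blocks)

    def test_against_enumeration_oracle(self, rng):
        m = 6
        for _ in range(50):
            cls = {}
            for i, j in itertools.combinations(range(m), 2):
                cls[(i, j)] = rng.choice(
                    ["strong_LD", "recombination", "uninformative"],
                    p=[0.6, 0.2, 0.2])
            part = self._run(cls, m)
            cands = cit_candidates_oracle(cls, m)
            # greedy by size then leftmost over the oracle's candidates
            expected = []
            for lo, hi in sorted(cands, key=lambda iv: (-(iv[1] - iv[0]), iv[0])):
                if all(hi < a or lo > b for a, b in expected):
                    expected.append((lo, hi))
            got = [(b.first_idx, b.last_idx) for b in part.blocks]
            assert got == sorted(expected)


class TestPartitionFgr:
    def test_three_gametes_no_break(self):
        # pool {00, 01, 10}: fourth gamete (11) absent -> one block
        pairs = [("00", "01")] * 25 + [("10", "00")] * 25 + [("01", "10")] * 10
        gm = make_gm(pairs)
        part = partition_fgr(gm)
        assert [(b.first_idx, b.last_idx) for b in part.blocks] == [(0, 1)]

    def test_fourth_gamete_above_cutoff_breaks(self):
        # all four gametes at >= 2% -> recombination between the markers
        pairs = ([("00", "00")] * 30 + [("11", "11")] * 30
                 + [("01", "01")] * 20 + [("10", "10")] * 20)
        gm = make_gm(pairs)
        part = partition_fgr(gm)
        assert part.blocks == []

    def test_rare_fourth_gamete_tolerated(self):
        # fourth gamete below the 1% cutoff -> still one block
        pairs = [("00", "00")] * 60 + [("11", "11")] * 39 + [("01", "00")] * 1
        gm = make_gm(pairs)
        assert len(partition_fgr(gm).blocks) == 1

    def test_compatible_pool_single_block_many_markers(self):
        pool = ["0000", "1000", "1100", "1110"]
        pairs = [(pool[i % 4], pool[(i + 1) % 4]) for i in range(40)]
        gm = make_gm(pairs)
        part = partition_fgr(gm)
        assert [(b.first_idx, b.last_idx) for b in part.blocks] == [(0, 3)]


class TestPartitionSsld:
    def _run(self, dprimes, m):
        gm = make_gm([("0" * m, "1" * m), ("0" * m, "0" * m),
                      ("1" * m, "1" * m)])
        ld = {p: fake_ld(*p, dprime=d) for p, d in dprimes.items()}
        return partition_ssld(gm, ld)

    def test_all_strong_one_block(self):
        d = {p: 0.9 for p in itertools.combinations(range(3), 2)}
        assert [(b.first_idx, b.last_idx)
                for b in self._run(d, 3).blocks] == [(0, 2)]

    def test_spine_tie_break_leftmost(self):
        d = {(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.9}
        # candidates {0,1} and {1,2} overlap; equal size -> leftmost wins
        assert [(b.first_idx, b.last_idx)
                for b in self._run(d, 3).blocks] == [(0, 1)]

    def test_no_strong_pairs_empty(self):
        d = {p: 0.5 for p in itertools.combinations(range(3), 2)}
        assert self._run(d, 3).blocks == []

    def test_backward_spine_found(self):
        # only the last marker anchors the interval: D'(0,2) and D'(1,2) high
        d = {(0, 1): 0.2, (0, 2): 0.9, (1, 2): 0.9}
        assert [(b.first_idx, b.last_idx)
                for b in self._run(d, 3).blocks] == [(0, 2)]


class TestPanConsensus:
    def _partition(self, k, gaps, m=15):
        """Partition with the given boundary gaps (list of (lo, hi) bp)."""
        region = (1000, 20_000)
        blocks = []
        cursor_pos, cursor_idx = region[0], 0
        for lo, hi in gaps:
            blocks.append(Block(cursor_idx, cursor_idx + 1, (cursor_pos, lo - 1)))
            cursor_pos, cursor_idx = hi + 1, cursor_idx + 2
        blocks.append(Block(cursor_idx, cursor_idx + 1, (cursor_pos, region[1])))
        return Partition(population=f"p{k}", method="SSLD", chrom="chr3",
                         region=region, blocks=blocks)

    def test_ten_of_fifteen_is_pan_boundary(self):
        gap = (5000, 5999)
        parts = [self._partition(k, [gap]) for k in range(10)]
        parts += [self._partition(k + 10, []) for k in range(5)]
        prof = pan_consensus(parts, threshold=10)
        assert prof.pan_boundaries == [gap]
        assert prof.support_at(5500) == 10

    def test_nine_of_fifteen_is_not(self):
        gap = (5000, 5999)
        parts = [self._partition(k, [gap]) for k in range(9)]
        parts += [self._partition(k + 9, []) for k in range(6)]
        prof = pan_consensus(parts, threshold=10)
        assert prof.pan_boundaries == []
        assert prof.pan_blocks == [prof.region]

    def test_support_capped_at_n_partitions(self):
        gap = (5000, 5999)
        parts = [self._partition(k, [gap]) for k in range(15)]
        prof = pan_consensus(parts, threshold=10)
        assert prof.max_support == 15 == prof.n_partitions

    def test_order_invariance(self, rng):
        gaps = [[(3000, 3500)], [(3000, 3999)], [], [(8000, 8999)]]
        parts = [self._partition(k, g) for k, g in enumerate(gaps * 3)]
        prof1 = pan_consensus(parts, threshold=4)
        order = rng.permutation(len(parts))
        prof2 = pan_consensus([parts[i] for i in order], threshold=4)
        assert prof1.segments == prof2.segments
        assert prof1.pan_boundaries == prof2.pan_boundaries

    def test_boundaries_and_blocks_tile_region(self):
        gaps = [[(3000, 3999)], [(3500, 4200)], [(9000, 9500)]]
        parts = [self._partition(k, g) for k, g in enumerate(gaps * 2)]
        prof = pan_consensus(parts, threshold=2)
        pieces = sorted(prof.pan_boundaries + prof.pan_blocks)
        cursor = prof.region[0]
        for s, e in pieces:
            assert s == cursor
            cursor = e + 1
        assert cursor == prof.region[1] + 1

    def test_mismatched_regions_error(self):
        p1 = self._partition(0, [])
        p2 = self._partition(1, [])
        p2.region = (1, 999)
        with pytest.raises(ValueError, match="mismatch"):
            pan_consensus([p1, p2])
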