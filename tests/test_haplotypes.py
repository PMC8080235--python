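"""Haplotype extraction, classification symmetry, minimal tag-SNV search
against the subset-enumeration oracle, phaser concordance, and the
window EM against an exhaustive likelihood oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from haploblocks import (SampleTable, classify_haplotype, em_window_phase,
                         extract_haplotypes, min_tag_snvs, phase_concordance)
import pandas as pd

from util import make_gm, min_tag_oracle


def sample_table(ids, status="control", population="NFE"):
    return SampleTable(pd.DataFrame({
        "sample_id": ids,
        "status": [status] * len(ids),
        "sex": ["female"] * len(ids),
        "population": [population] * len(ids),
    }))


class TestClassifyHaplotype:
    @pytest.mark.parametrize("s,expected", [
        ("0000000", "major"),
        ("1000000", "Q-major"),
        ("1110100", "mosaic"),
        ("0111111", "Q-minor"),
        ("1111111", "minor"),
    ])
    def test_minor_count_rule(self, s, expected):
        assert classify_haplotype(s) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classify_haplotype("000", "00")

    # L = 2 is degenerate (one minor allele is both "all but one major" and
    # "all but one minor"); the symmetry holds from L = 3 up
    @given(st.text(alphabet="01", min_size=3, max_size=12))
    def test_symmetric_under_global_relabeling(self, s):
        flipped = "".join("1" if c == "0" else "0" for c in s)
        swap = {"major": "minor", "minor": "major", "Q-major": "Q-minor",
                "Q-minor": "Q-major", "mosaic": "mosaic"}
        assert classify_haplotype(flipped) == swap[classify_haplotype(s)]


class TestExtractHaplotypes:
    def test_all_major_homozygote(self):
        gm = make_gm([("0000000", "0000000"), ("1111111", "0000000")])
        st_ = sample_table(gm.samples)
        catalog, diplos = extract_haplotypes(gm, [v.vid for v in gm.variants],
                                             st_)
        d0 = next(d for d in diplos if d.sample_id == "s0")
        assert d0.homozygous
        assert catalog.entry(d0.pair[0]).hap_class == "major"

    def test_catalog_bounded_by_haplotype_space(self):
        rng = np.random.default_rng(5)
        haps = ["".join(rng.choice(["0", "1"], 7)) for _ in range(600)]
        pairs = list(zip(haps[::2], haps[1::2]))
        gm = make_gm(pairs)
        st_ = sample_table(gm.samples)
        catalog, _ = extract_haplotypes(gm, [v.vid for v in gm.variants], st_)
        assert len(catalog.entries) <= 2 ** 7 == 128

    def test_pooled_frequency_labels_deterministic_across_cohorts(self):
        # same haplotypes, different per-cohort frequencies
        pairs = ([("000", "000")] * 6 + [("111", "111")] * 4
                 + [("000", "111")] * 2)
        gm = make_gm(pairs)
        ids = gm.samples
        st_ = SampleTable(pd.DataFrame({
            "sample_id": ids,
            "status": ["control"] * len(ids),
            "sex": ["female"] * len(ids),
            "population": ["A"] * 6 + ["B"] * 6,
        }))
        c1, _ = extract_haplotypes(gm, [v.vid for v in gm.variants], st_)
        c2, _ = extract_haplotypes(gm, [v.vid for v in gm.variants], st_)
        assert [e.allele_string for e in c1.entries] == \
               [e.allele_string for e in c2.entries]
        assert c1.entries[0].label == "Hap1"
        assert c1.entries[0].pooled_count >= c1.entries[1].pooled_count

    def test_frequencies_sum_to_one_per_cohort(self):
        rng = np.random.default_rng(11)
        haps = ["".join(rng.choice(["0", "1"], 5)) for _ in range(200)]
        gm = make_gm(list(zip(haps[::2], haps[1::2])))
        st_ = sample_table(gm.samples)
        catalog, diplos = extract_haplotypes(gm,
                                             [v.vid for v in gm.variants], st_)
        total = sum(e.frequencies.get("NFE", 0) for e in catalog.entries)
        assert total == pytest.approx(1.0, abs=1e-12)
        n_chrom = sum(e.counts.get("NFE", 0) for e in catalog.entries)
        assert n_chrom == 2 * len(diplos)

    def test_missing_target_snv_named(self):
        gm = make_gm([("00", "00")])
        with pytest.raises(KeyError, match="rs99"):
            extract_haplotypes(gm, ["rs1", "rs99"], sample_table(gm.samples))

    def test_unphased_sample_dropped(self):
        gm = make_gm([("01", "10"), ("00", "00")])
        gm.phased[0, :] = False  # het sample unphased -> dropped
        _, diplos = extract_haplotypes(gm, ["rs1", "rs2"],
                                       sample_table(gm.samples))
        assert [d.sample_id for d in diplos] == ["s1"]


class TestMinTagSnvs:
    def test_small_example_unique_set(self):
        res = min_tag_snvs(["000", "001", "011"])
        assert res["k"] == 2 and res["sets"] == [(1, 2)]

    def test_yin_yang_pair_any_position(self):
        res = min_tag_snvs(["0000", "1111"])
        assert res["k"] == 1
        assert res["sets"] == [(0,), (1,), (2,), (3,)]

    def test_full_space_needs_all_positions(self):
        entries = ["".join(bits) for bits in
                   itertools.product("01", repeat=4)]
        assert min_tag_snvs(entries)["k"] == 4

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            min_tag_snvs(["01", "01"])

    def test_redundant_groups_detected(self):
        # positions 0 and 2 identical, 1 complementary to 3
        entries = ["0000", "0101", "1011"]
        groups = min_tag_snvs(entries)["redundant_groups"]
        assert (0, 2) in groups or any(set(g) >= {0, 2} for g in groups)

    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 8))
        n = int(rng.integers(2, min(10, 2 ** L) + 1))
        space = ["".join(bits) for bits in itertools.product("01", repeat=L)]
        entries = list(rng.choice(space, size=n, replace=False))
        res = min_tag_snvs(entries)
        k_or, sets_or = min_tag_oracle(entries)
        assert res["k"] == k_or and res["sets"] == sets_or


class TestPhaseConcordance:
    CALLS = {"s1": ("0000000", "1111111")}

    def test_three_identical_accepted(self):
        out = phase_concordance({"beagle": self.CALLS, "shapeit": self.CALLS,
                                 "whatshap": self.CALLS})
        assert out["s1"]["accepted"] and out["s1"]["n_agree"] == 3

    def test_two_of_three_majority(self):
        other = {"s1": ("0000000", "1111110")}
        out = phase_concordance({"beagle": self.CALLS, "shapeit": self.CALLS,
                                 "whatshap": other})
        assert out["s1"]["accepted"]
        assert out["s1"]["diplotype"] == tuple(sorted(self.CALLS["s1"]))

    def test_three_way_disagreement_discarded(self):
        out = phase_concordance({
            "beagle": {"s1": ("0000000", "1111111")},
            "shapeit": {"s1": ("0000000", "1111110")},
            "whatshap": {"s1": ("0000001", "1111111")},
        })
        assert not out["s1"]["accepted"]

    def test_unordered_pair_comparison(self):
        flipped = {"s1": ("1111111", "0000000")}
        out = phase_concordance({"beagle": self.CALLS, "shapeit": flipped})
        assert out["s1"]["accepted"]

    def test_single_phaser_errors(self):
        with pytest.raises(ValueError):
            phase_concordance({"beagle": self.CALLS})


class TestEmWindowPhase:
    def test_homozygous_everywhere_exact(self):
        g = np.array([[0, 0, 0], [2, 2, 2], [0, 0, 0]])
        res = em_window_phase(g)
        assert res["frequencies"]["000"] == pytest.approx(2 / 3)
        assert res["frequencies"]["111"] == pytest.approx(1 / 3)
        assert not any(res["ambiguous"])

    def test_single_het_site_exact(self):
        g = np.array([[1, 0], [0, 0], [2, 0]])
        res = em_window_phase(g)
        assert res["frequencies"]["00"] == pytest.approx(3 / 6)
        assert res["frequencies"]["10"] == pytest.approx(3 / 6)

    def test_matches_exhaustive_oracle_k3(self):
        rng = np.random.default_rng(3)
        true = {"000": 0.5, "111": 0.3, "100": 0.2}
        haps = list(true)
        draws = rng.choice(len(haps), size=(120, 2), p=list(true.values()))
        g = np.array([[int(haps[a][p]) + int(haps[b][p]) for p in range(3)]
                      for a, b in draws])
        res = em_window_phase(g)

        # oracle: direct likelihood maximization over the 8-simplex
        from scipy.optimize import minimize

        def pair_lists(row):
            return [(h1, h2) for h1 in haps8 for h2 in haps8 if h1 <= h2
                    and all(int(h1[p]) + int(h2[p]) == row[p]
                            for p in range(3))]

        haps8 = ["".join(b) for b in itertools.product("01", repeat=3)]
        plists = [pair_lists(row) for row in g]

        def negll(x):
            w = np.exp(x - x.max())
            f = dict(zip(haps8, w / w.sum()))
            ll = 0.0
            for pl in plists:
                tot = sum(f[a] * f[b] * (1 if a == b else 2) for a, b in pl)
                ll += np.log(max(tot, 1e-300))
            return -ll

        best = None
        for s in range(5):
            r = minimize(negll, np.random.default_rng(s).normal(size=8),
                         method="Nelder-Mead",
                         options={"maxiter": 5000, "fatol": 1e-12})
            if best is None or r.fun < best.fun:
                best = r
        w = np.exp(best.x - best.x.max())
        oracle = dict(zip(haps8, w / w.sum()))
        for h in haps8:
            assert res["frequencies"].get(h, 0.0) == pytest.approx(
                oracle[h], abs=1e-3)

    def test_window_too_wide_errors(self):
        with pytest.raises(ValueError, match="external"):
            em_window_phase(np.zeros((2, 13), dtype=int))
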