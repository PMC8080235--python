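"""Shared helpers for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from haploblocks import GenotypeMatrix
from haploblocks.io_formats import _variant_from_alt_freq


def make_gm(hap_pairs, positions=None, chrom="chr3", phased=True,
            vid_prefix="rs"):
    """GenotypeMatrix from per-sample haplotype string pairs over {0,1}."""
    n = len(hap_pairs)
    L = len(hap_pairs[0][0])
    if positions is None:
        positions = [1000 * (k + 1) for k in range(L)]
    alleles = np.empty((n, L, 2), dtype=np.int8)
    for s, (h0, h1) in enumerate(hap_pairs):
        alleles[s, :, 0] = [int(c) for c in h0]
        alleles[s, :, 1] = [int(c) for c in h1]
    ph = np.full((n, L), bool(phased))
    variants = []
    for j in range(L):
        alt_freq = float(alleles[:, j, :].mean())
        variants.append(_variant_from_alt_freq(chrom, positions[j],
                                               f"{vid_prefix}{j + 1}",
                                               "A", "G", alt_freq))
    return GenotypeMatrix(variants, [f"s{k}" for k in range(n)], alleles, ph)


def fisher_two_sided_oracle(a, b, c, d):
    """Independent Fisher oracle: full hypergeometric enumeration over all
    tables with the observed margins, probability-mass two-sided rule."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    probs = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def min_tag_oracle(entries):
    """Independent minimal-tagging oracle using bitmask column signatures."""
    L = len(entries[0])
    n = len(entries)
    best_k, best_sets = None, []
    for k in range(1, L + 1):
        for subset in combinations(range(L), k):
            keys = {tuple(e[p] for p in subset) for e in entries}
            if len(keys) == n:
                best_sets.append(subset)
        if best_sets:
            best_k = k
            break
    return best_k, best_sets
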