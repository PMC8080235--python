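"""Haplotype-block partitioning and cross-partition consensus.

Three partitioning rules, run per population:

* **CIT** — the confidence-interval (Gabriel-style) test: pairs are classed
  as strong LD / historical recombination / uninformative from the D'
  confidence bounds, and a block is an interval whose outermost pair is in
  strong LD and in which at least 95% of informative pairs are strong.
* **FGR** — the four-gamete rule: recombination is inferred between two
  markers when all four gametes are observed (each above a frequency
  cutoff); blocks are maximal runs with no internal recombinant pair.
* **SSLD** — the solid spine of LD: a block is an interval whose first (or
  last) marker is in strong D' with every other marker in the interval.

Boundary intervals between consecutive inferred blocks are accumulated
per base across all (population x method) partitions; runs of positions
supported by at least ``threshold`` partitions (10 of 15 for five
populations and three methods) are the pan-boundaries, and the intervals
between them are the pan-blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import GenotypeMatrix
from .ld import PairwiseLD, em_two_locus, genotype_table_3x3, two_locus_counts_phased

# CIT defaults (Gabriel-style)
CIT_STRONG_LOW = 0.70
CIT_STRONG_HIGH = 0.98
CIT_RECOMB_HIGH = 0.90
CIT_MIN_STRONG_FRACTION = 0.95
# FGR / SSLD defaults
FGR_FOURTH_GAMETE_MIN = 0.01
SSLD_SPINE_DPRIME = 0.80
# consensus default: >= 10 of the 15 (population x method) partitions
CONSENSUS_THRESHOLD = 10


@dataclass(frozen=True)
class Block:
    """A marker interval [first_idx, last_idx] (inclusive) with its genomic
    span in 1-based inclusive coordinates."""

    first_idx: int
    last_idx: int
    span: tuple[int, int]

    def __post_init__(self):
        if self.first_idx >= self.last_idx:
            raise ValueError("a block needs at least two markers")

    @property
    def n_markers(self) -> int:
        return self.last_idx - self.first_idx + 1


@dataclass
class Partition:
    """Ordered, non-overlapping blocks from one (population, method) run."""

    population: str
    method: str  # SSLD | CIT | FGR
    chrom: str
    region: tuple[int, int]  # analyzed span, 1-based inclusive
    blocks: list[Block] = field(default_factory=list)

    def validate(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.first_idx <= a.last_idx:
                raise ValueError(
                    f"overlapping blocks {a} / {b} in {self.population}.{self.method}"
                )

    def boundary_intervals(self) -> list[tuple[int, int]]:
        """Gaps between consecutive block spans, 1-based inclusive.  Region
        flanks are not boundaries (only inter-block gaps count)."""
        self.validate()
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            lo, hi = a.span[1] + 1, b.span[0] - 1
            if lo <= hi:
                out.append((lo, hi))
        return out


@dataclass
class ConsensusProfile:
    """Per-base boundary support across partitions and the derived
    pan-boundaries / pan-blocks."""

    chrom: str
    region: tuple[int, int]
    n_partitions: int
    threshold: int
    # step function: segments [(start, end, support)] tiling the region
    segments: list[tuple[int, int, int]]
    pan_boundaries: list[tuple[int, int]]
    pan_blocks: list[tuple[int, int]]

    @property
    def max_support(self) -> int:
        return max((s for _, _, s in self.segments), default=0)

    def support_at(self, pos: int) -> int:
        for s, e, sup in self.segments:
            if s <= pos <= e:
                return sup
        raise ValueError(f"position {pos} outside region {self.region}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.segments, columns=["start", "end", "support"])


def classify_pair_cit(ld: PairwiseLD,
                      strong_low: float = CIT_STRONG_LOW,
                      strong_high: float = CIT_STRONG_HIGH,
                      recomb_high: float = CIT_RECOMB_HIGH) -> str:
    """Classify one pair from its D' confidence bounds: ``strong_LD`` if
    ci_low >= strong_low and ci_high >= strong_high; ``recombination`` if
    ci_high < recomb_high; else ``uninformative``."""
    if not ld.informative or not np.isfinite(ld.ci_low):
        return "uninformative"
    if ld.ci_low >= strong_low and ld.ci_high >= strong_high:
        return "strong_LD"
    if ld.ci_high < recomb_high:
        return "recombination"
    return "uninformative"


def _greedy_non_overlapping(candidates: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Resolve overlapping candidate intervals greedily: descending marker
    count, ties to the leftmost start; keep only candidates disjoint from
    all previously kept ones."""
    order = sorted(candidates, key=lambda iv: (-(iv[1] - iv[0]), iv[0]))
    kept: list[tuple[int, int]] = []
    for lo, hi in order:
        if all(hi < k_lo or lo > k_hi for k_lo, k_hi in kept):
            kept.append((lo, hi))
    return sorted(kept)


def _mk_partition(gm: GenotypeMatrix, population: str, method: str,
                  intervals: list[tuple[int, int]]) -> Partition:
    chrom, start, end = gm.region
    blocks = [Block(lo, hi, (gm.variants[lo].pos, gm.variants[hi].pos))
              for lo, hi in intervals]
    return Partition(population=population, method=method, chrom=chrom,
                     region=(start, end), blocks=blocks)


def partition_cit(gm: GenotypeMatrix,
                  ld_matrix: dict[tuple[int, int], PairwiseLD],
                  population: str = "pop",
                  strong_low: float = CIT_STRONG_LOW,
                  strong_high: float = CIT_STRONG_HIGH,
                  recomb_high: float = CIT_RECOMB_HIGH,
                  min_strong_fraction: float = CIT_MIN_STRONG_FRACTION) -> Partition:
    """Confidence-interval-test blocks.

    A candidate is a marker interval whose outermost pair is strong LD and
    in which strong pairs make up at least ``min_strong_fraction`` of the
    informative (strong + recombination) pairs; overlaps are resolved
    greedily by descending size then leftmost start.
    """
    m = gm.n_variants
    cls: dict[tuple[int, int], str] = {
        key: classify_pair_cit(ld, strong_low, strong_high, recomb_high)
        for key, ld in ld_matrix.items()
    }
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if cls.get((i, j), "uninformative") != "strong_LD":
                continue
            n_strong = n_recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    c = cls.get((a, b))
                    if c == "strong_LD":
                        n_strong += 1
                    elif c == "recombination":
                        n_recomb += 1
            if n_strong + n_recomb == 0:
                continue
            if n_strong / (n_strong + n_recomb) >= min_strong_fraction:
                candidates.append((i, j))
    return _mk_partition(gm, population, "CIT",
                         _greedy_non_overlapping(candidates))


def _gamete_freqs(gm: GenotypeMatrix, i: int, j: int) -> Optional[np.ndarray]:
    """Gamete frequencies for (i, j): phased counts when available, else
    EM-expected frequencies from the unphased genotype table."""
    c = two_locus_counts_phased(gm, i, j)
    if c.n > 0:
        return c.freqs()
    table = genotype_table_3x3(gm, i, j)
    if table.sum() == 0:
        return None
    p, _ = em_two_locus(table)
    return p


def partition_fgr(gm: GenotypeMatrix, population: str = "pop",
                  fourth_gamete_min: float = FGR_FOURTH_GAMETE_MIN,
                  max_distance: int = 500_000) -> Partition:
    """Four-gamete-rule blocks: a pair shows recombination iff all four
    gametes reach frequency >= ``fourth_gamete_min``; blocks are maximal
    intervals with no internal recombinant pair, emitted left to right."""
    m = gm.n_variants
    recomb = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            if gm.variants[j].pos - gm.variants[i].pos > max_distance:
                break
            p = _gamete_freqs(gm, i, j)
            if p is not None and np.all(p >= fourth_gamete_min):
                recomb[i, j] = True
    intervals = []
    i = 0
    while i < m - 1:
        j = i
        while j + 1 < m and not recomb[i:j + 2, i:j + 2].any():
            j += 1
        if j > i:
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return _mk_partition(gm, population, "FGR", intervals)


def partition_ssld(gm: GenotypeMatrix,
                   ld_matrix: dict[tuple[int, int], PairwiseLD],
                   population: str = "pop",
                   spine_dprime: float = SSLD_SPINE_DPRIME) -> Partition:
    """Solid-spine-of-LD blocks: maximal intervals whose first or last
    marker is in strong D' (>= ``spine_dprime``) with every other marker in
    the interval; overlaps resolved greedily by size then leftmost."""
    m = gm.n_variants

    def strong(a: int, b: int) -> bool:
        ld = ld_matrix.get((min(a, b), max(a, b)))
        return (ld is not None and ld.informative
                and np.isfinite(ld.Dprime) and ld.Dprime >= spine_dprime)

    candidates = set()
    for i in range(m):  # forward spine from i
        j = i
        while j + 1 < m and strong(i, j + 1):
            j += 1
        if j > i:
            candidates.add((i, j))
    for j in range(m):  # backward spine from j
        i = j
        while i - 1 >= 0 and strong(i - 1, j):
            i -= 1
        if j > i:
            candidates.add((i, j))
    # keep only maximal candidates (not contained in another candidate)
    maximal = [c for c in candidates
               if not any(o != c and o[0] <= c[0] and c[1] <= o[1]
                          for o in candidates)]
    return _mk_partition(gm, population, "SSLD",
                         _greedy_non_overlapping(maximal))


def pan_consensus(partitions: Sequence[Partition],
                  threshold: int = CONSENSUS_THRESHOLD) -> ConsensusProfile:
    """Aggregate boundary intervals across partitions into a per-base
    support profile; maximal runs with support >= ``threshold`` are the
    pan-boundaries and the intervals between them the pan-blocks."""
    if not partitions:
        raise ValueError("no partitions")
    regions = {(p.chrom, p.region) for p in partitions}
    if len(regions) > 1:
        raise ValueError(f"partitions cover mismatched regions: {regions}")
    chrom, (start, end) = next(iter(regions))

    # sweep over interval endpoints to build the support step function
    events: dict[int, int] = {}
    for p in partitions:
        for lo, hi in p.boundary_intervals():
            lo, hi = max(lo, start), min(hi, end)
            if lo > hi:
                continue
            events[lo] = events.get(lo, 0) + 1
            events[hi + 1] = events.get(hi + 1, 0) - 1
    cuts = sorted(set([start, end + 1]) | set(events))
    cuts = [c for c in cuts if start <= c <= end + 1]
    segments: list[tuple[int, int, int]] = []
    support = 0
    for a, b in zip(cuts, cuts[1:]):
        support += events.get(a, 0)
        if a <= end:
            segments.append((a, min(b - 1, end), support))
    # merge equal-support neighbours
    merged: list[tuple[int, int, int]] = []
    for seg in segments:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] + 1 == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(list(seg))  # type: ignore[arg-type]
    merged = [tuple(s) for s in merged]

    # maximal runs of support >= threshold (coalesce adjacent segments)
    pan_boundaries: list[tuple[int, int]] = []
    for s, e, sup in merged:
        if sup < threshold:
            continue
        if pan_boundaries and pan_boundaries[-1][1] + 1 == s:
            pan_boundaries[-1] = (pan_boundaries[-1][0], e)
        else:
            pan_boundaries.append((s, e))
    pan_blocks = []
    cursor = start
    for s, e in pan_boundaries:
        if cursor <= s - 1:
            pan_blocks.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= end:
        pan_blocks.append((cursor, end))

    return ConsensusProfile(chrom=chrom, region=(start, end),
                            n_partitions=len(partitions), threshold=threshold,
                            segments=merged, pan_boundaries=pan_boundaries,
                            pan_blocks=pan_blocks)
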