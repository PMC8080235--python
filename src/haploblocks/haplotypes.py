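"""Haplotype extraction, cataloging, classification, tagging, phasing.

Haplotypes over a chosen SNV set (e.g. the seven SNVs of a focal block)
are read directly off phase.  Allele strings use '0' for the major and '1'
for the minor allele at each position, so the all-major haplotype is
``"0" * L`` and its complementary ("yin-yang") partner ``"1" * L``.

Catalog labels Hap1, Hap2, ... are assigned by descending pooled frequency
across all cohorts, ties broken by lexicographic allele string — a
deterministic rule (the all-major haplotype is *not* hard-coded to Hap1;
it simply tends to be the most frequent one in European-ancestry data).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SampleTable, VariantInfo

logger = logging.getLogger("haploblocks")

# per-chromosome haplotype frequency cutoffs for the abundance classes
ABUNDANCE_COMMON = 0.05   # frequency > 5% -> common
ABUNDANCE_RARE = 0.01     # frequency < 1% -> rare

CLASSES = ("major", "Q-major", "mosaic", "Q-minor", "minor")

EM_PHASE_TOL = 1e-8
EM_PHASE_MAX_ITER = 2000
EM_PHASE_MAX_SNVS = 12


@dataclass
class CatalogEntry:
    label: str
    allele_string: str
    counts: dict[str, int]        # cohort -> chromosome count
    frequencies: dict[str, float]  # cohort -> per-chromosome frequency
    hap_class: str
    abundance_class: dict[str, str]  # cohort -> common/intermediate/rare

    @property
    def pooled_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class HaplotypeCatalog:
    snvs: list[VariantInfo]
    entries: list[CatalogEntry]

    def entry(self, label: str) -> CatalogEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def label_of(self, allele_string: str) -> str:
        for e in self.entries:
            if e.allele_string == allele_string:
                return e.label
        raise KeyError(allele_string)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        cohorts = sorted({c for e in self.entries for c in e.counts})
        rows = []
        for e in self.entries:
            row = {"label": e.label, "allele_string": e.allele_string,
                   "class": e.hap_class}
            for c in cohorts:
                row[f"count_{c}"] = e.counts.get(c, 0)
                row[f"freq_{c}"] = e.frequencies.get(c, 0.0)
                row[f"abundance_{c}"] = e.abundance_class.get(c, "absent")
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Diplotype:
    sample_id: str
    pair: tuple[str, str]  # unordered; stored sorted by label

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]

    @property
    def name(self) -> str:
        a, b = self.pair
        return f"{a}/{b}"


def classify_haplotype(allele_string: str, major_string: Optional[str] = None) -> str:
    """Class by the count m of minor alleles out of L positions: m=0 major,
    m=1 Q-major, m=L minor, m=L-1 Q-minor, otherwise mosaic.  (For the
    degenerate L=2, m=1 case the Q-major rule takes precedence.)"""
    if major_string is None:
        major_string = "0" * len(allele_string)
    if len(allele_string) != len(major_string):
        raise ValueError("allele_string and major_string lengths differ")
    L = len(allele_string)
    m = sum(a != b for a, b in zip(allele_string, major_string))
    if m == 0:
        return "major"
    if m == 1:
        return "Q-major"
    if m == L:
        return "minor"
    if m == L - 1:
        return "Q-minor"
    return "mosaic"


def _abundance(freq: float) -> str:
    if freq > ABUNDANCE_COMMON:
        return "common"
    if freq < ABUNDANCE_RARE:
        return "rare"
    return "intermediate"


def sample_haplotype_strings(gm: GenotypeMatrix, snv_idx: Sequence[int]
                             ) -> tuple[list[str], np.ndarray]:
    """Per-sample pair of major/minor haplotype strings at ``snv_idx``.

    Returns (kept_sample_ids, strings) where strings is an (n_kept, 2)
    object array; samples with any missing or unphased target genotype are
    dropped (count logged).
    """
    maj = np.array([gm.variants[i].major_index for i in snv_idx])
    sub = gm.alleles[:, snv_idx, :]           # samples x L x 2
    ph = gm.phased[:, snv_idx]                # samples x L
    complete = (sub >= 0).all(axis=(1, 2))
    het = sub[:, :, 0] != sub[:, :, 1]
    # phase only matters at heterozygous sites
    phase_ok = (ph | ~het).all(axis=1)
    keep = complete & phase_ok
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d samples with missing/unphased target SNVs",
                    n_drop)
    kept_ids = [s for s, k in zip(gm.samples, keep) if k]
    symbols = (sub[keep] != maj[None, :, None]).astype(np.uint8)  # 1 = minor
    strings = np.empty((len(kept_ids), 2), dtype=object)
    for r in range(symbols.shape[0]):
        strings[r, 0] = "".join(map(str, symbols[r, :, 0]))
        strings[r, 1] = "".join(map(str, symbols[r, :, 1]))
    return kept_ids, strings


def extract_haplotypes(gm: GenotypeMatrix, snv_ids: Sequence[str],
                       samples: SampleTable,
                       cohort_by: str = "population"
                       ) -> tuple[HaplotypeCatalog, list[Diplotype]]:
    """Build the haplotype catalog over ``snv_ids`` and per-sample
    diplotypes, grouped into cohorts by the ``cohort_by`` column of the
    sample table ('population' or 'status')."""
    try:
        snv_idx = [gm.variant_index(v) for v in snv_ids]
    except KeyError as exc:
        raise KeyError(f"target SNV {exc.args[0]!r} absent from genotypes") from exc
    if cohort_by not in ("population", "status"):
        raise ValueError("cohort_by must be 'population' or 'status'")
    cohort_of = dict(zip(samples.table["sample_id"],
                         samples.table[cohort_by]))
    kept_ids, strings = sample_haplotype_strings(gm, snv_idx)

    counts: dict[str, dict[str, int]] = {}
    per_sample: dict[str, tuple[str, str]] = {}
    for sid, (h0, h1) in zip(kept_ids, strings):
        if sid in cohort_of:
            per_sample[sid] = (h0, h1)
    for sid, (h0, h1) in per_sample.items():
        cohort = cohort_of[sid]
        for h in (h0, h1):
            counts.setdefault(h, {}).setdefault(cohort, 0)
            counts[h][cohort] += 1
    if not counts:
        raise ValueError("no samples usable for haplotype extraction")

    cohort_totals: dict[str, int] = {}
    for per in counts.values():
        for c, n in per.items():
            cohort_totals[c] = cohort_totals.get(c, 0) + n

    ordered = sorted(counts, key=lambda h: (-sum(counts[h].values()), h))
    L = len(snv_idx)
    entries = []
    for k, h in enumerate(ordered, 1):
        freqs = {c: counts[h].get(c, 0) / cohort_totals[c]
                 for c in cohort_totals if counts[h].get(c, 0) > 0}
        entries.append(CatalogEntry(
            label=f"Hap{k}", allele_string=h,
            counts=dict(counts[h]), frequencies=freqs,
            hap_class=classify_haplotype(h, "0" * L),
            abundance_class={c: _abundance(f) for c, f in freqs.items()},
        ))
    catalog = HaplotypeCatalog(snvs=[gm.variants[i] for i in snv_idx],
                               entries=entries)
    label = {e.allele_string: e.label for e in entries}
    diplotypes = [
        Diplotype(sample_id=sid,
                  pair=tuple(sorted((label[h0], label[h1]),
                                    key=_label_key)))
        for sid, (h0, h1) in per_sample.items()
    ]
    return catalog, diplotypes


def _label_key(label: str) -> tuple[int, str]:
    if label.startswith("Hap") and label[3:].isdigit():
        return (int(label[3:]), "")
    return (10 ** 9, label)


def min_tag_snvs(entries: Sequence[str]) -> dict:
    """Exhaustive minimal tag-SNV search.

    Finds the minimal cardinality k and every size-k subset of positions
    whose restriction keeps all ``entries`` pairwise distinct (the
    haplotype tag SNVs), plus a redundancy report: positions whose allele
    column, up to global complementation, duplicates another position's —
    such positions carry identical distinguishing information.

    Returns {"k": int, "sets": [tuple[int, ...]], "redundant_groups":
    [tuple[int, ...]]} with 0-based position indices.
    """
    entries = list(entries)
    if len(set(entries)) != len(entries):
        raise ValueError("duplicate haplotype entries are not distinguishable")
    if len(entries) < 2:
        raise ValueError("need at least two entries")
    L = len(entries[0])
    if any(len(e) != L for e in entries):
        raise ValueError("entries have unequal lengths")
    if L > 20:
        raise ValueError("exhaustive search limited to 20 positions")

    def distinguishes(subset: tuple[int, ...]) -> bool:
        seen = set()
        for e in entries:
            key = tuple(e[p] for p in subset)
            if key in seen:
                return False
            seen.add(key)
        return True

    result_sets: list[tuple[int, ...]] = []
    k = None
    for size in range(1, L + 1):
        hits = [s for s in itertools.combinations(range(L), size)
                if distinguishes(s)]
        if hits:
            k, result_sets = size, hits
            break
    assert k is not None  # size == L always distinguishes distinct entries

    # redundancy: group positions by column pattern up to complement
    groups: dict[tuple[str, ...], list[int]] = {}
    for p in range(L):
        col = tuple(e[p] for e in entries)
        comp = tuple("1" if c == "0" else "0" for c in col)
        key = min(col, comp)
        groups.setdefault(key, []).append(p)
    redundant_groups = [tuple(g) for g in groups.values() if len(g) > 1]
    return {"k": k, "sets": result_sets,
            "redundant_groups": sorted(redundant_groups)}


def phase_concordance(phasings: Mapping[str, Mapping[str, tuple[str, str]]]
                      ) -> dict[str, dict]:
    """Cross-phaser concordance rule.

    ``phasings`` maps phaser name -> {sample_id -> unordered haplotype
    string pair}.  A sample is accepted iff at least two phasers agree
    exactly on its diplotype (compared as an unordered pair); the consensus
    is the majority call.  Samples with no majority are discarded with a
    reason.
    """
    if len(phasings) < 2:
        raise ValueError("need at least two phasings to assess concordance")
    sample_ids = sorted(set().union(*[set(p) for p in phasings.values()]))
    out: dict[str, dict] = {}
    for sid in sample_ids:
        calls = [tuple(sorted(p[sid])) for p in phasings.values() if sid in p]
        if len(calls) < 2:
            out[sid] = {"accepted": False, "reason": "fewer than two calls"}
            continue
        best, best_n = None, 0
        for c in set(calls):
            n = calls.count(c)
            if n > best_n:
                best, best_n = c, n
        if best_n >= 2:
            out[sid] = {"accepted": True, "diplotype": best,
                        "n_agree": best_n, "n_calls": len(calls)}
        else:
            out[sid] = {"accepted": False,
                        "reason": "no two phasers agree"}
    return out


def em_window_phase(genotypes: np.ndarray, tol: float = EM_PHASE_TOL,
                    max_iter: int = EM_PHASE_MAX_ITER) -> dict:
    """Multi-locus haplotype-frequency EM (Excoffier–Slatkin style) over a
    small window of unphased genotypes, with per-sample maximum-posterior
    diplotypes.

    ``genotypes`` is (n_samples, k) with entries 0/1/2 counting minor
    alleles (k <= 12).  Frequencies start uniform over the 2^k haplotype
    space; iteration stops when the largest frequency change is below
    ``tol``.  Per-sample diplotype ties are broken lexicographically and
    flagged.

    Returns {"frequencies": {hap_string: freq}, "loglik": float,
    "diplotypes": [(hap_i, hap_j)], "ambiguous": [bool]}.
    """
    g = np.asarray(genotypes)
    n, k = g.shape
    if k > EM_PHASE_MAX_SNVS:
        raise ValueError(
            f"window of {k} SNVs exceeds the {EM_PHASE_MAX_SNVS}-SNV EM "
            "limit; use an external phaser"
        )
    H = 1 << k

    def hap_str(h: int) -> str:
        return format(h, f"0{k}b")

    # enumerate compatible (unordered) haplotype pairs per sample
    pair_lists: list[list[tuple[int, int]]] = []
    for s in range(n):
        het = [p for p in range(k) if g[s, p] == 1]
        base = sum((1 << (k - 1 - p)) for p in range(k) if g[s, p] == 2)
        pairs = []
        if het:
            fixed_first = het[0]
            for bits in itertools.product((0, 1), repeat=len(het) - 1):
                h1, h2 = base, base
                h1 |= 1 << (k - 1 - fixed_first)
                for p, b in zip(het[1:], bits):
                    if b:
                        h1 |= 1 << (k - 1 - p)
                    else:
                        h2 |= 1 << (k - 1 - p)
                pairs.append((min(h1, h2), max(h1, h2)))
        else:
            pairs.append((base, base))
        pair_lists.append(pairs)

    freq = np.full(H, 1.0 / H)
    for _ in range(max_iter):
        counts = np.zeros(H)
        for pairs in pair_lists:
            w = np.array([freq[a] * freq[b] * (1 if a == b else 2)
                          for a, b in pairs])
            tot = w.sum()
            if tot == 0:
                w = np.ones(len(pairs))
                tot = w.sum()
            w /= tot
            for (a, b), wt in zip(pairs, w):
                counts[a] += wt
                counts[b] += wt
        new = counts / (2 * n)
        delta = np.max(np.abs(new - freq))
        freq = new
        if delta < tol:
            break

    loglik = 0.0
    diplotypes, ambiguous = [], []
    for pairs in pair_lists:
        probs = [freq[a] * freq[b] * (1 if a == b else 2) for a, b in pairs]
        tot = sum(probs)
        loglik += np.log(tot) if tot > 0 else float("-inf")
        best_p = max(probs)
        best_pairs = sorted(p for p, pr in zip(pairs, probs)
                            if pr >= best_p * (1 - 1e-12))
        a, b = best_pairs[0]
        diplotypes.append((hap_str(a), hap_str(b)))
        ambiguous.append(len(best_pairs) > 1)

    frequencies = {hap_str(h): float(freq[h]) for h in range(H)
                   if freq[h] > 1e-12}
    return {"frequencies": frequencies, "loglik": float(loglik),
            "diplotypes": diplotypes, "ambiguous": ambiguous}
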