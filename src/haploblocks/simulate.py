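"""Seeded generator of multi-population phased cohorts with planted
haplotype-block structure and planted genotype-level disease effects.

The model is deliberately simple: each block carries a small pool of
haplotypes with per-population frequencies; a chromosome is built block by
block by drawing a pool index per block, kept from the previous block
unless a boundary recombination fires (free recombination at boundaries,
none inside blocks by default).  Case/control status follows a logistic
penetrance on the diplotype at a focal block: odds = baseline_odds x
effect(genotype class), so e.g. a recessive risk genotype gets a >1 odds
multiplier and a protective heterozygote a <1 multiplier.

Everything is deterministic given the seed, and a machine-readable
:class:`TruthRecord` carries the planted boundaries, frequencies, latent
diplotypes and effects so every downstream inference can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SampleTable, _variant_from_alt_freq

DEFAULT_ATTEMPT_FACTOR = 1000  # attempts allowed per requested individual


@dataclass
class BlockSpec:
    """One planted block: marker count, spacing, haplotype pool ('0' = ref
    allele, '1' = alt) and per-population pool frequencies."""

    n_markers: int
    inter_marker_bp: int
    pool: list[str]
    freqs: dict[str, list[float]]  # population -> frequency per pool entry

    def validate(self, populations: Sequence[str]) -> None:
        if self.n_markers < 2:
            raise ValueError("blocks need at least 2 markers")
        for h in self.pool:
            if len(h) != self.n_markers or set(h) - {"0", "1"}:
                raise ValueError(f"bad pool haplotype {h!r}")
        for pop in populations:
            if pop not in self.freqs:
                raise ValueError(f"no pool frequencies for population {pop!r}")
            f = self.freqs[pop]
            if len(f) != len(self.pool):
                raise ValueError("frequency vector length != pool size")
            if abs(sum(f) - 1.0) > 1e-9 or min(f) < 0:
                raise ValueError("pool frequencies must be a distribution")


@dataclass
class DiseaseSpec:
    """Penetrance model at the focal block.

    ``genotype_effects`` maps an unordered focal pool-index pair "i/j"
    (i <= j) to an odds multiplier; unlisted genotypes have multiplier 1.
    """

    focal_block: int
    genotype_effects: dict[str, float]
    baseline_odds: float
    n_cases: int
    n_controls: int
    case_population: str


@dataclass
class SimulationConfig:
    seed: int
    populations: list[dict]  # {name, n_diploids}
    blocks: list[BlockSpec]
    boundary_recomb: float = 1.0
    within_block_recomb: float = 0.0
    disease: Optional[DiseaseSpec] = None
    sex_ratio: float = 0.5
    chrom: str = "chr3"
    start_pos: int = 38_500_000
    boundary_gap_bp: int = 2_000
    attempt_factor: int = DEFAULT_ATTEMPT_FACTOR

    def validate(self) -> None:
        pops = [p["name"] for p in self.populations]
        if len(set(pops)) != len(pops):
            raise ValueError("duplicate population names")
        for b in self.blocks:
            b.validate(pops)
        for prob in (self.boundary_recomb, self.within_block_recomb,
                     self.sex_ratio):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.disease is not None:
            if not 0 <= self.disease.focal_block < len(self.blocks):
                raise ValueError("focal_block out of range")
            if self.disease.case_population not in pops:
                raise ValueError("case_population not among populations")


@dataclass
class TruthRecord:
    seed: int
    boundaries: list[tuple[int, int]]  # planted inter-block gaps, 1-based incl
    marker_positions: list[int]
    block_marker_ranges: list[tuple[int, int]]  # variant-index ranges
    haplotype_frequencies: dict[str, list[dict[str, float]]]  # pop -> per block {hap: freq}
    focal_diplotypes: dict[str, str]  # sample -> "i/j" focal pool-index pair
    genotype_effects: dict[str, float]
    baseline_odds: Optional[float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    samples: SampleTable
    truth: TruthRecord


def _positions(cfg: SimulationConfig) -> tuple[list[int], list[tuple[int, int]],
                                               list[tuple[int, int]]]:
    """Marker positions, per-block variant-index ranges, and the planted
    boundary intervals (the bp gaps between consecutive block spans)."""
    positions: list[int] = []
    ranges: list[tuple[int, int]] = []
    pos = cfg.start_pos
    for b in cfg.blocks:
        first = len(positions)
        for k in range(b.n_markers):
            positions.append(pos)
            pos += b.inter_marker_bp
        pos += cfg.boundary_gap_bp - b.inter_marker_bp
        ranges.append((first, len(positions) - 1))
    boundaries = []
    for (_, last), (nxt_first, _) in zip(ranges, ranges[1:]):
        boundaries.append((positions[last] + 1, positions[nxt_first] - 1))
    return positions, ranges, boundaries


def _draw_chromosome(cfg: SimulationConfig, pop: str,
                     rng: np.random.Generator) -> tuple[str, int]:
    """One chromosome as a concatenated allele string; also returns the
    pool index drawn at the focal block (or block 0 if no disease)."""
    focal = cfg.disease.focal_block if cfg.disease else 0
    segments = []
    idx = None
    focal_idx = 0
    for b_i, b in enumerate(cfg.blocks):
        f = np.asarray(b.freqs[pop])
        if idx is None or rng.random() < cfg.boundary_recomb or idx >= len(b.pool):
            idx = int(rng.choice(len(b.pool), p=f))
        hap = b.pool[idx]
        if cfg.within_block_recomb > 0:
            chars = list(hap)
            cur = idx
            for m in range(1, b.n_markers):
                if rng.random() < cfg.within_block_recomb:
                    cur = int(rng.choice(len(b.pool), p=f))
                chars[m] = b.pool[cur][m]
            hap = "".join(chars)
        segments.append(hap)
        if b_i == focal:
            focal_idx = idx
    return "".join(segments), focal_idx


def _penetrance(cfg: SimulationConfig, pair: tuple[int, int]) -> float:
    d = cfg.disease
    key = f"{min(pair)}/{max(pair)}"
    odds = d.baseline_odds * d.genotype_effects.get(key, 1.0)
    return odds / (1.0 + odds)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate the phased cohort, sample table and truth record.

    Populations without a disease spec are all-control panels of the
    requested size.  For the disease (case) population, individuals are
    drawn and assigned case status by the logistic penetrance until the
    requested case and control counts are reached; an error is raised
    after ``attempt_factor`` x (n_cases + n_controls) attempts if the case
    quota is unreachable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    positions, ranges, boundaries = _positions(cfg)
    n_markers = len(positions)

    sample_rows = []
    hap_strings: list[tuple[str, str]] = []
    focal_diplotypes: dict[str, str] = {}

    def add_individual(sid: str, pop: str, status: str,
                       h0: str, h1: str, f0: int, f1: int) -> None:
        sex = "male" if rng.random() < cfg.sex_ratio else "female"
        sample_rows.append({"sample_id": sid, "status": status, "sex": sex,
                            "population": pop})
        hap_strings.append((h0, h1))
        focal_diplotypes[sid] = f"{min(f0, f1)}/{max(f0, f1)}"

    for pop_spec in cfg.populations:
        pop = pop_spec["name"]
        n = pop_spec["n_diploids"]
        is_case_pop = cfg.disease is not None and cfg.disease.case_population == pop
        if not is_case_pop:
            for k in range(n):
                h0, f0 = _draw_chromosome(cfg, pop, rng)
                h1, f1 = _draw_chromosome(cfg, pop, rng)
                add_individual(f"{pop}_{k:05d}", pop, "control", h0, h1, f0, f1)
        else:
            d = cfg.disease
            want_cases, want_controls = d.n_cases, d.n_controls
            got_cases = got_controls = attempts = 0
            cap = cfg.attempt_factor * (want_cases + want_controls)
            while got_cases < want_cases or got_controls < want_controls:
                attempts += 1
                if attempts > cap:
                    raise RuntimeError(
                        "case/control quota unreachable under the penetrance "
                        f"model after {cap} attempts"
                    )
                h0, f0 = _draw_chromosome(cfg, pop, rng)
                h1, f1 = _draw_chromosome(cfg, pop, rng)
                is_case = rng.random() < _penetrance(cfg, (f0, f1))
                if is_case and got_cases < want_cases:
                    got_cases += 1
                    add_individual(f"{pop}_case_{got_cases:05d}", pop, "case",
                                   h0, h1, f0, f1)
                elif not is_case and got_controls < want_controls:
                    got_controls += 1
                    add_individual(f"{pop}_ctrl_{got_controls:05d}", pop,
                                   "control", h0, h1, f0, f1)

    n_samples = len(sample_rows)
    alleles = np.empty((n_samples, n_markers, 2), dtype=np.int8)
    for s, (h0, h1) in enumerate(hap_strings):
        alleles[s, :, 0] = np.frombuffer(h0.encode(), dtype=np.uint8) - ord("0")
        alleles[s, :, 1] = np.frombuffer(h1.encode(), dtype=np.uint8) - ord("0")
    phased = np.ones((n_samples, n_markers), dtype=bool)

    variants = []
    marker = 0
    for b_i, b in enumerate(cfg.blocks):
        for m in range(b.n_markers):
            j = ranges[b_i][0] + m
            alt_freq = float(alleles[:, j, :].mean())
            variants.append(_variant_from_alt_freq(
                cfg.chrom, positions[j], f"rs_b{b_i}_m{m}", "A", "G", alt_freq))
            marker += 1

    gm = GenotypeMatrix(variants, [r["sample_id"] for r in sample_rows],
                        alleles, phased)
    st = SampleTable(pd.DataFrame(sample_rows))
    truth = TruthRecord(
        seed=cfg.seed,
        boundaries=boundaries,
        marker_positions=positions,
        block_marker_ranges=ranges,
        haplotype_frequencies={
            p["name"]: [dict(zip(b.pool, b.freqs[p["name"]]))
                        for b in cfg.blocks]
            for p in cfg.populations
        },
        focal_diplotypes=focal_diplotypes,
        genotype_effects=dict(cfg.disease.genotype_effects) if cfg.disease else {},
        baseline_odds=cfg.disease.baseline_odds if cfg.disease else None,
    )
    return SimulatedCohort(genotypes=gm, samples=st, truth=truth)


# ---------------------------------------------------------------------------
# documented scenarios

# Focal-block pool mirroring the structure of a GWAS-hit-dense enhancer
# block: a yin-yang (fully complementary) pair, a mosaic sharing 4 major
# alleles with the all-major haplotype, two rarer mosaics with 3 and 2
# major alleles, and a Q-major haplotype.
FOCAL_POOL = [
    "0000000",  # all-major            (risk haplotype; recessive effect)
    "1001010",  # mosaic, 4 major      (protective partner 1)
    "1111111",  # all-minor, yin-yang  (protective partner 2)
    "1001110",  # mosaic, 3 major
    "1111010",  # mosaic, 2 major
    "0000001",  # Q-major
]
# Positions 0/3/5 share one allele column across the first five haplotypes
# and positions 1/2 another, so those groups are mutually redundant for
# tagging the common haplotypes — the structure reported for the real
# block.  The Q-major haplotype keeps every risk-haplotype allele the
# population-major one (carriers of the minor allele stay below 50% at all
# positions) while the risk haplotype itself sits at a realistic 42%, so
# its homozygote occurs in ~18% of controls.
FOCAL_FREQS_CASEPOP = [0.42, 0.16, 0.20, 0.06, 0.04, 0.12]

# Nested ("perfect phylogeny") pools: every marker pair shows at most three
# gametes, so the pools themselves carry no within-block recombination
# signal under any of the three partitioning principles.
_NESTED_POOL_4 = ["0000", "1000", "1100", "1111"]
_NESTED_POOL_5 = ["00000", "10000", "11000", "11100", "11111"]


def _jitter_freqs(base: Sequence[float], rng: np.random.Generator,
                  concentration: float = 250.0) -> list[float]:
    """Population-to-population frequency variation via a Dirichlet draw
    centred on ``base``.  The concentration keeps every pool haplotype
    common in every population (sd of a few percent), so the planted block
    structure is present in all populations — the consensus step, not the
    generator, is what reconciles residual disagreement."""
    alpha = np.asarray(base) * concentration
    f = rng.dirichlet(alpha)
    return [float(x) for x in f]


def default_scenario(seed: int = 0,
                     n_cases: int = 100, n_controls: int = 400) -> SimulationConfig:
    """The disease scenario: a 7-marker focal block with the five common
    haplotypes (including the yin-yang pair), two flanking blocks, a
    recessive odds multiplier of 6.28 for the all-major homozygote and a
    protective multiplier for the planted heterozygote pair (indices 1/2 =
    the mosaic / all-minor combination, emulating a protective compound
    genotype never seen among cases)."""
    pops = ["NFE"]
    flank = BlockSpec(n_markers=4, inter_marker_bp=1500,
                      pool=list(_NESTED_POOL_4),
                      freqs={"NFE": [0.35, 0.3, 0.2, 0.15]})
    focal = BlockSpec(n_markers=7, inter_marker_bp=1500,
                      pool=list(FOCAL_POOL),
                      freqs={"NFE": list(FOCAL_FREQS_CASEPOP)})
    flank2 = BlockSpec(n_markers=4, inter_marker_bp=1500,
                       pool=list(_NESTED_POOL_4),
                       freqs={"NFE": [0.35, 0.3, 0.2, 0.15]})
    disease = DiseaseSpec(
        focal_block=1,
        genotype_effects={"0/0": 6.28, "1/2": 0.05},
        baseline_odds=0.05,
        n_cases=n_cases, n_controls=n_controls,
        case_population="NFE",
    )
    return SimulationConfig(
        seed=seed,
        populations=[{"name": "NFE", "n_diploids": n_cases + n_controls}],
        blocks=[flank, focal, flank2],
        boundary_recomb=1.0,
        within_block_recomb=0.0,
        disease=disease,
    )


def recessive_scenario(seed: int = 0, n_cases: int = 100,
                       n_controls: int = 400) -> SimulationConfig:
    """The pure parameter-recovery scenario: identical to
    :func:`default_scenario` but with only the recessive risk effect
    planted, so the population recessive odds ratio is exactly 6.28."""
    cfg = default_scenario(seed, n_cases, n_controls)
    cfg.disease.genotype_effects = {"0/0": 6.28}
    return cfg


def null_scenario(seed: int = 0, n_cases: int = 100,
                  n_controls: int = 400) -> SimulationConfig:
    """All genotype effects 1: case status independent of genotype, for
    type-I-error / calibration checks.  Baseline odds of 1 (an even
    case/control split) — prevalence is immaterial when no effect is
    planted, and an even split fills both quotas quickly."""
    cfg = default_scenario(seed, n_cases, n_controls)
    cfg.disease.genotype_effects = {}
    cfg.disease.baseline_odds = 1.0
    return cfg


def block_recovery_scenario(seed: int = 0, n_diploids: int = 200) -> SimulationConfig:
    """The block-structure scenario: three blocks with nested haplotype
    pools, five populations of ``n_diploids`` each, free recombination at
    boundaries and none within blocks — the conditions under which all
    three partitioning methods should recover every planted boundary."""
    pops = ["NFE", "AFR", "AMR", "EAS", "SAS"]
    rng = np.random.default_rng(seed + 7_654_321)
    base4 = [0.35, 0.3, 0.2, 0.15]
    base5 = [0.3, 0.25, 0.2, 0.13, 0.12]
    blocks = []
    for pool, base in ((_NESTED_POOL_4, base4), (_NESTED_POOL_5, base5),
                       (_NESTED_POOL_4, base4)):
        freqs = {p: _jitter_freqs(base, rng) for p in pops}
        blocks.append(BlockSpec(n_markers=len(pool[0]), inter_marker_bp=1500,
                                pool=list(pool), freqs=freqs))
    return SimulationConfig(
        seed=seed,
        populations=[{"name": p, "n_diploids": n_diploids} for p in pops],
        blocks=blocks,
        boundary_recomb=1.0,
        within_block_recomb=0.0,
        disease=None,
    )
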