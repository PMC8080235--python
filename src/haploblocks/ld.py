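"""Pairwise linkage disequilibrium statistics.

D, D' (range-normalized), r^2, the LOD score (log10 likelihood ratio of the
estimated two-locus haplotype frequencies against linkage equilibrium), and
likelihood-based confidence bounds on D' — from phased gamete counts when
phase is available, otherwise via the classic two-locus EM over the 3x3
diploid genotype table (only the double heterozygote is phase-ambiguous).

Allele convention inside this module: A/a = major/minor at the first locus,
B/b at the second, so D > 0 means an excess of major-major gametes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000
CI_GRID_STEP = 0.001
CI_LO_Q = 0.05
CI_HI_Q = 0.95
MAX_PAIR_DISTANCE = 500_000  # bp; pairs farther apart are skipped


@dataclass
class TwoLocusCounts:
    """Chromosome counts of the four gametes; fractional when EM-expected."""

    n_AB: float
    n_Ab: float
    n_aB: float
    n_ab: float

    @property
    def n(self) -> float:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    def freqs(self) -> np.ndarray:
        n = self.n
        if n <= 0:
            raise ValueError("no observations")
        return np.array([self.n_AB, self.n_Ab, self.n_aB, self.n_ab]) / n

    @property
    def informative(self) -> bool:
        """Both loci polymorphic in the counted chromosomes."""
        if self.n <= 0:
            return False
        p = self.freqs()
        p_A = p[0] + p[1]
        p_B = p[0] + p[2]
        return 0 < p_A < 1 and 0 < p_B < 1


@dataclass
class PairwiseLD:
    i: int
    j: int
    D: float = float("nan")
    Dprime: float = float("nan")
    r2: float = float("nan")
    LOD: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    informative: bool = False


def two_locus_counts_phased(gm: GenotypeMatrix, i: int, j: int) -> TwoLocusCounts:
    """Direct gamete counts at variants i, j over phased, complete samples.

    A sample contributes its two chromosomes only if both variants are
    phased and non-missing for it.  Alleles are mapped to major/minor per
    variant (A = major at i, B = major at j).
    """
    ai = gm.alleles[:, i, :]
    aj = gm.alleles[:, j, :]
    ok = (gm.phased[:, i] & gm.phased[:, j]
          & (ai >= 0).all(axis=1) & (aj >= 0).all(axis=1))
    maj_i = gm.variants[i].major_index
    maj_j = gm.variants[j].major_index
    # chromosome-level major indicators
    hi = (ai[ok] == maj_i)   # n_ok x 2 booleans, True = major
    hj = (aj[ok] == maj_j)
    n_AB = int(np.sum(hi & hj))
    n_Ab = int(np.sum(hi & ~hj))
    n_aB = int(np.sum(~hi & hj))
    n_ab = int(np.sum(~hi & ~hj))
    return TwoLocusCounts(n_AB, n_Ab, n_aB, n_ab)


def genotype_table_3x3(gm: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """3x3 table of two-locus diploid genotypes (counts of major alleles
    2/1/0 at each locus), over samples complete at both variants."""
    ai = gm.alleles[:, i, :]
    aj = gm.alleles[:, j, :]
    ok = (ai >= 0).all(axis=1) & (aj >= 0).all(axis=1)
    maj_i = gm.variants[i].major_index
    maj_j = gm.variants[j].major_index
    gi = (ai[ok] == maj_i).sum(axis=1)  # 0..2 major-allele dosage
    gj = (aj[ok] == maj_j).sum(axis=1)
    table = np.zeros((3, 3), dtype=int)
    for a, b in zip(gi, gj):
        table[2 - a, 2 - b] += 1  # row 0 = AA, col 0 = BB
    return table


def _loglik_genotype_table(table: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under haplotype
    frequencies p = (p_AB, p_Ab, p_aB, p_ab), HWE at the haplotype level."""
    p_AB, p_Ab, p_aB, p_ab = p
    # genotype probabilities; double het = 2(p_AB p_ab + p_Ab p_aB)
    g = np.empty((3, 3))
    g[0, 0] = p_AB ** 2
    g[0, 1] = 2 * p_AB * p_Ab
    g[0, 2] = p_Ab ** 2
    g[1, 0] = 2 * p_AB * p_aB
    g[1, 1] = 2 * (p_AB * p_ab + p_Ab * p_aB)
    g[1, 2] = 2 * p_Ab * p_ab
    g[2, 0] = p_aB ** 2
    g[2, 1] = 2 * p_aB * p_ab
    g[2, 2] = p_ab ** 2
    with np.errstate(divide="ignore"):
        lg = np.log(g)
    mask = table > 0
    if np.any(np.isneginf(lg[mask])):
        return float("-inf")
    return float(np.sum(table[mask] * lg[mask]))


def em_two_locus(table: np.ndarray, tol: float = EM_TOL,
                 max_iter: int = EM_MAX_ITER) -> tuple[np.ndarray, float]:
    """Two-locus EM for haplotype frequencies from a 3x3 genotype table.

    Rows index the major-allele dosage at locus 1 (0 = AA, 2 = aa) and
    columns at locus 2.  Started at linkage equilibrium (products of allele
    frequencies); iterated until the largest absolute frequency change is
    below ``tol`` or ``max_iter`` is reached.

    Returns (p, loglik) with p = (p_AB, p_Ab, p_aB, p_ab).
    """
    table = np.asarray(table, dtype=float)
    n_ind = table.sum()
    if n_ind <= 0:
        raise ValueError("empty genotype table")
    n_chrom = 2.0 * n_ind
    # known gamete counts (everything except the double heterozygote)
    base = np.zeros(4)  # AB, Ab, aB, ab
    # cell (r, c): locus1 has (2-r) A alleles, locus2 has (2-c) B alleles
    for r in range(3):
        for c in range(3):
            cnt = table[r, c]
            if cnt == 0 or (r == 1 and c == 1):
                continue
            nA, nB = 2 - r, 2 - c
            # unambiguous decomposition into two gametes
            # e.g. AA/Bb -> AB + Ab; Aa/BB -> AB + aB; Aa/bb -> Ab + ab
            gam = {"AB": 0, "Ab": 0, "aB": 0, "ab": 0}
            a_allele = ["A"] * nA + ["a"] * (2 - nA)
            b_allele = ["B"] * nB + ["b"] * (2 - nB)
            for hap in (a_allele[0] + b_allele[0], a_allele[1] + b_allele[1]):
                gam[hap] += 1
            base += cnt * np.array([gam["AB"], gam["Ab"], gam["aB"], gam["ab"]])
    n_dh = table[1, 1]
    # allele frequencies (fixed by the margins)
    p_A = (2 * table[0].sum() + table[1].sum()) / n_chrom
    p_B = (2 * table[:, 0].sum() + table[:, 1].sum()) / n_chrom
    p = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
                  (1 - p_A) * (1 - p_B)])
    for _ in range(max_iter):
        if n_dh > 0:
            cis = p[0] * p[3]          # AB/ab resolution
            trans = p[1] * p[2]        # Ab/aB resolution
            tot = cis + trans
            w = 0.5 if tot == 0 else cis / tot
        else:
            w = 0.0
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        p_new = counts / n_chrom
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    return p, _loglik_genotype_table(table.astype(int), p)


def ld_statistics(c: TwoLocusCounts) -> tuple[float, float, float]:
    """(D, D', r^2) from gamete counts/frequencies.

    D = p_AB - p_A p_B; Dmax = min(p_A p_b, p_a p_B) for D > 0 else
    min(p_A p_B, p_a p_b); D' = |D| / Dmax (0 when D = 0);
    r^2 = D^2 / (p_A p_a p_B p_b).
    """
    if not c.informative:
        raise ValueError("monomorphic locus: LD statistics undefined")
    p_AB, p_Ab, p_aB, p_ab = c.freqs()
    p_A, p_a = p_AB + p_Ab, p_aB + p_ab
    p_B, p_b = p_AB + p_aB, p_Ab + p_ab
    D = p_AB - p_A * p_B
    if D > 0:
        Dmax = min(p_A * p_b, p_a * p_B)
    else:
        Dmax = min(p_A * p_B, p_a * p_b)
    Dprime = 0.0 if D == 0 else abs(D) / Dmax
    r2 = D * D / (p_A * p_a * p_B * p_b)
    return float(D), float(min(Dprime, 1.0)), float(min(r2, 1.0))


def _gamete_loglik(c: TwoLocusCounts, p: np.ndarray) -> float:
    counts = np.array([c.n_AB, c.n_Ab, c.n_aB, c.n_ab], dtype=float)
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    mask = counts > 0
    if np.any(np.isneginf(lp[mask])):
        return float("-inf")
    return float(np.sum(counts[mask] * lp[mask]))


def lod_score(c: TwoLocusCounts) -> float:
    """log10 likelihood ratio: observed gamete frequencies (the multinomial
    MLE) against linkage equilibrium at the same allele frequencies."""
    if not c.informative:
        raise ValueError("monomorphic locus: LOD undefined")
    p_hat = c.freqs()
    p_AB, p_Ab, p_aB, p_ab = p_hat
    p_A, p_B = p_AB + p_Ab, p_AB + p_aB
    p_eq = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
                     (1 - p_A) * (1 - p_B)])
    ll1 = _gamete_loglik(c, p_hat)
    ll0 = _gamete_loglik(c, p_eq)
    return max(0.0, (ll1 - ll0) / np.log(10.0))


def dprime_ci(c: TwoLocusCounts, grid_step: float = CI_GRID_STEP,
              lo_q: float = CI_LO_Q, hi_q: float = CI_HI_Q
              ) -> tuple[float, float]:
    """Likelihood-based confidence bounds on D'.

    The gamete likelihood is evaluated on a D' grid over [0, 1] with
    haplotype frequencies rebuilt from the allele-frequency MLEs and the
    sign of D fixed at its MLE; the profile is normalized to unit mass and
    the bounds are the grid values where the cumulative mass first reaches
    ``lo_q`` and ``hi_q``.
    """
    if not c.informative:
        raise ValueError("uninformative pair")
    p_AB, p_Ab, p_aB, p_ab = c.freqs()
    p_A, p_B = p_AB + p_Ab, p_AB + p_aB
    p_a, p_b = 1 - p_A, 1 - p_B
    D_mle = p_AB - p_A * p_B
    sign = 1.0 if D_mle >= 0 else -1.0
    if sign > 0:
        Dmax = min(p_A * p_b, p_a * p_B)
    else:
        Dmax = min(p_A * p_B, p_a * p_b)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    D_vals = sign * grid * Dmax
    probs = np.stack([
        p_A * p_B + D_vals,
        p_A * p_b - D_vals,
        p_a * p_B - D_vals,
        p_a * p_b + D_vals,
    ], axis=1)
    counts = np.array([c.n_AB, c.n_Ab, c.n_aB, c.n_ab], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(np.clip(probs, 0.0, None))
    ll = np.full(grid.shape, -np.inf)
    mask_cnt = counts > 0
    contrib = lp[:, mask_cnt] * counts[mask_cnt]
    valid = np.isfinite(contrib).all(axis=1)
    ll[valid] = contrib[valid].sum(axis=1)
    ll -= ll.max()
    w = np.exp(ll)
    total = w.sum()
    if total <= 0:
        return float("nan"), float("nan")
    cum = np.cumsum(w) / total
    ci_low = float(grid[np.searchsorted(cum, lo_q)])
    ci_high = float(grid[np.searchsorted(cum, hi_q)])
    return ci_low, ci_high


def pairwise_ld(gm: GenotypeMatrix, i: int, j: int,
                prefer_phased: bool = True) -> PairwiseLD:
    """Full LD record for one variant pair.

    Uses direct phased gamete counts when available for at least one
    complete sample pair; otherwise falls back to EM-expected gamete counts
    from the unphased genotype table.
    """
    c = two_locus_counts_phased(gm, i, j) if prefer_phased else None
    if c is None or c.n == 0:
        table = genotype_table_3x3(gm, i, j)
        if table.sum() == 0:
            return PairwiseLD(i=i, j=j, informative=False)
        p, _ = em_two_locus(table)
        n_chrom = 2.0 * table.sum()
        c = TwoLocusCounts(*(p * n_chrom))
    if not c.informative:
        return PairwiseLD(i=i, j=j, informative=False)
    D, Dprime, r2 = ld_statistics(c)
    lod = lod_score(c)
    ci_low, ci_high = dprime_ci(c)
    return PairwiseLD(i=i, j=j, D=D, Dprime=Dprime, r2=r2, LOD=lod,
                      ci_low=ci_low, ci_high=ci_high, informative=True)


def ld_matrix(gm: GenotypeMatrix,
              max_distance: int = MAX_PAIR_DISTANCE) -> dict[tuple[int, int], PairwiseLD]:
    """All within-distance pairwise LD records, keyed by (i, j) with i < j."""
    out: dict[tuple[int, int], PairwiseLD] = {}
    for i in range(gm.n_variants):
        for j in range(i + 1, gm.n_variants):
            if gm.variants[j].pos - gm.variants[i].pos > max_distance:
                break
            out[(i, j)] = pairwise_ld(gm, i, j)
    return out


def ld_matrix_to_frame(gm: GenotypeMatrix,
                       mat: dict[tuple[int, int], PairwiseLD]) -> pd.DataFrame:
    rows = []
    for (i, j), ld in sorted(mat.items()):
        rows.append({
            "i_vid": gm.variants[i].vid,
            "j_vid": gm.variants[j].vid,
            "distance_bp": gm.variants[j].pos - gm.variants[i].pos,
            "D": ld.D, "Dprime": ld.Dprime, "r2": ld.r2, "LOD": ld.LOD,
            "ci_low": ld.ci_low, "ci_high": ld.ci_high,
            "informative": ld.informative,
        })
    return pd.DataFrame(rows, columns=["i_vid", "j_vid", "distance_bp", "D",
                                       "Dprime", "r2", "LOD", "ci_low",
                                       "ci_high", "informative"])
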