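"""Case-control association at SNV, haplotype and genotype level, plus
transmission-model logistic fits.

Fisher's exact test (two-sided, probability-mass rule) with per-family
Bonferroni correction drives the SNV / haplotype / genotype contrasts;
the dominant / recessive / multiplicative inheritance models are fit by
unconditional logistic regression (optionally sex-adjusted), compared by
Wald p-values and BIC = k·ln(n) − 2·lnL.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import Diplotype, HaplotypeCatalog, _label_key
from .io_formats import GenotypeMatrix

logger = logging.getLogger("haploblocks")

ALPHA = 0.05
SEPARATION_BETA = 15.0  # |beta| beyond this flags (quasi-)separation
MODELS = ("dominant", "recessive", "multiplicative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: case/control; columns: feature present/absent."""

    a: int  # cases with feature
    b: int  # cases without
    c: int  # controls with feature
    d: int  # controls without

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def degenerate(self) -> bool:
        m = self.as_array
        return (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any()


@dataclass
class AssociationResult:
    feature: str
    table: ContingencyTable2x2
    p: float
    m: int
    alpha_corrected: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_corrected


@dataclass
class TransmissionFit:
    model: str
    beta: Optional[float]
    or_: Optional[float]
    ci95: Optional[tuple[float, float]]
    p: Optional[float]
    bic: Optional[float]
    sex_adjusted: bool
    converged: bool
    separation: bool


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (probability-mass rule: the summed
    hypergeometric probability of all tables with fixed margins no more
    likely than the observed one).  Degenerate margins give p = 1."""
    if t.degenerate:
        return 1.0
    return float(stats.fisher_exact(t.as_array, alternative="two-sided")[1])


def bonferroni(alpha: float = ALPHA, m: int = 1) -> float:
    """Per-test threshold alpha/m; rounding happens only at display."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def display_threshold(threshold: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures for reporting."""
    if threshold == 0:
        return 0.0
    from math import floor, log10

    d = sig - 1 - floor(log10(abs(threshold)))
    return round(threshold, d)


@dataclass
class ControlFrequencySummary:
    """Allele-frequency-only control cohort (e.g. a public reference panel
    where individual-level genotypes are not available): per variant id the
    counted-allele frequency and total chromosome count 2N."""

    freqs: Mapping[str, tuple[float, int]]  # vid -> (allele freq, n_chrom)

    def allele_counts(self, vid: str) -> tuple[int, int]:
        freq, n_chrom = self.freqs[vid]
        # round half-up, as printed frequencies are themselves rounded
        k = int(np.floor(freq * n_chrom + 0.5))
        return k, n_chrom - k

    def __contains__(self, vid: str) -> bool:
        return vid in self.freqs


def _case_minor_allele_counts(gm: GenotypeMatrix, idx: int) -> tuple[int, int]:
    calls = gm.alleles[:, idx, :].ravel()
    obs = calls[calls >= 0]
    minor_idx = 1 - gm.variants[idx].major_index
    k = int((obs == minor_idx).sum())
    return k, obs.size - k


def snv_association(cases: GenotypeMatrix, controls,
                    family: Optional[str] = None,
                    alpha: float = ALPHA) -> list[AssociationResult]:
    """Per-SNV allele-count association, cases vs controls.

    The counted (risk-candidate) allele is the minor allele as designated
    in the case matrix.  ``controls`` is either a GenotypeMatrix or a
    :class:`ControlFrequencySummary` (frequency-only mode, counts
    reconstructed as round(freq x 2N)).  ``family`` restricts the tested
    SNVs to one frequency class ('common' or 'low_frequency'); the
    Bonferroni m is the number of SNVs tested in the family.
    """
    tested: list[tuple[str, ContingencyTable2x2]] = []
    for i, v in enumerate(cases.variants):
        if family is not None and v.freq_class != family:
            continue
        a, b = _case_minor_allele_counts(cases, i)
        if isinstance(controls, ControlFrequencySummary):
            if v.vid not in controls:
                logger.info("SNV %s absent from control summary; excluded", v.vid)
                continue
            c, d = controls.allele_counts(v.vid)
        else:
            try:
                j = controls.variant_index(v.vid)
            except KeyError:
                logger.info("SNV %s absent from control genotypes; excluded", v.vid)
                continue
            # count the same physical allele in controls
            calls = controls.alleles[:, j, :].ravel()
            obs = calls[calls >= 0]
            minor_allele = v.minor_allele
            cv = controls.variants[j]
            target_idx = 0 if cv.ref_allele == minor_allele else 1
            c = int((obs == target_idx).sum())
            d = obs.size - c
        tested.append((v.vid, ContingencyTable2x2(a, b, c, d)))
    m = len(tested)
    if m == 0:
        return []
    thr = bonferroni(alpha, m)
    return [AssociationResult(vid, t, fisher_exact_two_sided(t), m, thr)
            for vid, t in tested]


def _chromosome_counts(catalog: HaplotypeCatalog, cohort: str) -> dict[str, int]:
    return {e.label: e.counts.get(cohort, 0) for e in catalog.entries}


def haplotype_association(catalog: HaplotypeCatalog, case_cohort: str,
                          control_cohort: str,
                          alpha: float = ALPHA) -> list[AssociationResult]:
    """Per-haplotype chromosome-count association (this haplotype vs all
    others) between two cohorts of the catalog; Bonferroni m = number of
    catalog haplotypes."""
    case_counts = _chromosome_counts(catalog, case_cohort)
    ctrl_counts = _chromosome_counts(catalog, control_cohort)
    n_case = sum(case_counts.values())
    n_ctrl = sum(ctrl_counts.values())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("a cohort has no chromosomes in the catalog")
    m = len(catalog.entries)
    thr = bonferroni(alpha, m)
    out = []
    for e in catalog.entries:
        a = case_counts[e.label]
        c = ctrl_counts[e.label]
        if a == 0 and c == 0:
            continue
        t = ContingencyTable2x2(a, n_case - a, c, n_ctrl - c)
        out.append(AssociationResult(e.label, t, fisher_exact_two_sided(t),
                                     m, thr))
    return out


def genotype_association(case_diplotypes: Sequence[Diplotype],
                         control_diplotypes: Sequence[Diplotype],
                         alpha: float = ALPHA) -> list[AssociationResult]:
    """Per-genotype (unordered haplotype pair Hap^i/j) individual-count
    association; Bonferroni m = number of genotypes observed in either
    cohort."""
    case_n = len(case_diplotypes)
    ctrl_n = len(control_diplotypes)
    genotypes = sorted(
        {d.name for d in case_diplotypes} | {d.name for d in control_diplotypes},
        key=lambda g: tuple(_label_key(x) for x in g.split("/")),
    )
    m = len(genotypes)
    if m == 0:
        return []
    thr = bonferroni(alpha, m)
    out = []
    for g in genotypes:
        a = sum(d.name == g for d in case_diplotypes)
        c = sum(d.name == g for d in control_diplotypes)
        t = ContingencyTable2x2(a, case_n - a, c, ctrl_n - c)
        out.append(AssociationResult(g, t, fisher_exact_two_sided(t), m, thr))
    return out


def _code_exposure(copies: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return (copies >= 1).astype(float)
    if model == "recessive":
        return (copies == 2).astype(float)
    if model == "multiplicative":
        return copies.astype(float)
    raise ValueError(f"unknown model {model!r}")


def fit_transmission_models(copy_number: Sequence[int],
                            phenotype: Sequence[int],
                            sex: Optional[Sequence[str]] = None
                            ) -> tuple[dict[str, TransmissionFit], Optional[str]]:
    """Fit the dominant / recessive / multiplicative logistic models.

    ``copy_number`` counts copies (0/1/2) of the focal haplotype or allele;
    ``phenotype`` is 1 for cases, 0 for controls; ``sex`` (optional) adds a
    male indicator covariate (female = reference; samples with unknown sex
    are excluded, logged).  Returns the per-model fits and the name of the
    best (lowest-BIC) converged model.
    """
    import statsmodels.api as sm

    copies = np.asarray(copy_number, dtype=int)
    y = np.asarray(phenotype, dtype=int)
    if copies.shape != y.shape:
        raise ValueError("copy_number and phenotype lengths differ")
    if not set(np.unique(copies)) <= {0, 1, 2}:
        raise ValueError("copy_number must be 0, 1 or 2")
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    sex_adjusted = sex is not None
    if sex_adjusted:
        sex_arr = np.asarray(sex, dtype=object)
        known = np.isin(sex_arr, ("male", "female"))
        n_unknown = int((~known).sum())
        if n_unknown:
            logger.info("excluding %d samples with unknown sex", n_unknown)
        copies, y, sex_arr = copies[known], y[known], sex_arr[known]
        male = (sex_arr == "male").astype(float)

    fits: dict[str, TransmissionFit] = {}
    for model in MODELS:
        x = _code_exposure(copies, model)
        if np.ptp(x) == 0:
            fits[model] = TransmissionFit(model, None, None, None, None, None,
                                          sex_adjusted, False, False)
            continue
        cols = [np.ones_like(x), x]
        if sex_adjusted and np.ptp(male) > 0:
            cols.append(male)
        X = np.column_stack(cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                fits[model] = TransmissionFit(model, None, None, None, None,
                                              None, sex_adjusted, False, True)
                continue
        beta = float(res.params[1])
        se = float(res.bse[1])
        # separation: runaway estimate or perfect classification by exposure
        perfect = (y[x > 0].min(initial=1) == 1 and y[x == 0].max(initial=0) == 0
                   ) if (x > 0).any() and (x == 0).any() else True
        separation = abs(beta) > SEPARATION_BETA or perfect
        n = len(y)
        k = X.shape[1]
        bic = k * np.log(n) - 2 * float(res.llf)
        if separation or not converged:
            fits[model] = TransmissionFit(model, None, None, None, None,
                                          bic if converged else None,
                                          sex_adjusted, converged, separation)
            continue
        ci = (float(np.exp(beta - 1.959963984540054 * se)),
              float(np.exp(beta + 1.959963984540054 * se)))
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        fits[model] = TransmissionFit(model, beta, float(np.exp(beta)), ci,
                                      float(p), float(bic), sex_adjusted,
                                      True, False)
    usable = {m: f for m, f in fits.items()
              if f.converged and not f.separation and f.bic is not None}
    best = min(usable, key=lambda m: usable[m].bic) if usable else None
    return fits, best


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [{"feature": r.feature, "a": r.table.a, "b": r.table.b,
             "c": r.table.c, "d": r.table.d, "p": r.p, "m": r.m,
             "alpha_corrected": r.alpha_corrected,
             "significant": r.significant} for r in results]
    return pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d", "p",
                                       "m", "alpha_corrected", "significant"])


def transmission_frame(feature: str, fits: Mapping[str, TransmissionFit],
                       best: Optional[str]) -> pd.DataFrame:
    nan = float("nan")
    rows = []
    for model in MODELS:
        f = fits[model]
        rows.append({
            "feature": feature, "model": model,
            "beta": nan if f.beta is None else f.beta,
            "OR": nan if f.or_ is None else f.or_,
            "ci_low": f.ci95[0] if f.ci95 else nan,
            "ci_high": f.ci95[1] if f.ci95 else nan,
            "p": nan if f.p is None else f.p,
            "bic": nan if f.bic is None else f.bic,
            "best_model": model == best,
            "separation": f.separation,
        })
    return pd.DataFrame(rows)
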