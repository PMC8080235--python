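"""Readers, writers, and the core in-memory containers.

Every downstream stage consumes the types defined here: a
:class:`GenotypeMatrix` of phased (or partly phased) biallelic SNV calls,
and a :class:`SampleTable` of case/control status, sex, and population
labels.  Coordinates are 1-based inclusive internally (the VCF convention);
conversion to BED's 0-based half-open intervals happens only at the I/O
edge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("haploblocks")

# MAF classes (common / low-frequency) follow the conventional cutoffs:
# common MAF >= 5%, low-frequency 0.5% <= MAF < 5%.
COMMON_MAF = 0.05
LOW_FREQ_MAF = 0.005

VALID_STATUS = ("case", "control")
VALID_SEX = ("male", "female", "unknown")


class EmptyResultError(ValueError):
    """Raised when a filter leaves zero records — an explicit signal, never
    a silently empty success."""


class VcfParseError(ValueError):
    """Malformed VCF input; the message names the offending record."""


@dataclass(frozen=True)
class VariantInfo:
    """One biallelic SNV.

    ``maf`` is the minor-allele frequency computed on the ingested samples;
    ``major_allele``/``minor_allele`` are consistent with it (at maf = 0.5
    the ref allele is designated major, deterministically).
    """

    chrom: str
    pos: int  # 1-based
    vid: str
    ref_allele: str
    alt_allele: str
    maf: float
    major_allele: str
    minor_allele: str

    @property
    def freq_class(self) -> str:
        if self.maf >= COMMON_MAF:
            return "common"
        if self.maf >= LOW_FREQ_MAF:
            return "low_frequency"
        return "below_threshold"

    @property
    def major_index(self) -> int:
        """Allele index (0 = ref, 1 = alt) of the major allele."""
        return 0 if self.major_allele == self.ref_allele else 1


def _variant_from_alt_freq(chrom, pos, vid, ref, alt, alt_freq) -> VariantInfo:
    if alt_freq > 0.5:
        major, minor, maf = alt, ref, 1.0 - alt_freq
    else:
        # ties (alt_freq == 0.5) resolve to ref = major
        major, minor, maf = ref, alt, alt_freq
    return VariantInfo(chrom, int(pos), vid, ref, alt, float(maf), major, minor)


@dataclass
class GenotypeMatrix:
    """Samples x ordered variants with per-sample ordered allele pairs.

    ``alleles`` has shape (n_samples, n_variants, 2) with entries 0 (ref),
    1 (alt) or -1 (missing); ``phased`` is a boolean (n_samples, n_variants)
    array.  Variant order is strictly increasing by (chrom, pos).
    """

    variants: list[VariantInfo]
    samples: list[str]
    alleles: np.ndarray
    phased: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n_s, n_v = len(self.samples), len(self.variants)
        if self.alleles.shape != (n_s, n_v, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n_s}, {n_v}, 2)"
            )
        if self.phased.shape != (n_s, n_v):
            raise ValueError(f"phased shape {self.phased.shape} != ({n_s}, {n_v})")
        keys = [(v.chrom, v.pos) for v in self.variants]
        for a, b in zip(keys, keys[1:]):
            if a[0] == b[0] and a[1] >= b[1]:
                raise ValueError(f"variant order not strictly increasing at {b}")
        seen = set()
        for v in self.variants:
            k = (v.chrom, v.pos, v.alt_allele)
            if k in seen:
                raise ValueError(f"duplicate variant {k}")
            seen.add(k)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, vid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.vid == vid:
                return i
        raise KeyError(f"variant {vid!r} not present")

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=list(sample_ids),
            alleles=self.alleles[idx].copy(),
            phased=self.phased[idx].copy(),
        )

    def recompute_frequencies(self) -> "GenotypeMatrix":
        """Re-derive MAF / major-minor designation from the current calls."""
        new_variants = []
        for j, v in enumerate(self.variants):
            calls = self.alleles[:, j, :].ravel()
            obs = calls[calls >= 0]
            alt_freq = float(obs.mean()) if obs.size else 0.0
            new_variants.append(
                _variant_from_alt_freq(v.chrom, v.pos, v.vid, v.ref_allele,
                                       v.alt_allele, alt_freq)
            )
        return GenotypeMatrix(new_variants, list(self.samples),
                              self.alleles, self.phased)

    @property
    def region(self) -> tuple[str, int, int]:
        """(chrom, first pos, last pos) of the analyzed span, 1-based incl."""
        if not self.variants:
            raise EmptyResultError("no variants")
        chroms = {v.chrom for v in self.variants}
        if len(chroms) > 1:
            raise ValueError("matrix spans multiple chromosomes")
        return (self.variants[0].chrom, self.variants[0].pos,
                self.variants[-1].pos)


@dataclass
class SampleTable:
    """Case/control status, sex and population per sample."""

    table: pd.DataFrame  # columns: sample_id, status, sex, population

    def __post_init__(self):
        required = ["sample_id", "status", "sex", "population"]
        for col in required:
            if col not in self.table.columns:
                raise ValueError(f"missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")
        bad = set(self.table["status"]) - set(VALID_STATUS)
        if bad:
            raise ValueError(
                f"invalid status {sorted(bad)}; allowed: {list(VALID_STATUS)}"
            )
        bad = set(self.table["sex"]) - set(VALID_SEX)
        if bad:
            raise ValueError(
                f"invalid sex {sorted(bad)}; allowed: {list(VALID_SEX)}"
            )
        self.table = self.table[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def status_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["status"].iloc[0]

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        sub = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleTable(sub.copy())


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"region {region!r} not of the form chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_phased_vcf(path, region: Optional[str] = None,
                    maf_floor: float = 0.0) -> GenotypeMatrix:
    """Read biallelic SNVs with MAF >= ``maf_floor`` from a VCF.

    Multiallelic sites and indels are dropped (counts logged).  The phased
    flag per call mirrors the GT separator ('|' phased, '/' unphased).
    ``region`` is chrom:start-end, 1-based inclusive.

    Raises
    ------
    EmptyResultError
        if no variant survives the filters.
    VcfParseError
        on malformed input.
    """
    from cyvcf2 import VCF

    want = parse_region(region) if region else None
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has no sample columns")

    rows_alleles, rows_phased, variants = [], [], []
    n_multi = n_indel = 0
    for rec in vcf:
        if want is not None:
            chrom, start, end = want
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_indel += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        alle = np.full((len(samples), 2), -1, dtype=np.int8)
        ph = np.zeros(len(samples), dtype=bool)
        for si, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 >= 0 and a1 >= 0:
                alle[si] = (a0, a1)
            ph[si] = bool(g[2])
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        obs = alle[alle >= 0]
        alt_freq = float(obs.mean()) if obs.size else 0.0
        v = _variant_from_alt_freq(rec.CHROM, rec.POS, vid, rec.REF,
                                   rec.ALT[0], alt_freq)
        if v.maf < maf_floor:
            continue
        variants.append(v)
        rows_alleles.append(alle)
        rows_phased.append(ph)
    if n_multi or n_indel:
        logger.info("dropped %d multiallelic and %d indel records", n_multi,
                    n_indel)
    if not variants:
        raise EmptyResultError(
            f"no biallelic SNVs with MAF >= {maf_floor} in {path}"
            + (f" region {region}" if region else "")
        )
    alleles = np.stack(rows_alleles, axis=1)  # samples x variants x 2
    phased = np.stack(rows_phased, axis=1)
    return GenotypeMatrix(variants, samples, alleles, phased)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only calls, preserving phase flags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants):
            calls = []
            for si in range(gm.n_samples):
                a0, a1 = gm.alleles[si, j]
                sep = "|" if gm.phased[si, j] else "/"
                if a0 < 0 or a1 < 0:
                    calls.append(f".{sep}.")
                else:
                    calls.append(f"{a0}{sep}{a1}")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_sample_table(path) -> SampleTable:
    """Read the tab-separated sample metadata table.

    Required header columns: sample_id, status, sex, population.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


def write_blocks_bed(obj, path, boundaries_path=None) -> None:
    """Write block spans as BED (0-based half-open); boundary intervals to a
    companion BED when ``boundaries_path`` is given.

    Accepts a single Partition, an iterable of Partitions (distinct name
    fields), or a ConsensusProfile (pan-blocks + pan-boundaries).
    """
    # imported here to keep io_formats importable without the blocks module
    from .blocks import ConsensusProfile, Partition

    def bed_line(chrom, start1, end1, name):
        return f"{chrom}\t{start1 - 1}\t{end1}\t{name}\n"

    if isinstance(obj, ConsensusProfile):
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for k, (s, e) in enumerate(obj.pan_blocks, 1):
                fh.write(bed_line(obj.chrom, s, e, f"pan_block_{k}"))
        if boundaries_path:
            with open(boundaries_path, "w") as fh:
                fh.write("#chrom\tstart\tend\tname\n")
                for k, (s, e) in enumerate(obj.pan_boundaries, 1):
                    fh.write(bed_line(obj.chrom, s, e, f"pan_boundary_{k}"))
        return

    partitions = [obj] if isinstance(obj, Partition) else list(obj)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for part in partitions:
            part.validate()
            for k, blk in enumerate(part.blocks, 1):
                name = f"{part.population}.{part.method}.block_{k}"
                fh.write(bed_line(part.chrom, blk.span[0], blk.span[1], name))
    if boundaries_path:
        with open(boundaries_path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for part in partitions:
                for k, (s, e) in enumerate(part.boundary_intervals(), 1):
                    name = f"{part.population}.{part.method}.boundary_{k}"
                    fh.write(bed_line(part.chrom, s, e, name))


def read_bed_spans(path) -> list[tuple[str, int, int, str]]:
    """Read a BED3+name file back to 1-based inclusive spans."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, *rest = line.rstrip("\n").split("\t")
            name = rest[0] if rest else ""
            out.append((chrom, int(start) + 1, int(end), name))
    return out


def write_results_tsv(df: pd.DataFrame, path, float_sig: int = 6) -> None:
    """Serialize a result table deterministically (fixed column and row
    order, floats at ``float_sig`` significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_sig}g")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
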