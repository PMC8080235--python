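"""End-to-end orchestration: LD -> blocks (x method x population) ->
consensus -> haplotype extraction at a focal SNV set -> classification and
tag-SNV search -> associations -> transmission-model fits.

Every stage is a pure function of (inputs, config, seed); the run
directory receives fixed-name TSV/BED artifacts plus a JSON summary and a
machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import association as assoc_mod
from . import blocks as blocks_mod
from . import haplotypes as hap_mod
from . import ld as ld_mod
from .io_formats import (EmptyResultError, GenotypeMatrix, SampleTable,
                         read_phased_vcf, read_sample_table, write_blocks_bed,
                         write_results_tsv)

logger = logging.getLogger("haploblocks")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its documented default."""

    # inputs (optional when a simulation scenario is used instead)
    vcf: Optional[str] = None
    sample_table: Optional[str] = None
    target_snvs: Optional[list[str]] = None  # vids of the focal SNV set
    out_dir: Optional[str] = None  # None: keep results in memory only
    seed: int = 0
    # ingest
    maf_floor: float = 0.005
    region: Optional[str] = None
    # LD
    max_pair_distance: int = ld_mod.MAX_PAIR_DISTANCE
    # CIT
    cit_strong_low: float = blocks_mod.CIT_STRONG_LOW
    cit_strong_high: float = blocks_mod.CIT_STRONG_HIGH
    cit_recomb_high: float = blocks_mod.CIT_RECOMB_HIGH
    cit_min_strong_fraction: float = blocks_mod.CIT_MIN_STRONG_FRACTION
    # FGR / SSLD
    fgr_fourth_gamete_min: float = blocks_mod.FGR_FOURTH_GAMETE_MIN
    ssld_spine_dprime: float = blocks_mod.SSLD_SPINE_DPRIME
    # consensus
    consensus_threshold: int = blocks_mod.CONSENSUS_THRESHOLD
    # association
    alpha: float = assoc_mod.ALPHA
    sex_adjusted: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def compute_partitions(gm_by_pop: dict[str, GenotypeMatrix],
                       cfg: PipelineConfig
                       ) -> tuple[dict[str, dict], list[blocks_mod.Partition]]:
    """Per-population LD matrices and the 3 x n_populations partitions."""
    ld_by_pop: dict[str, dict] = {}
    partitions: list[blocks_mod.Partition] = []
    for pop, gm in gm_by_pop.items():
        mat = ld_mod.ld_matrix(gm, max_distance=cfg.max_pair_distance)
        ld_by_pop[pop] = mat
        partitions.append(blocks_mod.partition_ssld(
            gm, mat, population=pop, spine_dprime=cfg.ssld_spine_dprime))
        partitions.append(blocks_mod.partition_cit(
            gm, mat, population=pop,
            strong_low=cfg.cit_strong_low, strong_high=cfg.cit_strong_high,
            recomb_high=cfg.cit_recomb_high,
            min_strong_fraction=cfg.cit_min_strong_fraction))
        partitions.append(blocks_mod.partition_fgr(
            gm, population=pop, fourth_gamete_min=cfg.fgr_fourth_gamete_min,
            max_distance=cfg.max_pair_distance))
    return ld_by_pop, partitions


def choose_focal_snvs(gm: GenotypeMatrix,
                      consensus: blocks_mod.ConsensusProfile,
                      cfg: PipelineConfig) -> list[str]:
    """Default focal SNV set: the variants inside the pan-block carrying
    the most markers (the analogue of the GWAS-hit-dense block)."""
    if cfg.target_snvs:
        return list(cfg.target_snvs)
    best, best_n = None, -1
    for s, e in consensus.pan_blocks:
        vids = [v.vid for v in gm.variants if s <= v.pos <= e]
        if len(vids) > best_n:
            best, best_n = vids, len(vids)
    if not best or best_n < 2:
        raise EmptyResultError("no pan-block with at least two SNVs")
    return best


def run_pipeline(gm: GenotypeMatrix, samples: SampleTable,
                 cfg: PipelineConfig,
                 out_dir: Optional[str] = None) -> dict:
    """Run every stage on an in-memory cohort; write artifacts if
    ``out_dir`` (or cfg.out_dir) is set, else to a discarded temporary
    directory; return the summary dict."""
    import tempfile

    target = out_dir or cfg.out_dir
    tmp = None
    if target is None:
        tmp = tempfile.TemporaryDirectory(prefix="haploblocks_")
        target = tmp.name
    out = Path(target)
    out.mkdir(parents=True, exist_ok=True)

    pops = sorted(samples.table["population"].unique())
    gm_by_pop = {}
    for pop in pops:
        ids = samples.table.loc[samples.table["population"] == pop,
                                "sample_id"].tolist()
        gm_by_pop[pop] = gm.subset_samples(ids).recompute_frequencies()

    stage = "ld/blocks"
    try:
        ld_by_pop, partitions = compute_partitions(gm_by_pop, cfg)
        for pop, mat in ld_by_pop.items():
            write_results_tsv(ld_mod.ld_matrix_to_frame(gm_by_pop[pop], mat),
                              out / f"ld.{pop}.tsv")
        for part in partitions:
            write_blocks_bed(part, out / f"blocks.{part.population}.{part.method}.bed")

        stage = "consensus"
        consensus = blocks_mod.pan_consensus(
            partitions, threshold=cfg.consensus_threshold)
        write_results_tsv(consensus.to_frame(), out / "consensus.tsv")
        write_blocks_bed(consensus, out / "consensus.bed",
                         boundaries_path=out / "consensus_boundaries.bed")

        stage = "haplotypes"
        focal_vids = choose_focal_snvs(gm, consensus, cfg)
        catalog, diplotypes = hap_mod.extract_haplotypes(
            gm.recompute_frequencies(), focal_vids, samples,
            cohort_by="status")
        write_results_tsv(catalog.to_frame(), out / "catalog.tsv")
        diplo_df = pd.DataFrame(
            [{"sample_id": d.sample_id, "hap_i": d.pair[0],
              "hap_j": d.pair[1]} for d in diplotypes])
        write_results_tsv(diplo_df, out / "diplotypes.tsv")
        tags = hap_mod.min_tag_snvs([e.allele_string for e in catalog.entries])

        stage = "association"
        status_of = dict(zip(samples.table["sample_id"],
                             samples.table["status"]))
        case_d = [d for d in diplotypes if status_of[d.sample_id] == "case"]
        ctrl_d = [d for d in diplotypes if status_of[d.sample_id] == "control"]
        have_cases = bool(case_d) and bool(ctrl_d)
        summary_assoc = {}
        if have_cases:
            case_ids = [d.sample_id for d in case_d]
            ctrl_ids = [d.sample_id for d in ctrl_d]
            gm_cases = gm.subset_samples(case_ids).recompute_frequencies()
            gm_ctrls = gm.subset_samples(ctrl_ids).recompute_frequencies()
            snv_res = assoc_mod.snv_association(gm_cases, gm_ctrls,
                                                family="common",
                                                alpha=cfg.alpha)
            hap_res = assoc_mod.haplotype_association(catalog, "case",
                                                      "control",
                                                      alpha=cfg.alpha)
            geno_res = assoc_mod.genotype_association(case_d, ctrl_d,
                                                      alpha=cfg.alpha)
            write_results_tsv(assoc_mod.association_frame(snv_res),
                              out / "assoc_snv.tsv")
            write_results_tsv(assoc_mod.association_frame(hap_res),
                              out / "assoc_hap.tsv")
            write_results_tsv(assoc_mod.association_frame(geno_res),
                              out / "assoc_geno.tsv")

            stage = "transmission"
            sample_order = [d.sample_id for d in diplotypes]
            sex_of = dict(zip(samples.table["sample_id"],
                              samples.table["sex"]))
            trans_frames = []
            trans_summary = {}
            for e in catalog.entries:
                copies = [list(d.pair).count(e.label) for d in diplotypes]
                pheno = [1 if status_of[s] == "case" else 0
                         for s in sample_order]
                if len(set(copies)) == 1:
                    continue
                fits, best = assoc_mod.fit_transmission_models(
                    copies, pheno,
                    sex=[sex_of[s] for s in sample_order]
                    if cfg.sex_adjusted else None)
                trans_frames.append(
                    assoc_mod.transmission_frame(e.label, fits, best))
                trans_summary[e.label] = {
                    "best_model": best,
                    "fits": {m: {"OR": f.or_, "p": f.p, "bic": f.bic,
                                 "separation": f.separation}
                             for m, f in fits.items()},
                }
            if trans_frames:
                write_results_tsv(pd.concat(trans_frames, ignore_index=True),
                                  out / "transmission.tsv")
            summary_assoc = {
                "snv_significant": [r.feature for r in snv_res if r.significant],
                "snv_bonferroni": {"m": snv_res[0].m,
                                   "threshold": snv_res[0].alpha_corrected}
                if snv_res else {},
                "haplotype_significant": [r.feature for r in hap_res
                                          if r.significant],
                "haplotype_bonferroni": {"m": hap_res[0].m,
                                         "threshold": hap_res[0].alpha_corrected}
                if hap_res else {},
                "genotype_significant": [r.feature for r in geno_res
                                         if r.significant],
                "genotype_bonferroni": {"m": geno_res[0].m,
                                        "threshold": geno_res[0].alpha_corrected}
                if geno_res else {},
                "genotype_direction": {
                    r.feature: ("enriched_in_cases"
                                if r.table.a / max(1, r.table.a + r.table.b)
                                > r.table.c / max(1, r.table.c + r.table.d)
                                else "depleted_in_cases")
                    for r in geno_res
                },
                "transmission": trans_summary,
            }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {cfg.fingerprint()}): {exc}"
        ) from exc

    summary = {
        "config_fingerprint": cfg.fingerprint(),
        "n_samples": gm.n_samples,
        "n_variants": gm.n_variants,
        "populations": pops,
        "n_partitions": len(partitions),
        "consensus": {
            "threshold": cfg.consensus_threshold,
            "max_support": consensus.max_support,
            "pan_boundaries": consensus.pan_boundaries,
            "pan_blocks": consensus.pan_blocks,
        },
        "focal_snvs": focal_vids,
        "catalog": {
            "n_haplotypes": len(catalog.entries),
            "classes": {e.label: e.hap_class for e in catalog.entries},
        },
        "tag_snvs": {"k": tags["k"],
                     "sets": [list(s) for s in tags["sets"]],
                     "redundant_groups": [list(g) for g in
                                          tags["redundant_groups"]]},
        "association": summary_assoc,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_fingerprint": cfg.fingerprint(),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if tmp is not None:
        tmp.cleanup()
    return summary


def run_from_files(cfg: PipelineConfig) -> dict:
    if not cfg.vcf or not cfg.sample_table:
        raise ValueError("config must name a VCF and a sample table")
    gm = read_phased_vcf(cfg.vcf, region=cfg.region, maf_floor=cfg.maf_floor)
    samples = read_sample_table(cfg.sample_table)
    return run_pipeline(gm, samples, cfg)
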