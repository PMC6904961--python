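"""End-to-end two-stage pipeline on synthetic cohorts.

Stage 1 simulates several discovery cohorts, derives the six early-growth
traits per child from the fitted growth models, runs the per-SNP additive
association scan per study and trait, applies QC and per-study genomic
control, and combines studies by inverse-variance meta-analysis with a
second layer of genomic control.  SNPs passing the selection rule are
followed up in independently simulated stage-2 cohorts, the two stages are
combined, significance tiers assigned, and the formula-level post-GWAS
statistics reported.

Every artifact is a plain TSV/JSON file with provenance header lines, and
the whole run is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ggio
from .assoc import QCThresholds, association_scan, genomic_control, \
    prepare_trait, qc_filter
from .growth import derive_all_traits
from .meta import SelectionConfig, classify_significance, double_gc_meta, \
    meta_analyze, select_for_followup
from .postgwas import effective_tests, variance_explained, winners_curse_mle
from .synthetic import CausalEffect, CohortConfig, SnpSpec, hwe_chisq_p, \
    simulate_study, DEFAULT_SEED, DEFAULT_SNP_PANEL
from .traits import TRAITS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full synthetic two-stage run."""

    n_individuals: int = 300
    stage1_studies: int = 4
    stage2_studies: int = 6
    traits: tuple[str, ...] = TRAITS
    snp_panel: tuple[SnpSpec, ...] = DEFAULT_SNP_PANEL
    causal_effects: dict[str, CausalEffect] = field(default_factory=dict)
    between_study_sd: float = 0.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    winners_curse_alphas: tuple[float, ...] = (1e-5, 1e-6, 1e-7)
    #: apply double genomic control; disable for demonstration panels too
    #: small for a stable inflation-factor median
    apply_gc: bool = True
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.stage1_studies < 1:
            raise ValueError("stage1_studies must be >= 1")
        if self.stage2_studies < 0:
            raise ValueError("stage2_studies must be >= 0")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")
        self._cohort_config(1).validate()

    def _cohort_config(self, n_studies: int) -> CohortConfig:
        return CohortConfig(
            n_individuals=self.n_individuals,
            n_studies=n_studies,
            snp_panel=self.snp_panel,
            causal_effects=dict(self.causal_effects),
            between_study_sd=self.between_study_sd,
            seed=self.seed,
        )

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_individuals": self.n_individuals,
            "stage1_studies": self.stage1_studies,
            "stage2_studies": self.stage2_studies,
            "traits": list(self.traits),
            "snp_panel": [dataclasses.asdict(s) for s in self.snp_panel],
            "causal_effects": {
                k: {"trait": v.trait, "beta": v.beta}
                for k, v in self.causal_effects.items()
            },
            "between_study_sd": self.between_study_sd,
            "qc": dataclasses.asdict(self.qc),
            "selection": {
                "p_strict": self.selection.p_strict,
                "p_candidate": self.selection.p_candidate,
                "candidate_snps": sorted(self.selection.candidate_snps),
                "override_snps": sorted(self.selection.override_snps),
                "genome_wide": self.selection.genome_wide,
                "suggestive": self.selection.suggestive,
            },
            "winners_curse_alphas": list(self.winners_curse_alphas),
            "apply_gc": self.apply_gc,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sel = doc.get("selection", {})
        return cls(
            n_individuals=doc.get("n_individuals", 300),
            stage1_studies=doc.get("stage1_studies", 4),
            stage2_studies=doc.get("stage2_studies", 6),
            traits=tuple(doc.get("traits", TRAITS)),
            snp_panel=tuple(SnpSpec(**s) for s in doc.get(
                "snp_panel", [dataclasses.asdict(s) for s in DEFAULT_SNP_PANEL])),
            causal_effects={
                k: CausalEffect(**v)
                for k, v in doc.get("causal_effects", {}).items()
            },
            between_study_sd=doc.get("between_study_sd", 0.0),
            qc=QCThresholds(**doc.get("qc", {})),
            selection=SelectionConfig(
                p_strict=sel.get("p_strict", 1e-7),
                p_candidate=sel.get("p_candidate", 1e-5),
                candidate_snps=frozenset(sel.get("candidate_snps", [])),
                override_snps=frozenset(sel.get("override_snps", [])),
                genome_wide=sel.get("genome_wide", 5e-8),
                suggestive=sel.get("suggestive", 5e-6),
            ),
            winners_curse_alphas=tuple(doc.get("winners_curse_alphas",
                                               (1e-5, 1e-6, 1e-7))),
            apply_gc=doc.get("apply_gc", True),
            seed=doc.get("seed", DEFAULT_SEED),
        )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full two-stage pipeline; returns a results dict and writes
    all artifacts (phenotypes, genotypes, summary stats, meta tables,
    selection report, post-GWAS report, resolved config) under ``out_dir``."""
    t0 = time.time()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    ss = np.random.SeedSequence(config.seed)
    n_total = config.stage1_studies + config.stage2_studies
    seeds = ss.generate_state(n_total + 1)
    shift_rng = np.random.default_rng(seeds[-1])

    def make_studies(count, offset, stage):
        studies = []
        for j in range(count):
            shifts = {
                snp: float(shift_rng.normal(0.0, config.between_study_sd))
                if config.between_study_sd > 0 else 0.0
                for snp in config.causal_effects
            }
            cohort = config._cohort_config(1)
            sd = simulate_study(cohort, f"stage{stage}_study{j + 1}",
                                int(seeds[offset + j]), shifts)
            studies.append(sd)
        return studies

    stage1 = make_studies(config.stage1_studies, 0, 1)
    stage2 = make_studies(config.stage2_studies, config.stage1_studies, 2)

    for sd in stage1 + stage2:
        ggio.write_phenotypes(sd.measurements, out / f"{sd.study_id}.pheno.tsv")
        ggio.write_vcf(sd.genotypes, out / f"{sd.study_id}.vcf")
    ggio.write_truth_json(out / "ground_truth.json", config._cohort_config(n_total),
                          stage1 + stage2)
    logger.info("simulated %d studies in %.1fs", n_total, time.time() - t0)

    results: dict = {"traits": {}, "lambda": {}}
    derived_pool = []

    # stage 1 GWAS per study, trait by trait
    stage1_stats: dict[str, list[pd.DataFrame]] = {t: [] for t in config.traits}
    for sd in stage1:
        t1 = time.time()
        derived, _ = derive_all_traits(sd.measurements)
        derived_pool.append(derived)
        covars = derived[["sex", "ga_weeks"]]
        panel = {s.snp_id: s for s in sd.genotypes.panel}
        for trait in config.traits:
            tv = prepare_trait(derived[trait], trait)
            stats_df = association_scan(tv, sd.genotypes.dosages, covars,
                                        study=sd.study_id, stage=1)
            stats_df["chrom"] = [panel[s].chrom for s in stats_df["snp_id"]]
            stats_df["pos"] = [panel[s].pos for s in stats_df["snp_id"]]
            stats_df["ea"] = [panel[s].effect_allele for s in stats_df["snp_id"]]
            stats_df["oa"] = [panel[s].other_allele for s in stats_df["snp_id"]]
            stats_df["hwe_p"] = [
                hwe_chisq_p(sd.genotypes.dosages[s].to_numpy())
                for s in stats_df["snp_id"]
            ]
            stats_df, _ = qc_filter(stats_df, config.qc)
            if config.apply_gc:
                stats_df, lam = genomic_control(stats_df)
            else:
                lam = float("nan")
            results["lambda"][f"{sd.study_id}:{trait}"] = lam
            ggio.write_summary_stats(
                stats_df, out / f"sumstats.{trait}.{sd.study_id}.tsv",
                provenance={"stage": 1, "study": sd.study_id, "trait": trait,
                            "lambda": f"{lam:.6f}", "seed": config.seed})
            stage1_stats[trait].append(stats_df)
        logger.info("stage-1 GWAS for %s in %.1fs", sd.study_id, time.time() - t1)

    # stage 1 meta with double GC, selection
    selected_by_trait: dict[str, pd.DataFrame] = {}
    for trait in config.traits:
        if config.apply_gc:
            meta1, lam_meta = double_gc_meta(stage1_stats[trait], stage="stage1")
        else:
            meta1 = meta_analyze(stage1_stats[trait], stage="stage1")
            lam_meta = float("nan")
        results["lambda"][f"meta:{trait}"] = lam_meta
        ggio.write_summary_stats(
            meta1, out / f"meta.stage1.{trait}.tsv",
            provenance={"stage": 1, "trait": trait, "lambda": f"{lam_meta:.6f}",
                        "seed": config.seed})
        selected = select_for_followup(meta1, config.selection)
        selected.to_csv(out / f"selection.{trait}.tsv", sep="\t", index=False)
        selected_by_trait[trait] = selected
        results["traits"][trait] = {"stage1_meta": meta1, "selected": selected}

    # stage 2 follow-up of selected SNPs, combined analysis
    for trait in config.traits:
        selected = selected_by_trait[trait]
        if len(selected) == 0 or not stage2:
            results["traits"][trait]["combined"] = pd.DataFrame()
            continue
        snp_ids = list(selected["snp_id"])
        stage2_tables = []
        for sd in stage2:
            derived, _ = derive_all_traits(sd.measurements)
            covars = derived[["sex", "ga_weeks"]]
            tv = prepare_trait(derived[trait], trait)
            stats_df = association_scan(
                tv, sd.genotypes.dosages[snp_ids], covars,
                study=sd.study_id, stage=2)
            stage2_tables.append(stats_df)
        meta2 = meta_analyze(stage2_tables, stage="stage2")
        combined = meta_analyze(
            [results["traits"][trait]["stage1_meta"]
             .loc[lambda d: d["snp_id"].isin(snp_ids)], meta2],
            stage="combined")
        combined["tier"] = classify_significance(combined, config.selection).to_numpy()
        ggio.write_summary_stats(
            combined, out / f"meta.combined.{trait}.tsv",
            provenance={"stage": "combined", "trait": trait, "seed": config.seed})
        results["traits"][trait]["combined"] = combined

    # post-GWAS report
    pooled = pd.concat(derived_pool)
    corr = pooled[list(config.traits)].corr().to_numpy()
    m_eff = effective_tests(corr, alpha=config.selection.genome_wide)
    report: dict = {
        "m_eff": m_eff.m_eff,
        "alpha_corrected": m_eff.alpha_corrected,
        "lambda": results["lambda"],
        "variance_explained": {},
        "winners_curse": {},
    }
    for trait in config.traits:
        combined = results["traits"][trait]["combined"]
        for _, row in combined.iterrows():
            if np.isfinite(row.get("eaf", np.nan)):
                report["variance_explained"][row["snp_id"]] = variance_explained(
                    row["beta"], row["eaf"])
        for _, row in results["traits"][trait]["selected"].iterrows():
            for a in config.winners_curse_alphas:
                try:
                    wc = winners_curse_mle(row["beta"], row["se"], a)
                except ValueError:
                    continue
                report["winners_curse"].setdefault(row["snp_id"], {})[f"{a:g}"] = {
                    "naive": wc.naive, "mle": wc.mle, "compromise": wc.compromise,
                }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    results["report"] = report
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return results
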