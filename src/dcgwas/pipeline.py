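"""End-to-end orchestration: simulate -> QC -> association ->
differential effects -> burden -> enrichment -> polygenic onset.

Everything is driven by one :class:`~dcgwas.simulate.SimulationConfig`
and is bit-reproducible given its seed.  Derived seeds for the
read-evidence, gene-set, permutation and summary-statistic draws are
small fixed offsets of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, burden, diff_effects, enrichment, prs, qc
from .simulate import (
    EffectSpec,
    SimulationConfig,
    gene_id,
    simulate_cohorts,
    simulate_external_sumstats,
    simulate_read_evidence,
)

N_PCS = 5
DE_THRESHOLD = 0.01
N_GWAS_EXTERNAL = 300_000


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: a case cohort of 3181 against
    disease-control cohorts of 1140 and 2450, 2000 common and 2000 rare
    variants in 500 genes, with a handful of injected case-disease loci,
    one control-A-only locus and one control-B-only locus (the signals
    the differential-effects filter exists to catch), and three genes
    with rare-variant burden effects."""
    effects = [
        EffectSpec("v00100", "case_disease", 1.30),
        EffectSpec("v00400", "case_disease", 1.25),
        EffectSpec("v00800", "case_disease", 1.45),
        EffectSpec("v01200", "ctrl_a_disease", 2.00),
        EffectSpec("v01600", "ctrl_b_disease", 1.80),
        EffectSpec("G0010", "case_disease", 1.50),
        EffectSpec("G0020", "case_disease", 1.50),
        EffectSpec("G0030", "case_disease", 1.40),
    ]
    return SimulationConfig(seed=seed, effect_table=effects)


@dataclass
class PipelineResult:
    config: SimulationConfig
    sample_sheet: pd.DataFrame
    annotations: pd.DataFrame
    truth: object
    variant_report: pd.DataFrame
    sample_report: pd.DataFrame
    kept_samples: pd.Index
    pcs: pd.DataFrame
    assoc_pooled: pd.DataFrame
    assoc_ctrl_a: pd.DataFrame
    assoc_ctrl_b: pd.DataFrame
    inflation: assoc.InflationReport
    design: diff_effects.ComparisonDesign
    de_table: pd.DataFrame
    assoc_retained: pd.DataFrame
    assoc_flagged: pd.DataFrame
    burden_tables: dict = field(default_factory=dict)
    gene_sets: dict = field(default_factory=dict)
    enrichment_results: list = field(default_factory=list)
    prs_weights: dict = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    onset_table: pd.DataFrame | None = None
    harmonization: dict = field(default_factory=dict)


def make_gene_sets(
    cfg: SimulationConfig, truth, seed: int
) -> dict[str, list[str]]:
    """Three candidate gene-sets: one seeded with the genes carrying
    true burden effects plus random genes, two purely random (sized
    like candidate lists from external common-variant studies, scaled
    to the simulated gene count)."""
    rng = np.random.default_rng(seed)
    all_genes = [gene_id(j) for j in range(cfg.n_genes)]
    effect_genes = [
        g for g in truth.genes.index
        if (truth.genes.loc[g] != 0).any()
    ]
    n1, n2, n3 = 40, 10, 25
    pool = [g for g in all_genes if g not in effect_genes]
    set1 = sorted(
        set(effect_genes)
        | set(rng.choice(pool, size=max(0, n1 - len(effect_genes)), replace=False))
    )
    set2 = sorted(rng.choice(all_genes, size=n2, replace=False))
    set3 = sorted(rng.choice(all_genes, size=n3, replace=False))
    return {"allergic_like": set1, "severe_like": set2, "lung_like": set3}


def run_pipeline(
    cfg: SimulationConfig,
    n_perm: int = 5000,
    run_prs: bool = True,
) -> PipelineResult:
    """Run the whole analysis from one config and seed."""
    matrix, sample_sheet, annotations, truth = simulate_cohorts(cfg)

    # --- read-level evidence and genotype-quality masking ---------------
    lowq = np.where(truth.variants["noisy"].to_numpy(bool), 0.10, 0.02)
    biased = set(truth.variants.index[truth.variants["ad_biased"].to_numpy(bool)])
    ad_ref, ad_alt, gq = simulate_read_evidence(
        matrix, mean_depth=cfg.mean_depth, biased_variants=biased,
        bias=cfg.ad_bias, seed=cfg.seed + 1, lowq_rates=lowq,
    )
    matrix.ad_ref, matrix.ad_alt, matrix.gq = ad_ref, ad_alt, gq
    matrix = qc.apply_gq_mask(matrix)

    # --- variant and sample QC ------------------------------------------
    kept_variants, variant_report = qc.filter_variants(matrix)
    matrix_qc = matrix.subset(variant_ids=kept_variants)
    sqc = qc.sample_qc(matrix_qc, sample_sheet)
    matrix_qc = matrix_qc.subset(sample_ids=sqc.kept)
    sheet_qc = sample_sheet.loc[sqc.kept]

    vrep = variant_report.loc[kept_variants]
    common_ids = vrep.index[vrep["common"]]
    rare_maf = vrep["maf"]

    common_mx = matrix_qc.subset(variant_ids=common_ids)
    pcs = pd.DataFrame(
        qc.compute_pcs(common_mx, N_PCS),
        index=matrix_qc.samples,
        columns=[f"PC{i + 1}" for i in range(N_PCS)],
    )
    covar = np.column_stack(
        [sheet_qc["sex"].to_numpy(float), pcs.to_numpy()]
    )

    cohort = sheet_qc["cohort"]
    is_case = (cohort == "case").to_numpy()
    is_a = (cohort == "ctrl_a").to_numpy()
    is_b = (cohort == "ctrl_b").to_numpy()

    def scan(mx, sel_ctrl):
        sel = is_case | sel_ctrl
        sub = mx.subset(sample_ids=mx.samples[sel])
        return assoc.run_gwas(sub, is_case[sel].astype(int), covar[sel])

    assoc_pooled = scan(common_mx, is_a | is_b)
    assoc_a = scan(common_mx, is_a)
    assoc_b = scan(common_mx, is_b)

    infl = assoc.inflation_report(
        assoc_pooled["p"].dropna(), int(is_case.sum()), int((is_a | is_b).sum())
    )

    design = diff_effects.ComparisonDesign(
        n_k1=int(is_case.sum()), n_k0=int(is_a.sum()),
        n_l1=int(is_case.sum()), n_l0=int(is_b.sum()),
        n_kl1=int(is_case.sum()), n_kl0=0,
    )
    de_table = diff_effects.diff_effects_table(assoc_a, assoc_b, design)
    merged = assoc_pooled.join(de_table[["z_de", "p_de"]])
    retained, flagged = diff_effects.apply_de_filter(merged, DE_THRESHOLD)

    # --- rare-variant burden, per mask, with gene-level DE ---------------
    burden_tables = {}
    for mask in (burden.LOF_HC, burden.LOF_PLUS_MODERATE):
        def bscan(sel_ctrl):
            sel = is_case | sel_ctrl
            sub = matrix_qc.subset(sample_ids=matrix_qc.samples[sel])
            return burden.run_burden(
                sub, annotations, is_case[sel].astype(int), covar[sel],
                mask=mask, maf=rare_maf,
            )

        tab = bscan(is_a | is_b)
        tab_a = bscan(is_a)
        tab_b = bscan(is_b)
        gde = diff_effects.diff_effects_table(
            tab_a.loc[tab_a["tested"]], tab_b.loc[tab_b["tested"]], design
        )
        tab = tab.join(gde[["z_de", "p_de"]])
        tab["p_bonf"] = burden.bonferroni(tab["p"])
        burden_tables[mask.name] = tab

    # --- gene-set enrichment ---------------------------------------------
    gene_sets = make_gene_sets(cfg, truth, seed=cfg.seed + 2)
    enr = []
    for mask_name, tab in burden_tables.items():
        gt = tab.loc[tab["tested"]][["p", "n_qualifying_variants", "p_de"]]
        for set_name, members in gene_sets.items():
            try:
                res = enrichment.matched_permutation(
                    gt, members, n_perm=n_perm, seed=cfg.seed + 3,
                    set_name=f"{set_name}:{mask_name}", de_threshold=DE_THRESHOLD,
                )
            except ValueError:
                # set has no tested members (or an unmatchable stratum)
                # under this mask; nothing to test
                continue
            enr.append(res)

    result = PipelineResult(
        config=cfg, sample_sheet=sheet_qc, annotations=annotations,
        truth=truth, variant_report=variant_report, sample_report=sqc.removed,
        kept_samples=sqc.kept, pcs=pcs,
        assoc_pooled=assoc_pooled, assoc_ctrl_a=assoc_a, assoc_ctrl_b=assoc_b,
        inflation=infl, design=design, de_table=de_table,
        assoc_retained=retained, assoc_flagged=flagged,
        burden_tables=burden_tables, gene_sets=gene_sets,
        enrichment_results=enr,
    )
    if not run_prs:
        return result

    # --- polygenic scores and age of onset --------------------------------
    study_variants = matrix_qc.variants
    study_maf = vrep["maf"]
    case_mx = matrix_qc.subset(sample_ids=matrix_qc.samples[is_case])
    r2 = prs.pairwise_r2_from_dosages(common_mx)
    scores = {}
    for t_i, trait in enumerate(cfg.traits):
        ss = simulate_external_sumstats(
            truth, trait, n_gwas=N_GWAS_EXTERNAL, seed=cfg.seed + 10 + t_i,
            variants=matrix.variants,
        )
        weights, rep = prs.harmonize(study_variants, ss, study_maf=study_maf)
        index_w = prs.ld_clump(weights, r2_lookup=r2)
        result.harmonization[trait] = rep
        result.prs_weights[trait] = index_w
        if len(index_w):
            scores[trait] = prs.score_samples(case_mx, index_w)
    score_df = pd.DataFrame(scores)
    result.scores = score_df

    onset_class = prs.dichotomize_onset_series(
        sheet_qc.loc[case_mx.samples, "age_onset"]
    )
    covar_case = pd.DataFrame(
        covar[is_case], index=case_mx.samples,
        columns=["sex"] + [f"PC{i + 1}" for i in range(N_PCS)],
    )
    if {"childhood", "adult"} <= set(onset_class.unique()):
        result.onset_table = prs.onset_association(
            score_df, onset_class, covariates=covar_case,
            n_scores=len(scores),
        )
    return result
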