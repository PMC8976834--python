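"""Simulation studies over the pipeline: calibration, power, recovery.

These are the repeatable numerical experiments behind the analysis
drivers: type-I error of the differential-effects test under the null,
its power against a control-disease-only locus, and parameter recovery
for single-variant and gene-burden effects.  All are pure functions of
their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diff_effects
from .assoc import run_gwas_fast
from .simulate import EffectSpec, SimulationConfig, simulate_cohorts

DE_THRESHOLD = 0.01

#: Study-sized cohorts: shared cases vs the two disease-control cohorts.
N_CASE, N_CTRL_A, N_CTRL_B = 3181, 1140, 2450


def _null_config(seed: int, m_common: int, **kw) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_case=kw.pop("n_case", N_CASE),
        n_ctrl_a=kw.pop("n_ctrl_a", N_CTRL_A),
        n_ctrl_b=kw.pop("n_ctrl_b", N_CTRL_B),
        m_common=m_common,
        m_rare_per_gene=1,
        n_genes=1,
        frac_ad_biased=0.0,
        frac_noisy=0.0,
        frac_hwe_bad=0.0,
        **kw,
    )


def _shared_case_design(n_case: int, n_a: int, n_b: int) -> diff_effects.ComparisonDesign:
    return diff_effects.ComparisonDesign(
        n_k1=n_case, n_k0=n_a, n_l1=n_case, n_l0=n_b,
        n_kl1=n_case, n_kl0=0,
    )


@dataclass
class CalibrationResult:
    n_variants: int
    n_flagged: int
    fraction_flagged: float
    threshold: float
    corr: float
    p_de: np.ndarray


def de_null_calibration(
    n_variants: int = 20_000,
    seed: int = 0,
    n_case: int = N_CASE,
    n_ctrl_a: int = N_CTRL_A,
    n_ctrl_b: int = N_CTRL_B,
    threshold: float = DE_THRESHOLD,
) -> CalibrationResult:
    """Empirical type-I error of the differential-effects test.

    Simulates ``n_variants`` common variants (MAF uniform on the
    configured range, Hardy-Weinberg genotypes) with no effect on any
    disease, assembles the shared-case / disjoint-control cohorts, runs
    both case-vs-control logistic scans, applies the test with the
    design's overlap correlation, and reports the fraction of variants
    flagged at the threshold.
    """
    cfg = _null_config(
        seed, n_variants, n_case=n_case, n_ctrl_a=n_ctrl_a, n_ctrl_b=n_ctrl_b
    )
    matrix, sheet, _, _ = simulate_cohorts(cfg)
    common = matrix.subset(variant_ids=matrix.variants.index[:n_variants])
    cohort = sheet["cohort"].to_numpy()
    is_case = cohort == "case"

    def scan(label):
        sel = is_case | (cohort == label)
        sub = common.subset(sample_ids=common.samples[sel])
        return run_gwas_fast(sub, is_case[sel].astype(int))

    tab_a, tab_b = scan("ctrl_a"), scan("ctrl_b")
    design = _shared_case_design(n_case, n_ctrl_a, n_ctrl_b)
    de = diff_effects.diff_effects_table(tab_a, tab_b, design)
    p = de["p_de"].to_numpy(float)
    p = p[np.isfinite(p)]
    n_flagged = int((p < threshold).sum())
    return CalibrationResult(
        n_variants=p.size, n_flagged=n_flagged,
        fraction_flagged=n_flagged / p.size, threshold=threshold,
        corr=diff_effects.overlap_correlation(design), p_de=p,
    )


def de_power_planted(
    n_reps: int = 200,
    odds_ratio: float = 2.0,
    phenotype: str = "ctrl_a_disease",
    seed: int = 0,
    threshold: float = DE_THRESHOLD,
) -> float:
    """Power of the differential-effects filter against a planted
    control-disease-only locus (e.g. an OR-2 effect confined to the
    first control disease).  Returns the fraction of replicates in
    which the locus is flagged at the threshold."""
    design = _shared_case_design(N_CASE, N_CTRL_A, N_CTRL_B)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cfg = _null_config(int(rng.integers(2**31 - 1)), 1)
        cfg.effect_table = [EffectSpec("v00000", phenotype, odds_ratio)]
        matrix, sheet, _, _ = simulate_cohorts(cfg)
        common = matrix.subset(variant_ids=matrix.variants.index[:1])
        cohort = sheet["cohort"].to_numpy()
        is_case = cohort == "case"

        def scan(label):
            sel = is_case | (cohort == label)
            sub = common.subset(sample_ids=common.samples[sel])
            return run_gwas_fast(sub, is_case[sel].astype(int))

        de = diff_effects.diff_effects_table(scan("ctrl_a"), scan("ctrl_b"), design)
        if float(de["p_de"].iloc[0]) < threshold:
            hits += 1
    return hits / n_reps


def variant_effect_recovery(
    n_reps: int = 200,
    odds_ratio: float = 1.3,
    maf: float = 0.3,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which a planted common-variant effect
    is recovered within 2 standard errors, in a case vs pooled-control
    scan at study size (3181 vs 3590)."""
    beta_true = float(np.log(odds_ratio))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cfg = _null_config(int(rng.integers(2**31 - 1)), 1,
                           maf_range_common=(maf, maf))
        cfg.effect_table = [EffectSpec("v00000", "case_disease", odds_ratio)]
        matrix, sheet, _, _ = simulate_cohorts(cfg)
        common = matrix.subset(variant_ids=matrix.variants.index[:1])
        is_case = (sheet["cohort"] == "case").to_numpy().astype(int)
        tab = run_gwas_fast(common, is_case)
        b, se = float(tab["beta"].iloc[0]), float(tab["se"].iloc[0])
        if np.isfinite(b) and abs(b - beta_true) < 2.0 * se:
            hits += 1
    return hits / n_reps


def burden_effect_recovery(
    n_reps: int = 200,
    odds_ratio: float = 1.5,
    seed: int = 0,
    min_carriers: int = 50,
) -> float:
    """Fraction of replicates in which a planted gene-burden effect is
    recovered within 2 standard errors (case vs pooled controls, genes
    with at least ``min_carriers`` carriers)."""
    from .assoc import fit_additive_logistic
    from .burden import carrier_status

    beta_true = float(np.log(odds_ratio))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_reps:
        cfg = _null_config(int(rng.integers(2**31 - 1)), 1)
        cfg.m_rare_per_gene = 3
        cfg.maf_max_rare = 0.01
        cfg.effect_table = [EffectSpec("G0000", "case_disease", odds_ratio)]
        matrix, sheet, annotations, _ = simulate_cohorts(cfg)
        carrier = carrier_status(matrix, list(annotations.index))
        if int(carrier.sum()) < min_carriers:
            continue  # gene too sparse for the recovery condition
        is_case = (sheet["cohort"] == "case").to_numpy().astype(int)
        r = fit_additive_logistic(carrier, is_case)
        done += 1
        if np.isfinite(r.beta) and abs(r.beta - beta_true) < 2.0 * r.se:
            hits += 1
    return hits / n_reps
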