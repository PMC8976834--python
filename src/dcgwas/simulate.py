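"""Synthetic cohorts with the structure of a case / dual disease-control study.

The generator emulates a sequencing study in which one case cohort is
compared against two disjoint disease-control cohorts drawn from
patients with unrelated diseases.  Individuals are drawn from a
population with Hardy-Weinberg genotypes at configured allele
frequencies; three binary disease phenotypes (the case disease and the
two control diseases) follow logistic models whose intercepts are
solved numerically to hit configured prevalences; cohorts are assembled
by rejection sampling, with disease priority case > control A >
control B so cohorts are disjoint and controls never carry the case
disease.  Rare variants are grouped into genes with optional gene-level
burden effects; per-genotype read depths, allele depths and genotype
qualities are generated separately; external GWAS summary statistics
for scored traits are derived from the ground truth with sampling noise
and deliberate allele-orientation flips.

Identifier scheme (deterministic given the config): common variants
``v00000``..., rare variants ``r00000``..., genes ``G0000``...,
samples ``S000000``....  Effect-table entries reference these ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, TruthLedger

PHENOTYPES = ("case_disease", "ctrl_a_disease", "ctrl_b_disease")

#: Traits for which external summary statistics are simulated: the case
#: disease itself, allergy, blood eosinophil count and four lung
#: function measures.
DEFAULT_TRAITS = ("asthma", "allergy", "eosinophil", "fev1", "fvc", "pef", "fev1_fvc")

_CHROMS = [str(c) for c in range(1, 23)]
_POS_START = 1_000_000
_POS_STEP = 300_000
_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class EffectSpec:
    """One injected effect: a variant or gene id, the phenotype it
    affects, and its per-allele (or per-carrier) odds ratio."""

    target: str
    phenotype: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass
class OnsetModel:
    """Links latent trait scores to the probability of childhood onset.

    ``trait_coefs`` multiply within-case standardised latent scores in
    logit P(childhood onset); positive coefficients push toward
    childhood onset.  ``intermediate_frac`` of cases get an onset age
    in the excluded 13-24 band; ``age_available_frac`` of cases have a
    recorded age at all.
    """

    intercept: float = -0.1
    trait_coefs: dict = field(
        default_factory=lambda: {
            "allergy": 0.9, "asthma": 0.7, "fev1_fvc": -0.6, "pef": -0.5,
        }
    )
    intermediate_frac: float = 0.15
    age_available_frac: float = 0.6


@dataclass
class SimulationConfig:
    seed: int = 0
    n_case: int = 3181
    n_ctrl_a: int = 1140
    n_ctrl_b: int = 2450
    m_common: int = 2000
    m_rare_per_gene: int = 4
    n_genes: int = 500
    maf_range_common: tuple = (0.05, 0.5)
    maf_max_rare: float = 0.01
    effect_table: list = field(default_factory=list)
    mean_depth: float = 30.0
    onset_model: OnsetModel = field(default_factory=OnsetModel)
    prevalence: dict = field(
        default_factory=lambda: {
            "case_disease": 0.10, "ctrl_a_disease": 0.05, "ctrl_b_disease": 0.08,
        }
    )
    #: number of causal common variants per scored trait and the SD of
    #: their per-allele effects
    trait_n_loci: int = 25
    trait_beta_sd: float = 0.15
    traits: tuple = DEFAULT_TRAITS
    #: log-OR of male sex on the case disease (observed covariate)
    sex_effect: float = 0.1
    #: log-OR per SD of each latent confounder axis, all phenotypes
    confounder_effect: float = 0.0
    #: genotyping-artifact rates (set to 0 for clean null simulations)
    frac_ad_biased: float = 0.01
    ad_bias: float = 0.25
    frac_noisy: float = 0.02
    frac_hwe_bad: float = 0.01
    hwe_inbreeding: float = 0.5
    #: optional exchangeable-correlation LD blocks over common variants
    ld_block_size: int = 0
    ld_block_r: float = 0.8
    #: rejection-sampling controls
    batch_size: int = 20_000
    max_batches: int = 80

    def __post_init__(self) -> None:
        for name in ("n_case", "n_ctrl_a", "n_ctrl_b", "m_common",
                     "m_rare_per_gene", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range_common
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range_common must lie within (0, 0.5]")
        if not (0 < self.maf_max_rare <= 0.5):
            raise ValueError("maf_max_rare must lie in (0, 0.5]")
        for eff in self.effect_table:
            if eff.odds_ratio <= 0:
                raise ValueError("odds ratios must be positive")

    @property
    def m_rare(self) -> int:
        return self.n_genes * self.m_rare_per_gene

    @property
    def m_total(self) -> int:
        return self.m_common + self.m_rare


def common_variant_id(j: int) -> str:
    return f"v{j:05d}"


def rare_variant_id(j: int) -> str:
    return f"r{j:05d}"


def gene_id(j: int) -> str:
    return f"G{j:04d}"


def _variant_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign ids, coordinates, alleles and kinds to all variants."""
    ids, chroms, poss, kinds, genes = [], [], [], [], []
    per_chrom = -(-cfg.m_common // len(_CHROMS))  # ceil
    for j in range(cfg.m_common):
        ids.append(common_variant_id(j))
        chroms.append(_CHROMS[j // per_chrom])
        poss.append(_POS_START + (j % per_chrom) * _POS_STEP)
        kinds.append("common")
        genes.append("")
    # rare variants clustered by gene, genes laid out beyond the common block
    gene_chrom_span = per_chrom * _POS_STEP + _POS_START
    for g in range(cfg.n_genes):
        chrom = _CHROMS[g % len(_CHROMS)]
        gstart = gene_chrom_span + 10_000_000 + (g // len(_CHROMS)) * 100_000
        for k in range(cfg.m_rare_per_gene):
            j = g * cfg.m_rare_per_gene + k
            ids.append(rare_variant_id(j))
            chroms.append(chrom)
            poss.append(gstart + k * 1_000)
            kinds.append("rare")
            genes.append(gene_id(g))
    ref = rng.choice(_BASES, size=len(ids))
    alt = np.array([
        rng.choice([b for b in _BASES if b != r]) for r in ref
    ])
    return pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": ref, "alt": alt,
         "kind": kinds, "gene": genes},
        index=pd.Index(ids, name="variant_id"),
    )


def _draw_genotypes(
    n: int,
    maf: np.ndarray,
    rng: np.random.Generator,
    hwe_bad: np.ndarray | None = None,
    inbreeding: float = 0.0,
    ld_block_size: int = 0,
    ld_block_r: float = 0.0,
    n_common: int = 0,
) -> np.ndarray:
    """Hardy-Weinberg genotype draws; optional het-deficit artifact
    variants and optional exchangeable-correlation LD blocks over the
    first ``n_common`` variants (Gaussian copula preserving the
    marginal HWE genotype distribution)."""
    m = maf.size
    # Binomial(2, f) as a sum of two Bernoulli draws, chunked over
    # variants to bound the intermediate float allocations
    g = np.empty((n, m), dtype=np.int8)
    step = max(1, 8_000_000 // max(n, 1))
    for s in range(0, m, step):
        e = min(s + step, m)
        p = maf[None, s:e]
        g[:, s:e] = (rng.random((n, e - s)) < p).astype(np.int8) + (
            rng.random((n, e - s)) < p
        ).astype(np.int8)
    if ld_block_size and ld_block_size > 1 and n_common > 1:
        r = ld_block_r
        q0 = (1 - maf) ** 2
        q1 = 2 * maf * (1 - maf)
        for start in range(0, n_common, ld_block_size):
            stop = min(start + ld_block_size, n_common)
            width = stop - start
            shared = rng.standard_normal(n)
            z = (
                np.sqrt(r) * shared[:, None]
                + np.sqrt(1 - r) * rng.standard_normal((n, width))
            )
            u = stats.norm.cdf(z)
            t0 = q0[start:stop][None, :]
            t1 = (q0 + q1)[start:stop][None, :]
            g[:, start:stop] = ((u > t0).astype(np.int8)
                                + (u > t1).astype(np.int8))
    if hwe_bad is not None and hwe_bad.any() and inbreeding > 0:
        f = maf[hwe_bad]
        F = inbreeding
        p0 = (1 - f) ** 2 + F * f * (1 - f)
        p1 = 2 * f * (1 - f) * (1 - F)
        u = rng.random((n, int(hwe_bad.sum())))
        g[:, hwe_bad] = ((u > p0[None, :]).astype(np.int8)
                         + (u > (p0 + p1)[None, :]).astype(np.int8))
    return g


def _solve_intercept(eta_no_intercept: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean sigmoid(c + eta) equals the prevalence."""

    def f(c):
        return np.mean(1.0 / (1.0 + np.exp(-(c + eta_no_intercept)))) - prevalence

    return float(optimize.brentq(f, -25.0, 25.0, xtol=1e-10))


def simulate_cohorts(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Generate (genotypes, sample sheet, variant annotations, truth).

    Raises ``RuntimeError`` if the configured cohort sizes cannot be
    reached within ``cfg.max_batches`` rejection-sampling batches.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _variant_layout(cfg, rng)
    m_common, m_rare = cfg.m_common, cfg.m_rare
    maf = np.empty(cfg.m_total)
    lo, hi = cfg.maf_range_common
    maf[:m_common] = rng.uniform(lo, hi, size=m_common)
    maf[m_common:] = rng.uniform(cfg.maf_max_rare / 20, cfg.maf_max_rare, size=m_rare)
    variants["true_maf"] = maf

    # --- per-variant and per-gene true effects -------------------------
    beta_pheno = {ph: np.zeros(cfg.m_total) for ph in PHENOTYPES}
    gene_beta = {ph: np.zeros(cfg.n_genes) for ph in PHENOTYPES}
    vindex = {vid: j for j, vid in enumerate(variants.index)}
    gindex = {gene_id(j): j for j in range(cfg.n_genes)}
    for eff in cfg.effect_table:
        b = float(np.log(eff.odds_ratio))
        if eff.target in vindex:
            beta_pheno[eff.phenotype][vindex[eff.target]] += b
        elif eff.target in gindex:
            gene_beta[eff.phenotype][gindex[eff.target]] += b
        else:
            raise ValueError(f"effect target {eff.target!r} is not a simulated id")

    # trait architectures over common variants
    trait_beta = {}
    for t in cfg.traits:
        b = np.zeros(m_common)
        loci = rng.choice(m_common, size=min(cfg.trait_n_loci, m_common), replace=False)
        b[loci] = rng.normal(0.0, cfg.trait_beta_sd, size=loci.size)
        trait_beta[t] = b

    # artifact variants (genotyping noise injected downstream)
    hwe_bad = np.zeros(cfg.m_total, dtype=bool)
    n_hwe_bad = int(round(cfg.frac_hwe_bad * m_common))
    if n_hwe_bad:
        hwe_bad[rng.choice(m_common, size=n_hwe_bad, replace=False)] = True
    ad_biased = np.zeros(cfg.m_total, dtype=bool)
    n_biased = int(round(cfg.frac_ad_biased * m_common))
    if n_biased:
        ad_biased[rng.choice(m_common, size=n_biased, replace=False)] = True
    noisy = np.zeros(cfg.m_total, dtype=bool)
    n_noisy = int(round(cfg.frac_noisy * cfg.m_total))
    if n_noisy:
        noisy[rng.choice(cfg.m_total, size=n_noisy, replace=False)] = True

    gene_cols = np.array(
        [gindex[g] if g else -1 for g in variants["gene"]], dtype=int
    )
    rare_cols = np.nonzero(gene_cols >= 0)[0]

    # --- rejection sampling --------------------------------------------
    need = {"case": cfg.n_case, "ctrl_a": cfg.n_ctrl_a, "ctrl_b": cfg.n_ctrl_b}
    got: dict[str, list] = {k: [] for k in need}
    n_got = {k: 0 for k in need}
    intercepts: dict[str, float] = {}
    centers = 2.0 * maf

    # only columns carrying effects enter the linear predictors; this
    # keeps the float work tiny even for genome-scale null simulations
    beta_mat = np.column_stack([beta_pheno[ph] for ph in PHENOTYPES])
    eff_cols = np.nonzero(np.any(beta_mat != 0, axis=1))[0]
    trait_mat = np.column_stack([trait_beta[t] for t in cfg.traits])
    tcols = np.nonzero(np.any(trait_mat != 0, axis=1))[0]
    gene_mat = np.column_stack([gene_beta[ph] for ph in PHENOTYPES])
    need_carrier = bool(np.any(gene_mat != 0))

    for _batch in range(cfg.max_batches):
        if all(n_got[k] >= need[k] for k in need):
            break
        n = cfg.batch_size
        G = _draw_genotypes(
            n, maf, rng, hwe_bad=hwe_bad, inbreeding=cfg.hwe_inbreeding,
            ld_block_size=cfg.ld_block_size, ld_block_r=cfg.ld_block_r,
            n_common=m_common,
        )
        sex = rng.integers(0, 2, size=n).astype(np.int8)
        conf = rng.standard_normal((n, 5))

        eta_gen = np.zeros((n, len(PHENOTYPES)))
        if eff_cols.size:
            eta_gen = (
                G[:, eff_cols].astype(float) - centers[eff_cols][None, :]
            ) @ beta_mat[eff_cols]
        if need_carrier:
            carrier = np.zeros((cfg.n_genes, n))
            rc = (G[:, rare_cols] > 0).T.astype(float)
            np.maximum.at(carrier, gene_cols[rare_cols], rc)
            eta_gen = eta_gen + carrier.T @ gene_mat

        status = {}
        for j, ph in enumerate(PHENOTYPES):
            eta = eta_gen[:, j].copy()
            if ph == "case_disease":
                eta += cfg.sex_effect * (sex - 0.5)
            if cfg.confounder_effect:
                eta += cfg.confounder_effect * conf[:, 0]
            if ph not in intercepts:
                intercepts[ph] = _solve_intercept(eta, cfg.prevalence[ph])
            prob = 1.0 / (1.0 + np.exp(-(intercepts[ph] + eta)))
            status[ph] = rng.random(n) < prob

        cohort = np.full(n, "", dtype=object)
        cohort[status["case_disease"]] = "case"
        free = cohort == ""
        cohort[free & status["ctrl_a_disease"]] = "ctrl_a"
        free = cohort == ""
        cohort[free & status["ctrl_b_disease"]] = "ctrl_b"

        zscores = np.zeros((n, len(cfg.traits)))
        if tcols.size:
            zscores = (
                G[:, tcols].astype(float) - centers[tcols][None, :]
            ) @ trait_mat[tcols]
        status_arr = np.column_stack([status[ph] for ph in PHENOTYPES])
        for k in need:
            short = need[k] - n_got[k]
            if short <= 0:
                continue
            rows = np.nonzero(cohort == k)[0][:short]
            if rows.size:
                got[k].append(
                    (G[rows].copy(), sex[rows].copy(), conf[rows].copy(),
                     zscores[rows].copy(), status_arr[rows].copy())
                )
                n_got[k] += rows.size
    shortfall = {k: need[k] - n_got[k] for k in need if n_got[k] < need[k]}
    if shortfall:
        raise RuntimeError(
            f"unreachable cohort sizes after {cfg.max_batches} batches: "
            f"missing {shortfall} (disease too rare for the configured n?)"
        )

    order = [("case", cfg.n_case), ("ctrl_a", cfg.n_ctrl_a), ("ctrl_b", cfg.n_ctrl_b)]
    n_total = sum(c for _, c in order)
    dosages = np.empty((n_total, cfg.m_total), dtype=np.int8)
    sex_col = np.empty(n_total, dtype=np.int8)
    conf_cols = np.empty((n_total, 5))
    z_cols = np.empty((n_total, len(cfg.traits)))
    status_cols = np.empty((n_total, len(PHENOTYPES)), dtype=bool)
    cohort_col = []
    i = 0
    for k, cnt in order:
        blocks = got[k]
        taken = 0
        for Gb, sb, cb, zb, stb in blocks:
            take = min(cnt - taken, Gb.shape[0])
            dosages[i:i + take] = Gb[:take]
            sex_col[i:i + take] = sb[:take]
            conf_cols[i:i + take] = cb[:take]
            z_cols[i:i + take] = zb[:take]
            status_cols[i:i + take] = stb[:take]
            cohort_col.extend([k] * take)
            i += take
            taken += take
            if taken >= cnt:
                break
    sample_ids = pd.Index([f"S{j:06d}" for j in range(n_total)], name="sample_id")

    ancestry = np.clip(rng.beta(40, 2, size=n_total), 0, 1)

    # --- age of onset for cases ----------------------------------------
    om = cfg.onset_model
    age = np.full(n_total, np.nan)
    onset_class = np.array(["none"] * n_total, dtype=object)
    child_prob = np.full(n_total, np.nan)
    case_rows = np.arange(cfg.n_case)
    zc = z_cols[case_rows]
    zsd = zc.std(axis=0)
    zstd = (zc - zc.mean(axis=0)) / np.where(zsd > 0, zsd, 1.0)
    eta = np.full(cfg.n_case, om.intercept)
    for t, coef in om.trait_coefs.items():
        if t in cfg.traits:
            eta += coef * zstd[:, cfg.traits.index(t)]
    pc = 1.0 / (1.0 + np.exp(-eta))
    child_prob[case_rows] = pc
    u = rng.random(cfg.n_case)
    is_child = u < pc
    inter = rng.random(cfg.n_case) < om.intermediate_frac
    a = np.where(
        inter,
        rng.integers(13, 25, size=cfg.n_case),
        np.where(is_child, rng.integers(0, 13, size=cfg.n_case),
                 rng.integers(25, 61, size=cfg.n_case)),
    ).astype(float)
    onset_class[case_rows] = np.where(inter, "excluded",
                                      np.where(is_child, "childhood", "adult"))
    has_age = rng.random(cfg.n_case) < om.age_available_frac
    a[~has_age] = np.nan
    age[case_rows] = a

    sample_sheet = pd.DataFrame(
        {
            "cohort": cohort_col,
            "sex": sex_col,
            "ancestry_frac": ancestry,
            "age_onset": age,
            **{f"conf{j + 1}": conf_cols[:, j] for j in range(5)},
        },
        index=sample_ids,
    )

    # --- annotations for rare variants ---------------------------------
    rare_ids = variants.index[variants["kind"] == "rare"]
    impact = rng.choice(
        ["HIGH", "MODERATE", "LOW"], size=len(rare_ids), p=[0.15, 0.55, 0.30]
    )
    lof_hc = (impact == "HIGH") & (rng.random(len(rare_ids)) < 0.7)
    score = rng.random(len(rare_ids))
    annotations = pd.DataFrame(
        {
            "gene": variants.loc[rare_ids, "gene"],
            "impact": impact,
            "lof_hc": lof_hc,
            "score": score,
            "maf": variants.loc[rare_ids, "true_maf"],
        },
        index=rare_ids,
    )

    # --- truth ledger ---------------------------------------------------
    tv = pd.DataFrame(
        {
            "true_maf": maf,
            "hwe_bad": hwe_bad,
            "ad_biased": ad_biased,
            "noisy": noisy,
            **{f"beta_{ph}": beta_pheno[ph] for ph in PHENOTYPES},
        },
        index=variants.index,
    )
    for t in cfg.traits:
        col = np.zeros(cfg.m_total)
        col[:m_common] = trait_beta[t]
        tv[f"beta_trait_{t}"] = col
    tg = pd.DataFrame(
        {ph: gene_beta[ph] for ph in PHENOTYPES},
        index=pd.Index([gene_id(j) for j in range(cfg.n_genes)], name="gene"),
    )
    ts = pd.DataFrame(
        {
            "cohort": cohort_col,
            **{ph: status_cols[:, j] for j, ph in enumerate(PHENOTYPES)},
            **{f"z_{t}": z_cols[:, j] for j, t in enumerate(cfg.traits)},
            "childhood_prob": child_prob,
            "onset_class": onset_class,
        },
        index=sample_ids,
    )
    truth = TruthLedger(
        variants=tv, genes=tg, samples=ts,
        prevalence={**cfg.prevalence, "intercepts": intercepts},
    )

    matrix = GenotypeMatrix(dosages=dosages, samples=sample_ids, variants=variants)
    return matrix, sample_sheet, annotations, truth


def simulate_read_evidence(
    matrix: GenotypeMatrix,
    mean_depth: float = 30.0,
    biased_variants: set | None = None,
    bias: float = 0.25,
    seed: int = 0,
    lowq_rates: np.ndarray | None = None,
    base_lowq_rate: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-genotype (ref depth, alt depth, genotype quality).

    Depth is Poisson(mean_depth); alternate reads at heterozygotes are
    Binomial(depth, 1/2), or Binomial(depth, bias) at variants in
    ``biased_variants``; homozygotes draw alt fractions near 0 / 1
    (sequencing-error rate 0.002).  GQ is depth-scaled with a small
    low-quality mixture component (rate ``base_lowq_rate`` per genotype,
    overridable per variant via ``lowq_rates``) that lands below the
    usual GQ < 20 mask.
    """
    if not (0 < bias < 1):
        raise ValueError("bias must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n, m = matrix.dosages.shape
    depth = rng.poisson(mean_depth, size=(n, m))
    frac = np.full((n, m), 0.002)
    frac[matrix.dosages == 2] = 0.998
    het = matrix.dosages == 1
    frac[het] = 0.5
    if biased_variants:
        cols = matrix.variants.index.get_indexer(pd.Index(sorted(biased_variants)))
        if (cols < 0).any():
            raise KeyError("biased variant not in matrix")
        sub = het[:, cols]
        fsub = frac[:, cols]
        fsub[sub] = bias
        frac[:, cols] = fsub
    ad_alt = rng.binomial(depth, frac).astype(np.int32)
    ad_ref = (depth - ad_alt).astype(np.int32)

    gq = np.clip(rng.normal(2.2 * depth, 12.0), 0, 99)
    rate = np.full(m, base_lowq_rate) if lowq_rates is None else np.asarray(lowq_rates)
    lowq = rng.random((n, m)) < rate[None, :]
    gq_low = rng.integers(0, 20, size=(n, m))
    gq = np.where(lowq, gq_low, gq).astype(np.int16)
    gq[depth == 0] = 0
    return ad_ref, ad_alt, gq


def simulate_external_sumstats(
    truth: TruthLedger,
    trait: str,
    n_gwas: int,
    seed: int = 0,
    flip_frac: float = 0.3,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """External GWAS summary statistics for one scored trait.

    Per common variant: estimate = true effect + normal noise with
    standard error 1 / sqrt(2 n f (1 - f)) (standardised-trait Wald
    scale), p from the Wald statistic.  A fraction of rows is emitted
    with flipped allele orientation (effect allele = study reference,
    sign negated) to exercise harmonisation; strand-ambiguous variants
    arise naturally from the simulated ref/alt alleles.
    """
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    col = f"beta_trait_{trait}"
    if col not in truth.variants.columns:
        raise KeyError(f"trait {trait!r} not in truth ledger")
    rng = np.random.default_rng(seed)
    tv = truth.variants
    common = tv.index[tv.index.str.startswith("v")]
    beta_true = tv.loc[common, col].to_numpy(float)
    f = tv.loc[common, "true_maf"].to_numpy(float)
    se = 1.0 / np.sqrt(2.0 * n_gwas * f * (1.0 - f))
    beta_hat = beta_true + rng.normal(0.0, se)
    p = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)

    if variants is None:
        raise ValueError("variant table with alleles/positions is required")
    va = variants.loc[common]
    ea = va["alt"].to_numpy(object).copy()
    oa = va["ref"].to_numpy(object).copy()
    flip = rng.random(len(common)) < flip_frac
    ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
    beta_out = np.where(flip, -beta_hat, beta_hat)
    return pd.DataFrame(
        {
            "variant_id": common,
            "chrom": va["chrom"].to_numpy(),
            "pos": va["pos"].to_numpy(),
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta_out,
            "se": se,
            "p": p,
            "n": n_gwas,
        }
    )
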