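"""Polygenic scores from external GWAS and age-of-onset association.

External summary statistics are harmonised to the study's allele coding
(sign-flipping weights coded on the other allele, dropping
strand-ambiguous A/T and C/G pairs, the HLA window, and low-frequency
variants), clumped to independent genome-wide-significant index
variants (P < 5e-8, pairwise r^2 < 0.05, >= 1 Mb apart), and summed as
dosage x log-odds per sample.  Asthma age of onset is dichotomised into
childhood (<= 12 years) vs adult (>= 25 years) onset and regressed on
each standardised score with sex and five principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .containers import MISSING, GenotypeMatrix

#: Strand-ambiguous allele pairs (indistinguishable from their
#: reverse-complement, so orientation cannot be verified).
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: Extended MHC exclusion window, GRCh38 coordinates (configurable).
HLA_WINDOW = ("6", 25_000_000, 34_000_000)

P_THRESHOLD = 5e-8
R2_MAX = 0.05
WINDOW_BP = 1_000_000
MAF_MIN = 0.01

CHILDHOOD_MAX_AGE = 12
ADULT_MIN_AGE = 25


@dataclass
class HarmonizationReport:
    n_input: int
    n_matched: int
    dropped: dict = field(default_factory=dict)  # reason -> count


def harmonize(
    study_variants: pd.DataFrame,
    sumstats: pd.DataFrame,
    study_maf: pd.Series | None = None,
    hla_window: tuple[str, int, int] = HLA_WINDOW,
    maf_min: float = MAF_MIN,
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align external summary statistics to the study's alt-allele coding.

    ``study_variants`` is indexed by variant id with ``chrom``, ``pos``,
    ``ref``, ``alt`` columns; ``sumstats`` carries ``variant_id``,
    ``effect_allele``, ``other_allele``, ``beta``, ``p`` (plus ``se`` if
    available).  Weights coded on the study's reference allele have
    their sign flipped so every returned weight applies to the
    alternate allele.  Dropped variants are counted per reason
    (not_in_study, allele_mismatch, strand_ambiguous, hla_region,
    low_maf); count(in) = count(matched) + sum of drops.
    """
    ss = sumstats.set_index("variant_id") if "variant_id" in sumstats.columns else sumstats
    dropped = {
        "not_in_study": 0, "allele_mismatch": 0, "strand_ambiguous": 0,
        "hla_region": 0, "low_maf": 0,
    }
    rows = []
    hla_chrom, hla_lo, hla_hi = hla_window
    for vid, row in ss.iterrows():
        vid = str(vid)
        if vid not in study_variants.index:
            dropped["not_in_study"] += 1
            continue
        sv = study_variants.loc[vid]
        ref, alt = str(sv["ref"]), str(sv["alt"])
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        if (ea, oa) == (alt, ref):
            weight = float(row["beta"])
        elif (ea, oa) == (ref, alt):
            weight = -float(row["beta"])
        else:
            dropped["allele_mismatch"] += 1
            continue
        if (ref, alt) in AMBIGUOUS_PAIRS:
            dropped["strand_ambiguous"] += 1
            continue
        if str(sv["chrom"]) == hla_chrom and hla_lo <= int(sv["pos"]) <= hla_hi:
            dropped["hla_region"] += 1
            continue
        if study_maf is not None:
            f = float(study_maf.get(vid, np.nan))
            if not np.isfinite(f) or f <= maf_min:
                dropped["low_maf"] += 1
                continue
        rows.append(
            (vid, str(sv["chrom"]), int(sv["pos"]), alt, weight, float(row["p"]))
        )
    weights = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "effect_allele", "weight", "p"]
    ).set_index("variant_id")
    report = HarmonizationReport(len(ss), len(weights), dropped)
    assert report.n_input == report.n_matched + sum(dropped.values())
    return weights, report


def ld_clump(
    weights: pd.DataFrame,
    r2_lookup=None,
    p_threshold: float = P_THRESHOLD,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Greedy selection of independent index variants.

    Significant variants (p < p_threshold) are visited by ascending p;
    a variant is accepted iff every previously accepted variant on the
    same chromosome is both >= window_bp away AND in low LD
    (r^2 < r2_max) with it — proximity or LD alone excludes it.
    ``r2_lookup(id_a, id_b)`` returns pairwise r^2; None means no LD
    information (treated as 0, leaving the distance rule).
    """
    sig = weights.loc[weights["p"].to_numpy(float) < p_threshold]
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    accepted: list[str] = []
    for vid, row in sig.iterrows():
        ok = True
        for aid in accepted:
            arow = sig.loc[aid]
            if str(arow["chrom"]) != str(row["chrom"]):
                continue
            if abs(int(arow["pos"]) - int(row["pos"])) < window_bp:
                ok = False
                break
            if r2_lookup is not None and r2_lookup(str(vid), str(aid)) >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(str(vid))
    return weights.loc[accepted]


def pairwise_r2_from_dosages(matrix: GenotypeMatrix):
    """r^2 lookup backed by squared Pearson correlation of dosages.

    Missing genotypes are mean-imputed per variant before correlating.
    """
    idx = {str(v): j for j, v in enumerate(matrix.variant_ids)}
    D = matrix.dosages.astype(float)
    D[D == MISSING] = np.nan
    col_mean = np.nanmean(D, axis=0)
    nanpos = np.where(np.isnan(D))
    D[nanpos] = np.take(col_mean, nanpos[1])

    def r2(a: str, b: str) -> float:
        xa, xb = D[:, idx[a]], D[:, idx[b]]
        if xa.std() == 0 or xb.std() == 0:
            return 0.0
        return float(np.corrcoef(xa, xb)[0, 1] ** 2)

    return r2


def score_samples(matrix: GenotypeMatrix, weights: pd.DataFrame) -> pd.Series:
    """Per-sample polygenic score: sum over variants of dosage x weight.

    Weights must be aligned to the matrix's alternate alleles (see
    :func:`harmonize`).  A missing dosage contributes the variant's
    mean observed dosage times its weight (mean imputation).
    """
    common = weights.index.intersection(matrix.variant_ids)
    if len(common) == 0:
        raise ValueError("no overlap between weight variants and genotype matrix")
    sub = matrix.subset(variant_ids=list(common))
    D = sub.dosages.astype(float)
    D[D == MISSING] = np.nan
    col_mean = np.nanmean(D, axis=0)
    nanpos = np.where(np.isnan(D))
    D[nanpos] = np.take(col_mean, nanpos[1])
    w = weights.loc[common, "weight"].to_numpy(float)
    return pd.Series(D @ w, index=matrix.samples, name="score")


def dichotomize_onset(age: float | None) -> str:
    """Classify an age of onset: childhood (<= 12), adult (>= 25), else
    excluded.  Missing ages are excluded."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "excluded"
    if age < 0:
        raise ValueError("age of onset must be non-negative")
    if age <= CHILDHOOD_MAX_AGE:
        return "childhood"
    if age >= ADULT_MIN_AGE:
        return "adult"
    return "excluded"


def dichotomize_onset_series(ages: pd.Series) -> pd.Series:
    return ages.map(dichotomize_onset)


def onset_association(
    scores: pd.DataFrame,
    onset_class: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_scores: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress childhood-vs-adult onset on each standardised score.

    Outcome coding: childhood onset = 1, adult onset = 0; samples with
    class ``excluded`` are dropped.  Each score is standardised to zero
    mean and unit variance within the analysed samples, so the reported
    odds ratio is per SD of score.  Significance is Bonferroni at
    alpha / n_scores (default n_scores = number of score columns).
    """
    keep = onset_class.isin(["childhood", "adult"])
    oc = onset_class.loc[keep]
    if oc.nunique() < 2:
        raise ValueError("both onset classes must be represented")
    y = (oc == "childhood").to_numpy(float)
    n = int(keep.sum())
    m = n_scores if n_scores is not None else scores.shape[1]
    C = None
    if covariates is not None:
        C = covariates.loc[oc.index].to_numpy(float)

    rows = []
    for trait in scores.columns:
        s = scores.loc[oc.index, trait].to_numpy(float)
        sd = s.std()
        if sd == 0:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan, False, "constant_score"))
            continue
        z = (s - s.mean()) / sd
        cols = [np.ones(n), z]
        if C is not None:
            cols.extend(C.T)
        X = np.column_stack(cols)
        beta_vec, cov, _, flag = _glm.irls_logistic(X, y)
        if flag:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan, False, flag))
            continue
        beta = float(beta_vec[1])
        se = float(np.sqrt(cov[1, 1]))
        p = float(2.0 * stats.norm.sf(abs(beta) / se))
        rows.append((trait, beta, float(np.exp(beta)), se, p, p < alpha / m, ""))
    return pd.DataFrame(
        rows,
        columns=["trait", "beta", "or_per_sd", "se", "p", "significant", "flag"],
    ).set_index("trait")
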