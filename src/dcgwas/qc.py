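"""Variant- and sample-level genotype quality control.

Variant filters: genotype-quality masking (GQ < 20 set to missing),
missingness (> 0.05 removed), exact Hardy-Weinberg equilibrium test
(p < 1e-6 removed) and an allelic-depth balance binomial test at
heterozygote carriers (p < 0.01 removed).  Removal thresholds are
strict inequalities, so a variant sitting exactly on a threshold is
kept.

Sample filters: missingness, ancestry fraction, heterozygosity
outliers, a supplied pairwise relatedness statistic, and iterative
principal-component outlier removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix


@dataclass
class VariantQCThresholds:
    missingness_max: float = 0.05
    hwe_p_min: float = 1e-6
    ad_balance_p_min: float = 0.01
    gq_min: int = 20
    maf_common_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.missingness_max <= 1):
            raise ValueError("missingness_max must lie in [0, 1]")
        for name in ("hwe_p_min", "ad_balance_p_min"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.maf_common_min < 0.5):
            raise ValueError("maf_common_min must lie in [0, 0.5)")


@dataclass
class SampleQCThresholds:
    missingness_max: float = 0.1
    het_sd: float = 3.0
    relatedness_stat_max: float = 0.4
    ancestry_min: float = 0.85
    pca_sd: float = 6.0
    pca_iterations: int = 5
    pca_components: int = 10


def ad_balance_test(ref_depth: int, alt_depth: int) -> float:
    """Two-sided exact binomial test of allele-depth balance.

    Depths are summed over heterozygous carriers of a variant; under
    clean genotyping, alternate reads at heterozygotes are
    Binomial(total, 1/2).  Two-sided p is min(1, 2 * min(lower tail,
    upper tail)).  Zero total depth is undefined; returns 1 (the caller
    flags it).
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    n = ref_depth + alt_depth
    if n == 0:
        return 1.0
    k = alt_depth
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose probability does not exceed that of
    the observed count.  Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0

    # support of the conditional distribution: het counts with the
    # parity of the minor-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalised log-probabilities via the multinomial coefficient
    # n! / (n_aa! n_ab! n_bb!) * 2^het
    n_common = 2 * n - n_rare
    hom_r = (n_rare - hets) // 2
    hom_c = (n_common - hets) // 2
    valid = hom_c >= 0
    hets, hom_r, hom_c = hets[valid], hom_r[valid], hom_c[valid]
    logp = (
        hets * math.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = min(n_het, n_rare)
    p_obs = probs[np.searchsorted(hets, obs)]
    # 1+1e-12 guard against float noise when summing equal-probability bins
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def apply_gq_mask(matrix: GenotypeMatrix, gq_min: int = 20) -> GenotypeMatrix:
    """Set genotypes with GQ strictly below ``gq_min`` to missing."""
    if matrix.gq is None:
        raise ValueError("matrix has no GQ channel")
    d = matrix.dosages.copy()
    d[matrix.gq < gq_min] = MISSING
    return GenotypeMatrix(
        dosages=d, samples=matrix.samples, variants=matrix.variants,
        gq=matrix.gq, ad_ref=matrix.ad_ref, ad_alt=matrix.ad_alt,
    )


def filter_variants(
    matrix: GenotypeMatrix, thresholds: VariantQCThresholds | None = None
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply variant-level QC; return kept variant ids and a full report.

    A variant is kept iff missingness <= missingness_max AND HWE
    p >= hwe_p_min AND allele-depth balance p >= ad_balance_p_min.
    The report records each statistic, the failure reasons, the
    post-mask MAF and the common (MAF > maf_common_min) classification.
    The AD-balance test aggregates read depths across all heterozygous
    carriers of the variant; without AD channels it is skipped (p NaN).
    """
    thr = thresholds or VariantQCThresholds()
    miss = matrix.missingness()
    gcounts = matrix.genotype_counts()
    hwe_p = np.array([hwe_exact_test(*row) for row in gcounts])

    if matrix.ad_ref is not None and matrix.ad_alt is not None:
        het = matrix.dosages == 1
        ref_sum = np.where(het, matrix.ad_ref, 0).sum(axis=0)
        alt_sum = np.where(het, matrix.ad_alt, 0).sum(axis=0)
        ad_p = np.array(
            [ad_balance_test(int(r), int(a)) for r, a in zip(ref_sum, alt_sum)]
        )
        ad_zero = (ref_sum + alt_sum) == 0
    else:
        ad_p = np.full(matrix.n_variants, np.nan)
        ad_zero = np.zeros(matrix.n_variants, dtype=bool)

    maf = matrix.minor_allele_freq()
    fail_miss = miss > thr.missingness_max
    fail_hwe = hwe_p < thr.hwe_p_min
    fail_ad = np.isfinite(ad_p) & (ad_p < thr.ad_balance_p_min)
    keep = ~(fail_miss | fail_hwe | fail_ad)

    reasons = []
    for fm, fh, fa in zip(fail_miss, fail_hwe, fail_ad):
        r = [name for name, f in
             (("missingness", fm), ("hwe", fh), ("ad_balance", fa)) if f]
        reasons.append(",".join(r))

    report = pd.DataFrame(
        {
            "missingness": miss,
            "hwe_p": hwe_p,
            "ad_balance_p": ad_p,
            "ad_zero_depth": ad_zero,
            "maf": maf,
            "common": maf > thr.maf_common_min,
            "keep": keep,
            "fail_reasons": reasons,
        },
        index=matrix.variant_ids,
    )
    return matrix.variant_ids[keep], report


def heterozygosity_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls."""
    d = matrix.dosages
    called = (d != MISSING).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, het / np.maximum(called, 1), np.nan)


def compute_pcs(matrix: GenotypeMatrix, k: int) -> np.ndarray:
    """Scores of the top-k principal components of the genotype matrix.

    Missing genotypes are mean-imputed per variant, dosages standardised,
    constant variants dropped.  The sign of each component is fixed so
    that the loading with the largest magnitude is positive.  Uses exact
    SVD for small matrices and a seeded randomized SVD for large ones.
    """
    n, m = matrix.dosages.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    X = matrix.dosages.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= col_mean
    sd = X.std(axis=0)
    nz = sd > 0
    X = X[:, nz] / sd[nz]
    if X.shape[1] == 0:
        return np.zeros((n, k))
    k_eff = min(k, min(X.shape) - 1) if min(X.shape) > 1 else 1
    if min(X.shape) <= 500:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, Vt = U[:, :k_eff], S[:k_eff], Vt[:k_eff]
    else:
        from sklearn.utils.extmath import randomized_svd

        U, S, Vt = randomized_svd(X, n_components=k_eff, n_iter=7, random_state=0)
    # sign convention: largest-magnitude loading positive
    for c in range(k_eff):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            U[:, c] *= -1
            Vt[c] *= -1
    scores = U * S
    if k_eff < k:
        scores = np.column_stack([scores, np.zeros((n, k - k_eff))])
    return scores


@dataclass
class SampleQCReport:
    kept: pd.Index
    removed: pd.DataFrame  # sample_id -> reason
    n_pca_iterations_used: int = 0
    notes: list = field(default_factory=list)


def sample_qc(
    matrix: GenotypeMatrix,
    sample_sheet: pd.DataFrame,
    thresholds: SampleQCThresholds | None = None,
    relatedness: pd.DataFrame | None = None,
) -> SampleQCReport:
    """Sample-level QC: missingness, ancestry, heterozygosity, relatedness,
    then iterative PCA outlier removal.

    ``sample_sheet`` is indexed by sample id with an ``ancestry_frac``
    column.  ``relatedness`` is an optional table with columns
    ``sample_1, sample_2, stat``; for each pair whose statistic meets
    the exclusion threshold, the member with the higher missingness is
    dropped.  PCA outliers (>= pca_sd SDs from the mean on any of the
    top pca_components PCs) are removed and the PCs recomputed, iterated
    pca_iterations times.
    """
    thr = thresholds or SampleQCThresholds()
    notes: list[str] = []
    removed: dict[str, str] = {}
    d = matrix.dosages
    miss = (d == MISSING).mean(axis=1)
    het = heterozygosity_rate(matrix)
    het_z = (het - np.nanmean(het)) / (np.nanstd(het) if np.nanstd(het) > 0 else 1.0)
    ancestry = sample_sheet.reindex(matrix.samples)["ancestry_frac"].to_numpy(float)

    for i, sid in enumerate(matrix.samples):
        if miss[i] > thr.missingness_max:
            removed.setdefault(str(sid), "missingness")
        elif ancestry[i] <= thr.ancestry_min:
            removed.setdefault(str(sid), "ancestry")
        elif abs(het_z[i]) >= thr.het_sd:
            removed.setdefault(str(sid), "heterozygosity")

    if relatedness is not None and len(relatedness):
        miss_by_id = dict(zip(map(str, matrix.samples), miss))
        for _, row in relatedness.iterrows():
            if row["stat"] >= thr.relatedness_stat_max:
                a, b = str(row["sample_1"]), str(row["sample_2"])
                if a in removed or b in removed:
                    continue
                drop = a if miss_by_id.get(a, 0) >= miss_by_id.get(b, 0) else b
                removed.setdefault(drop, "relatedness")

    kept = pd.Index([s for s in matrix.samples if str(s) not in removed])

    n_iter_used = 0
    k = thr.pca_components
    for _ in range(thr.pca_iterations):
        sub = matrix.subset(sample_ids=kept)
        k_use = min(k, sub.n_samples - 1)
        if k_use < k:
            notes.append(
                f"reduced PCA components to {k_use} for {sub.n_samples} samples"
            )
        if k_use < 1:
            break
        scores = compute_pcs(sub, k_use)
        sd = scores.std(axis=0)
        mean = scores.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(scores - mean) / np.where(sd > 0, sd, np.inf)
        outlier = (z >= thr.pca_sd).any(axis=1)
        n_iter_used += 1
        if not outlier.any():
            break
        for sid in kept[outlier]:
            removed.setdefault(str(sid), "pca_outlier")
        kept = kept[~outlier]

    removed_df = pd.DataFrame(
        {"reason": pd.Series(removed, dtype=object)}
    ).rename_axis("sample_id")
    return SampleQCReport(kept, removed_df, n_iter_used, notes)
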