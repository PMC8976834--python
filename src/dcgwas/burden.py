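"""Gene-level rare-variant collapsing burden tests.

Rare variants (MAF < 1%) are aggregated per gene under an annotation
mask; each individual is coded 0/1 for carrying at least one qualifying
alternate allele, and disease status is regressed on this binary carrier
indicator with the same covariates as the single-variant scan.  Two
masks are provided: high-impact variants with a high-confidence
loss-of-function flag, and all high-impact plus moderate-impact variants
with a deleteriousness score > 0.5.  Only genes with >= 2 qualifying
variants and >= 5 carriers are tested.  Evidence across studies is
combined by inverse-variance fixed-effect meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fit_additive_logistic
from .containers import MISSING, GenotypeMatrix

VALID_IMPACTS = {"HIGH", "MODERATE", "LOW"}

MIN_QUALIFYING_VARIANTS = 2
MIN_CARRIERS = 5


@dataclass(frozen=True)
class BurdenMask:
    """Predicate over (impact, high-confidence LoF flag, score)."""

    name: str
    rule: Callable[[str, bool, float], bool]

    def qualifies(self, impact: str, lof_hc: bool, score: float) -> bool:
        if impact not in VALID_IMPACTS:
            raise ValueError(f"unknown impact label {impact!r}")
        return self.rule(impact, lof_hc, score)


#: High-impact variants flagged as high-confidence loss of function.
LOF_HC = BurdenMask("lof_hc", lambda imp, hc, s: imp == "HIGH" and hc)

#: All high-impact variants plus moderate-impact with score > 0.5 (strict).
LOF_PLUS_MODERATE = BurdenMask(
    "lof_plus_moderate",
    lambda imp, hc, s: imp == "HIGH" or (imp == "MODERATE" and s > 0.5),
)

MASKS = {m.name: m for m in (LOF_HC, LOF_PLUS_MODERATE)}


def select_qualifying_variants(
    annotations: pd.DataFrame,
    mask: BurdenMask,
    maf: pd.Series | None = None,
    maf_max: float = 0.01,
) -> dict[str, list[str]]:
    """Per-gene qualifying-variant sets under an annotation mask.

    ``annotations`` is indexed by variant id with ``gene``, ``impact``,
    ``lof_hc`` and ``score`` columns.  ``maf`` (post-QC minor allele
    frequencies, indexed by variant id) restricts to rare variants
    (MAF < maf_max, strict); if None the annotation table's ``maf``
    column is used.
    """
    if maf is None:
        maf = annotations["maf"]
    out: dict[str, list[str]] = {}
    maf_v = maf.reindex(annotations.index).to_numpy(float)
    for (vid, row), f in zip(annotations.iterrows(), maf_v):
        if not np.isfinite(f) or f >= maf_max:
            continue
        if mask.qualifies(str(row["impact"]), bool(row["lof_hc"]), float(row["score"])):
            out.setdefault(str(row["gene"]), []).append(str(vid))
    return out


def carrier_status(matrix: GenotypeMatrix, qualifying: Sequence[str]) -> np.ndarray:
    """Binary carrier coding: 1 iff >= 1 alternate allele at any
    qualifying variant.  Missing genotypes count as non-carrier."""
    if len(qualifying) == 0:
        raise ValueError("empty qualifying-variant set")
    sub = matrix.subset(variant_ids=list(qualifying))
    d = sub.dosages
    return ((d != MISSING) & (d > 0)).any(axis=1).astype(np.int8)


@dataclass
class GeneBurdenResult:
    gene: str
    mask: str
    n_qualifying_variants: int
    n_carriers: int
    beta: float
    se: float
    p: float
    flag: str = ""
    skip_reason: str = ""

    @property
    def tested(self) -> bool:
        return self.skip_reason == ""


def burden_test(
    carrier: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    gene: str = "",
    mask_name: str = "",
    n_qualifying_variants: int = 0,
) -> GeneBurdenResult:
    """Logistic regression of disease status on the binary carrier code.

    Genes failing the eligibility rule (>= 2 qualifying variants and
    >= 5 carriers among analysed samples) are returned with a skip
    reason, never silently dropped.
    """
    carrier = np.asarray(carrier)
    n_carriers = int((carrier == 1).sum())
    if n_qualifying_variants < MIN_QUALIFYING_VARIANTS:
        return GeneBurdenResult(
            gene, mask_name, n_qualifying_variants, n_carriers,
            np.nan, np.nan, np.nan,
            skip_reason=f"n_variants < {MIN_QUALIFYING_VARIANTS}",
        )
    if n_carriers < MIN_CARRIERS:
        return GeneBurdenResult(
            gene, mask_name, n_qualifying_variants, n_carriers,
            np.nan, np.nan, np.nan,
            skip_reason=f"n_carriers < {MIN_CARRIERS}",
        )
    r = fit_additive_logistic(carrier, status, covariates, variant_id=gene)
    return GeneBurdenResult(
        gene, mask_name, n_qualifying_variants, n_carriers,
        r.beta, r.se, r.p, flag=r.flag,
    )


def run_burden(
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: BurdenMask = LOF_PLUS_MODERATE,
    maf: pd.Series | None = None,
    maf_max: float = 0.01,
) -> pd.DataFrame:
    """Burden tests for every gene under a mask; one row per gene.

    Includes skipped (ineligible) genes with their skip reason so the
    eligibility audit is explicit; ``tested`` marks fitted genes.
    """
    per_gene = select_qualifying_variants(annotations, mask, maf=maf, maf_max=maf_max)
    rows = []
    for gene in sorted(per_gene):
        vids = per_gene[gene]
        carrier = carrier_status(matrix, vids)
        r = burden_test(
            carrier, status, covariates, gene=gene, mask_name=mask.name,
            n_qualifying_variants=len(vids),
        )
        rows.append(
            (r.gene, r.mask, r.n_qualifying_variants, r.n_carriers,
             r.beta, r.se, r.p, r.flag, r.skip_reason, r.tested)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "mask", "n_qualifying_variants", "n_carriers",
                 "beta", "se", "p", "flag", "skip_reason", "tested"],
    ).set_index("gene")


def meta_analyze(results: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect meta-analysis of (beta, se) pairs.

    Weights are 1/se^2; returns (beta_meta, se_meta, two-sided Wald p).
    A study with infinite se contributes zero weight.
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    w_sum = 0.0
    bw_sum = 0.0
    for beta, se in results:
        if se <= 0:
            raise ValueError("standard errors must be positive")
        if math.isinf(se):
            continue
        w = 1.0 / se**2
        w_sum += w
        bw_sum += w * beta
    if w_sum == 0:
        raise ValueError("no informative studies")
    beta_meta = bw_sum / w_sum
    se_meta = 1.0 / math.sqrt(w_sum)
    p_meta = float(2.0 * stats.norm.sf(abs(beta_meta) / se_meta))
    return beta_meta, se_meta, p_meta


def bonferroni(p: pd.Series | np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values over the tested genes of one mask."""
    p = np.asarray(p, dtype=float)
    n = n_tests if n_tests is not None else int(np.isfinite(p).sum())
    return np.minimum(p * n, 1.0)
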