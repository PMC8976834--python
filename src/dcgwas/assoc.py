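"""Single-variant additive logistic association and inflation statistics.

Disease status is regressed on allele dosage under an additive genetic
model with optional covariates (genetic sex and leading principal
components in the standard design).  Genomic inflation is summarised by
the genomic-control factor lambda_gc (median Wald chi-square against the
null median) and its rescaling lambda_1000 to a notional study of 1000
cases and 1000 controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .containers import MISSING, GenotypeMatrix

#: Genome-wide significance threshold for common-variant associations.
GENOME_WIDE_ALPHA = 5e-8

#: Median of the 1-df chi-square distribution.
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass
class AssocResult:
    """Per-variant (or per-gene) association estimate for the coded allele."""

    variant_id: str
    beta: float
    se: float
    p: float
    n_case: int
    n_control: int
    raf_case: float
    raf_control: float
    flag: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for a Wald statistic beta/se."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def fit_additive_logistic(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
) -> AssocResult:
    """Fit logit P(case) = b0 + beta * dosage (+ covariates).

    Samples with missing dosage (-1 or NaN) are dropped from the fit
    (complete-case analysis; missing genotypes are not imputed).
    Non-convergence or separation yields a flagged result with NaN
    estimates, never a silent number.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    keep = np.isfinite(d) & (d != MISSING)
    d, y = d[keep], y[keep]
    C = None if covariates is None else np.asarray(covariates, dtype=float)[keep]

    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    raf_case = float(d[y == 1].mean() / 2.0) if n_case else np.nan
    raf_control = float(d[y == 0].mean() / 2.0) if n_control else np.nan

    def flagged(reason: str) -> AssocResult:
        return AssocResult(
            variant_id, np.nan, np.nan, np.nan, n_case, n_control,
            raf_case, raf_control, flag=reason,
        )

    if n_case < 2 or n_control < 2:
        return flagged("too_few_samples")
    if np.ptp(d) == 0:
        return flagged("monomorphic")

    cols = [np.ones_like(d), d]
    if C is not None:
        cols.extend(C.T)
    X = np.column_stack(cols)
    beta_vec, cov, converged, flag = _glm.irls_logistic(X, y)
    if flag:
        return flagged(flag)
    beta = float(beta_vec[1])
    se = float(np.sqrt(cov[1, 1]))
    return AssocResult(
        variant_id, beta, se, wald_p(beta, se),
        n_case, n_control, raf_case, raf_control,
    )


def run_gwas(
    matrix: GenotypeMatrix,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant additive logistic scan; one row per variant.

    Columns: beta, or (exp beta), se, p, n_case, n_control, raf_case,
    raf_control, flag.  Flagged variants carry NaN estimates.
    """
    rows = []
    for j, vid in enumerate(matrix.variant_ids):
        r = fit_additive_logistic(
            matrix.dosages[:, j], status, covariates, variant_id=str(vid)
        )
        rows.append(
            (r.variant_id, r.beta, r.se, r.p, r.n_case, r.n_control,
             r.raf_case, r.raf_control, r.flag)
        )
    out = pd.DataFrame(
        rows,
        columns=["variant_id", "beta", "se", "p", "n_case", "n_control",
                 "raf_case", "raf_control", "flag"],
    ).set_index("variant_id")
    out.insert(1, "or", np.exp(out["beta"]))
    return out


def run_gwas_fast(
    matrix: GenotypeMatrix, status: np.ndarray
) -> pd.DataFrame:
    """Covariate-free additive scan from genotype count tables.

    Equivalent to :func:`run_gwas` without covariates (the genotype
    count table is the sufficient statistic), vectorised across
    variants for genome-scale null simulations.
    """
    y = np.asarray(status)
    d = matrix.dosages
    counts = {}
    for grp, sel in (("case", y == 1), ("ctrl", y == 0)):
        sub = d[sel]
        counts[grp] = np.stack([(sub == g).sum(axis=0) for g in (0, 1, 2)], axis=1)
    beta, se = _glm.newton_dosage_counts(counts["case"], counts["ctrl"])
    with np.errstate(invalid="ignore"):
        z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    out = pd.DataFrame(
        {
            "beta": beta,
            "or": np.exp(beta),
            "se": se,
            "p": p,
            "n_case": counts["case"].sum(axis=1),
            "n_control": counts["ctrl"].sum(axis=1),
            "flag": np.where(np.isnan(beta), "degenerate", ""),
        },
        index=matrix.variant_ids,
    )
    cc, cn = counts["case"].astype(float), counts["ctrl"].astype(float)
    out["raf_case"] = (cc[:, 1] + 2 * cc[:, 2]) / (2 * np.maximum(cc.sum(1), 1))
    out["raf_control"] = (cn[:, 1] + 2 * cn[:, 2]) / (2 * np.maximum(cn.sum(1), 1))
    return out


def genomic_inflation(p_values) -> float:
    """Genomic-control inflation factor lambda_gc.

    Median of the 1-df chi-square quantiles of the p-values divided by
    the null median 0.4549364.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def lambda_1000(lambda_gc: float, n_case: int, n_control: int) -> float:
    """Rescale lambda_gc to a 1000-case / 1000-control study.

    lambda_1000 = 1 + (lambda_gc - 1) * (1/n_case + 1/n_control) / (2/1000).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample counts must be positive")
    return 1.0 + (lambda_gc - 1.0) * (1.0 / n_case + 1.0 / n_control) / (2.0 / 1000.0)


def subtype_prevalence(overall_prevalence: float, subtype_fraction: float) -> float:
    """Population prevalence of a disease subtype.

    The product of the overall disease prevalence and the fraction of
    patients in the subtype (e.g. 0.084 overall asthma prevalence times
    a 10% moderate-to-severe share gives 0.0084), as used when
    converting heritability estimates to the liability scale.
    """
    if not (0 < overall_prevalence <= 1 and 0 < subtype_fraction <= 1):
        raise ValueError("prevalence and fraction must lie in (0, 1]")
    return overall_prevalence * subtype_fraction


@dataclass
class InflationReport:
    lambda_gc: float
    lambda_1000: float
    n_case: int
    n_control: int


def inflation_report(p_values, n_case: int, n_control: int) -> InflationReport:
    lam = genomic_inflation(p_values)
    return InflationReport(lam, lambda_1000(lam, n_case, n_control), n_case, n_control)
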