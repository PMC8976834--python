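"""Differential-effects test for dual disease-control designs.

When the same cases are compared against two different disease-control
cohorts, the two effect estimates for a variant are correlated because
they share samples.  Under the null hypothesis that the variant has the
same true effect in both comparisons, the difference of the two log-odds
estimates is normal with variance

    se_k^2 + se_l^2 - 2 * corr * se_k * se_l,

where ``corr`` depends only on the overlap structure of the two designs.
A variant with a small two-sided p-value on this difference (default
threshold 0.01) is flagged as likely driven by one of the control
diseases rather than by the cases.  The test cannot distinguish a true
case-disease effect from a variant affecting both control diseases
equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComparisonDesign:
    """Sample counts of two case-control comparisons that share samples.

    ``k`` and ``l`` index the two comparisons; suffix 1 = cases,
    0 = controls; ``n_kl1`` / ``n_kl0`` are the numbers of cases /
    controls shared between the comparisons.
    """

    n_k1: int
    n_k0: int
    n_l1: int
    n_l0: int
    n_kl1: int
    n_kl0: int

    def __post_init__(self) -> None:
        for name in ("n_k1", "n_k0", "n_l1", "n_l0", "n_kl1", "n_kl0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_kl1 > min(self.n_k1, self.n_l1):
            raise ValueError("shared cases exceed a case group")
        if self.n_kl0 > min(self.n_k0, self.n_l0):
            raise ValueError("shared controls exceed a control group")

    @property
    def n_k(self) -> int:
        return self.n_k1 + self.n_k0

    @property
    def n_l(self) -> int:
        return self.n_l1 + self.n_l0


@dataclass
class DiffEffectsResult:
    corr: float
    z: float
    p_de: float


def overlap_correlation(design: ComparisonDesign) -> float:
    """Correlation between effect estimates from two overlapping comparisons.

    corr = ( n_kl0 * sqrt(n_k1 n_l1 / (n_k0 n_l0))
           + n_kl1 * sqrt(n_k0 n_l0 / (n_k1 n_l1)) ) / sqrt(n_k n_l)

    The approximation uses sample counts only, so it is computed once
    per design, not per variant.
    """
    d = design
    term0 = 0.0
    if d.n_kl0:
        if d.n_k0 == 0 or d.n_l0 == 0 or d.n_k1 == 0 or d.n_l1 == 0:
            raise ValueError("shared controls require non-empty groups on both sides")
        term0 = d.n_kl0 * math.sqrt((d.n_k1 * d.n_l1) / (d.n_k0 * d.n_l0))
    term1 = 0.0
    if d.n_kl1:
        if d.n_k1 == 0 or d.n_l1 == 0 or d.n_k0 == 0 or d.n_l0 == 0:
            raise ValueError("shared cases require non-empty groups on both sides")
        term1 = d.n_kl1 * math.sqrt((d.n_k0 * d.n_l0) / (d.n_k1 * d.n_l1))
    if d.n_k == 0 or d.n_l == 0:
        raise ValueError("empty comparison")
    return (term0 + term1) / math.sqrt(d.n_k * d.n_l)


def diff_effects_test(
    beta_k: float, se_k: float, beta_l: float, se_l: float, corr: float
) -> DiffEffectsResult:
    """Z-test on the difference between two correlated effect estimates."""
    if se_k <= 0 or se_l <= 0:
        raise ValueError("standard errors must be positive")
    var = se_k**2 + se_l**2 - 2.0 * corr * se_k * se_l
    if var <= 0:
        raise ValueError(
            f"non-positive variance of the effect difference (corr={corr}, "
            f"se={se_k}, {se_l}): degenerate overlap design"
        )
    z = (beta_k - beta_l) / math.sqrt(var)
    return DiffEffectsResult(corr, z, float(2.0 * stats.norm.sf(abs(z))))


def diff_effects_table(
    table_k: pd.DataFrame,
    table_l: pd.DataFrame,
    design: ComparisonDesign,
) -> pd.DataFrame:
    """Vectorised differential-effects test over two association tables.

    Tables must share an index (variant or gene ids) and carry ``beta``
    and ``se`` columns.  Items missing or flagged in either table get
    NaN results.
    """
    corr = overlap_correlation(design)
    common = table_k.index.intersection(table_l.index)
    bk = table_k.loc[common, "beta"].to_numpy(float)
    sk = table_k.loc[common, "se"].to_numpy(float)
    bl = table_l.loc[common, "beta"].to_numpy(float)
    sl = table_l.loc[common, "se"].to_numpy(float)
    var = sk**2 + sl**2 - 2.0 * corr * sk * sl
    with np.errstate(invalid="ignore"):
        ok = var > 0
        z = np.where(ok, (bk - bl) / np.sqrt(np.where(ok, var, np.nan)), np.nan)
    p_de = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta_k": bk, "se_k": sk, "beta_l": bl, "se_l": sl,
            "corr": corr, "z_de": z, "p_de": p_de,
        },
        index=common,
    )


def apply_de_filter(
    results: pd.DataFrame, threshold: float = 0.01, p_col: str = "p_de"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a results table into retained and flagged items.

    Items with p_de strictly below ``threshold`` are flagged (likely
    driven by a control cohort); items with p_de == threshold or NaN
    are retained.  Applies identically to single-variant, gene-burden
    and enrichment-input tables.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    p = results[p_col].to_numpy(float)
    flagged = np.isfinite(p) & (p < threshold)
    return results.loc[~flagged], results.loc[flagged]
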