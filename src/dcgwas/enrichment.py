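"""Variant-count matched permutation gene-set enrichment.

Tests whether burden association p-values within a candidate gene-set
are collectively smaller than expected, against a null built by
resampling genes matched on their number of qualifying rare variants.
The statistic is the sum of -log10(p) over set members; the permutation
p-value is the fraction of matched random draws whose sum is as or more
significant (>=) than the observed sum.  Genes flagged by the
differential-effects test (p_de < 0.01) must be excluded upstream; a
``p_de`` column, if present, is filtered here defensively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default qualifying-variant-count bins used to match random draws to
#: the gene-set: 2-3, 4-6, 7-10, 11+.
DEFAULT_BINS: tuple[tuple[int, float], ...] = (
    (2, 3), (4, 6), (7, 10), (11, float("inf")),
)

DEFAULT_N_PERMUTATIONS = 5000


@dataclass
class EnrichmentResult:
    gene_set: str
    observed_sum: float
    n_permutations: int
    perm_p: float
    n_set_tested: int
    n_set_dropped: int
    strata_sizes: dict = field(default_factory=dict)


def _bin_index(count: int, bins) -> int:
    for i, (lo, hi) in enumerate(bins):
        if lo <= count <= hi:
            return i
    raise ValueError(f"variant count {count} falls in no matching bin")


def observed_statistic(
    table: pd.DataFrame, gene_set: set[str] | list[str]
) -> tuple[float, int]:
    """Sum of -log10(burden p) over set members present in the table.

    Returns (sum, n_dropped) where n_dropped counts set members that
    were not tested.  An empty intersection is an error.
    """
    members = pd.Index(sorted(set(map(str, gene_set))))
    present = members.intersection(table.index)
    if len(present) == 0:
        raise ValueError("gene set has no overlap with tested genes")
    p = table.loc[present, "p"].to_numpy(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("burden p-values must lie in (0, 1]")
    return float(np.sum(-np.log10(p))), len(members) - len(present)


def matched_permutation(
    table: pd.DataFrame,
    gene_set: set[str] | list[str],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    bins=DEFAULT_BINS,
    set_name: str = "",
    de_threshold: float = 0.01,
) -> EnrichmentResult:
    """Permutation enrichment test matched on qualifying-variant counts.

    ``table`` is indexed by gene id with columns ``p`` (burden p-value)
    and ``n_qualifying_variants``; an optional ``p_de`` column excludes
    genes below ``de_threshold`` before anything else.  Each permutation
    draws, for every set gene, one gene uniformly from the set of all
    tested genes in the same variant-count bin — without replacement
    within a draw, with replacement across permutations — so the
    variant-count bin multiset of every draw equals the set's exactly.
    """
    if "p_de" in table.columns:
        pde = table["p_de"].to_numpy(float)
        table = table.loc[~(np.isfinite(pde) & (pde < de_threshold))]
    table = table.loc[np.isfinite(table["p"].to_numpy(float))]

    observed, n_dropped = observed_statistic(table, gene_set)
    members = pd.Index(sorted(set(map(str, gene_set)))).intersection(table.index)

    neglogp = -np.log10(table["p"].to_numpy(float))
    counts = table["n_qualifying_variants"].to_numpy(int)
    bin_of = np.array([_bin_index(c, bins) for c in counts])

    # how many set genes fall in each bin
    member_pos = table.index.get_indexer(members)
    need = np.bincount(bin_of[member_pos], minlength=len(bins))

    pool: dict[int, np.ndarray] = {}
    strata_sizes = {}
    for b in np.nonzero(need)[0]:
        cand = np.nonzero(bin_of == b)[0]
        if len(cand) < need[b]:
            lo, hi = bins[b]
            raise ValueError(
                f"variant-count stratum {lo}-{hi} has {len(cand)} candidates "
                f"but the gene set needs {need[b]}"
            )
        pool[b] = cand
        strata_sizes[f"{bins[b][0]}-{bins[b][1]}"] = int(len(cand))

    rng = np.random.default_rng(seed)
    sums = np.zeros(n_perm)
    for b, cand in pool.items():
        k = int(need[b])
        vals = neglogp[cand]
        if k == 1:
            draws = rng.integers(0, len(cand), size=n_perm)
            sums += vals[draws]
        else:
            for i in range(n_perm):
                idx = rng.choice(len(cand), size=k, replace=False)
                sums[i] += vals[idx].sum()
    perm_p = float((sums >= observed - 1e-12).sum() / n_perm)
    return EnrichmentResult(
        set_name, observed, n_perm, perm_p, len(members), n_dropped, strata_sizes
    )


def bonferroni_over_tests(p_values: dict[str, float]) -> dict[str, float]:
    """Bonferroni correction across gene-set x mask combinations."""
    n = len(p_values)
    return {k: min(1.0, v * n) for k, v in p_values.items()}
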