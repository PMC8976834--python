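"""Variant- and sample-level QC: exact tests, masks, filters, PCA."""

import math
from itertools import accumulate

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcgwas import qc
from dcgwas.containers import MISSING

from conftest import toy_matrix


class TestAdBalance:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (50, 50, 1.0),                    # perfectly balanced
            (0, 10, 0.001953125),             # 2 * 0.5**10, fails 0.01
            (2, 8, 0.109375),                 # 2 * (1+10+45)/1024, passes
        ],
    )
    def test_exact_values(self, ref, alt, expected):
        assert qc.ad_balance_test(ref, alt) == pytest.approx(expected, abs=1e-12)

    def test_zero_depth_returns_one(self):
        assert qc.ad_balance_test(0, 0) == 1.0

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        assert qc.ad_balance_test(a, b) == pytest.approx(
            qc.ad_balance_test(b, a), abs=1e-12
        )

    def test_matches_enumeration_oracle_small(self):
        # exact tail enumeration with big-int arithmetic, totals <= 40
        for n in range(1, 41):
            pref = list(accumulate(math.comb(n, i) for i in range(n + 1)))
            tot = 1 << n
            for k in range(n + 1):
                lower = pref[k]
                upper = tot - (pref[k - 1] if k else 0)
                oracle = min(1.0, 2 * min(lower, upper) / tot)
                assert qc.ad_balance_test(n - k, k) == pytest.approx(
                    oracle, abs=1e-12
                )


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact conditional HWE p by integer enumeration of genotype tables."""
    n = n_hom_ref + n_het + n_hom_alt
    m = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    ways = {}
    for het in range(m % 2, m + 1, 2):
        hr = (m - het) // 2
        hc = (2 * n - m - het) // 2
        if hc < 0:
            continue
        ways[het] = (
            math.factorial(n)
            // (math.factorial(hr) * math.factorial(het) * math.factorial(hc))
            * (1 << het)
        )
    total = sum(ways.values())
    w_obs = ways[n_het]
    return sum(v for v in ways.values() if v <= w_obs) / total


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(100, 0, 0) == 1.0
        assert qc.hwe_exact_test(0, 0, 100) == 1.0

    def test_balanced_mid_table_matches_enumeration(self):
        # 100 minor alleles in 100 diploids, support {0, 2, ..., 100}
        expected = hwe_enumeration_oracle(25, 50, 25)
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(expected, abs=1e-12)

    def test_zero_hets_with_balanced_alleles_is_extreme(self):
        assert qc.hwe_exact_test(50, 0, 50) < 1e-6

    def test_matches_enumeration_oracle_small(self):
        for n in range(1, 26):
            for m in range(n + 1):
                for het in range(m % 2, m + 1, 2):
                    hr = (m - het) // 2
                    hc = (2 * n - m - het) // 2
                    if hc < 0:
                        continue
                    got = qc.hwe_exact_test(hc, het, hr)
                    assert got == pytest.approx(
                        hwe_enumeration_oracle(hc, het, hr), abs=1e-12
                    )

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_allele_relabel_invariance(self, a, h, b):
        assert qc.hwe_exact_test(a, h, b) == pytest.approx(
            qc.hwe_exact_test(b, h, a), abs=1e-12
        )


class TestGqMask:
    def test_high_gq_unchanged(self):
        m = toy_matrix([[0, 1], [2, 1]], gq=[[99, 99], [99, 99]])
        out = qc.apply_gq_mask(m, 20)
        assert np.array_equal(out.dosages, m.dosages)

    def test_all_low_gq_all_missing(self):
        m = toy_matrix([[0, 1], [2, 1]], gq=[[0, 0], [0, 0]])
        out = qc.apply_gq_mask(m, 20)
        assert (out.dosages == MISSING).all()

    def test_strict_boundary_at_threshold(self):
        m = toy_matrix([[0, 1, 2]], gq=[[19, 20, 21]])
        out = qc.apply_gq_mask(m, 20)
        assert out.dosages[0, 0] == MISSING
        assert out.dosages[0, 1] == 1 and out.dosages[0, 2] == 2

    def test_requires_gq_channel(self):
        with pytest.raises(ValueError):
            qc.apply_gq_mask(toy_matrix([[0, 1]]), 20)


class TestFilterVariants:
    def _fixture(self):
        # 40 samples x 5 variants: v0 fails missingness, v1 fails HWE,
        # v2 fails AD balance, v3 fails two rules, v4 passes everything
        rng = np.random.default_rng(0)
        n = 40
        d = np.ones((n, 5), dtype=np.int8)
        d[:, 0] = rng.binomial(2, 0.3, n)
        d[:4, 0] = MISSING                      # missingness 0.10 > 0.05
        d[:20, 1] = 0
        d[20:, 1] = 2                           # no hets: HWE extreme
        d[:20, 2] = 1                           # hets carry biased depths
        d[20:30, 2] = 0
        d[30:, 2] = 2                           # (10, 20, 10): HWE-ideal
        d[:20, 3] = 0
        d[20:, 3] = 2
        d[:4, 3] = MISSING                      # HWE + missingness
        d[:, 4] = rng.binomial(2, 0.4, n)       # clean HWE draw
        ad_alt = np.full((n, 5), 15)
        ad_alt[:, 2] = 1                        # strong imbalance at v2
        ad_ref = np.full((n, 5), 15)
        return toy_matrix(d, ad_ref=ad_ref, ad_alt=ad_alt)

    def test_each_rule_fires_once(self):
        kept, report = qc.filter_variants(self._fixture())
        assert "missingness" in report.loc["var0", "fail_reasons"]
        assert "hwe" in report.loc["var1", "fail_reasons"]
        assert "ad_balance" in report.loc["var2", "fail_reasons"]
        assert set(report.loc["var3", "fail_reasons"].split(",")) == {
            "missingness", "hwe",
        }
        assert report.loc["var4", "keep"]
        assert list(kept) == ["var4"]

    def test_extreme_thresholds_keep_everything(self):
        thr = qc.VariantQCThresholds(
            missingness_max=1.0, hwe_p_min=0.0, ad_balance_p_min=0.0
        )
        kept, _ = qc.filter_variants(self._fixture(), thr)
        assert len(kept) == 5

    def test_boundary_missingness_is_kept(self):
        # exactly 1/20 = 0.05 missing: strict '>' removal keeps it
        d = np.ones((20, 1), dtype=np.int8)
        d[10:, 0] = 0
        d[0, 0] = MISSING
        m = toy_matrix(d)
        _, report = qc.filter_variants(m)
        assert report["missingness"].iloc[0] == pytest.approx(0.05)
        assert report["keep"].iloc[0]

    def test_idempotent(self):
        m = self._fixture()
        kept1, _ = qc.filter_variants(m)
        sub = m.subset(variant_ids=kept1)
        kept2, _ = qc.filter_variants(sub)
        assert list(kept1) == list(kept2)


class TestComputePcs:
    def test_identical_rows_give_zero_scores(self):
        m = toy_matrix(np.ones((10, 6), dtype=np.int8))
        assert np.allclose(qc.compute_pcs(m, 2), 0.0)

    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.1, size=(15, 40))
        b = rng.binomial(2, 0.9, size=(15, 40))
        m = toy_matrix(np.vstack([a, b]))
        pc1 = qc.compute_pcs(m, 2)[:, 0]
        assert (pc1[:15] > 0).all() != (pc1[15:] > 0).all()
        assert np.sign(pc1[:15]).std() == 0 and np.sign(pc1[15:]).std() == 0

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.binomial(2, 0.3, size=(50, 200)))
        scores = qc.compute_pcs(m, 5)
        # independent oracle: eigendecomposition of the standardized
        # genotype covariance
        X = m.dosages.astype(float)
        X = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        idx = np.argsort(evals)[::-1][:5]
        V = evecs[:, idx]
        for c in range(5):
            j = np.argmax(np.abs(V[:, c]))
            if V[j, c] < 0:
                V[:, c] *= -1
        assert np.allclose(scores, X @ V, atol=1e-8)


class TestSampleQC:
    def test_clean_cohort_keeps_everyone(self):
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.binomial(2, 0.3, size=(40, 60)))
        sheet = pd.DataFrame({"ancestry_frac": np.full(40, 0.99)}, index=m.samples)
        rep = qc.sample_qc(m, sheet)
        assert len(rep.kept) == 40 and rep.removed.empty

    def test_low_ancestry_removed_with_reason(self):
        rng = np.random.default_rng(4)
        m = toy_matrix(rng.binomial(2, 0.3, size=(30, 50)))
        anc = np.full(30, 0.95)
        anc[7] = 0.5
        sheet = pd.DataFrame({"ancestry_frac": anc}, index=m.samples)
        rep = qc.sample_qc(m, sheet)
        assert rep.removed.loc["s7", "reason"] == "ancestry"

    def test_high_missingness_removed(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, size=(30, 50)).astype(np.int8)
        d[3, :20] = MISSING  # 40% missing
        m = toy_matrix(d)
        sheet = pd.DataFrame({"ancestry_frac": np.full(30, 0.95)}, index=m.samples)
        rep = qc.sample_qc(m, sheet)
        assert rep.removed.loc["s3", "reason"] == "missingness"

    def test_relatedness_drops_one_member_of_pair(self):
        rng = np.random.default_rng(6)
        m = toy_matrix(rng.binomial(2, 0.3, size=(30, 50)))
        sheet = pd.DataFrame({"ancestry_frac": np.full(30, 0.95)}, index=m.samples)
        rel = pd.DataFrame(
            {"sample_1": ["s1"], "sample_2": ["s2"], "stat": [0.5]}
        )
        rep = qc.sample_qc(m, sheet, relatedness=rel)
        dropped = set(rep.removed.index[rep.removed["reason"] == "relatedness"])
        assert len(dropped & {"s1", "s2"}) == 1

    def test_planted_pca_outlier_removed_first_iteration(self):
        rng = np.random.default_rng(7)
        # low-frequency variants: hom-alt across the board is a huge
        # standardized displacement aligned with a single axis, which
        # the leading PC picks up; the heterozygosity rule is disabled
        # here to isolate the PCA path
        d = rng.binomial(2, 0.05, size=(100, 50)).astype(np.int8)
        d[99] = 2
        m = toy_matrix(d)
        sheet = pd.DataFrame({"ancestry_frac": np.full(100, 0.95)}, index=m.samples)
        thr = qc.SampleQCThresholds(het_sd=1e9)
        rep = qc.sample_qc(m, sheet, thresholds=thr)
        assert rep.removed.loc["s99", "reason"] == "pca_outlier"
        assert rep.n_pca_iterations_used >= 1
        assert len(rep.kept) == 99
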