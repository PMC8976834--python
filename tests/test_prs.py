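"""Polygenic scoring: harmonisation, clumping, scoring, onset analysis."""

import numpy as np
import pandas as pd
import pytest

from dcgwas import prs
from dcgwas.containers import MISSING

from conftest import toy_matrix


def study_variants(rows):
    """rows: (variant_id, chrom, pos, ref, alt)"""
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id")


def sumstat_rows(rows):
    """rows: (variant_id, effect_allele, other_allele, beta, p)"""
    return pd.DataFrame(
        rows, columns=["variant_id", "effect_allele", "other_allele", "beta", "p"]
    )


class TestHarmonize:
    SV = study_variants(
        [
            ("v1", "1", 1000, "A", "G"),
            ("v2", "1", 2000, "C", "T"),
            ("v3", "2", 3000, "A", "T"),       # strand-ambiguous
            ("v4", "6", 26_000_000, "A", "C"),  # inside the HLA window
            ("v5", "3", 4000, "A", "G"),
        ]
    )

    def test_alt_coded_weight_kept_ref_coded_flipped(self):
        ss = sumstat_rows(
            [("v1", "G", "A", 0.3, 1e-10), ("v2", "C", "T", 0.2, 1e-10)]
        )
        w, rep = prs.harmonize(self.SV, ss)
        assert w.loc["v1", "weight"] == pytest.approx(0.3)
        # v2 coded on the study reference allele: sign flips
        assert w.loc["v2", "weight"] == pytest.approx(-0.2)

    def test_ambiguous_and_hla_variants_dropped(self):
        ss = sumstat_rows(
            [("v3", "T", "A", 0.5, 1e-20), ("v4", "C", "A", 0.4, 1e-20)]
        )
        w, rep = prs.harmonize(self.SV, ss)
        assert len(w) == 0
        assert rep.dropped["strand_ambiguous"] == 1
        assert rep.dropped["hla_region"] == 1

    def test_allele_mismatch_dropped(self):
        ss = sumstat_rows([("v1", "C", "T", 0.3, 1e-10)])
        w, rep = prs.harmonize(self.SV, ss)
        assert rep.dropped["allele_mismatch"] == 1

    def test_counts_conserved_across_filters(self):
        ss = sumstat_rows(
            [
                ("v1", "G", "A", 0.3, 1e-10),
                ("v3", "T", "A", 0.5, 1e-20),
                ("v4", "C", "A", 0.4, 1e-20),
                ("vX", "A", "G", 0.1, 0.5),   # not in the study
                ("v5", "C", "T", 0.1, 0.5),   # mismatching alleles
            ]
        )
        w, rep = prs.harmonize(self.SV, ss)
        assert rep.n_input == rep.n_matched + sum(rep.dropped.values())
        assert rep.n_matched == len(w) == 1

    def test_low_maf_filter(self):
        ss = sumstat_rows([("v1", "G", "A", 0.3, 1e-10)])
        maf = pd.Series({"v1": 0.005})
        w, rep = prs.harmonize(self.SV, ss, study_maf=maf)
        assert rep.dropped["low_maf"] == 1

    def test_simulated_flips_round_trip(self):
        """Deliberately flipped summary-statistic rows recover the
        unflipped weights after harmonisation."""
        from dcgwas.simulate import SimulationConfig, simulate_cohorts
        from dcgwas.simulate import simulate_external_sumstats

        cfg = SimulationConfig(
            seed=21, n_case=60, n_ctrl_a=30, n_ctrl_b=30, m_common=60,
            m_rare_per_gene=1, n_genes=2, batch_size=2000,
        )
        matrix, _, _, truth = simulate_cohorts(cfg)
        kw = dict(truth=truth, trait="allergy", n_gwas=100_000, seed=9,
                  variants=matrix.variants)
        flipped = simulate_external_sumstats(flip_frac=0.6, **kw)
        plain = simulate_external_sumstats(flip_frac=0.0, **kw)
        w_f, _ = prs.harmonize(matrix.variants, flipped)
        w_p, _ = prs.harmonize(matrix.variants, plain)
        common = w_f.index.intersection(w_p.index)
        assert len(common) > 10
        np.testing.assert_allclose(
            w_f.loc[common, "weight"], w_p.loc[common, "weight"], atol=1e-12
        )


class TestLdClump:
    def _weights(self, rows):
        """rows: (variant_id, chrom, pos, weight, p)"""
        return pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "weight", "p"]
        ).set_index("variant_id")

    def test_single_significant_variant_retained(self):
        w = self._weights([("v1", "1", 1_000_000, 0.3, 1e-10)])
        assert list(prs.ld_clump(w).index) == ["v1"]

    def test_sub_threshold_variants_never_enter(self):
        w = self._weights([("v1", "1", 1_000_000, 0.3, 1e-7)])
        assert len(prs.ld_clump(w)) == 0

    def test_nearby_pair_keeps_only_the_stronger(self):
        # 500 kb apart, low LD: the distance rule removes the weaker
        w = self._weights(
            [
                ("v1", "1", 1_000_000, 0.3, 1e-10),
                ("v2", "1", 1_500_000, 0.2, 1e-9),
            ]
        )
        got = prs.ld_clump(w, r2_lookup=lambda a, b: 0.01)
        assert list(got.index) == ["v1"]

    def test_distant_low_ld_pair_both_retained(self):
        w = self._weights(
            [
                ("v1", "1", 1_000_000, 0.3, 1e-10),
                ("v2", "1", 3_000_000, 0.2, 1e-9),
            ]
        )
        got = prs.ld_clump(w, r2_lookup=lambda a, b: 0.01)
        assert sorted(got.index) == ["v1", "v2"]

    def test_distant_high_ld_pair_pruned(self):
        w = self._weights(
            [
                ("v1", "1", 1_000_000, 0.3, 1e-10),
                ("v2", "1", 3_000_000, 0.2, 1e-9),
            ]
        )
        got = prs.ld_clump(w, r2_lookup=lambda a, b: 0.5)
        assert list(got.index) == ["v1"]

    def test_different_chromosomes_independent(self):
        w = self._weights(
            [
                ("v1", "1", 1_000_000, 0.3, 1e-10),
                ("v2", "2", 1_100_000, 0.2, 1e-9),
            ]
        )
        got = prs.ld_clump(w, r2_lookup=lambda a, b: 0.99)
        assert sorted(got.index) == ["v1", "v2"]

    def test_accepted_set_is_pairwise_independent(self):
        rng = np.random.default_rng(22)
        rows = [
            (f"v{i}", str(rng.integers(1, 4)), int(rng.integers(1, 2e8)),
             0.1, 10.0 ** -rng.uniform(8, 30))
            for i in range(60)
        ]
        w = self._weights(rows)
        got = prs.ld_clump(w)
        for i, a in enumerate(got.index):
            for b in got.index[i + 1:]:
                same = got.loc[a, "chrom"] == got.loc[b, "chrom"]
                if same:
                    assert abs(got.loc[a, "pos"] - got.loc[b, "pos"]) >= 1_000_000


class TestScoreSamples:
    def _weights(self, ids, weights):
        return pd.DataFrame(
            {"weight": weights},
            index=pd.Index(ids, name="variant_id"),
        )

    def test_hand_arithmetic(self):
        m = toy_matrix([[0, 1, 2]])
        s = prs.score_samples(m, self._weights(["var0", "var1", "var2"],
                                               [0.1, -0.2, 0.3]))
        assert s.iloc[0] == pytest.approx(0.4, abs=1e-12)

    def test_zero_weights_zero_scores(self):
        m = toy_matrix([[0, 1, 2], [2, 2, 2]])
        s = prs.score_samples(m, self._weights(["var0", "var1", "var2"], [0, 0, 0]))
        assert (s == 0).all()

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(23)
        m = toy_matrix(rng.binomial(2, 0.3, size=(20, 5)))
        ids = [f"var{j}" for j in range(5)]
        w = rng.normal(0, 0.2, 5)
        s1 = prs.score_samples(m, self._weights(ids, w))
        s2 = prs.score_samples(m, self._weights(ids, 2 * w))
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        m = toy_matrix([[2], [0], [MISSING]])
        s = prs.score_samples(m, self._weights(["var0"], [1.0]))
        assert s.iloc[2] == pytest.approx(1.0)  # mean dosage of (2, 0)

    def test_no_overlap_is_an_error(self):
        m = toy_matrix([[0, 1]])
        with pytest.raises(ValueError):
            prs.score_samples(m, self._weights(["other"], [0.5]))


class TestOnsetDichotomization:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (12, "childhood"), (25, "adult"), (18, "excluded"),
            (0, "childhood"), (60, "adult"), (13, "excluded"),
            (24, "excluded"), (np.nan, "excluded"), (None, "excluded"),
        ],
    )
    def test_bins(self, age, expected):
        assert prs.dichotomize_onset(age) == expected

    def test_negative_age_is_an_error(self):
        with pytest.raises(ValueError):
            prs.dichotomize_onset(-1)


class TestOnsetAssociation:
    def _fixture(self, n=600, seed=24):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)])
        strong = rng.standard_normal(n)
        weak = rng.standard_normal(n)
        eta = 1.2 * strong
        y_child = rng.random(n) < 1 / (1 + np.exp(-eta))
        onset = pd.Series(np.where(y_child, "childhood", "adult"), index=idx)
        scores = pd.DataFrame({"strong": strong, "weak": weak}, index=idx)
        return scores, onset

    def test_planted_predictor_found_null_not_significant(self):
        scores, onset = self._fixture()
        out = prs.onset_association(scores, onset, n_scores=7)
        assert out.loc["strong", "significant"]
        assert out.loc["strong", "beta"] > 0
        assert not out.loc["weak", "significant"]

    def test_significance_is_bonferroni_at_alpha_over_n(self):
        scores, onset = self._fixture()
        out = prs.onset_association(scores, onset, n_scores=7)
        for _, row in out.iterrows():
            assert bool(row["significant"]) == (row["p"] < 0.05 / 7)

    def test_excluded_samples_dropped(self):
        scores, onset = self._fixture(n=100)
        onset.iloc[:20] = "excluded"
        out = prs.onset_association(scores, onset, n_scores=2)
        assert np.isfinite(out["p"]).all()

    def test_single_class_is_an_error(self):
        scores, onset = self._fixture(n=50)
        onset[:] = "adult"
        with pytest.raises(ValueError):
            prs.onset_association(scores, onset)
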