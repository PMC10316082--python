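import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pepdesc as pp
from pepdesc import DEParams
from pepdesc.descore import protein_de_score

from conftest import make_design, make_table
from oracles import brute_force_pairwise_median, exact_wilcoxon_p, rank_sum_u


class TestPairwiseRatioMedian:
    @pytest.mark.parametrize("x1, x2, median, n", [
        ([4, 4], [2, 2], 2.0, 4),          # constant ratio
        ([8, 2], [2, 2], 2.5, 4),          # ratios {4,4,1,1} -> midpoint 2.5
        ([4, 0], [2, 2], 1.0, 4),          # zero policy: {2,2,0,0} -> 1.0
        ([4, 4], [0, 0], math.inf, 4),     # absent denominator group
        ([0, 0], [2, 2], 0.0, 4),          # absent numerator group
    ])
    def test_known_medians(self, x1, x2, median, n):
        got, got_n = pp.pairwise_ratio_median(x1, x2)
        assert got_n == n
        assert got == median

    def test_all_zero_pairs_dropped(self):
        med, n = pp.pairwise_ratio_median([0, 0], [0, 0])
        assert n == 0 and math.isnan(med)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m, n = rng.integers(2, 9, size=2)
            x1 = np.where(rng.random(m) < 0.3, 0.0, rng.lognormal(0, 1, m))
            x2 = np.where(rng.random(n) < 0.3, 0.0, rng.lognormal(0, 1, n))
            exp_med, exp_n = brute_force_pairwise_median(x1, x2)
            got_med, got_n = pp.pairwise_ratio_median(x1, x2)
            assert got_n == exp_n
            if exp_n:
                if math.isinf(exp_med):
                    assert math.isinf(got_med)
                else:
                    assert got_med == pytest.approx(exp_med, rel=1e-12)


class TestPeptideDeScore:
    @pytest.mark.parametrize("median, score", [
        (2.0, 1.0), (16.0, 1.5), (1.0, 0.0),
        (1 / 16, -1.5), (0.0, -1.5), (math.inf, 1.5),
    ])
    def test_log2_with_clipping(self, median, score):
        assert pp.peptide_de_score(median, clip=1.5) == score

    def test_nan_propagates(self):
        assert math.isnan(pp.peptide_de_score(float("nan")))


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        assert pp.wilcoxon_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert pp.wilcoxon_two_sided([2, 2, 3], [3, 2, 2]) == 1.0
        assert pp.wilcoxon_two_sided([5, 5, 5], [5, 5, 5]) == 1.0

    def test_matches_exact_enumeration_oracle(self):
        """Exact agreement with brute-force rank enumeration, all sizes <= 5."""
        rng = np.random.default_rng(7)
        for m in range(2, 6):
            for n in range(2, 6):
                for _ in range(10):
                    pooled = rng.permutation(rng.uniform(0, 1, m + n))
                    x1, x2 = pooled[:m], pooled[m:]
                    assert pp.wilcoxon_two_sided(x1, x2) == pytest.approx(
                        exact_wilcoxon_p(x1, x2), abs=1e-12)

    @given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_u_statistics_sum_to_mn(self, m, n, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.integers(0, 5, m).astype(float)  # ties likely
        x2 = rng.integers(0, 5, n).astype(float)
        u1, u2 = rank_sum_u(x1, x2)
        assert u1 + u2 == pytest.approx(m * n)


class TestPositivePearson:
    def test_perfect_and_negative_and_constant(self):
        x = np.array([1.0, 2, 3, 4])
        assert pp.positive_pearson(x, 2 * x) == pytest.approx(1.0)
        assert pp.positive_pearson(x, -x + 10) == 0.0
        assert pp.positive_pearson(np.full(4, 3.0), x) == 0.0


class TestPeptideWeights:
    def test_identical_profiles_weighted_by_mean(self):
        base = np.array([1, 2, 3, 4.0])
        X = np.vstack([10 * base / base.mean(), 30 * base / base.mean()])
        w = pp.peptide_weights(X)
        np.testing.assert_allclose(w, [0.25, 0.75])

    def test_symmetric_peptides_share_weight_equally(self):
        X = np.tile([5.0, 6, 7, 8], (4, 1))
        np.testing.assert_allclose(pp.peptide_weights(X), np.full(4, 0.25))

    def test_uncorrelated_peptides_fall_back_to_abundance(self):
        # orthogonal fluctuations -> r+ = 0 off-diagonal, self-terms only
        x1 = np.array([10.0, 10, 9, 11, 10, 10])
        x2 = np.array([30.0, 31, 30, 30, 29, 30])
        assert pp.positive_pearson(x1, x2) == 0.0
        w = pp.peptide_weights(np.vstack([x1, x2]))
        np.testing.assert_allclose(w, [0.25, 0.75], atol=1e-12)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weights_always_normalized(self, n_pep, seed):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(1, 1, size=(n_pep, 8))
        w = pp.peptide_weights(X)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()


class TestProteinDeScore:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["de_score", "p_value", "weight",
                                           "median_ratio"])

    def test_all_nonsignificant_scores_zero(self):
        df = self._df([[1.5, 0.06, 0.5, 2.8], [1.0, 0.9, 0.5, 2.0]])
        assert protein_de_score(df, DEParams()) == 0.0

    def test_single_peptide_unclipped_log2(self):
        df = self._df([[1.0, 0.01, 1.0, 2.0]])
        assert protein_de_score(df, DEParams()) == pytest.approx(1.0)
        big = self._df([[1.5, 0.01, 1.0, 16.0]])  # |log2| past the clip
        assert protein_de_score(big, DEParams()) == pytest.approx(4.0)
        assert protein_de_score(big, DEParams(clip_single_peptide=True)) == 1.5

    def test_two_identical_significant_peptides(self):
        df = self._df([[1.0, 0.01, 0.5, 2.0], [1.0, 0.01, 0.5, 2.0]])
        assert protein_de_score(df, DEParams()) == pytest.approx(1.0)

    def test_gate_applied_per_peptide(self):
        df = self._df([[1.0, 0.01, 0.6, 2.0], [1.0, 0.9, 0.4, 2.0]])
        assert protein_de_score(df, DEParams()) == pytest.approx(0.6)


class TestRunPepdesc:
    def _noise_free(self, seed=5):
        cfg = pp.SimConfig(seed=seed, n_stable_proteins=40, n_de_proteins=5,
                           protein_abundance_sdlog=0.0, measurement_cv=0.0,
                           dropout=False, n_contaminant_peptides=0,
                           n_masquerading_peptides=0)
        return pp.simulate_mixed_benchmark(cfg)

    def test_halved_proteins_score_minus_one_stable_zero(self):
        out = self._noise_free()
        res = pp.run_pepdesc(out.table, out.design, out.contaminant_annotation)
        ps = res.protein_scores.set_index("protein_accession")
        lab = out.truth.labels.reindex(ps.index)
        np.testing.assert_allclose(ps.de_score[lab == "changing"], -1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(ps.de_score[lab == "stable"], 0.0,
                                   atol=1e-9)

    def test_contaminant_only_table_gives_empty_output(self):
        t = make_table(np.ones((3, 4)), accessions=["CON_A", "CON_B", "REV_C"])
        res = pp.run_pepdesc(t, make_design(2, 2))
        assert len(res.protein_scores) == 0
        assert res.report.n_removed_by_accession == 3

    def test_deterministic(self):
        out = self._noise_free()
        r1 = pp.run_pepdesc(out.table, out.design, out.contaminant_annotation)
        r2 = pp.run_pepdesc(out.table, out.design, out.contaminant_annotation)
        pd.testing.assert_frame_equal(r1.protein_scores, r2.protein_scores)
        pd.testing.assert_frame_equal(r1.peptide_scores, r2.peptide_scores)

    def test_antisymmetry_under_group_swap(self):
        """Swapping group labels negates peptide scores (exactly for odd
        pair counts; within the median-interpolation discrepancy otherwise)."""
        rng = np.random.default_rng(11)
        values = rng.lognormal(3, 1, size=(40, 6))  # 3x3: odd pair count
        t = make_table(values, accessions=[f"P{i}" for i in range(40)])
        fwd = make_design(3, 3)
        rev = pp.SampleDesign(sample_ids=fwd.sample_ids,
                              group_labels=fwd.group_labels,
                              group_names=("group2", "group1"))
        a = pp.score_peptides(t, fwd).set_index("peptide_id")
        b = pp.score_peptides(t, rev).set_index("peptide_id")
        np.testing.assert_allclose(a.de_score, -b.de_score, atol=1e-9)
        np.testing.assert_allclose(a.p_value, b.p_value, atol=1e-12)

    def test_antisymmetry_even_pair_counts_approximate(self):
        rng = np.random.default_rng(12)
        values = rng.lognormal(3, 0.5, size=(30, 8))
        t = make_table(values, accessions=[f"P{i}" for i in range(30)])
        fwd = make_design(4, 4)
        rev = pp.SampleDesign(sample_ids=fwd.sample_ids,
                              group_labels=fwd.group_labels,
                              group_names=("group2", "group1"))
        a = pp.score_peptides(t, fwd).set_index("peptide_id")
        b = pp.score_peptides(t, rev).set_index("peptide_id")
        nonzero = a.de_score.abs() > 1e-6
        assert (np.sign(a.de_score[nonzero]) == -np.sign(b.de_score[nonzero])).all()
        np.testing.assert_allclose(a.de_score, -b.de_score, atol=0.2)
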