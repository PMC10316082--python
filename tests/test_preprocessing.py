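import numpy as np
import pandas as pd
import pytest

from pepdesc import (
    ContaminantAnnotation,
    FilterParams,
    NormalizationParams,
    ValidationError,
    apply_filters,
    detect_outlier_samples,
    filter_by_missingness,
    filter_contaminant_accessions,
    filter_contaminant_features,
    normalize_samples,
)
from pepdesc.tables_io import PepdescError

from conftest import make_design, make_table


class TestAccessionFilter:
    def test_prefixed_accessions_removed_others_kept(self):
        t = make_table(np.ones((3, 4)),
                       accessions=["CON_P12345", "REV_X", "P12345"])
        out, rep = filter_contaminant_accessions(t, ContaminantAnnotation())
        assert list(out.protein_accession) == ["P12345"]
        assert rep.n_removed_by_accession == 2
        assert set(rep.removed_by_accession) == {"pep1", "pep2"}

    def test_empty_prefix_list_is_identity(self):
        t = make_table(np.ones((2, 4)), accessions=["CON_A", "B"])
        out, rep = filter_contaminant_accessions(
            t, ContaminantAnnotation(accession_prefixes=()))
        assert out.n_peptides == 2 and rep.n_removed == 0


class TestMissingnessFilter:
    @pytest.mark.parametrize("n_missing, kept", [(7, False), (6, True), (0, True)])
    def test_strictly_over_threshold_removed(self, n_missing, kept):
        """'Over 60%' is strict: 7/10 missing removed, 6/10 retained."""
        row = [0.0] * n_missing + [1.0] * (10 - n_missing)
        t = make_table([row])
        out, rep = filter_by_missingness(t, 0.6)
        assert (out.n_peptides == 1) == kept
        assert rep.n_removed_by_missingness == (0 if kept else 1)

    def test_threshold_out_of_range_rejected(self):
        t = make_table(np.ones((1, 4)))
        with pytest.raises(ValidationError):
            filter_by_missingness(t, 0.0)
        with pytest.raises(ValidationError):
            filter_by_missingness(t, 1.5)


class TestFeatureFilter:
    ann = ContaminantAnnotation(feature_table=np.array([[10.0, 500.0]]))

    @pytest.mark.parametrize("rt, mz, removed", [
        (10.03, 501.3, True),   # 0.03 < 0.05 and 1.3 < 2
        (10.06, 501.3, False),  # 0.06 >= 0.05: strict boundary
        (10.03, 502.0, False),  # Δmz = 2 is not < 2
    ])
    def test_strict_tolerance_matching(self, rt, mz, removed):
        t = make_table(np.ones((1, 4)), rt=[rt], mz=[mz])
        out, rep = filter_contaminant_features(t, self.ann, FilterParams())
        assert (out.n_peptides == 0) == removed

    def test_empty_feature_table_is_identity(self):
        t = make_table(np.ones((2, 4)), rt=[10, 11], mz=[500, 600])
        out, _ = filter_contaminant_features(t, ContaminantAnnotation(), FilterParams())
        assert out.n_peptides == 2

    def test_table_without_features_is_noop(self):
        t = make_table(np.ones((2, 4)))
        out, _ = filter_contaminant_features(t, self.ann, FilterParams())
        assert out.n_peptides == 2


def test_filter_order_and_count_conservation():
    """Rules run accession -> missingness -> feature; counts conserve rows,
    and re-filtering the output is a no-op (idempotence)."""
    values = np.ones((4, 10))
    values[1, :7] = 0  # 70% missing -> missingness rule
    t = make_table(values, accessions=["CON_X", "CON_Y", "P1", "P2"],
                   rt=[10.0, 10.0, 10.0, 20.0], mz=[500.0, 500, 500, 900])
    ann = ContaminantAnnotation(feature_table=np.array([[10.0, 500.0]]))
    out, rep = apply_filters(t, ann)
    # pep2 is both CON-prefixed and 70% missing: attributed to the first rule
    assert set(rep.removed_by_accession) == {"pep1", "pep2"}
    assert rep.removed_by_missingness == []
    assert rep.removed_by_feature_match == ["pep3"]
    assert t.n_peptides == out.n_peptides + rep.n_removed
    again, rep2 = apply_filters(out, ann)
    assert rep2.n_removed == 0
    pd.testing.assert_frame_equal(again.abundances, out.abundances)


class TestOutlierSamples:
    def test_identical_samples_flag_nothing(self):
        t = make_table(np.full((5, 8), 3.0))
        assert detect_outlier_samples(t, make_design(4, 4)) == []

    def test_mostly_missing_sample_flagged(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(3, 0.2, size=(100, 8))
        values[:96, 0] = 0  # 96% missing in sample s1
        t = make_table(values)
        assert "s1" in detect_outlier_samples(t, make_design(4, 4),
                                              max_missing=0.95)

    def test_extreme_total_intensity_flagged_by_mad_rule(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(3, 0.1, size=(50, 20))
        values[:, 3] *= 100.0
        t = make_table(values)
        flagged = detect_outlier_samples(t, make_design(10, 10))
        assert flagged == ["s4"]

    def test_small_groups_skip_detection(self):
        t = make_table(np.ones((3, 4)))
        assert detect_outlier_samples(t, make_design(2, 2)) == []


class TestNormalization:
    def test_global_median_rescaling_matches_hand_computation(self):
        # sample medians 10 and 20 -> both rescaled to their midpoint 15
        t = make_table([[5.0, 10.0], [10.0, 20.0], [10.0, 20.0], [20.0, 40.0]])
        d = make_design(1, 1)
        out = normalize_samples(t, d, NormalizationParams(method="median",
                                                          per_group=False))
        med = out.abundances.median(axis=0)
        np.testing.assert_allclose(med.to_numpy(), [15.0, 15.0])

    def test_auto_switches_to_mean_over_half_missing(self):
        values = np.ones((20, 4))
        values[:11, 0] = 0  # sample s1 at 55% missing
        t = make_table(values + np.arange(20)[:, None] * 0.0)
        # make medians != means so the choice is observable
        t.abundances.iloc[0, :] = [0, 100, 100, 100]
        d = make_design(2, 2)
        out = normalize_samples(t, d, NormalizationParams(method="auto"))
        exp = normalize_samples(t, d, NormalizationParams(method="mean"))
        pd.testing.assert_frame_equal(out.abundances, exp.abundances)

    def test_idempotent_and_missing_cells_stay_zero(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(2, 1, size=(30, 6))
        values[rng.random(values.shape) < 0.2] = 0
        t = make_table(values)
        d = make_design(3, 3)
        once = normalize_samples(t, d)
        twice = normalize_samples(once, d)
        pd.testing.assert_frame_equal(once.abundances, twice.abundances)
        assert (once.abundances.to_numpy()[values == 0] == 0).all()

    @pytest.mark.parametrize("c", [1e-3, 7.0])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(3)
        values = rng.lognormal(2, 1, size=(30, 6))
        t = make_table(values)
        d = make_design(3, 3)
        a = normalize_samples(make_table(values * c), d).abundances
        b = normalize_samples(t, d).abundances * c
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_per_group_rescaling_cancels_composition_shift(self):
        """Halving many proteins in group 1 must not bias stable ratios."""
        rng = np.random.default_rng(4)
        values = rng.lognormal(5, 1, size=(200, 8))
        values[:60, :4] *= 0.5  # 30% of peptides halved in group 1
        t = make_table(values, accessions=[f"P{i}" for i in range(200)])
        d = make_design(4, 4)
        out = normalize_samples(t, d, NormalizationParams(method="median",
                                                          per_group=True))
        stable = out.abundances.iloc[60:]
        ratio = (stable.iloc[:, :4].mean(axis=1) / stable.iloc[:, 4:].mean(axis=1))
        assert abs(np.log2(ratio).mean()) < 0.05

    def test_all_missing_sample_errors(self):
        values = np.ones((4, 4))
        values[:, 2] = 0
        with pytest.raises(PepdescError):
            normalize_samples(make_table(values), make_design(2, 2))
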