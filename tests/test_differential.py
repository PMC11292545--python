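import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pepiso.digest import IsoformCatalog
from pepiso.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
)
from pepiso.io_formats import AnalysisThresholds, SampleDesign
from pepiso.differential import (
    call_isoform_discordance,
    compare_proportions,
    differential_abundance,
    pca_qc,
    permutation_fdr,
    students_t,
)
from pepiso.normalization import NormalizedMatrix

finite_floats = st.floats(min_value=-50, max_value=50, allow_nan=False)
sample_lists = st.lists(finite_floats, min_size=2, max_size=8)


class TestStudentsT:
    def test_identical_groups_give_null_result(self):
        assert students_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_hand_computed_pooled_variance_example(self):
        t, p = students_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_degenerate_variance_with_unequal_means(self):
        with pytest.raises(DegenerateVarianceError):
            students_t([0, 0, 0], [1, 1, 1])

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            students_t([1.0], [1.0, 2.0])

    @given(sample_lists, sample_lists)
    def test_matches_scipy_pooled_ttest(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, p = students_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    @given(
        st.lists(st.integers(-50, 50).map(float), min_size=2, max_size=8),
        st.lists(st.integers(-50, 50).map(float), min_size=2, max_size=8),
    )
    def test_antisymmetric_and_shift_invariant(self, a, b):
        if np.var(a) == 0 and np.var(b) == 0:
            return
        t, p = students_t(a, b)
        t_swap, p_swap = students_t(b, a)
        assert t_swap == pytest.approx(-t, rel=1e-9, abs=1e-12)
        assert p_swap == pytest.approx(p, rel=1e-9, abs=1e-12)
        t_shift, p_shift = students_t([x + 11.5 for x in a], [x + 11.5 for x in b])
        assert t_shift == pytest.approx(t, rel=1e-6, abs=1e-9)
        assert p_shift == pytest.approx(p, rel=1e-6, abs=1e-9)


def _normalized(values: pd.DataFrame) -> NormalizedMatrix:
    meta = pd.DataFrame(
        {
            "accessions": values.index,
            "family": values.index,
            "pclass": "UNIQUE",
            "n_peptides": 1,
        },
        index=values.index,
    )
    return NormalizedMatrix(
        values, meta, {g: [] for g in values.index},
        pd.Series(0.0, index=values.columns),
    )


def exhaustive_fdr_oracle(X: np.ndarray, n_a: int) -> np.ndarray:
    """Brute-force permutation FDR over all label splits, via scipy t-tests."""
    n = X.shape[1]
    obs_p = np.array(
        [stats.ttest_ind(row[:n_a], row[n_a:], equal_var=True).pvalue for row in X]
    )
    null_p = []
    for cols in itertools.combinations(range(n), n_a):
        comp = [c for c in range(n) if c not in cols]
        for row in X:
            null_p.append(
                stats.ttest_ind(row[list(cols)], row[comp], equal_var=True).pvalue
            )
    null_p = np.array(null_p)
    n_perm = math.comb(n, n_a)
    q = np.empty_like(obs_p)
    for i, p in enumerate(obs_p):
        mean_null = (null_p <= p).sum() / n_perm
        q[i] = min(1.0, mean_null / (obs_p <= p).sum())
    order = np.argsort(obs_p, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    return q


class TestPermutationFdr:
    def test_matches_exhaustive_oracle_on_three_vs_three(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 6))
        X[0, 3:] += 4.0  # one real effect
        design = SampleDesign(
            tuple((f"a{i}", "A") for i in range(3))
            + tuple((f"b{i}", "B") for i in range(3))
        )
        values = pd.DataFrame(
            X, index=[f"g{i}" for i in range(8)], columns=design.samples
        )
        th = AnalysisThresholds(permutations=1000, seed=0)
        q = permutation_fdr(_normalized(values), design, th)
        expected = exhaustive_fdr_oracle(X, 3)
        np.testing.assert_allclose(q.to_numpy(), expected, rtol=1e-12)

    def test_exhaustive_result_independent_of_budget_beyond_20(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 6))
        design = SampleDesign(
            tuple((f"a{i}", "A") for i in range(3))
            + tuple((f"b{i}", "B") for i in range(3))
        )
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(5)], columns=design.samples)
        q20 = permutation_fdr(_normalized(values), design, AnalysisThresholds(permutations=20, seed=0))
        q999 = permutation_fdr(_normalized(values), design, AnalysisThresholds(permutations=999, seed=7))
        pd.testing.assert_series_equal(q20, q999)

    def test_constant_features_get_q_of_one(self, small_design):
        values = pd.DataFrame(
            np.ones((4, 4)), index=list("abcd"), columns=small_design.samples
        )
        th = AnalysisThresholds(permutations=50, seed=0, min_obs_per_group=2)
        q = permutation_fdr(_normalized(values), small_design, th)
        assert (q == 1.0).all()


class TestDifferentialAbundance:
    def _study_design(self):
        return SampleDesign(
            tuple((f"f{i}", "A") for i in range(12))
            + tuple((f"i{i}", "B") for i in range(11))
        )

    def test_planted_fold_recovered_and_flagged(self):
        rng = np.random.default_rng(3)
        design = self._study_design()
        sigma = math.sqrt(math.log(1 + 0.2**2)) / math.log(2)
        X = rng.normal(0, sigma, size=(40, 23))
        X[0, 12:] += 2.0  # 4-fold planted shift
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(40)], columns=design.samples)
        th = AnalysisThresholds(permutations=100, seed=0)
        records = differential_abundance(_normalized(values), design, th)
        top = records.set_index("group_id").loc["g0"]
        assert top["significant"]
        assert top["fold"] == pytest.approx(4.0, rel=0.3)
        assert top["direction"] == "higher_in_B"

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(4)
        design = self._study_design()
        X = rng.normal(size=(500, 23))
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(500)], columns=design.samples)
        th = AnalysisThresholds(permutations=1, seed=0)
        records = differential_abundance(_normalized(values), design, th, compute_q=False)
        frac = (records["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / 500)
        assert frac <= 0.05 + 3 * se

    def test_min_observation_filter(self, small_design):
        values = pd.DataFrame(
            [[1.0, np.nan, 2.0, 3.0]], index=["g0"], columns=small_design.samples
        )
        th = AnalysisThresholds(permutations=10, seed=0, min_obs_per_group=2)
        records = differential_abundance(_normalized(values), small_design, th)
        assert not records.loc[0, "testable"]
        assert math.isnan(records.loc[0, "p"])

    def test_records_sorted_by_p(self, small_design):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(
            rng.normal(size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=small_design.samples,
        )
        th = AnalysisThresholds(permutations=10, seed=0, min_obs_per_group=2)
        records = differential_abundance(_normalized(values), small_design, th)
        assert records["p"].is_monotonic_increasing


def _record(
    group_id, family, pclass, log2fc, p, *, testable=True, q=np.nan, n_pep=2
):
    return {
        "group_id": group_id,
        "accessions": group_id,
        "family": family,
        "pclass": pclass,
        "n_peptides": n_pep,
        "n_A": 12,
        "n_B": 11,
        "mean_A": 0.0,
        "mean_B": log2fc,
        "log2fc": log2fc,
        "fold": 2 ** abs(log2fc),
        "direction": "higher_in_B" if log2fc > 0 else "lower_in_B",
        "t_stat": 0.0,
        "p": p,
        "q": q,
        "testable": testable,
        "significant": testable and p < 0.05 and 2 ** abs(log2fc) >= 2,
    }


class TestIsoformDiscordance:
    @pytest.fixture
    def catalog(self):
        return IsoformCatalog(
            {"T1": ("T1-1", "T1-2"), "U1": ("U1-1", "U1-2"), "V1": ("V1-1", "V1-2")}
        )

    def test_flat_common_with_specific_shift_is_discordant(self, catalog):
        records = pd.DataFrame(
            [
                _record("T1-1;T1-2", "T1", "SHARED_ISOFORMS", 0.1, 0.6),
                _record("T1-2", "T1", "ISOFORM_SPECIFIC", -4.0, 1e-9),
            ]
        )
        calls = call_isoform_discordance(records, catalog, AnalysisThresholds())
        call = calls.set_index("family").loc["T1"]
        assert call["verdict"] == "SPLICING_DISCORDANT"
        assert call["specific_fold"] == pytest.approx(16.0)

    def test_common_and_specific_shifting_together_is_concordant(self, catalog):
        records = pd.DataFrame(
            [
                _record("T1-1;T1-2", "T1", "SHARED_ISOFORMS", 2.0, 1e-6),
                _record("T1-2", "T1", "ISOFORM_SPECIFIC", 2.1, 1e-7),
            ]
        )
        calls = call_isoform_discordance(records, catalog, AnalysisThresholds())
        assert calls.set_index("family").loc["T1", "verdict"] == "ABUNDANCE_CONCORDANT"

    def test_family_without_specific_record_untestable(self, catalog):
        records = pd.DataFrame(
            [_record("U1-1;U1-2", "U1", "SHARED_ISOFORMS", 0.0, 0.9)]
        )
        calls = call_isoform_discordance(records, catalog, AnalysisThresholds())
        call = calls.set_index("family").loc["U1"]
        assert call["verdict"] == "UNTESTABLE"
        assert call["reason"] == "no_testable_specific_group"

    def test_untestable_common_blocks_the_call(self, catalog):
        records = pd.DataFrame(
            [
                _record("V1-1;V1-2", "V1", "SHARED_ISOFORMS", 0.0, np.nan, testable=False),
                _record("V1-2", "V1", "ISOFORM_SPECIFIC", -4.0, 1e-9),
            ]
        )
        calls = call_isoform_discordance(records, catalog, AnalysisThresholds())
        call = calls.set_index("family").loc["V1"]
        assert call["verdict"] == "UNTESTABLE"
        assert call["reason"] == "no_testable_common_group"

    def test_specific_shift_without_divergence_from_common_not_called(self, catalog):
        # whole-protein shift measured marginally below the fold filter on the
        # common group: not an isoform-usage change
        records = pd.DataFrame(
            [
                _record("T1-1;T1-2", "T1", "SHARED_ISOFORMS", 0.93, 1e-6),
                _record("T1-2", "T1", "ISOFORM_SPECIFIC", 1.05, 1e-7),
            ]
        )
        calls = call_isoform_discordance(records, catalog, AnalysisThresholds())
        assert calls.set_index("family").loc["T1", "verdict"] == "UNTESTABLE"


class TestPcaQc:
    def test_rank_one_structure_separates_duplicated_profiles(self, small_design):
        profile_a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        profile_b = profile_a + np.array([2.0, -2.0, 2.0, -2.0, 2.0])
        values = pd.DataFrame(
            np.column_stack([profile_a, profile_a, profile_b, profile_b]),
            index=[f"g{i}" for i in range(5)],
            columns=small_design.samples,
        )
        result = pca_qc(_normalized(values), small_design)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        # within-cohort spread is numerically ~0, so the separation score
        # is effectively unbounded
        assert result.separation > 1e3 or result.separation == math.inf

    def test_insufficient_complete_features_rejected(self, small_design):
        values = pd.DataFrame(
            [[1.0, 2.0, np.nan, 3.0], [1.0, 2.0, 3.0, 4.0]],
            index=["g0", "g1"],
            columns=small_design.samples,
        )
        with pytest.raises(InsufficientDataError):
            pca_qc(_normalized(values), small_design)

    def test_zero_variance_everywhere_rejected(self, small_design):
        values = pd.DataFrame(
            np.ones((5, 4)), index=[f"g{i}" for i in range(5)],
            columns=small_design.samples,
        )
        with pytest.raises(InsufficientDataError):
            pca_qc(_normalized(values), small_design)


class TestCompareProportions:
    def test_study_defect_counts_display_percentages(self):
        res = compare_proportions(149, 4891, 851, 4263)
        assert res.pct1 == 3
        assert res.pct2 == 20
        assert res.p1 == pytest.approx(0.0305, abs=5e-4)
        assert res.p2 == pytest.approx(0.1996, abs=5e-4)
        assert res.p < 1e-100

    def test_identical_proportions_are_null(self):
        res = compare_proportions(5, 10, 5, 10)
        assert (res.diff, res.chi2, res.p) == (0.0, 0.0, 1.0)

    def test_extreme_table_matches_hand_chi_square(self):
        res = compare_proportions(0, 10, 10, 10)
        assert res.chi2 == pytest.approx(20.0, rel=1e-12)
        assert (res.p1, res.p2) == (0.0, 1.0)

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(11, 10, 1, 10)
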