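import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rulemvpa import decoding as dec
from rulemvpa.conditions import CONDITIONS_OF_INTEREST

from conftest import make_pattern_set


@pytest.fixture(scope="module")
def beta_volumes():
    """Complete (condition, run) -> 3D volume mapping for one session."""
    rng = np.random.default_rng(0)
    from rulemvpa.conditions import TASK_CONDITIONS

    return {
        (c, r): rng.standard_normal((6, 6, 4))
        for c in TASK_CONDITIONS
        for r in (1, 2, 3, 4)
    }


@pytest.fixture(scope="module")
def roi_mask():
    mask = np.zeros((6, 6, 4), dtype=bool)
    mask[1:4, 1:4, 1:3] = True
    return mask


class TestExtractPatterns:
    def test_bookkeeping_32_betas_16_patterns_8_per_search(self, beta_volumes, roi_mask):
        assert len(beta_volumes) == 32  # eight task conditions x four runs
        ps = dec.extract_patterns(beta_volumes, roi_mask)
        assert ps.X.shape[0] == 16  # four conditions of interest x four runs
        by_search = ps.split_by_search()
        assert {k: v.X.shape[0] for k, v in by_search.items()} == {
            "separate": 8,
            "parallel": 8,
        }
        for sub in by_search.values():
            for r in (1, 2, 3, 4):
                in_run = sub.domains[sub.runs == r]
                assert sorted(in_run) == ["spatial", "verbal"]

    def test_row_order_run_major_then_condition(self, beta_volumes, roi_mask):
        ps = dec.extract_patterns(beta_volumes, roi_mask)
        assert list(ps.runs[:4]) == [1, 1, 1, 1]
        np.testing.assert_array_equal(
            ps.X[0], beta_volumes[(CONDITIONS_OF_INTEREST[0], 1)][roi_mask]
        )

    def test_single_voxel_mask(self, beta_volumes):
        mask = np.zeros((6, 6, 4), dtype=bool)
        mask[2, 3, 1] = True
        ps = dec.extract_patterns(beta_volumes, mask)
        assert ps.X.shape == (16, 1)
        assert ps.X[0, 0] == beta_volumes[(CONDITIONS_OF_INTEREST[0], 1)][2, 3, 1]

    def test_empty_mask_rejected(self, beta_volumes):
        with pytest.raises(ValueError, match="empty"):
            dec.extract_patterns(beta_volumes, np.zeros((6, 6, 4), dtype=bool))

    def test_missing_condition_run_listed(self, beta_volumes, roi_mask):
        partial = {k: v for k, v in beta_volumes.items() if k != ("disc_verbal_separate", 3)}
        with pytest.raises(KeyError, match="disc_verbal_separate"):
            dec.extract_patterns(partial, roi_mask)

    def test_normalization_zscores_rows(self, beta_volumes, roi_mask):
        ps = dec.extract_patterns(beta_volumes, roi_mask, normalize=True)
        np.testing.assert_allclose(ps.X.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(ps.X.std(axis=1), 1.0, atol=1e-12)


class TestLORO:
    def test_separable_patterns_decode_perfectly(self):
        ps = make_pattern_set(
            np.random.default_rng(1), pattern_sd=3.0, noise_sd=0.05
        ).split_by_search()["separate"]
        result = dec.loro_decode(ps)
        assert result.accuracy == 1.0

    def test_four_runs_give_four_folds(self):
        ps = make_pattern_set(np.random.default_rng(2)).split_by_search()["separate"]
        assert len(dec.loro_decode(ps).fold_accuracies) == 4

    def test_identical_class_rows_sit_at_chance(self):
        # verbal and spatial rows drawn from the same distribution: the
        # mean accuracy over many simulated subjects must approach 0.5
        accs = [
            dec.loro_decode(
                make_pattern_set(np.random.default_rng(10_000 + i))
                .split_by_search()["separate"]
            ).accuracy
            for i in range(200)
        ]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se + 1e-9

    def test_unbalanced_run_rejected(self):
        ps = make_pattern_set(np.random.default_rng(3)).split_by_search()["separate"]
        y = ps.domains.copy()
        y[:] = "verbal"
        with pytest.raises(ValueError, match="one sample per class"):
            dec.loro_decode(ps, labels=y)


class TestGroupDecode:
    def test_group_mean_and_sem_match_hand_oracle(self):
        rng = np.random.default_rng(4)
        sets = [
            make_pattern_set(rng, pattern_sd=1.0, subject=i).split_by_search()["separate"]
            for i in range(1, 4)
        ]
        result = dec.group_decode(sets)
        accs = result.subject_accuracies
        assert result.mean == pytest.approx(np.mean(accs))
        assert result.sem == pytest.approx(np.std(accs, ddof=1) / np.sqrt(3))

    def test_constant_accuracies_have_zero_sem(self):
        r = dec.DecodingResult(subject_accuracies=np.full(13, 0.5))
        assert r.mean == 0.5
        assert r.sem == 0.0
        assert len(r.subject_accuracies) == 13


@pytest.fixture(scope="module")
def subject_sets():
    rng = np.random.default_rng(5)
    return [
        make_pattern_set(rng, n_voxels=12, subject=i).split_by_search()["separate"]
        for i in range(1, 6)
    ]


class TestPermutationNull:
    def test_default_stores_exactly_1000_estimates(self, subject_sets):
        null = dec.permutation_null(subject_sets, seed=1)
        assert len(null.values) == 1000

    def test_null_mean_near_chance_on_noise(self, subject_sets):
        null = dec.permutation_null(subject_sets, n_perm=1000, seed=2)
        se = null.values.std(ddof=1) / np.sqrt(len(null.values))
        # permuted labels on exchangeable data: mean within MC error of 0.5
        assert abs(null.values.mean() - 0.5) < 0.03

    def test_significance_is_strictly_greater(self, subject_sets):
        null = dec.permutation_null(subject_sets, n_perm=200, seed=3)
        assert not null.is_significant(null.critical_value)
        assert null.is_significant(null.critical_value + 1e-9)
        assert null.critical_value >= np.median(null.values)

    def test_small_n_perm_warns(self, subject_sets):
        with pytest.warns(RuntimeWarning, match="n_perm"):
            dec.permutation_null(subject_sets, n_perm=50, seed=4)

    def test_deterministic_given_seed(self, subject_sets):
        a = dec.permutation_null(subject_sets, n_perm=150, seed=7)
        b = dec.permutation_null(subject_sets, n_perm=150, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestCrossSession:
    def test_identical_sessions_transfer_perfectly(self):
        rng = np.random.default_rng(6)
        s1 = [make_pattern_set(rng, pattern_sd=2.0, noise_sd=0.05).split_by_search()["separate"]]
        result = dec.cross_session_decode(s1, s1)
        assert result.mean == 1.0

    def test_voxel_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        a = [make_pattern_set(rng, n_voxels=10).split_by_search()["separate"]]
        b = [make_pattern_set(rng, n_voxels=12).split_by_search()["separate"]]
        with pytest.raises(ValueError, match="voxel-count mismatch"):
            dec.cross_session_decode(a, b)

    def test_both_directions_are_separate_results(self):
        rng = np.random.default_rng(8)
        s1 = [make_pattern_set(rng, pattern_sd=1.0).split_by_search()["separate"]]
        s2 = [make_pattern_set(rng, pattern_sd=1.0).split_by_search()["separate"]]
        r12 = dec.cross_session_decode(s1, s2)
        r21 = dec.cross_session_decode(s2, s1)
        assert r12.subject_accuracies.shape == r21.subject_accuracies.shape
        # directions use different train/test data, results need not agree
        assert isinstance(r12.mean, float) and isinstance(r21.mean, float)


class TestFeatureCurve:
    def test_default_grid_ten_sizes_ten_draws(self):
        rng = np.random.default_rng(9)
        sets = [
            make_pattern_set(rng, n_voxels=120, pattern_sd=1.0, subject=i)
            .split_by_search()["separate"]
            for i in (1, 2)
        ]
        curve = dec.feature_curve(sets, seed=1)
        assert curve.sizes == tuple(range(10, 101, 10))
        assert curve.n_draws == 10
        assert curve.per_subject.shape == (2, 10)

    def test_oversized_subsets_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        sets = [make_pattern_set(rng, n_voxels=35).split_by_search()["separate"]]
        with pytest.warns(RuntimeWarning, match="skipped"):
            curve = dec.feature_curve(sets, seed=1)
        assert curve.sizes == (10, 20, 30)

    def test_all_sizes_oversized_rejected(self):
        rng = np.random.default_rng(11)
        sets = [make_pattern_set(rng, n_voxels=5).split_by_search()["separate"]]
        with pytest.raises(ValueError, match="exceed"):
            dec.feature_curve(sets, seed=1)

    def test_more_voxels_help_at_high_snr(self):
        rng = np.random.default_rng(12)
        sets = [
            make_pattern_set(rng, n_voxels=100, pattern_sd=0.6, subject=i)
            .split_by_search()["separate"]
            for i in range(1, 6)
        ]
        curve = dec.feature_curve(sets, sizes=(10, 100), n_draws=5, seed=2)
        assert curve.group_mean[1] >= curve.group_mean[0]


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), n_voxels=st.integers(2, 25))
def test_accuracy_bounds_and_fold_bookkeeping(seed, n_voxels):
    ps = make_pattern_set(
        np.random.default_rng(seed), n_voxels=n_voxels, pattern_sd=0.5
    ).split_by_search()["parallel"]
    res = dec.loro_decode(ps)
    assert len(res.fold_accuracies) == 4
    assert np.all((0.0 <= res.fold_accuracies) & (res.fold_accuracies <= 1.0))
    assert res.accuracy == pytest.approx(np.mean(res.fold_accuracies))
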