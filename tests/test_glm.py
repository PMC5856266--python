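import numpy as np
import pytest
from scipy import stats as sps

from rulemvpa import glm
from rulemvpa.conditions import ALL_CONDITIONS, TASK_CONDITIONS
from rulemvpa.synth import NoiseParams, simulate_bold
from rulemvpa.synth.design import Epoch


def normal_equations_betas(X, Y):
    """Independent brute-force OLS oracle: solve X'X b = X'Y."""
    return np.linalg.solve(X.T @ X, X.T @ Y)


class TestHRF:
    def test_peak_near_five_seconds_and_zero_at_origin(self):
        h = glm.canonical_hrf(dt=0.01)
        t_peak = np.argmax(h.values) * 0.01
        assert t_peak == pytest.approx(5.0, abs=0.02)
        assert h.values[0] == 0.0
        assert h.values.max() == 1.0

    def test_undershoot_then_decay(self):
        h = glm.canonical_hrf(dt=0.1)
        assert h.values.min() < 0  # undershoot
        assert abs(h.values[-1]) < 0.01  # tail decays

    def test_peak_location_stable_under_grid_refinement(self):
        coarse = glm.canonical_hrf(dt=0.2)
        fine = glm.canonical_hrf(dt=0.1)
        assert abs(np.argmax(coarse.values) * 0.2 - np.argmax(fine.values) * 0.1) <= 0.2

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(dt=0.0)


def _full_run_epochs(n_conditions=9, start=4.0, dur=6.0, gap=10.0):
    return [
        Epoch(ALL_CONDITIONS[i], start + i * (dur + gap), dur) for i in range(n_conditions)
    ]


class TestDesignMatrix:
    def test_column_count_all_conditions_present(self):
        epochs = _full_run_epochs()
        n_scans = [90] * 4
        motion = [np.zeros((90, 6)) for _ in range(4)]
        X = glm.build_design_matrix([epochs] * 4, 2.0, n_scans, motion=motion)
        # 9 conditions x 4 runs + 6 motion x 4 runs + 4 constants
        assert X.matrix.shape == (360, 9 * 4 + 6 * 4 + 4)

    def test_absent_condition_gets_no_column(self):
        full = _full_run_epochs()
        partial = [e for e in full if e.condition != "error"]
        X = glm.build_design_matrix([full, partial], 2.0, [90, 90])
        assert "run1:error" in X.labels
        assert "run2:error" not in X.labels

    def test_condition_column_zero_outside_its_run(self):
        epochs = _full_run_epochs()
        X = glm.build_design_matrix([epochs, epochs], 2.0, [90, 90])
        col = X.matrix[:, X.column_index("run2:disc_verbal_separate")]
        assert np.all(col[:90] == 0.0)
        assert col[90:].max() > 0

    def test_convolution_matches_direct_oracle(self):
        # single 17 s epoch: support starts at onset, decays after offset + tail
        tr, onset, dur, n_scans = 2.0, 10.0, 17.0, 40
        epochs = [Epoch("disc_verbal_separate", onset, dur)]
        X = glm.build_design_matrix([epochs], tr, [n_scans])
        col = X.matrix[:, 0]
        dt = tr / 16
        hrf = glm.canonical_hrf(dt)
        fine = np.zeros(int(n_scans * tr / dt) + 1)
        fine[int(onset / dt) : int((onset + dur) / dt)] = 1.0
        expected = np.convolve(fine, hrf.values)[: len(fine)][:: 16][:n_scans]
        np.testing.assert_allclose(col, expected, atol=1e-12)
        assert np.all(col[: int(onset / tr)] == 0.0)
        assert abs(col[-1]) < 0.01  # decayed by run end (offset 27 s + 32 s tail < 80 s)

    def test_epoch_beyond_run_end_names_run(self):
        epochs = [Epoch("disc_verbal_separate", 70.0, 17.0)]
        with pytest.raises(ValueError, match="run 1"):
            glm.build_design_matrix([epochs], 2.0, [40])


class TestFitGLM:
    def test_betas_match_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, p, v = 20, 5, 10
            X = glm.DesignMatrix(
                matrix=rng.standard_normal((n, p)),
                labels=tuple(f"run1:c{i}" for i in range(p)),
                frame_times=np.arange(n) * 2.0,
            )
            Y = rng.standard_normal((n, v))
            fit = glm.fit_glm([Y.T.reshape(v, 1, 1, n)], X)
            expected = normal_equations_betas(X.matrix, Y)
            np.testing.assert_allclose(fit.beta.reshape(p, v), expected, atol=1e-8)

    def test_duplicated_column_warns_and_uses_pseudoinverse(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((20, 3))
        X = glm.DesignMatrix(
            matrix=np.hstack([base, base[:, :1]]),
            labels=("run1:a", "run1:b", "run1:c", "run1:d"),
            frame_times=np.arange(20) * 2.0,
        )
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            fit = glm.fit_glm([rng.standard_normal((1, 1, 20)).reshape(1, 1, 1, 20)], X)
        assert np.all(np.isfinite(fit.beta))

    def test_dimension_mismatch_raises(self):
        X = glm.build_design_matrix([_full_run_epochs()], 2.0, [90])
        with pytest.raises(ValueError, match="scans"):
            glm.fit_glm([np.zeros((2, 2, 2, 50))], X)

    def test_noise_free_round_trip(self, tiny_design, tiny_scene):
        dataset = simulate_bold(
            tiny_design, tiny_scene, NoiseParams(sigma=0.0), seed=11, subjects=[1]
        )
        runs = list(tiny_design.runs)
        X = glm.build_design_matrix(
            [tiny_design.epochs[(1, 1, r)] for r in runs],
            tiny_design.params.tr,
            [tiny_design.n_scans((1, 1, r)) for r in runs],
            motion=[dataset.runs[(1, 1, r)].motion for r in runs],
        )
        fit = glm.fit_glm([dataset.runs[(1, 1, r)].data for r in runs], X)
        for cond in TASK_CONDITIONS:
            for r in runs:
                err = np.abs(
                    fit.condition_beta(cond, r) - tiny_scene.amplitude(1, 1, cond)
                ).max()
                assert err <= 1e-6


class TestContrast:
    @staticmethod
    def _toy_fit(seed=0, n=24, v=4):
        rng = np.random.default_rng(seed)
        X = glm.DesignMatrix(
            matrix=np.column_stack(
                [rng.standard_normal((n, 3)), np.ones(n)]
            ),
            labels=("run1:a", "run1:b", "run1:ctrl", "run1:constant"),
            frame_times=np.arange(n) * 2.0,
        )
        Y = rng.standard_normal((n, v))
        return glm.fit_glm([Y.T.reshape(v, 1, 1, n)], X), X, Y

    def test_zero_contrast_gives_zero_map(self):
        fit, _, _ = self._toy_fit()
        smap = glm.contrast_t(fit, {"a": 0.0, "b": 0.0})
        np.testing.assert_array_equal(smap.values, 0.0)

    def test_t_matches_scalar_oracle(self):
        fit, X, Y = self._toy_fit(seed=3)
        weights = {"a": 1.0, "ctrl": -2.0}
        smap = glm.contrast_t(fit, weights)
        # brute-force oracle at one voxel
        c = np.array([1.0, 0.0, -2.0, 0.0])
        b = normal_equations_betas(X.matrix, Y)
        resid = Y - X.matrix @ b
        dof = X.matrix.shape[0] - 4
        s2 = (resid[:, 2] ** 2).sum() / dof
        t_expect = (c @ b[:, 2]) / np.sqrt(s2 * c @ np.linalg.inv(X.matrix.T @ X.matrix) @ c)
        assert smap.values.ravel()[2] == pytest.approx(t_expect, abs=1e-8)
        assert smap.dof == dof

    def test_unknown_label_rejected(self):
        fit, _, _ = self._toy_fit()
        with pytest.raises(KeyError, match="unknown condition"):
            glm.contrast_t(fit, {"nonexistent": 1.0})

    def test_weights_split_over_runs(self):
        # two runs: the expanded contrast puts w/2 on each run's column
        epochs = _full_run_epochs()
        X = glm.build_design_matrix([epochs, epochs], 2.0, [90, 90])
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((180, 2))
        fit = glm.fit_glm([Y.T.reshape(2, 1, 1, 180)], X)
        c = glm._expand_contrast(fit, {"disc_verbal_separate": 1.0})
        cols = [i for i, lab in enumerate(fit.labels) if lab.endswith("disc_verbal_separate")]
        assert [c[i] for i in cols] == [0.5, 0.5]
        assert c.sum() == pytest.approx(1.0)


class TestGroupMap:
    def test_matches_one_sample_t_oracle(self):
        rng = np.random.default_rng(5)
        vols = [rng.standard_normal((3, 3, 3)) for _ in range(5)]
        gmap = glm.group_map(vols)
        data = np.stack(vols).reshape(5, -1)
        t_expect, _ = sps.ttest_1samp(data, 0.0, axis=0)
        np.testing.assert_allclose(gmap.values.ravel(), t_expect, atol=1e-8)
        assert gmap.dof == 4

    def test_thirteen_subjects_give_df_12(self):
        vols = [np.random.default_rng(i).standard_normal((2, 2, 2)) for i in range(13)]
        assert glm.group_map(vols).dof == 12

    def test_identical_nonzero_maps_flagged_infinite(self):
        vol = np.full((2, 2, 2), 0.7)
        gmap = glm.group_map([vol] * 6)
        assert np.all(np.isposinf(gmap.values))
        gmap = glm.group_map([np.zeros((2, 2, 2))] * 6)
        assert np.all(gmap.values == 0.0)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            glm.group_map([np.zeros((2, 2, 2)), np.zeros((3, 3, 3))])
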