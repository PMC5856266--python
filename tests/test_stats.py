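import numpy as np
import pytest
from scipy import stats as sps

from rulemvpa import stats as rstats
from rulemvpa.conditions import CONDITIONS_OF_INTEREST

from conftest import make_pattern_set


def constant_pattern_set(cell_means: dict[str, float], subject=1, n_voxels=8):
    """Pattern set whose rows are constant at the given per-condition mean."""
    rng = np.random.default_rng(0)
    ps = make_pattern_set(rng, n_voxels=n_voxels, subject=subject)
    for cond, mean in cell_means.items():
        from rulemvpa.conditions import domain_of, search_of

        rows = (ps.domains == domain_of(cond)) & (ps.searches == search_of(cond))
        ps.X[rows] = mean
    return ps


class TestMeanBetaTable:
    def test_worked_differences_match_printed_cells(self):
        # separate-search cells 0.25 vs 0.14 -> 0.11; parallel 0.53 vs 0.05 -> 0.48
        sets = {
            "L_IFG": [
                constant_pattern_set(
                    {
                        "disc_verbal_separate": 0.25,
                        "disc_spatial_separate": 0.14,
                        "disc_verbal_parallel": 0.50,
                        "disc_spatial_parallel": 0.21,
                    }
                )
            ],
            "L_OG": [
                constant_pattern_set(
                    {
                        "disc_verbal_separate": 0.28,
                        "disc_spatial_separate": -0.03,
                        "disc_verbal_parallel": 0.53,
                        "disc_spatial_parallel": 0.05,
                    }
                )
            ],
        }
        table = rstats.mean_beta_table(sets)
        assert table.differences.loc["L_IFG", "separate"] == pytest.approx(0.11, abs=1e-12)
        assert table.differences.loc["L_OG", "parallel"] == pytest.approx(0.48, abs=1e-12)
        roi, search, value = table.max_difference()
        assert (roi, search) == ("L_OG", "parallel")
        assert value == pytest.approx(0.48, abs=1e-12)

    def test_identical_amplitudes_give_zero_differences(self):
        sets = {"roi": [constant_pattern_set({c: 0.4 for c in CONDITIONS_OF_INTEREST})]}
        table = rstats.mean_beta_table(sets)
        assert (table.differences.to_numpy() == 0).all()

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        subjects = [make_pattern_set(rng, subject=i) for i in range(1, 5)]
        a = rstats.mean_beta_table({"roi": subjects})
        b = rstats.mean_beta_table({"roi": subjects[::-1]})
        np.testing.assert_allclose(a.means.to_numpy(), b.means.to_numpy())
        np.testing.assert_allclose(a.differences.to_numpy(), b.differences.to_numpy())

    def test_covers_all_conditions_of_interest(self):
        table = rstats.mean_beta_table(
            {"roi": [make_pattern_set(np.random.default_rng(1))]}
        )
        assert tuple(table.means.columns) == CONDITIONS_OF_INTEREST
        assert (table.differences.to_numpy() >= 0).all()


def anova_ss_oracle(data):
    """Brute-force cell-means sums-of-squares decomposition for 2x2 RM."""
    n = data.shape[0]
    grand = data.mean()
    ss = {}
    ss["A"] = sum(2 * n * (data[:, i, :].mean() - grand) ** 2 for i in range(2))
    ss["B"] = sum(2 * n * (data[:, :, j].mean() - grand) ** 2 for j in range(2))
    ss["AB"] = sum(
        n * (data[:, i, j].mean() - data[:, i, :].mean() - data[:, :, j].mean() + grand) ** 2
        for i in range(2)
        for j in range(2)
    )
    ss["AS"] = sum(
        2 * (data[s, i, :].mean() - data[:, i, :].mean() - data[s].mean() + grand) ** 2
        for s in range(n)
        for i in range(2)
    )
    ss["BS"] = sum(
        2 * (data[s, :, j].mean() - data[:, :, j].mean() - data[s].mean() + grand) ** 2
        for s in range(n)
        for j in range(2)
    )
    return ss


class TestRMAnova:
    def test_df_is_1_and_n_minus_1(self):
        data = np.random.default_rng(0).standard_normal((13, 2, 2))
        res = rstats.rm_anova_2x2(data, factor_names=("hemisphere", "session"))
        for eff in res.effects.values():
            assert eff.df == (1, 12)

    def test_all_cells_equal_per_subject_gives_zero_F(self):
        subj = np.random.default_rng(1).standard_normal(8)
        data = np.repeat(subj, 4).reshape(8, 2, 2)
        res = rstats.rm_anova_2x2(data)
        for eff in res.effects.values():
            assert eff.F == 0.0
            assert eff.p == 1.0

    def test_matches_ss_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            data = rng.standard_normal((6, 2, 2))
            res = rstats.rm_anova_2x2(data)
            oracle = anova_ss_oracle(data)
            n = 6
            for name, key in (("A", "A"), ("B", "B"), ("A*B", "AB")):
                err_key = {"A": "AS", "B": "BS"}.get(key)
                if err_key:
                    F_expect = oracle[key] / (oracle[err_key] / (n - 1))
                    assert res.effects[name].F == pytest.approx(F_expect, abs=1e-8)
                assert res.ss_components[name] == pytest.approx(oracle[key], abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        data = rng.standard_normal((9, 2, 2))
        rows = [
            {"subject": s, "A": a, "B": b, "y": data[s, a, b]}
            for s in range(9)
            for a in range(2)
            for b in range(2)
        ]
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subject"
        )
        res = rstats.rm_anova_2x2(data, factor_names=("A", "B"))
        for effect, key in (("A", "A"), ("B", "B"), ("A * B", "A*B")):
            expected = float(table.loc[table.Source == effect, "F"].iloc[0])
            assert res.effects[key].F == pytest.approx(expected, rel=1e-6)

    def test_total_ss_conserved(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            data = rng.standard_normal((7, 2, 2))
            res = rstats.rm_anova_2x2(data)
            assert sum(res.ss_components.values()) == pytest.approx(res.ss_total, abs=1e-10)

    def test_incomplete_design_rejected(self):
        data = np.random.default_rng(5).standard_normal((6, 2, 2))
        data[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rstats.rm_anova_2x2(data)


class TestPairedT:
    def test_equal_samples_give_t0_p1(self):
        x = np.arange(5.0)
        res = rstats.paired_t(x, x)
        assert (res.t, res.p) == (0.0, 1.0)
        assert res.degenerate

    def test_df_is_pairs_minus_1(self):
        rng = np.random.default_rng(6)
        res = rstats.paired_t(rng.standard_normal(13), rng.standard_normal(13))
        assert res.df == 12

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(4), rng.standard_normal(4)
        res = rstats.paired_t(x, y)
        t_expect, p_expect = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(t_expect, abs=1e-10)
        assert res.p == pytest.approx(p_expect, abs=1e-10)

    def test_constant_nonzero_difference_degenerate_infinite(self):
        x = np.arange(5.0)
        res = rstats.paired_t(x + 1.0, x)
        assert res.degenerate and np.isposinf(res.t) and res.p == 0.0

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(8)
        ps = [
            rstats.paired_t(rng.standard_normal(13), rng.standard_normal(13)).p
            for _ in range(1000)
        ]
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01
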