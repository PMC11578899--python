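"""Mixed 2x2x2 ANCOVA, post-hoc contrasts, effect sizes, cluster extent."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import noveltytask as nt
from noveltytask.cohort import CouplingConfig, sample_couplings
from noveltytask.group import (
    ExploreAncova,
    _type3_anova,
    cluster_threshold,
    partial_eta_squared,
    posthoc_tests,
    run_ancova,
)


def random_cohort(n_per_cell, seed, d=0.0):
    rng = np.random.default_rng(seed)
    return sample_couplings(n_per_cell, CouplingConfig(d_neglect_explore=d), rng)


def statsmodels_type3(df: pd.DataFrame):
    """Independent Type-III oracle: statsmodels OLS + anova_lm on M and D."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    dd = df.copy()
    dd["A"] = np.where(dd["abuse"], "hi", "lo")
    dd["N"] = np.where(dd["neglect"], "hi", "lo")
    dd["M"] = (dd["b_explore"] + dd["b_nonexplore"]) / 2
    dd["D"] = dd["b_explore"] - dd["b_nonexplore"]
    terms = {
        "C(A, Sum)": "abuse",
        "C(N, Sum)": "neglect",
        "C(A, Sum):C(N, Sum)": "abuse:neglect",
        "np": "np",
        "C(A, Sum):np": "abuse:np",
        "C(N, Sum):np": "neglect:np",
        "C(A, Sum):C(N, Sum):np": "abuse:neglect:np",
    }
    out = {}
    for resp, prefix in (("M", None), ("D", "explore")):
        fit = smf.ols(f"{resp} ~ C(A, Sum) * C(N, Sum) * np", data=dd).fit()
        table = anova_lm(fit, typ=3)
        for term, effect in terms.items():
            name = effect if prefix is None else f"{prefix}:{effect}"
            out[name] = float(table.loc[term, "F"])
        if prefix:
            out["explore"] = float(table.loc["Intercept", "F"])
    return out


class TestAncovaAgainstOracle:
    def test_every_effect_matches_statsmodels_type3(self):
        df = random_cohort(6, seed=2)
        mine = run_ancova(df).table["F"]
        oracle = statsmodels_type3(df)
        assert set(oracle) == set(mine.index)
        for effect, F in oracle.items():
            assert mine[effect] == pytest.approx(F, abs=1e-9), effect

    def test_unbalanced_cells_still_match_oracle(self):
        df = random_cohort(8, seed=3).iloc[:-5]  # drop 5 subjects from one cell
        mine = run_ancova(df).table["F"]
        oracle = statsmodels_type3(df)
        for effect, F in oracle.items():
            assert mine[effect] == pytest.approx(F, abs=1e-9), effect

    def test_degrees_of_freedom_consistent_with_design(self):
        df = random_cohort(10, seed=4)
        table = run_ancova(df).table
        assert (table["df1"] == 1).all()
        assert (table["df2"] == len(df) - 8).all()  # 8 between-subject parameters
        assert (table["F"] >= 0).all()
        assert table["partial_eta_sq"].between(0, 1).all()


class TestAncovaValidation:
    def test_empty_cell_rejected(self):
        df = random_cohort(5, seed=5)
        df = df[~(df.abuse & df.neglect)]
        with pytest.raises(ValueError, match="cell"):
            run_ancova(df)

    def test_zero_np_variance_rejected(self):
        df = random_cohort(5, seed=6).assign(np=0.0)
        with pytest.raises(ValueError, match="NP"):
            run_ancova(df)

    def test_saturated_model_rejected(self):
        df = random_cohort(2, seed=7)  # 8 subjects, 8 parameters
        with pytest.raises(ValueError, match="degrees of freedom"):
            run_ancova(df)

    def test_np_interactions_can_be_dropped(self):
        df = random_cohort(2, seed=8)
        table = run_ancova(df, include_np_interactions=False).table
        assert "abuse:np" not in table.index
        assert table.loc["neglect", "df2"] == 8 - 5


class TestPosthoc:
    def test_identical_groups_give_near_zero_t(self):
        df = random_cohort(40, seed=9)
        base = df[~df.neglect].reset_index(drop=True)
        mirrored = pd.concat(
            [base, base.assign(neglect=True)], ignore_index=True
        )
        res = posthoc_tests(mirrored, "neglect")
        assert res["t"].abs().max() < 1e-12

    def test_sign_convention_exposed_lower_is_negative(self):
        df = random_cohort(30, seed=10, d=1.5)
        res = posthoc_tests(df, "explore:neglect")
        assert res.loc["neglect (explore)", "t"] < 0

    def test_t_squared_equals_one_df_anova_f(self):
        df = random_cohort(12, seed=11)
        y = (df["b_explore"] + df["b_nonexplore"]).to_numpy() / 2
        res = posthoc_tests(df, "neglect")
        t = res.loc["neglect (mean)", "t"]
        F = stats.f_oneway(y[df.neglect], y[~df.neglect]).statistic
        assert t**2 == pytest.approx(F, rel=1e-10)

    def test_tiny_group_rejected(self):
        df = random_cohort(20, seed=12)
        df = pd.concat([df[~df.neglect], df[df.neglect].iloc[:1]])
        with pytest.raises(ValueError, match="at least 2"):
            posthoc_tests(df, "neglect")

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError, match="post-hoc"):
            posthoc_tests(random_cohort(5, seed=13), "explore:np")


class TestPartialEtaSquared:
    def test_boundary_values(self):
        assert partial_eta_squared(0.0, 5.0) == 0.0
        assert partial_eta_squared(3.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1.0)

    def test_equals_t_squared_identity_for_one_df_effect(self):
        # for a model containing just the group contrast,
        # partial eta^2 = t^2 / (t^2 + df)
        rng = np.random.default_rng(14)
        n = 24
        grp = np.repeat([1.0, -1.0], n // 2)
        y = rng.normal(0.3 * grp, 1.0)
        X = np.column_stack([np.ones(n), grp])
        rows = _type3_anova(y, X, ["intercept", "group"])
        peta = rows[0]["partial_eta_sq"]
        t, _ = stats.ttest_ind(y[: n // 2], y[n // 2:])
        df = n - 2
        assert peta == pytest.approx(t**2 / (t**2 + df), rel=1e-10)
        assert rows[0]["F"] == pytest.approx(t**2, rel=1e-10)


class TestMonotonicity:
    def test_interaction_f_grows_with_injected_effect(self):
        mean_F = []
        for d in (0.0, 0.3, 0.5, 0.8):
            fs = [
                run_ancova(random_cohort(45, seed=100 + rep, d=d)).table.loc[
                    "explore:neglect", "F"
                ]
                for rep in range(40)
            ]
            mean_F.append(np.mean(fs))
        assert all(b > a for a, b in zip(mean_F, mean_F[1:]))


class TestClusterThreshold:
    @staticmethod
    def grid_with_blob(shape, voxels, p=1e-5):
        grid = np.full(shape, 0.5)
        for v in voxels:
            grid[v] = p
        return grid

    def test_sixteen_voxel_blob_removed_at_k17(self):
        voxels = [(0, i, j) for i in range(4) for j in range(4)]
        cm = cluster_threshold(self.grid_with_blob((3, 8, 8), voxels), 0.001, 17)
        assert cm.n_clusters == 0

    def test_eighteen_voxel_blob_retained_at_k17(self):
        voxels = [(0, i, j) for i in range(3) for j in range(6)]
        cm = cluster_threshold(self.grid_with_blob((3, 8, 8), voxels), 0.001, 17)
        assert cm.n_clusters == 1
        assert cm.clusters[0].size == 18

    def test_diagonal_blobs_not_merged_under_face_connectivity(self):
        # 10-voxel and 9-voxel blobs touching only at a corner: 19 voxels
        # combined, but face connectivity keeps them separate -> both removed
        blob_a = [(0, 0, j) for j in range(10)]
        blob_b = [(1, 1, 10 + j) for j in range(9)]
        grid = self.grid_with_blob((3, 3, 20), blob_a + blob_b)
        cm = cluster_threshold(grid, 0.001, 17)
        assert cm.n_clusters == 0
        # sanity: each survives a small-k threshold as its own cluster
        cm2 = cluster_threshold(grid, 0.001, 5)
        assert cm2.n_clusters == 2
        assert sorted(c.size for c in cm2.clusters) == [9, 10]

    def test_peak_statistic_reported(self):
        voxels = [(0, 0, j) for j in range(20)]
        stat = np.zeros((2, 2, 20))
        stat[0, 0, 7] = -6.5
        cm = cluster_threshold(
            self.grid_with_blob((2, 2, 20), voxels), 0.001, 17, stat_grid=stat
        )
        assert cm.clusters[0].peak_coord == (0, 0, 7)
        assert cm.clusters[0].peak_stat == -6.5

    def test_invalid_thresholds_rejected(self):
        grid = np.full((2, 2, 2), 0.5)
        with pytest.raises(ValueError):
            cluster_threshold(grid, 0.0, 17)
        with pytest.raises(ValueError):
            cluster_threshold(grid, 0.001, 0)


def test_results_summary_lists_every_effect():
    df = random_cohort(10, seed=15)
    res = ExploreAncova(df).fit()
    text = res.summary()
    for effect in res.table.index:
        assert effect in text
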