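"""GLM, TFCE, permutation inference, SVC, diagnostics — against closed-form
and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acmap import stats as gs
from acmap.core_io import CohortDesign, MaskVolume, ValidationError
from acmap.dti import ScalarMap


def _design(groups, ages=None, genders=None, maskv=None):
    n = len(groups)
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": ages if ages is not None else 40 + rng.random(n) * 20,
            "gender": genders if genders is not None else rng.integers(0, 2, n),
            "mask_voxels": maskv if maskv is not None else 5000 + rng.integers(0, 500, n),
        }
    )
    return CohortDesign(table=table)


def _dm_no_covariates(groups):
    design = _design(groups)
    labels = np.asarray(groups)
    cols, names = [], []
    for g in sorted(set(groups)):
        cols.append((labels == g).astype(float))
        names.append(f"group:{g}")
    return gs.DesignMatrix(X=np.column_stack(cols), columns=names, group_labels=labels)


class TestSmoothing:
    def test_constant_map_unchanged_in_interior(self):
        # interior = further from the boundary than the truncated kernel radius
        m = ScalarMap(np.full((16, 16, 16), 3.5), np.diag([2.0, 2, 2, 1]), "FA")
        out = gs.smooth_map(m, 4.0)
        np.testing.assert_allclose(out.data[6:-6, 6:-6, 6:-6], 3.5, rtol=1e-6)

    def test_impulse_centre_matches_analytic_gaussian(self):
        # 4 mm FWHM on 2 mm voxels: sigma = 4/2.3548 mm
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        m = ScalarMap(data, np.diag([2.0, 2, 2, 1]), "FA")
        out = gs.smooth_map(m, 4.0)
        sigma_mm = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        # discrete kernel normalisation: product over axes of the sampled
        # 1-D Gaussian at voxel centres (2 mm spacing)
        offs = np.arange(-7, 8) * 2.0
        g1 = np.exp(-(offs**2) / (2 * sigma_mm**2))
        g1 /= g1.sum()
        expected_centre = g1[7] ** 3
        assert np.isclose(out.data[7, 7, 7], expected_centre, rtol=1e-4)
        # and the analytic continuous value is close at this resolution
        analytic = (2.0 / (np.sqrt(2 * np.pi) * sigma_mm)) ** 3
        assert np.isclose(out.data[7, 7, 7], analytic, rtol=0.02)

    def test_mass_conserved_away_from_boundary(self):
        rng = np.random.default_rng(1)
        data = np.zeros((20, 20, 20))
        data[6:14, 6:14, 6:14] = rng.random((8, 8, 8))
        m = ScalarMap(data, np.diag([2.0, 2, 2, 1]), "FA")
        out = gs.smooth_map(m, 4.0)
        assert np.isclose(out.data.sum(), data.sum(), rtol=1e-6)

    def test_fwhm_zero_identity(self):
        rng = np.random.default_rng(2)
        data = rng.random((5, 5, 5))
        m = ScalarMap(data, np.eye(4), "FA")
        np.testing.assert_array_equal(gs.smooth_map(m, 0.0).data, data)


class TestGLM:
    def test_two_sample_t_matches_closed_form(self):
        # pooled-variance two-sample t on printed values {1,2,3} vs {2,3,4}
        y = np.array([1.0, 2, 3, 2, 3, 4]).reshape(6, 1)
        dm = _dm_no_covariates(["A"] * 3 + ["B"] * 3)
        c = np.array([1.0, -1.0])
        t = gs.glm_stat(y, dm, c)[0]
        # independent closed form
        a, b = y[:3, 0], y[3:, 0]
        sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        sp2 /= 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert np.isclose(t, t_oracle, atol=1e-12)
        # and scipy agrees
        assert np.isclose(t, sps.ttest_ind(a, b).statistic, atol=1e-12)

    def test_three_group_f_matches_anova(self):
        rng = np.random.default_rng(3)
        y = rng.random((9, 1)) * 10
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        dm = _dm_no_covariates(groups)
        F = gs.glm_stat(y, dm, gs.group_f_contrast(dm))[0]
        F_oracle = sps.f_oneway(y[:3, 0], y[3:6, 0], y[6:, 0]).statistic
        assert np.isclose(F, F_oracle, atol=1e-10)

    def test_orthogonal_covariate_contrast_is_zero(self):
        # age pattern balanced across groups and data orthogonalized against
        # it: the fitted age coefficient, hence its t, is exactly zero
        rng = np.random.default_rng(4)
        age = np.array([30.0, 35, 40, 45, 50] * 2)
        c_age = age - age.mean()
        y = rng.random(10)
        y -= c_age * (c_age @ y) / (c_age @ c_age)
        design = _design(["A"] * 5 + ["B"] * 5, ages=age)
        dm = gs.build_design_matrix(design, covariates=("age",))
        c = np.zeros(3)
        c[dm.columns.index("age")] = 1.0
        t = gs.glm_stat(y.reshape(10, 1), dm, c)[0]
        assert abs(t) < 1e-8

    def test_rank_deficiency_names_columns(self):
        ages = np.array([1.0, 2, 3, 4, 5, 6])
        with pytest.raises(ValidationError, match="mask_voxels|age"):
            design = _design(["A"] * 3 + ["B"] * 3, ages=ages, maskv=ages * 2 + 1)
            gs.build_design_matrix(design)

    def test_location_invariance_of_group_contrast(self):
        rng = np.random.default_rng(5)
        y = rng.random((8, 27))
        design = _design(["A"] * 4 + ["B"] * 4)
        dm = gs.build_design_matrix(design)
        c = gs.group_contrast(dm, "A>B")
        t1 = gs.glm_stat(y, dm, c)
        t2 = gs.glm_stat(y + 17.3, dm, c)
        np.testing.assert_allclose(t1, t2, atol=1e-8)


def _tfce_bruteforce(stat, E, H, dh, connectivity=26):
    """Independent discrete threshold-integration oracle (BFS clustering)."""
    pos = np.clip(stat, 0, None)
    out = np.zeros_like(pos)
    hmax = pos.max()
    if hmax <= 0:
        return out
    thresholds = dh * np.arange(1, int(np.floor(hmax / dh + 1e-9)) + 1)
    shape = pos.shape
    neigh = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and (connectivity == 26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    for h in thresholds:
        above = pos >= h
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(above)):
            if seen[start]:
                continue
            stack, cluster = [start], [start]
            seen[start] = True
            while stack:
                v = stack.pop()
                for d in neigh:
                    w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if all(0 <= w[a] < shape[a] for a in range(3)) and above[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
                        cluster.append(w)
            val = len(cluster) ** E * h**H * dh
            for v in cluster:
                out[v] += val
    return out


class TestTFCE:
    def test_all_zero_map(self):
        assert (gs.tfce(np.zeros((4, 4, 4))) == 0).all()

    def test_uniform_cluster_closed_form(self):
        stat = np.zeros((6, 6, 6))
        stat[2:4, 2:4, 2] = 1.0  # k=4 voxels at height 1
        E, H = 0.5, 2.0
        dh = 0.01
        out = gs.tfce(stat, E=E, H=H, dh=dh)
        heights = np.arange(dh, 1.0 + 1e-12, dh)
        expected = 4**E * np.sum(heights**H) * dh
        np.testing.assert_allclose(out[2:4, 2:4, 2], expected, atol=1e-10)
        assert out[out > 0].size == 4

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bruteforce_oracle_on_random_maps(self, connectivity):
        rng = np.random.default_rng(6)
        for shape in [(8, 8, 8), (10, 10, 5)]:
            stat = rng.normal(0, 1, shape)
            stat[rng.random(shape) < 0.5] = 0.0
            dh = max(stat.max(), 1e-9) / 20
            ours = gs.tfce(stat, dh=dh, connectivity=connectivity)
            oracle = _tfce_bruteforce(stat, 0.5, 2.0, dh, connectivity)
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_scale_monotonicity(self):
        rng = np.random.default_rng(7)
        stat = np.clip(rng.normal(0, 1, (8, 8, 8)), 0, None)
        a = gs.tfce(stat)
        b = gs.tfce(2.5 * stat)
        assert (b >= a - 1e-12).all()

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(ValidationError):
            gs.tfce(np.ones((3, 3, 3)), dh=0.0)


class TestPermutation:
    def _null_cohort(self, n=10, shape=(6, 6, 6), seed=0):
        rng = np.random.default_rng(seed)
        maps = rng.normal(0, 1, (n,) + shape)
        design = _design(["A"] * (n // 2) + ["B"] * (n - n // 2))
        dm = gs.build_design_matrix(design)
        return maps, dm

    def test_min_attainable_p(self):
        maps, dm = self._null_cohort(n=10, seed=1)
        maps[5:] += 50.0  # enormous effect
        c = gs.group_contrast(dm, "B>A")
        res = gs.permutation_test(maps, dm, c, n_perm=199, seed=0)
        assert res.min_attainable_p == 1 / 200
        assert np.isclose(res.p_fwe.min(), 1 / 200)

    def test_null_p_values_super_uniform(self):
        # under the null, P(p <= a) <= a on the attainable grid
        hits = 0
        reps = 15
        for r in range(reps):
            maps, dm = self._null_cohort(n=10, seed=100 + r)
            c = gs.group_contrast(dm, "A>B")
            res = gs.permutation_test(maps, dm, c, n_perm=199, seed=r, tfce_on=True)
            if res.p_fwe.min() < 0.05:
                hits += 1
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_exhaustive_enumeration_warns(self):
        maps, _ = self._null_cohort(n=10)
        design = _design(["A"] * 2 + ["B"] * 2)
        labels = np.array(["A", "A", "B", "B"])
        dm = gs.DesignMatrix(
            X=np.column_stack([(labels == "A").astype(float), (labels == "B").astype(float)]),
            columns=["group:A", "group:B"],
            group_labels=labels,
        )
        rng = np.random.default_rng(0)
        small = rng.normal(0, 1, (4, 3, 3, 3))
        with pytest.warns(UserWarning, match="enumerat"):
            res = gs.permutation_test(small, dm, np.array([1.0, -1.0]), n_perm=100, seed=0)
        assert res.meta["exhaustive"]
        assert res.meta["n_perm"] == 24

    def test_detects_planted_effect_one_tailed(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(0, 1, (12, 6, 6, 6))
        maps[6:, 2:4, 2:4, 2:4] += 4.0  # strong localized effect in group B
        design = _design(["A"] * 6 + ["B"] * 6)
        dm = gs.build_design_matrix(design)
        c = gs.group_contrast(dm, "B>A")
        res = gs.permutation_test(maps, dm, c, n_perm=199, seed=0)
        assert res.p_fwe[2:4, 2:4, 2:4].max() < 0.05
        assert res.p_fwe[res.p_fwe < 0.05].size <= 2 * 8  # effect stays local


class TestSVC:
    def _result_with_effect(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(0, 1, (12, 6, 6, 6))
        maps[6:, 1:3, 1:3, 1:3] += 3.0
        design = _design(["A"] * 6 + ["B"] * 6)
        dm = gs.build_design_matrix(design)
        c = gs.group_contrast(dm, "B>A")
        res = gs.permutation_test(maps, dm, c, n_perm=199, seed=0, keep_null_maps=True)
        return res

    def test_whole_mask_roi_equals_global(self):
        res = self._result_with_effect()
        roi = MaskVolume(np.ones((6, 6, 6), dtype=np.uint8), np.eye(4))
        svc = gs.small_volume_correct(res, roi)
        np.testing.assert_allclose(svc.p_fwe, res.p_fwe, atol=1e-12)

    def test_svc_p_never_exceeds_global_p(self):
        res = self._result_with_effect()
        roi_data = np.zeros((6, 6, 6), dtype=np.uint8)
        roi_data[1:3, 1:3, 1:3] = 1
        svc = gs.small_volume_correct(res, MaskVolume(roi_data, np.eye(4)))
        sel = roi_data.astype(bool)
        assert (svc.p_fwe[sel] <= res.p_fwe[sel] + 1e-12).all()
        assert svc.n_significant >= 1
        assert svc.peak_p < 0.05

    def test_single_voxel_roi_is_uncorrected_p(self):
        res = self._result_with_effect()
        roi_data = np.zeros((6, 6, 6), dtype=np.uint8)
        roi_data[2, 2, 2] = 1
        svc = gs.small_volume_correct(res, MaskVolume(roi_data, np.eye(4)))
        # oracle: per-voxel permutation p from the retained null maps
        v = np.ravel_multi_index((2, 2, 2), (6, 6, 6))
        null_here = res.null_maps[:, v]
        obs = res.enhanced[2, 2, 2]
        p_unc = (1 + (null_here >= obs).sum()) / (len(null_here) + 1)
        assert np.isclose(svc.p_fwe[2, 2, 2], p_unc, atol=1e-12)

    def test_empty_roi_rejected(self):
        res = self._result_with_effect()
        roi = MaskVolume(np.ones((6, 6, 6), dtype=np.uint8), np.eye(4))
        roi.data[:] = False
        with pytest.raises(ValidationError):
            gs.small_volume_correct(res, roi)


class TestDiagnostics:
    def test_gaussian_residuals_reject_at_nominal_rate(self):
        rng = np.random.default_rng(10)
        maps = rng.normal(0, 1, (40, 8, 8, 4))
        design = _design(["A"] * 20 + ["B"] * 20)
        dm = gs.build_design_matrix(design)
        out = gs.residual_normality_check(maps, dm)
        # Lilliefors is approximately calibrated; MC tolerance around 0.05
        assert abs(out["rejection_fraction"] - 0.05) < 0.04

    def test_heavy_tailed_residuals_reject_more(self):
        rng = np.random.default_rng(11)
        maps = rng.standard_t(3, (40, 8, 8, 4))
        design = _design(["A"] * 20 + ["B"] * 20)
        dm = gs.build_design_matrix(design)
        out = gs.residual_normality_check(maps, dm)
        assert out["rejection_fraction"] > 0.10

    def test_constant_residuals_flagged_degenerate(self):
        maps = np.ones((10, 3, 3, 3))
        design = _design(["A"] * 5 + ["B"] * 5)
        dm = gs.build_design_matrix(design)
        out = gs.residual_normality_check(maps, dm)
        assert out["degenerate"].all()

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(0, 1, (6, 2, 2, 2))
        design = _design(
            ["A"] * 3 + ["B"] * 3,
            ages=[30.0, 40, 50, 35, 45, 55],
            genders=[0, 1, 0, 1, 0, 1],
            maskv=[5000, 5300, 5100, 5250, 5400, 5050],
        )
        dm = gs.build_design_matrix(design)
        with pytest.raises(ValidationError):
            gs.residual_normality_check(maps, dm)


class TestICVCorrelation:
    def test_perfect_linear_relation(self):
        roi = MaskVolume(np.ones((2, 2, 2), dtype=np.uint8), np.eye(4))
        icv = np.array([1.0, 2, 3, 4])
        acms = [np.full((2, 2, 2), 2 * v + 1) for v in icv]
        out = gs.icv_correlation(acms, roi, icv, ["A"] * 4)
        r, p = out["A"]
        assert np.isclose(r, 1.0)

    def test_six_pair_closed_form(self):
        # hand computation on {(1,2),(2,4),(3,5),(4,4),(5,5),(6,7)}
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 4, 5, 4, 5, 7])
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        roi = MaskVolume(np.ones((1, 1, 1), dtype=np.uint8), np.eye(4))
        acms = [np.full((1, 1, 1), v) for v in y]
        out = gs.icv_correlation(acms, roi, x, ["G"] * 6)
        r, p = out["G"]
        assert np.isclose(r, r_oracle, atol=1e-12)
        t_or = r_oracle * np.sqrt(4 / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t_or), 4)
        assert np.isclose(p, p_oracle, atol=1e-12)

    def test_permuted_pairing_shrinks_r(self):
        rng = np.random.default_rng(12)
        icv = np.linspace(1, 2, 12)
        vals = 3 * icv + rng.normal(0, 0.05, 12)
        roi = MaskVolume(np.ones((1, 1, 1), dtype=np.uint8), np.eye(4))
        acms = [np.full((1, 1, 1), v) for v in vals]
        r_true = gs.icv_correlation(acms, roi, icv, ["G"] * 12)["G"][0]
        rs = []
        for i in range(20):
            perm = rng.permutation(12)
            rs.append(gs.icv_correlation([acms[j] for j in perm], roi, icv, ["G"] * 12)["G"][0])
        assert abs(np.mean(rs)) < abs(r_true)

    def test_zero_variance_rejected(self):
        roi = MaskVolume(np.ones((1, 1, 1), dtype=np.uint8), np.eye(4))
        acms = [np.full((1, 1, 1), 1.0)] * 4
        with pytest.raises(ValidationError):
            gs.icv_correlation(acms, roi, [1.0, 2, 3, 4], ["A"] * 4)
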