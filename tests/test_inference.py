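"""Group statistics: t maps, TFCE enhancement, permutation p-values, summary tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

import boldphysio as bp
from boldphysio.inference import _pooled_t


def tfce_oracle(stat_map, E=0.5, H=2.0, n_steps=1000):
    """Fine-integration brute-force TFCE (midpoint rule, independent loop)."""
    m = np.asarray(stat_map, float)
    out = np.zeros_like(m)
    hmax = m.max()
    if hmax <= 0:
        return out
    dh = hmax / n_steps
    struct = np.ones((3, 3, 3), bool)
    for j in range(1, n_steps + 1):
        h = (j - 0.5) * dh
        if h >= hmax:
            break
        labels, nlab = ndimage.label(m > h, structure=struct)
        for lab in range(1, nlab + 1):
            sel = labels == lab
            out[sel] += sel.sum() ** E * h**H * dh
    return out


class TestTwoSampleTMap:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 3, 3, 3))
        t = bp.two_sample_tmap(A, A.copy())
        assert np.allclose(np.nan_to_num(t), 0.0)

    def test_matches_hand_computed_pooled_t(self):
        A = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        B = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1)
        t = bp.two_sample_tmap(A, B)
        # pooled: mean diff -3, s_p^2 = 1, se = sqrt(2/3)
        assert t[0, 0, 0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))

    def test_covariate_adjustment_matches_scipy_on_null_covariate(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((8, 2, 2, 2)) + 1.0
        B = rng.standard_normal((8, 2, 2, 2))
        cov = np.zeros((16, 1))
        cov[:, 0] = rng.standard_normal(16) * 1e-12  # effectively no covariate
        t_plain = bp.two_sample_tmap(A, B)
        t_cov = bp.two_sample_tmap(A, B, covariates=rng.standard_normal((16, 1)))
        assert np.all(np.isfinite(t_cov))
        assert np.corrcoef(t_plain.ravel(), t_cov.ravel())[0, 1] > 0.9

    def test_collinear_covariate_rejected(self):
        A = np.ones((3, 2, 2, 2))
        B = np.zeros((3, 2, 2, 2))
        group_indicator = np.array([1.0, 1, 1, 0, 0, 0])[:, None]
        with pytest.raises(bp.DataError, match="collinear"):
            bp.two_sample_tmap(A, B, covariates=group_indicator)


class TestPairedDiffMaps:
    def test_equal_sessions_give_zero(self):
        maps = {f"s{i}": np.full((2, 2, 2), float(i)) for i in range(4)}
        diff, ids = bp.paired_diff_maps(maps, {k: v.copy() for k, v in maps.items()})
        assert np.allclose(diff, 0.0) and len(ids) == 4

    def test_constant_offset_recovered(self):
        pre = {f"s{i}": np.random.default_rng(i).standard_normal((2, 2, 2)) for i in range(3)}
        post = {k: v + 1.5 for k, v in pre.items()}
        diff, _ = bp.paired_diff_maps(pre, post)
        assert np.allclose(diff, 1.5)

    def test_unmatched_subjects_listed(self):
        with pytest.raises(bp.DataError, match="s9"):
            bp.paired_diff_maps({"s1": np.zeros(2), "s9": np.zeros(2)}, {"s1": np.zeros(2)})


class TestTFCE:
    def test_zero_map_enhances_to_zero(self):
        assert np.all(bp.tfce_enhance(np.zeros((4, 4, 4))) == 0)

    def test_single_voxel_closed_form(self):
        # isolated voxel of height h0: integral of h^H dh from 0..h0 = h0^3/3
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 3.0
        v = bp.tfce_enhance(m, dh=3.0 / 2000)[2, 2, 2]
        assert v == pytest.approx(27.0 / 3.0, rel=1e-3)

    def test_default_integration_matches_fine_oracle_at_map_max(self):
        rng = np.random.default_rng(2)
        m = np.abs(rng.standard_normal((8, 8, 8)))
        fast = bp.tfce_enhance(m)  # default 100 midpoint steps
        slow = tfce_oracle(m, n_steps=1000)
        idx = np.unravel_index(np.argmax(m), m.shape)
        assert fast[idx] == pytest.approx(slow[idx], rel=0.01)

    def test_monotone_in_pointwise_domination(self):
        rng = np.random.default_rng(3)
        dh = 0.05
        for _ in range(100):
            a = np.abs(rng.standard_normal((5, 5, 5)))
            b = a + rng.uniform(0, 0.5, a.shape)
            ta = bp.tfce_enhance(a, dh=dh)
            tb = bp.tfce_enhance(b, dh=dh)
            assert np.all(tb >= ta - 1e-12)

    def test_nonfinite_values_rejected(self):
        m = np.zeros((3, 3, 3))
        m[0, 0, 0] = np.nan
        with pytest.raises(bp.DataError):
            bp.tfce_enhance(m)


@pytest.fixture(scope="module")
def strong_effect():
    rng = np.random.default_rng(4)
    A = rng.standard_normal((6, 4, 4, 4)) + 5.0
    B = rng.standard_normal((6, 4, 4, 4))
    maps = np.concatenate([A, B])
    labels = ["a"] * 6 + ["b"] * 6
    return bp.permutation_test(maps, labels, n_perm=400, seed=0)


class TestPermutationTest:
    def test_p_floor_follows_permutation_definition(self, strong_effect):
        # random shuffles may re-draw the observed labeling a handful of times,
        # so the strongest voxel sits within a few counts of the 1/(n+1) floor
        res = strong_effect
        pmin = np.nanmin(res.p_corr_pos)
        assert 1.0 / (res.n_perm + 1) <= pmin <= 3.0 / (res.n_perm + 1)
        assert np.nanmax(res.p_corr_pos) <= 1.0

    def test_small_cohort_enumerated_exactly(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((8, 3, 3, 3))
        res = bp.permutation_test(maps, ["a"] * 4 + ["b"] * 4, n_perm=200, seed=1)
        assert res.exact and res.n_perm == 70  # C(8, 4)

    def test_directions_are_complementary(self, strong_effect):
        res = strong_effect
        # effect injected as a > b: positive direction significant, negative not
        assert np.nanmin(res.p_corr_pos) < 0.01
        assert np.nanmin(res.p_corr_neg) > 0.5

    def test_too_few_permutations_rejected(self):
        maps = np.zeros((6, 2, 2, 2))
        with pytest.raises(bp.DataError):
            bp.permutation_test(maps, ["a"] * 3 + ["b"] * 3, n_perm=50, seed=0)


class TestLagwiseTissueTest:
    @staticmethod
    def _stack(n, offset=0.0, sd=0.1, seed=0, n_lags=18):
        rng = np.random.default_rng(seed)
        grid = bp.LagGrid(1.4 * np.arange(n_lags))
        out = []
        for _ in range(n):
            r = np.clip(0.1 + sd * rng.standard_normal(n_lags), -1, 1)
            r[4] += offset
            out.append(bp.TissueXCorr(r={"gray": r}, grid=grid, physio_kind="hr_bpm"))
        return out

    def test_identical_stacks_have_no_significant_lags(self):
        A = self._stack(10, seed=1)
        res = bp.lagwise_tissue_test(A, self._stack(10, seed=1))
        assert not res.sig_corrected["gray"].any()

    def test_bonferroni_threshold_for_18_lags(self):
        res = bp.lagwise_tissue_test(self._stack(6, seed=2), self._stack(6, seed=3))
        assert res.bonferroni_alpha == pytest.approx(0.05 / 18)
        assert res.bonferroni_alpha == pytest.approx(0.002778, abs=1e-6)

    def test_large_offset_detected_after_correction(self):
        A = self._stack(20, offset=0.3, seed=4)
        B = self._stack(20, offset=0.0, seed=5)
        res = bp.lagwise_tissue_test(A, B)
        assert res.sig_corrected["gray"][4]
        assert res.t["gray"][4] > 0

    def test_grid_mismatch_rejected(self):
        A = self._stack(5, n_lags=18)
        B = self._stack(5, n_lags=10)
        with pytest.raises(bp.DataError, match="grid"):
            bp.lagwise_tissue_test(A, B)


class TestCohortSummaryTests:
    @staticmethod
    def _frame(shift=0.0, paired_shift=0.0):
        rows = []
        rng = np.random.default_rng(6)
        for g, base in (("young", 0.0), ("old", shift)):
            for i in range(8):
                pre = base + rng.standard_normal()
                for ses, extra in (("pre", 0.0), ("post", paired_shift)):
                    rows.append(
                        {"subject": f"{g}{i}", "age_group": g, "session": ses,
                         "metric": pre + extra}
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_t(self):
        df = self._frame()
        df.loc[df.age_group == "old", "metric"] = (
            df.loc[df.age_group == "young", "metric"].to_numpy()
        )
        res = bp.cohort_summary_tests(df, ["metric"], session_col="session")
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_welch_oracle(self):
        df = self._frame(shift=1.0)
        res = bp.cohort_summary_tests(df, ["metric"], session_col="session")
        base = df[df.session == "pre"]
        a = base[base.age_group == "old"].metric
        b = base[base.age_group == "young"].metric
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.loc[0, "t"] == pytest.approx(t)
        assert res.loc[0, "p"] == pytest.approx(p)

    def test_equal_sessions_give_zero_paired_t(self):
        df = self._frame(paired_shift=0.0)
        res = bp.cohort_summary_tests(df, ["metric"], session_col="session")
        assert res.loc[0, "t_postpre_young"] == pytest.approx(0.0, abs=1e-12)

    def test_small_group_skipped_with_note(self):
        df = self._frame().iloc[:6]  # too few per group
        df = pd.concat([df, self._frame()[self._frame().age_group == "old"]])
        res = bp.cohort_summary_tests(df, ["metric"], session_col="session")
        assert "note" in res.columns
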