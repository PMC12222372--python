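import itertools

import numpy as np
import pandas as pd
import pytest

from hepaflow.curves import FrameTAC, SampledCurve, frame_average
from hepaflow.metrics import (
    UndefinedCorrelationError,
    cohort_summary,
    compute_metrics,
    mann_whitney_u,
    pearson_with_t_test,
    wilcoxon_signed_rank,
)


def curve_and_frames(schedule, values_280):
    curve = SampledCurve(np.asarray(values_280, float))
    return curve, frame_average(curve, schedule)


class TestFitMetrics:
    def test_perfect_fit(self, schedule, rng):
        curve, frames = curve_and_frames(schedule, rng.uniform(1e3, 5e4, 280))
        m = compute_metrics(curve, frames, n_params=6, mse_floor=1e-12)
        assert m.mre == pytest.approx(0.0, abs=1e-12)
        assert m.mse == pytest.approx(0.0, abs=1e-18)
        assert m.aic == pytest.approx(24 * np.log(1e-12) + 12)

    def test_one_kbq_offset_gives_unit_mse_and_aic_2n(self, schedule, rng):
        base = rng.uniform(1e4, 5e4, 280)
        curve, _ = curve_and_frames(schedule, base)
        _, frames = curve_and_frames(schedule, base + 1000.0)  # +1 kBq/mL
        m = compute_metrics(curve, frames, n_params=6)
        assert m.mse == pytest.approx(1.0)
        assert m.aic == pytest.approx(12.0)

    def test_matches_loop_oracle(self, schedule, rng):
        curve, _ = curve_and_frames(schedule, rng.uniform(1e3, 5e4, 280))
        frames = FrameTAC(schedule, rng.uniform(1e3, 5e4, 24))
        m = compute_metrics(curve, frames, n_params=4)
        fitted = frame_average(curve, schedule).values
        mre = np.mean(
            [abs(frames.values[i] - fitted[i]) / frames.values[i] for i in range(24)]
        )
        mse = np.mean(
            [((frames.values[i] - fitted[i]) / 1000.0) ** 2 for i in range(24)]
        )
        assert m.mre == pytest.approx(mre)
        assert m.mse == pytest.approx(mse)
        assert m.aic == pytest.approx(24 * np.log(mse) + 8)

    def test_equal_mse_fits_differ_by_twice_the_parameter_gap(self, schedule, rng):
        base = rng.uniform(1e4, 5e4, 280)
        curve, _ = curve_and_frames(schedule, base)
        _, frames = curve_and_frames(schedule, base + 500.0)
        m4 = compute_metrics(curve, frames, n_params=4)
        m6 = compute_metrics(curve, frames, n_params=6)
        assert m6.aic - m4.aic == pytest.approx(4.0)

    def test_mre_scale_invariant_mse_quadratic(self, schedule, rng):
        base = rng.uniform(1e4, 5e4, 280)
        curve, _ = curve_and_frames(schedule, base)
        _, frames = curve_and_frames(schedule, base * 1.07)
        m = compute_metrics(curve, frames, n_params=6)
        c = 3.0
        curve_s, _ = curve_and_frames(schedule, c * base)
        _, frames_s = curve_and_frames(schedule, c * base * 1.07)
        m_s = compute_metrics(curve_s, frames_s, n_params=6)
        assert m_s.mre == pytest.approx(m.mre, rel=1e-9)
        assert m_s.mse == pytest.approx(c**2 * m.mse, rel=1e-9)

    def test_near_zero_frames_excluded_with_warning(self, schedule):
        curve = SampledCurve(np.full(280, 1000.0))
        values = np.full(24, 2000.0)
        values[0] = 0.0
        frames = FrameTAC(schedule, values)
        with pytest.warns(UserWarning, match="excluded"):
            m = compute_metrics(curve, frames, n_params=4)
        # remaining 23 frames each contribute |2000-1000|/2000 = 0.5
        assert m.mre == pytest.approx(0.5)

    def test_midpoint_sampling_option(self, schedule):
        t = np.arange(1, 281, dtype=float)
        curve = SampledCurve(100.0 * t)
        frames = FrameTAC(schedule, np.interp(schedule.midpoints, t, curve.values))
        m = compute_metrics(curve, frames, n_params=4, sample_at_midpoint=True)
        assert m.mse == pytest.approx(0.0, abs=1e-18)


class TestWilcoxon:
    def test_unit_shift_is_highly_significant(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=20)
        a = b + 1.0
        assert wilcoxon_signed_rank(a, b, alternative="greater") < 0.001

    def test_all_zero_differences_warn_and_return_one(self):
        a = np.ones(8)
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(a, a) == 1.0

    def test_small_sample_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        got = wilcoxon_signed_rank(a, b, alternative="greater")
        # enumerate all 2^6 sign assignments of the rank statistic
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        count = 0
        total = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for s, r in zip(signs, ranks) if s)
            total += 1
            if w >= w_obs:
                count += 1
        assert got == pytest.approx(count / total)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 2.0, size=15)
        b = rng.uniform(0.5, 2.0, size=15)
        p1 = wilcoxon_signed_rank(a, b)
        p2 = wilcoxon_signed_rank(np.log(a * 10), np.log(b * 10))
        # signed ranks depend only on the ordering of |differences| -- a
        # monotone transform of the *paired differences* is not available in
        # general, but a common positive scaling is
        p3 = wilcoxon_signed_rank(7.0 * a, 7.0 * b)
        assert p1 == pytest.approx(p3)
        assert 0 <= p2 <= 1


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        a = np.arange(10.0)
        assert mann_whitney_u(a, a.copy()) == pytest.approx(1.0)

    def test_fully_separated_groups_are_significant(self):
        a = np.arange(10.0)
        b = a + 100.0
        assert mann_whitney_u(a, b) < 0.001

    def test_small_sample_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        got = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for idx in combos:
            u = ranks[list(idx)].sum() - 4 * 5 / 2
            # two-sided: as or more extreme in either tail
            if min(u, 16 - u) <= min(u_obs, 16 - u_obs):
                count += 1
        assert got == pytest.approx(count / len(combos))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 5, size=12)
        b = rng.uniform(1, 5, size=9)
        assert mann_whitney_u(a, b) == pytest.approx(
            mann_whitney_u(np.exp(a), np.exp(b))
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.array([]), np.ones(3))


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_with_t_test(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_strong_negative_relation(self, rng):
        x = rng.uniform(0, 1, 50)
        y = -x + rng.normal(0, 0.02, 50)
        r, p = pearson_with_t_test(x, y)
        assert r < -0.9
        assert p < 1e-6

    def test_agrees_with_scipy_reference(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r, p = pearson_with_t_test(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_t_test(np.ones(10), np.arange(10.0))


class TestCohortSummary:
    def test_single_subject_mean_is_value_and_sd_zero(self):
        table = pd.DataFrame(
            {"subject": ["s1"], "model": ["1tcm"], "f_total": [1.2], "mre": [0.2]}
        )
        out = cohort_summary(table)
        assert out["means"].loc["1tcm", "f_total"] == 1.2
        assert out["sds"].loc["1tcm", "f_total"] == 0.0

    def test_two_subjects_sample_sd(self):
        table = pd.DataFrame(
            {
                "subject": ["s1", "s2"],
                "model": ["1tcm", "1tcm"],
                "f_total": [1.0, 3.0],
            }
        )
        out = cohort_summary(table)
        assert out["means"].loc["1tcm", "f_total"] == pytest.approx(2.0)
        assert out["sds"].loc["1tcm", "f_total"] == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_on_synthetic_cohort(self, rng):
        rows = []
        for s in range(12):
            for model in ("1tcm", "new_dual_input"):
                rows.append(
                    {
                        "subject": f"s{s:02d}",
                        "model": model,
                        "f_total": rng.uniform(0.5, 2.0),
                        "mre": rng.uniform(0.1, 0.4),
                        "mse": rng.uniform(0.05, 1.5),
                        "aic": rng.uniform(5, 20),
                    }
                )
        table = pd.DataFrame(rows)
        out = cohort_summary(table)
        for model in ("1tcm", "new_dual_input"):
            sub = table[table["model"] == model]
            assert out["means"].loc[model, "f_total"] == pytest.approx(
                sub["f_total"].mean()
            )
            assert out["sds"].loc[model, "mre"] == pytest.approx(
                sub["mre"].std(ddof=1)
            )
            assert out["error_medians"].loc[model, "mse"] == pytest.approx(
                sub["mse"].median()
            )
        p = out["comparisons"]["mre"].loc["1tcm", "new_dual_input"]
        wide = table.pivot(index="subject", columns="model", values="mre")
        expected = wilcoxon_signed_rank(
            wide["1tcm"].to_numpy(), wide["new_dual_input"].to_numpy(), "greater"
        )
        assert p == pytest.approx(expected)
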