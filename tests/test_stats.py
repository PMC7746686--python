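import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from octarep.stats import (
    PairedMeasurements,
    bland_altman,
    build_report,
    icc_band,
    icc_two_way,
    paired_t_test,
    pearson_with_ci,
)


def _pm(v1, v2):
    v1 = np.asarray(v1, float)
    return PairedMeasurements(list(range(len(v1))), v1, np.asarray(v2, float))


def icc21_oracle(data):
    """From-definitions two-way ANOVA variance-components oracle.

    Written with explicit loops over the data table, independent of the
    vectorized implementation under test.
    """
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(data[i]) / k for i in range(n)]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestPairedT:
    def test_identical_visits_flagged(self):
        t, df, p, degen = paired_t_test(_pm([1, 2, 3, 4], [1, 2, 3, 4]))
        assert degen and p == 1.0 and df == 3

    def test_alternating_differences_give_t_zero(self):
        v1 = np.array([5.0, 5.0, 5.0, 5.0])
        d = np.array([1.0, -1.0, 1.0, -1.0])
        t, df, p, degen = paired_t_test(_pm(v1 + d, v1))
        assert not degen
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_nonzero_difference_flagged(self):
        _, _, p, degen = paired_t_test(_pm([2, 3, 4, 5], [1, 2, 3, 4]))
        assert degen and p == 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            _pm([1, 2], [1, 2])


class TestICC:
    def test_identical_visits_give_one(self):
        icc, ci, band, degen = icc_two_way(_pm([1, 2, 3, 4], [1, 2, 3, 4]))
        assert icc == pytest.approx(1.0)
        assert band == "excellent"

    def test_constant_table_degenerate_convention(self):
        icc, ci, band, degen = icc_two_way(_pm([2, 2, 2], [2, 2, 2]))
        assert degen and icc == 1.0 and ci == (1.0, 1.0)

    def test_absolute_agreement_penalizes_offset(self):
        """ICC(2,1) on a 4-subject table with a constant visit shift, checked
        against the hand-computed ANOVA mean squares."""
        v1 = np.array([1.0, 2.0, 3.0, 4.0])
        icc, _, _, _ = icc_two_way(_pm(v1, v1 + 2.0))
        oracle = icc21_oracle(np.column_stack([v1, v1 + 2.0]))
        assert icc < 1.0
        assert icc == pytest.approx(oracle, abs=1e-12)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 21))
            data = rng.normal(0, 1, (n, 2)) + rng.normal(0, 2, (n, 1))
            icc, _, _, _ = icc_two_way(_pm(data[:, 0], data[:, 1]))
            assert icc == pytest.approx(icc21_oracle(data), abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 16))
            data = rng.normal(0, 1, (n, 2)) + rng.normal(0, 1, (n, 1))
            icc, _, _, _ = icc_two_way(_pm(data[:, 0], data[:, 1]))
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(["a", "b"], n),
                "scores": data.ravel(),
            })
            res = pg.intraclass_corr(df, "targets", "raters", "scores")
            ref = res[res["Type"] == "ICC(A,1)"]["ICC"].iloc[0]
            assert icc == pytest.approx(ref, abs=1e-10)

    @given(st.floats(0.5, 3.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 1, (8, 2)) + rng.normal(0, 1, (8, 1))
        icc1, _, _, _ = icc_two_way(_pm(data[:, 0], data[:, 1]))
        icc2, _, _, _ = icc_two_way(_pm(a * data[:, 0] + b, a * data[:, 1] + b))
        assert icc1 == pytest.approx(icc2, abs=1e-9)

    @pytest.mark.parametrize("value,band", [
        (0.49, "poor"), (0.50, "moderate"), (0.74, "moderate"),
        (0.75, "good"), (0.90, "good"), (0.901, "excellent"),
    ])
    def test_band_cutpoints(self, value, band):
        assert icc_band(value) == band

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, (10, 1))
        icc, (lo, hi), _, _ = icc_two_way(_pm(data[:, 0], data[:, 1]))
        assert lo <= icc <= hi


class TestBlandAltman:
    def test_identical_visits_zero(self):
        ba = bland_altman(_pm([1, 2, 3], [1, 2, 3]))
        assert (ba["mean_diff"], ba["loa_lo"], ba["loa_hi"]) == (0.0, 0.0, 0.0)

    def test_two_point_limits(self):
        ba = bland_altman(_pm([1.0, 2.0, 4.0], [2.0, 1.0, 4.0]))
        # d = (-1, 1, 0): mean 0, sample SD 1 -> LoA = +/- 1.96
        assert ba["mean_diff"] == pytest.approx(0.0)
        assert ba["loa_hi"] == pytest.approx(1.96)
        assert ba["loa_lo"] == pytest.approx(-1.96)

    @given(st.floats(-10.0, 10.0))
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(3)
        v1 = rng.normal(0, 1, 6)
        v2 = rng.normal(0, 1, 6)
        ba = bland_altman(_pm(v1, v2))
        ba_c = bland_altman(_pm(v1, v2 + c))
        assert ba_c["mean_diff"] == pytest.approx(ba["mean_diff"] - c, abs=1e-9)
        assert ba_c["loa_lo"] == pytest.approx(ba["loa_lo"] - c, abs=1e-9)
        assert ba_c["loa_hi"] == pytest.approx(ba["loa_hi"] - c, abs=1e-9)

    def test_limits_contain_most_normal_differences(self):
        rng = np.random.default_rng(4)
        v1 = rng.normal(10, 2, 2000)
        v2 = v1 + rng.normal(0, 1, 2000)
        ba = bland_altman(_pm(v1, v2))
        d = v1 - v2
        frac = np.mean((d >= ba["loa_lo"]) & (d <= ba["loa_hi"]))
        assert frac >= 0.93


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, ci, p = pearson_with_ci(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _, _ = pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_type_i_error_rate(self):
        """Under the null (true r = 0, n = 14), p < 0.05 occurs in ~5% of
        replicates (binomial band 5% +/- 1.5% over 2000 draws)."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 14)
            y = rng.normal(0, 1, 14)
            _, _, p = pearson_with_ci(x, y)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)


class TestBuildReport:
    @staticmethod
    def _long(n=6, metrics=("m1",), variants=("none", "hessian"), sd_w=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for metric in metrics:
            for variant in variants:
                base = rng.normal(30, 3, n)
                for i in range(n):
                    for visit in (1, 2):
                        rows.append({
                            "subject_id": f"S{i}", "visit": visit, "slab": "SCP",
                            "region": "macula", "variant": variant, "metric": metric,
                            "value": base[i] + rng.normal(0, sd_w),
                        })
        return pd.DataFrame(rows)

    def test_row_count_schema(self):
        df = self._long(metrics=("m1", "m2"), variants=("none", "hessian", "gabor"))
        rep = build_report(df, {"m1": "none", "m2": "none"})
        assert len(rep) == 2 * 3  # metrics x variants x regions(1)

    def test_reference_column(self):
        rep = build_report(self._long(), {"m1": "none"})
        ref = rep[rep["variant"] == "none"].iloc[0]
        other = rep[rep["variant"] == "hessian"].iloc[0]
        assert ref["reference"] == "reference" and np.isnan(ref["pearson_r"])
        assert np.isfinite(other["pearson_r"])

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="missing"):
            build_report(self._long(variants=("hessian",)), {"m1": "none"})

    def test_identical_visit_cohort_degenerate(self):
        df = self._long(sd_w=0.0)
        rep = build_report(df, {"m1": "none"})
        assert (rep["icc"] == 1.0).all()
        assert (rep["t_p_value"] == 1.0).all()
        assert rep["degenerate"].all()

    def test_missing_visit_drops_subject(self):
        df = self._long(n=6)
        df = df[~((df.subject_id == "S0") & (df.visit == 2) & (df.variant == "none"))]
        rep = build_report(df, {"m1": "none"})
        assert rep[rep["variant"] == "none"]["n"].iloc[0] == 5
        assert rep[rep["variant"] == "hessian"]["n"].iloc[0] == 6
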