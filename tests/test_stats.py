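import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from calvapit.stats import (
    PowerSpec,
    fold_change,
    percent_decrease,
    sample_size_two_groups,
    sex_contrasts,
    summarize_sample,
    tukey_hsd,
    two_way_anova,
)

from test_review import candidate


def balanced_table(cell_values, treatments=("a", "b"), sexes=("M", "F")):
    """cell_values[(treatment, sex)] -> list of outcomes."""
    rows = []
    for t in treatments:
        for s in sexes:
            for v in cell_values[(t, s)]:
                rows.append({"treatment": t, "sex": s, "y": float(v)})
    return pd.DataFrame(rows)


def confirmed_pit(pit_id, volume_um3):
    from calvapit.pits import PitCandidate

    return PitCandidate(
        pit_id=pit_id,
        voxel_count=1,
        volume_um3=volume_um3,
        centroid_voxel=(0.0, 0.0, 0.0),
        bbox=(0, 1, 0, 1, 0, 1),
        surface_class="outer",
        touches_roi_boundary=False,
        status="confirmed",
    )


class TestSummarize:
    def test_basic_sum_and_mean(self):
        cands = [confirmed_pit(i, v) for i, v in enumerate((2.0, 3.0, 5.0), start=1)]
        count, total, mean = summarize_sample(cands, 7.5)
        assert (count, total) == (3, 10.0)
        assert mean == pytest.approx(10.0 / 3)

    def test_empty_sample(self):
        assert summarize_sample([], 7.5) == (0, 0.0, 0.0)

    def test_rejects_unconfirmed(self):
        with pytest.raises(ValueError):
            summarize_sample([candidate(1)], 7.5)


class TestEffectSizes:
    def test_fold_change_identity(self):
        assert fold_change(123.4, 123.4) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(1e-3, 1e6),
        b=st.floats(1e-3, 1e6),
    )
    def test_fold_change_reciprocal(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_fold_change_zero_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_percent_decrease(self):
        assert percent_decrease(100.0, 50.0) == pytest.approx(50.0)
        assert percent_decrease(42.0, 42.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)


class TestTwoWayAnova:
    def test_no_effect_design(self):
        """Every cell {m-1, m+1} with the same m: all effect SS are 0."""
        cells = {(t, s): [9.0, 11.0] for t in ("a", "b") for s in ("M", "F")}
        res = two_way_anova(balanced_table(cells), "y")
        for e in res.effects:
            assert e.sum_sq == pytest.approx(0.0, abs=1e-12)
            assert e.F == pytest.approx(0.0, abs=1e-12)
            assert e.p == pytest.approx(1.0)
        assert res.residual_sum_sq == pytest.approx(8.0)

    def test_zero_residual_variance_errors(self):
        cells = {("a", "M"): [0, 0], ("a", "F"): [0, 0], ("b", "M"): [0, 0], ("b", "F"): [5, 5]}
        with pytest.raises(ValueError, match="residual"):
            two_way_anova(balanced_table(cells), "y")

    def test_empty_cell_errors(self):
        df = pd.DataFrame(
            {"treatment": ["a", "a", "b"], "sex": ["M", "F", "M"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df, "y")

    def test_balanced_sums_of_squares_are_complete(self):
        rng = np.random.default_rng(4)
        cells = {
            (t, s): rng.normal(10 * (t == "b") + 3 * (s == "F"), 2, size=4)
            for t in ("a", "b")
            for s in ("M", "F")
        }
        df = balanced_table(cells)
        res = two_way_anova(df, "y")
        y = df["y"].to_numpy()
        total_ss = float(((y - y.mean()) ** 2).sum())
        parts = sum(e.sum_sq for e in res.effects) + res.residual_sum_sq
        assert parts == pytest.approx(total_ss, rel=1e-12)
        for e in res.effects:
            assert e.sum_sq >= 0

    def test_balanced_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        cells = {
            (t, s): rng.normal(5 * (t == "b") - 2 * (s == "F") * (t == "a"), 1.5, 3)
            for t in ("a", "b")
            for s in ("M", "F")
        }
        df = balanced_table(cells)
        res = two_way_anova(df, "y")
        aov = sm.stats.anova_lm(
            smf.ols("y ~ C(treatment) * C(sex)", data=df).fit(), typ=2
        )
        assert res.effect("treatment").sum_sq == pytest.approx(
            aov.loc["C(treatment)", "sum_sq"], rel=1e-9
        )
        assert res.effect("sex").sum_sq == pytest.approx(
            aov.loc["C(sex)", "sum_sq"], rel=1e-9
        )
        assert res.effect("treatment:sex").p == pytest.approx(
            aov.loc["C(treatment):C(sex)", "PR(>F)"], rel=1e-9
        )

    def test_unbalanced_design_runs_type2(self):
        rng = np.random.default_rng(12)
        rows = []
        for t, s, n in (("a", "M", 4), ("a", "F", 3), ("b", "M", 5), ("b", "F", 4)):
            for v in rng.normal(2 * (t == "b"), 1, n):
                rows.append({"treatment": t, "sex": s, "y": v})
        res = two_way_anova(pd.DataFrame(rows), "y")
        assert res.residual_df == 16 - 4
        assert all(e.sum_sq >= 0 for e in res.effects)


class TestTukey:
    def test_identical_means_give_p_one(self):
        comps = tukey_hsd({"a": 5.0, "b": 5.0}, {"a": 4, "b": 4}, 2.0, 6)
        assert comps[0].mean_diff == 0.0
        assert comps[0].adjusted_p == pytest.approx(1.0)

    def test_adjusted_p_conservative_vs_t_test(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        groups = {g: rng.normal(i, 1, 5) for i, g in enumerate("abc")}
        means = {g: float(v.mean()) for g, v in groups.items()}
        ns = {g: 5 for g in groups}
        pooled = np.concatenate([v - v.mean() for v in groups.values()])
        df_res = sum(ns.values()) - len(ns)
        ms = float((pooled**2).sum()) / df_res
        comps = tukey_hsd(means, ns, ms, df_res)
        for c in comps:
            se = math.sqrt(ms * (1 / 5 + 1 / 5))
            t = abs(c.mean_diff) / se
            p_t = 2 * sps.t.sf(t, df_res)
            assert c.adjusted_p >= p_t - 1e-12

    def test_df_validation(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 1.0, "b": 2.0}, {"a": 2, "b": 2}, 1.0, 0)


class TestSexContrasts:
    def table_with_shift(self, rng, shift_treatment=None, shift=0.0, n=25):
        rows = []
        for t in ("pristine", "vehicle", "rankl", "rankl_za"):
            for s in ("M", "F"):
                mu = shift if (t == shift_treatment and s == "M") else 0.0
                for v in rng.normal(mu, 1.0, n):
                    rows.append({"treatment": t, "sex": s, "y": v})
        return pd.DataFrame(rows)

    def test_identical_sexes_give_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 6)
        rows = []
        for t in ("a", "b"):
            for s in ("M", "F"):
                for v in vals:
                    rows.append({"treatment": t, "sex": s, "y": v})
        for sc in sex_contrasts(pd.DataFrame(rows), "y"):
            assert sc.mean_diff == pytest.approx(0.0, abs=1e-12)
            assert sc.adjusted_p == pytest.approx(1.0)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        df = self.table_with_shift(rng, "rankl", 1.0, n=6)
        swapped = df.assign(sex=df["sex"].map({"M": "F", "F": "M"}))
        for a, b in zip(sex_contrasts(df, "y"), sex_contrasts(swapped, "y")):
            assert a.treatment == b.treatment
            assert a.mean_diff == pytest.approx(-b.mean_diff)
            assert a.adjusted_p == pytest.approx(b.adjusted_p)

    def test_detects_single_treatment_dimorphism(self):
        """A male-only shift in one treatment is flagged there and only
        there in >= 95% of replicates."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            df = self.table_with_shift(rng, "rankl", 2.0, n=25)
            contrasts = {c.treatment: c.adjusted_p for c in sex_contrasts(df, "y")}
            ok = contrasts["rankl"] < 0.05 and all(
                p > 0.05 for t, p in contrasts.items() if t != "rankl"
            )
            hits += ok
        assert hits >= math.ceil(0.95 * reps)

    def test_missing_sex_errors(self):
        df = pd.DataFrame(
            {"treatment": ["a", "a", "b", "b"], "sex": ["M"] * 4, "y": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError):
            sex_contrasts(df, "y")


class TestSampleSize:
    def test_unit_effect_size_needs_17(self):
        spec = PowerSpec(pct_difference=100.0, reference_mean=1.0, sd=1.0)
        assert sample_size_two_groups(spec) == 17

    def test_monotone_in_effect_size(self):
        ns = []
        for pct in (25.0, 50.0, 75.0, 100.0, 200.0):
            spec = PowerSpec(pct_difference=pct, reference_mean=1.0, sd=1.0)
            ns.append(sample_size_two_groups(spec))
        assert ns == sorted(ns, reverse=True)
        # doubling the percent difference never increases n
        for a, b in zip(ns, ns[1:]):
            assert b <= a

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(pct_difference=0.0, reference_mean=1.0, sd=1.0)
        with pytest.raises(ValueError):
            PowerSpec(pct_difference=50.0, reference_mean=1.0, sd=1.0, power=1.5)
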