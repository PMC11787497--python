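"""Group-level inference: t tests, JZS Bayes factors, rm-ANOVA, Holm, CIs."""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from tvareport import (
    ValidationError,
    holm_adjust,
    jzs_bf01,
    jzs_bf10,
    mean_accuracy_difference,
    paired_t_test,
    rm_anova_2x2,
    within_subject_ci,
)


class TestPairedT:
    def test_identically_zero_differences_are_null(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.degenerate
        assert res.t == 0.0 and res.p == 1.0 and res.d_z == 0.0
        assert res.bf10 < 1

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and math.isnan(res.t)

    def test_zero_mean_difference(self):
        res = paired_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.t == pytest.approx(0.0)
        assert res.d_z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_arithmetic(self):
        res = paired_t_test([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res.d_z == pytest.approx(2.0, rel=1e-12)
        assert res.df == 2

    def test_agrees_with_scipy_and_dz_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0.3, 1, 12), rng.normal(0, 1, 12)
        res = paired_t_test(x, y)
        from scipy import stats as sps

        t_ref, p_ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert res.d_z == pytest.approx(res.t / math.sqrt(12), rel=1e-12)


class TestJzsBayesFactor:
    def test_against_pingouin(self):
        """Independent implementation of the same JZS integral."""
        for t, n in [(2.868, 9), (-5.7879, 9), (0.5, 20), (10.248, 9), (207.63, 9)]:
            ours = jzs_bf10(t, n, 0.707)
            ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert ours == pytest.approx(ref, rel=1e-6), (t, n)

    def test_reciprocal_identity(self):
        for t in (0.0, 1.7, -4.2):
            assert jzs_bf10(t, 9) * jzs_bf01(t, 9) == pytest.approx(1.0, rel=1e-9)

    def test_monotone_in_abs_t_and_below_one_at_null(self):
        bfs = [jzs_bf10(t, 9) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 50.0, 250.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert bfs[0] < 1
        assert jzs_bf10(-3.0, 9) == pytest.approx(jzs_bf10(3.0, 9), rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            jzs_bf10(math.inf, 9)
        with pytest.raises(ValidationError):
            jzs_bf10(1.0, 1)


class TestRmAnova2x2:
    @staticmethod
    def _long(cube, subjects=None):
        n = cube.shape[0]
        subjects = subjects or [f"s{i}" for i in range(n)]
        rows = []
        for i, j, k in itertools.product(range(n), range(2), range(2)):
            rows.append(
                {
                    "subject": subjects[i],
                    "A": f"a{j}",
                    "B": f"b{k}",
                    "y": cube[i, j, k],
                }
            )
        return pd.DataFrame(rows)

    def test_no_condition_variance(self):
        rng = np.random.default_rng(2)
        cube = np.repeat(rng.normal(size=(6, 1, 1)), 2, axis=1).repeat(2, axis=2)
        res = rm_anova_2x2(self._long(cube), "y", "subject", "A", "B")
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0, abs=1e-12)
            assert eff.eta_g_sq == pytest.approx(0.0, abs=1e-12)

    def test_sums_of_squares_conserved(self):
        rng = np.random.default_rng(3)
        cube = rng.normal(size=(9, 2, 2))
        res = rm_anova_2x2(self._long(cube), "y", "subject", "A", "B")
        parts = sum(v for k, v in res.ss_components.items() if k != "total")
        assert parts == pytest.approx(res.ss_components["total"], rel=1e-12)

    def test_matches_brute_force_and_pingouin(self):
        """F and generalized eta squared agree with an independent loop-based
        sums-of-squares computation and with pingouin's two-way rm ANOVA."""
        rng = np.random.default_rng(4)
        cube = rng.normal(size=(9, 2, 2)) + rng.normal(size=(9, 1, 1))
        long = self._long(cube)
        res = rm_anova_2x2(long, "y", "subject", "A", "B")

        # brute force: main effect F equals the squared paired t on the
        # per-subject marginal differences
        d_a = cube.mean(axis=2)[:, 0] - cube.mean(axis=2)[:, 1]
        t_a = np.mean(d_a) / (np.std(d_a, ddof=1) / 3.0)
        assert res.effects["A"].F == pytest.approx(t_a**2, rel=1e-9)
        d_b = cube.mean(axis=1)[:, 0] - cube.mean(axis=1)[:, 1]
        t_b = np.mean(d_b) / (np.std(d_b, ddof=1) / 3.0)
        assert res.effects["B"].F == pytest.approx(t_b**2, rel=1e-9)
        d_ab = cube[:, 0, 0] - cube[:, 0, 1] - cube[:, 1, 0] + cube[:, 1, 1]
        t_ab = np.mean(d_ab) / (np.std(d_ab, ddof=1) / 3.0)
        assert res.effects["A:B"].F == pytest.approx(t_ab**2, rel=1e-9)

        ref = pg.rm_anova(
            data=long, dv="y", within=["A", "B"], subject="subject",
            detailed=True, effsize="ng2",
        ).set_index("Source")
        for src, key in [("A", "A"), ("B", "B"), ("A * B", "A:B")]:
            assert res.effects[key].F == pytest.approx(float(ref.loc[src, "F"]), rel=1e-9)
            assert res.effects[key].eta_g_sq == pytest.approx(
                float(ref.loc[src, "ng2"]), rel=1e-9
            )

    def test_additive_subject_offsets_shrink_eta(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(1, 2, 2)) * 0.01
        cube = base + rng.normal(scale=10.0, size=(12, 1, 1))
        res = rm_anova_2x2(self._long(cube), "y", "subject", "A", "B")
        for eff in res.effects.values():
            assert eff.eta_g_sq < 0.01

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(6)
        long = self._long(rng.normal(size=(4, 2, 2))).iloc[:-1]
        with pytest.raises(ValidationError):
            rm_anova_2x2(long, "y", "subject", "A", "B")


class TestHolm:
    @pytest.mark.parametrize(
        "p_in,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.05, 0.05, 0.05], [0.15, 0.15, 0.15]),
        ],
    )
    def test_worked_examples(self, p_in, expected):
        assert holm_adjust(p_in) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_bounds_and_statsmodels_agreement(self, pvals):
        """Holm output dominates raw p, is dominated by Bonferroni, and matches
        statsmodels' reference implementation."""
        adj = np.asarray(holm_adjust(pvals))
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(1.0, len(p) * p) + 1e-12)
        ref = multipletests(p, method="holm")[1]
        assert adj == pytest.approx(ref, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])


class TestWithinSubjectCI:
    def test_pure_offsets_give_zero_width(self):
        profile = np.array([0.2, 0.5, 0.9])
        table = pd.DataFrame(profile[None, :] + np.array([[0.0], [1.0], [-0.5], [2.0]]))
        res = within_subject_ci(table)
        assert res.half_widths == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(8, 3)))
        shifted = table + rng.normal(size=(8, 1)) * 5
        a = within_subject_ci(table)
        b = within_subject_ci(shifted)
        assert a.half_widths == pytest.approx(b.half_widths, rel=1e-9)

    def test_two_conditions_match_paired_difference_ci(self):
        """For M=2 the normalized scores are d_i/2 + const, so after the Morey
        factor of 2 the half-width is the paired-difference CI half-width
        divided by sqrt(2), in both conditions."""
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(9, 2)))
        res = within_subject_ci(table)
        d = table[0] - table[1]
        hw_diff = sps.t.ppf(0.975, 8) * d.std(ddof=1) / 3.0
        assert res.half_widths[0] == pytest.approx(hw_diff / math.sqrt(2), rel=1e-9)
        assert res.half_widths[1] == pytest.approx(hw_diff / math.sqrt(2), rel=1e-9)

    def test_hand_computed_toy_table(self):
        table = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        # step-by-step: subject means (1.5, 3, 3), grand mean 2.5
        normalized = np.array([[2.0, 3.0], [1.5, 3.5], [2.5, 2.5]])
        var = normalized.var(axis=0, ddof=1) * 2.0  # Morey factor M/(M-1) = 2
        from scipy import stats as sps

        hw = sps.t.ppf(0.975, 2) * np.sqrt(var / 3)
        res = within_subject_ci(table)
        assert res.means == pytest.approx((2.0, 3.0))
        assert res.half_widths == pytest.approx(tuple(hw), rel=1e-12)

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            within_subject_ci(pd.DataFrame([[1.0], [2.0]]))


class TestMeanAccuracyDifference:
    def test_identical_accuracies_give_zero(self):
        df = pd.DataFrame(
            {
                "observer_id": ["o1"] * 4,
                "duration_ms": [50.0, 50.0, 100.0, 100.0],
                "loc_correct": [1, 0, 1, 1],
                "id_correct": [1, 0, 1, 1],
            }
        )
        assert mean_accuracy_difference(df) == pytest.approx(0.0)

    def test_toy_two_duration_table(self):
        # loc 0.8/0.6 vs id 0.6/0.5 -> (0.2 + 0.1)/2 = 0.15
        rows = []
        for dur, (pl, pi) in [(50.0, (0.8, 0.6)), (100.0, (0.6, 0.5))]:
            for i in range(10):
                rows.append(
                    {
                        "observer_id": "o1",
                        "duration_ms": dur,
                        "loc_correct": int(i < pl * 10),
                        "id_correct": int(i < pi * 10),
                    }
                )
        assert mean_accuracy_difference(pd.DataFrame(rows)) == pytest.approx(0.15)

    def test_simulated_location_advantage_is_positive(self, exp2_trials):
        assert mean_accuracy_difference(exp2_trials) > 0.0
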