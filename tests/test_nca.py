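"""Non-compartmental descriptors against hand-computed and analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xanpk import (
    PKParameters,
    UndefinedResultError,
    auc_trapezoid,
    disproportionality,
    half_life_c50,
    kel_loglinear,
    overnight_residual,
    parent_conc,
    peak,
    summarize_nca,
)

from .conftest import profile_from_arrays

LN2 = np.log(2.0)


class TestPeak:
    def test_strictly_decreasing_profile_peaks_at_first_post_dose_sample(self):
        prof = profile_from_arrays([1.75, 3.75, 5.75], [5.0, 3.0, 1.0])
        cmax, tmax = peak(prof, last_dose_time=0.0)
        assert (cmax, tmax) == (5.0, 1.75)

    def test_tie_broken_by_earliest_time(self):
        prof = profile_from_arrays([2.0, 4.0, 6.0], [3.0, 3.0, 1.0])
        assert peak(prof, 0.0) == (3.0, 2.0)

    def test_pre_dose_samples_ignored(self):
        prof = profile_from_arrays([-1.0, 1.0, 3.0], [9.0, 4.0, 2.0])
        assert peak(prof, 0.0) == (4.0, 1.0)

    def test_censored_samples_ignored(self):
        prof = profile_from_arrays([1.0, 2.0, 3.0], [0.0, 2.0, 1.0],
                                   censored=[True, False, False])
        assert peak(prof, 0.0) == (2.0, 2.0)

    def test_no_post_dose_samples_is_an_error(self):
        prof = profile_from_arrays([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedResultError):
            peak(prof, last_dose_time=5.0)


class TestHalfLifeC50:
    def test_hand_computed_log_linear_crossing(self):
        # cmax 4.0 at 2 h; crossing at 2 + 4*ln(2)/ln(4) = 4.0 h -> 2.0 h
        prof = profile_from_arrays([2.0, 6.0], [4.0, 1.0])
        assert half_life_c50(prof, 0.0) == pytest.approx(2.0, abs=1e-12)

    def test_linear_interpolation_switch(self):
        prof = profile_from_arrays([2.0, 6.0], [4.0, 1.0])
        # linear: 2 + 4*(4-2)/(4-1) = 4.667 -> half-life 2.667 h
        assert half_life_c50(prof, 0.0, interpolation="linear") == pytest.approx(
            2.0 + 4.0 * 2.0 / 3.0 - 2.0
        )

    def test_constant_profile_undefined(self):
        prof = profile_from_arrays([1.0, 3.0, 5.0], [2.0, 2.0, 2.0])
        assert np.isnan(half_life_c50(prof, 0.0))

    def test_monoexponential_recovery_is_exact_on_any_bracketing_grid(self):
        """On noise-free exponential decline the log-linear C50 crossing
        recovers ln2/k regardless of sample spacing."""
        k = LN2 / 4.33
        for times in ([0.5, 2.0, 3.1, 4.9, 7.7, 11.0], np.linspace(0.2, 24, 9)):
            times = np.asarray(times, float)
            prof = profile_from_arrays(times, 5.0 * np.exp(-k * times))
            assert half_life_c50(prof, 0.0) == pytest.approx(4.33, abs=1e-10)

    def test_monoexponential_dense_grid_matches_table_value(self):
        k = LN2 / 4.33
        t = np.arange(0.25, 24.0, 0.25)
        prof = profile_from_arrays(t, np.exp(-k * t))
        assert half_life_c50(prof, 0.0) == pytest.approx(4.33, abs=0.01)


class TestKelLogLinear:
    def test_pure_exponential_recovers_rate(self):
        k = LN2 / 4.95
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        prof = profile_from_arrays(t, 5.0 * np.exp(-k * t))
        assert round(kel_loglinear(prof, 0.0), 2) == 0.14
        assert kel_loglinear(prof, 0.0) == pytest.approx(k, rel=1e-10)

    def test_fewer_than_three_post_peak_samples_undefined(self):
        prof = profile_from_arrays([1.0, 2.0, 3.0], [5.0, 3.0, 2.0])
        assert np.isnan(kel_loglinear(prof, 0.0))

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(7)
        t = np.linspace(1, 12, 9)
        c = 5.0 * np.exp(-0.2 * t) * np.exp(rng.normal(0, 0.1, t.size))
        prof = profile_from_arrays(np.concatenate([[0.5], t]),
                                   np.concatenate([[10.0], c]))
        got = kel_loglinear(prof, 0.0)
        # normal-equations slope on the post-peak samples
        y = np.log(c)
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert got == pytest.approx(-slope, abs=1e-10)


class TestAUC:
    def test_trapezoid_geometry(self):
        prof = profile_from_arrays([0.0, 1.0, 2.0, 3.0], [0.0, 2.0, 2.0, 0.0])
        assert auc_trapezoid(prof, 0.0, 3.0) == 4.0

    def test_all_zero_profile(self):
        prof = profile_from_arrays([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        assert auc_trapezoid(prof, 0.0, 2.0) == 0.0

    def test_additive_over_adjacent_windows(self):
        t = np.linspace(0, 10, 21)
        prof = profile_from_arrays(t, np.exp(-0.3 * t))
        whole = auc_trapezoid(prof, 0.0, 10.0)
        split = auc_trapezoid(prof, 0.0, 4.0) + auc_trapezoid(prof, 4.0, 10.0)
        assert whole == pytest.approx(split, rel=1e-12)

    def test_censored_samples_enter_as_zero(self):
        prof = profile_from_arrays([0.0, 1.0, 2.0], [2.0, 0.0, 2.0],
                                   censored=[False, True, False])
        assert auc_trapezoid(prof, 0.0, 2.0) == 2.0

    def test_dense_single_dose_converges_to_dose_over_clearance(self, params):
        """AUC(0->inf) of the one-compartment oral model is D/(V*ke); the
        trapezoid on a 0.05 h grid over 0-120 h agrees within 0.1%."""
        t = np.arange(0.0, 120.0001, 0.05)
        prof = profile_from_arrays(t, parent_conc(t, 150.0, params))
        analytic = 150.0 / (params.v_parent * params.ke)
        assert auc_trapezoid(prof, 0.0, 120.0) == pytest.approx(analytic, rel=1e-3)

    def test_second_order_convergence_in_grid_spacing(self, params):
        analytic = 150.0 / (params.v_parent * params.ke)
        errs = []
        for h in (0.4, 0.2, 0.1):
            t = np.arange(0.0, 150.0001, h)
            prof = profile_from_arrays(t, parent_conc(t, 150.0, params))
            errs.append(abs(auc_trapezoid(prof, 0.0, 150.0) - analytic))
        # halving h divides the error by ~4
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_too_few_samples_in_window(self):
        prof = profile_from_arrays([0.0, 5.0], [1.0, 1.0])
        with pytest.raises(UndefinedResultError):
            auc_trapezoid(prof, 1.0, 2.0)


class TestResidualAndRatio:
    def test_residual_reads_baseline_sample(self):
        prof = profile_from_arrays([10.0, 12.0], [1.2, 3.0])
        assert overnight_residual(prof, 10.0) == 1.2

    def test_censored_baseline_is_zero(self):
        prof = profile_from_arrays([10.0, 12.0], [0.0, 3.0], censored=[True, False])
        assert overnight_residual(prof, 10.0) == 0.0

    def test_missing_baseline_is_an_error(self):
        prof = profile_from_arrays([10.0, 12.0], [1.2, 3.0])
        with pytest.raises(UndefinedResultError):
            overnight_residual(prof, 9.0)

    def test_disproportionality(self):
        assert disproportionality(1.0, 1.0) == 1.0
        assert disproportionality(0.0, 36.1) == 0.0
        assert disproportionality(84.8, 36.1) == pytest.approx(2.349, abs=5e-4)
        assert np.isnan(disproportionality(84.8, 0.0))


class TestSummarize:
    @staticmethod
    def _table(values, analyte="caffeine"):
        import pandas as pd

        n = len(values)
        return pd.DataFrame(
            dict(
                subject_id=[f"S{i}" for i in range(n)],
                analyte=analyte,
                tmax=values, half_life=values, kel=values, cmax=values,
                residual=values, auc_c=values, auc_w=values,
            )
        )

    def test_single_subject_degenerate(self):
        s = summarize_nca(self._table([2.0]))
        row = s[s["metric"] == "kel_per_h"].iloc[0]
        assert row["mean"] == 2.0 and row["sd"] == 0.0
        med = s[s["metric"] == "half_life_h"].iloc[0]
        assert med["median"] == med["q1"] == med["q3"] == 2.0

    def test_identical_values_zero_spread(self):
        s = summarize_nca(self._table([3.0, 3.0, 3.0]))
        row = s[s["metric"] == "peak_level_ug_ml"].iloc[0]
        assert row["sd"] == 0.0 and row["max"] - row["min"] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 50.0), min_size=2, max_size=25))
    def test_matches_order_statistics_oracle_and_permutation_invariance(self, vals):
        import pandas as pd

        s = summarize_nca(self._table(vals))
        med = s[s["metric"] == "half_life_h"].iloc[0]
        srt = np.sort(vals)
        assert med["median"] == pytest.approx(float(np.median(srt)))
        assert med["q1"] == pytest.approx(float(np.percentile(srt, 25)))
        mean_row = s[s["metric"] == "auc_c_ug_h_ml"].iloc[0]
        assert mean_row["mean"] == pytest.approx(float(np.mean(vals)))
        assert mean_row["sd"] == pytest.approx(float(np.std(vals, ddof=1)))
        # invariance to subject ordering
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(vals))
        s2 = summarize_nca(self._table(shuffled))
        pd.testing.assert_frame_equal(
            s.drop(columns=["analyte"]), s2.drop(columns=["analyte"])
        )

    def test_nan_values_excluded_and_counted(self):
        s = summarize_nca(self._table([2.0, float("nan"), 4.0]))
        row = s[s["metric"] == "half_life_h"].iloc[0]
        assert row["n_used"] == 2 and row["n_excluded"] == 1
        assert row["median"] == 3.0

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(UndefinedResultError):
            summarize_nca(pd.DataFrame())
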