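"""Agreement statistics on the packaged clinical validation pairs.

The fixture ships the seven-lesion cohort of measured (catheter) and virtual
(simulated) resting Pd/Pa ratios; the frozen expected statistics are the
published summary values for that cohort.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from renalflow.agreement import (
    AgreementError,
    PairedSeries,
    agreement_report,
    binomial_ci,
    bland_altman,
    diagnostic_accuracy,
    export_validation_figures,
    mean_absolute_error,
    pearson_r,
    percentage_error_variants,
)
from renalflow.pipeline import validation_pairs_path


@pytest.fixture(scope="module")
def cohort():
    return PairedSeries.from_csv(validation_pairs_path())


class TestPairedSeries:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(AgreementError):
            PairedSeries(("a", "b"), np.array([0.9, 0.8]), np.array([0.9]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(AgreementError):
            PairedSeries(("a", "b"), np.array([0.9, 0.0]), np.array([0.9, 0.8]))


class TestBlandAltman:
    def test_cohort_mean_difference_and_sd(self, cohort):
        ba = bland_altman(cohort)
        assert ba["mean_difference"] == pytest.approx(0.015, abs=5e-4)
        assert ba["sd_differences"] == pytest.approx(0.087, abs=5e-4)

    def test_cohort_ci_halfwidth(self, cohort):
        # t(0.975, 6) * sd / sqrt(7)
        ba = bland_altman(cohort)
        oracle = sps.t.ppf(0.975, 6) * ba["sd_differences"] / np.sqrt(7)
        assert ba["ci_mean_difference_halfwidth"] == pytest.approx(oracle, rel=1e-12)
        assert round(ba["ci_mean_difference_halfwidth"], 2) == 0.08

    def test_identical_pairs(self):
        p = PairedSeries(("a", "b", "c"), np.full(3, 0.9), np.full(3, 0.9))
        ba = bland_altman(p)
        assert ba["mean_difference"] == 0.0
        assert ba["sd_differences"] == 0.0

    def test_limits_bracket_mean(self, cohort):
        ba = bland_altman(cohort)
        lo, hi = ba["limits_of_agreement"]
        assert lo < ba["mean_difference"] < hi
        assert hi - ba["mean_difference"] == pytest.approx(
            2.0 * ba["sd_differences"]
        )


class TestMeanAbsoluteError:
    def test_cohort(self, cohort):
        assert mean_absolute_error(cohort) == pytest.approx(0.064, abs=5e-4)

    def test_identical_pairs(self):
        p = PairedSeries(("a", "b"), np.array([0.9, 0.8]), np.array([0.9, 0.8]))
        assert mean_absolute_error(p) == 0.0

    def test_hand_arithmetic(self):
        p = PairedSeries(("a", "b"), np.array([1.0, 0.8]), np.array([0.9, 1.0]))
        assert mean_absolute_error(p) == pytest.approx(0.15)

    def test_percentage_error_variants_reported(self, cohort):
        pct = percentage_error_variants(cohort)
        # no single convention reproduces a unique 'percentage error'; both
        # standard readings are computed and exposed
        assert pct["mae_over_mean_measured"] == pytest.approx(
            100.0 * 0.0641 / np.mean(cohort.measured), abs=0.1
        )
        assert pct["mean_relative"] > 0.0


class TestPearson:
    def test_cohort(self, cohort):
        assert pearson_r(cohort) == pytest.approx(0.604, abs=5e-4)

    def test_perfect_linear(self):
        m = np.array([0.5, 0.7, 0.9])
        p = PairedSeries(("a", "b", "c"), m, 2.0 * m + 0.1)
        assert pearson_r(p) == pytest.approx(1.0)

    def test_matches_definitional_oracle(self, cohort):
        m, v = cohort.measured, cohort.virtual
        cov = np.mean((m - m.mean()) * (v - v.mean()))
        oracle = cov / (m.std() * v.std())
        assert pearson_r(cohort) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        p = PairedSeries(("a", "b", "c"), np.full(3, 0.9), np.array([0.7, 0.8, 0.9]))
        with pytest.raises(AgreementError):
            pearson_r(p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scale_invariance(self, cohort, a, b):
        scaled = PairedSeries(cohort.case_ids, a * cohort.measured, b * cohort.virtual)
        assert pearson_r(scaled) == pytest.approx(pearson_r(cohort), abs=1e-12)

    def test_sign_convention_on_swap(self, cohort):
        swapped = PairedSeries(cohort.case_ids, cohort.virtual, cohort.measured)
        assert bland_altman(swapped)["mean_difference"] == pytest.approx(
            -bland_altman(cohort)["mean_difference"], abs=1e-15
        )
        assert mean_absolute_error(swapped) == mean_absolute_error(cohort)
        assert bland_altman(swapped)["sd_differences"] == pytest.approx(
            bland_altman(cohort)["sd_differences"], abs=1e-15
        )
        assert pearson_r(swapped) == pytest.approx(pearson_r(cohort), abs=1e-15)


class TestBinomialCI:
    def test_four_of_four(self):
        lo, hi = binomial_ci(4, 4)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1.0 / 4.0), rel=1e-9)
        assert (round(lo, 1), round(hi, 1)) == (0.4, 1.0)

    def test_all_successes_closed_form(self):
        for n in (2, 5, 9):
            lo, hi = binomial_ci(n, n)
            assert hi == 1.0
            assert lo == pytest.approx(0.025 ** (1.0 / n), rel=1e-12)

    def test_two_of_two(self):
        lo, _ = binomial_ci(2, 2)
        assert lo == pytest.approx(np.sqrt(0.025), rel=1e-12)

    def test_zero_trials_rejected(self):
        with pytest.raises(AgreementError):
            binomial_ci(0, 0)

    def test_coverage_on_simulated_binomials(self):
        # exact interval must cover p at least nominally (94%+ here)
        rng = np.random.default_rng(12345)
        p_true, n = 0.5, 7
        ks = rng.binomial(n, p_true, size=10_000)
        covered = 0
        for k in np.bincount(ks, minlength=n + 1).nonzero()[0]:
            lo, hi = binomial_ci(int(k), n)
            if lo <= p_true <= hi:
                covered += int(np.sum(ks == k))
        assert covered / 10_000 >= 0.94


class TestDiagnosticAccuracy:
    def test_cohort_confusion(self, cohort):
        d = diagnostic_accuracy(cohort)
        # one discordant lesion: measured 0.958 (negative), virtual 0.862
        # (positive) -> false positive
        assert d["confusion"] == {"TP": 4, "FP": 1, "TN": 2, "FN": 0}

    def test_cohort_metrics(self, cohort):
        d = diagnostic_accuracy(cohort)
        assert d["sensitivity"]["value"] == pytest.approx(1.0)
        assert d["specificity"]["value"] == pytest.approx(2.0 / 3.0)
        assert d["ppv"]["value"] == pytest.approx(0.8)
        assert d["npv"]["value"] == pytest.approx(1.0)
        assert d["accuracy"]["value"] == pytest.approx(6.0 / 7.0)

    def test_cohort_sensitivity_ci(self, cohort):
        d = diagnostic_accuracy(cohort)
        lo, hi = d["sensitivity"]["ci"]
        assert (round(lo, 1), round(hi, 1)) == (0.4, 1.0)

    def test_all_concordant_positive(self):
        p = PairedSeries(
            ("a", "b", "c"), np.array([0.8, 0.7, 0.85]), np.array([0.82, 0.71, 0.8])
        )
        d = diagnostic_accuracy(p)
        assert d["sensitivity"]["value"] == 1.0
        assert d["accuracy"]["value"] == 1.0
        assert np.isnan(d["specificity"]["value"])  # no negatives: undefined

    def test_enumeration_against_brute_force(self):
        # all 2^4 patterns of (reference, test) positivity for 4 pairs
        for mask_m in range(16):
            for mask_v in range(16):
                m = np.where(
                    [(mask_m >> i) & 1 for i in range(4)], 0.85, 0.95
                )
                v = np.where(
                    [(mask_v >> i) & 1 for i in range(4)], 0.85, 0.95
                )
                p = PairedSeries(tuple("abcd"), m, v)
                d = diagnostic_accuracy(p)["confusion"]
                ref = np.array([(mask_m >> i) & 1 for i in range(4)], bool)
                tst = np.array([(mask_v >> i) & 1 for i in range(4)], bool)
                assert d["TP"] == int(np.sum(ref & tst))
                assert d["FP"] == int(np.sum(~ref & tst))
                assert d["TN"] == int(np.sum(~ref & ~tst))
                assert d["FN"] == int(np.sum(ref & ~tst))
                assert sum(d.values()) == 4

    def test_threshold_rounding_boundary(self, cohort):
        # a measured 0.903 rounds to 0.90 and is reference-positive, which
        # is what makes the cohort sensitivity exactly 1.0
        assert 0.903 in np.round(cohort.measured, 3)
        d = diagnostic_accuracy(cohort)
        assert d["sensitivity"]["value"] == 1.0


class TestFigures:
    def test_export_and_ols_oracle(self, cohort, tmp_path):
        report = agreement_report(cohort)
        paths = export_validation_figures(cohort, report, tmp_path)
        for p in paths.values():
            assert (tmp_path / p).exists() or p.startswith(str(tmp_path))
        # OLS slope/intercept vs normal-equations brute force
        import pandas as pd

        fit = pd.read_csv(paths["correlation_csv"])
        m, v = cohort.measured, cohort.virtual
        X = np.column_stack([m, np.ones_like(m)])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        assert fit["slope"][0] == pytest.approx(beta[0], abs=1e-10)
        assert fit["intercept"][0] == pytest.approx(beta[1], abs=1e-10)

    def test_bland_altman_lines_from_report(self, cohort, tmp_path):
        report = agreement_report(cohort)
        ba = report.bland_altman
        lo, hi = ba["limits_of_agreement"]
        assert lo == pytest.approx(ba["mean_difference"] - 2 * ba["sd_differences"])
        assert hi == pytest.approx(ba["mean_difference"] + 2 * ba["sd_differences"])
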