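import numpy as np
import pytest
from scipy import stats

from bowelperf.cohort_stats import (
    PairedSample,
    PowerSpec,
    modality_comparison_report,
    retrospective_power,
    shapiro_wilk,
    spearman,
    wilcoxon_signed_rank,
)
from bowelperf.errors import DegenerateSampleError, InsufficientCasesError, ValidationError
from bowelperf.synthetic import CohortScenario, simulate_cohort

import oracles


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            _, p = shapiro_wilk(x)
            rejections += p <= 0.05
        assert rejections <= 10

    def test_exponential_samples_usually_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(1.0, 200)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 95

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk(np.full(20, 3.0))


class TestWilcoxon:
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 9, 10])
    def test_exact_p_equals_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        a, b = rng.normal(0, 1, n), rng.normal(0.4, 1, n)
        _, p = wilcoxon_signed_rank(PairedSample(a, b))
        assert p == pytest.approx(oracles.wilcoxon_exact_brute(a - b), abs=1e-12)

    @pytest.mark.parametrize("n", [8, 12, 18])
    def test_exact_p_matches_scipy(self, n):
        rng = np.random.default_rng(100 + n)
        a, b = rng.normal(0, 1, n), rng.normal(0.3, 1, n)
        _, p = wilcoxon_signed_rank(PairedSample(a, b))
        assert p == pytest.approx(stats.wilcoxon(a, b, mode="exact").pvalue, abs=1e-12)

    def test_symmetric_differences_give_p_one(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        _, p = wilcoxon_signed_rank(PairedSample(d, np.zeros(6)))
        assert p == 1.0

    def test_all_positive_n6(self):
        _, p = wilcoxon_signed_rank(PairedSample(np.arange(1.0, 7.0), np.zeros(6)))
        assert p == pytest.approx(2.0 / 64.0)

    def test_all_zero_differences_degenerate(self):
        x = np.ones(6)
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank(PairedSample(x, x))

    def test_tie_corrected_normal_path_close_to_scipy(self):
        rng = np.random.default_rng(7)
        a = np.round(rng.normal(0, 1, 40), 1)
        b = np.round(rng.normal(0.2, 1, 40), 1)
        keep = (a - b) != 0
        _, p = wilcoxon_signed_rank(PairedSample(a[keep], b[keep]))
        ref = stats.wilcoxon(a[keep], b[keep], mode="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_type_one_error_controlled_under_null(self):
        """Empirical size <= 0.06 at nominal 0.05 (symmetric null, n = 18)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 10_000
        for _ in range(n_sims):
            d = rng.normal(0, 1, 18)
            _, p = wilcoxon_signed_rank(PairedSample(d, np.zeros(18)))
            rejections += p < 0.05
        assert rejections / n_sims <= 0.06


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson(self, rng):
        x = np.round(rng.normal(0, 1, 30), 1)
        y = np.round(x + rng.normal(0, 0.5, 30), 1)
        rho, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        pearson = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            spearman(np.ones(10), np.arange(10.0))


class TestPower:
    def test_vanishing_effect_gives_alpha(self):
        power = retrospective_power(PowerSpec(delta_cm=1e-9, sd_paired_diff=1.0))
        assert power == pytest.approx(0.05, abs=1e-3)

    def test_matches_monte_carlo_oracle(self):
        """Noncentral-t power within 0.005 of 200k simulated paired-t tests."""
        spec = PowerSpec(delta_cm=1.0, alpha=0.05, n=18, sd_paired_diff=1.0)
        analytic = retrospective_power(spec)
        rng = np.random.default_rng(99)
        sims = rng.normal(1.0, 1.0, (200_000, 18))
        t_stats = sims.mean(axis=1) / (sims.std(axis=1, ddof=1) / np.sqrt(18))
        crit = stats.t.ppf(0.975, 17)
        assert analytic == pytest.approx((np.abs(t_stats) > crit).mean(), abs=0.005)

    def test_monotone_in_effect_and_sample_size(self):
        powers_d = [retrospective_power(PowerSpec(delta_cm=d, sd_paired_diff=1.0)) for d in (0.2, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(powers_d) > 0)
        powers_n = [retrospective_power(PowerSpec(n=n, sd_paired_diff=1.0)) for n in (6, 12, 18, 36, 72)]
        assert np.all(np.diff(powers_n) > 0)

    def test_wilcoxon_mode_slightly_below_t_mode(self):
        spec = PowerSpec(delta_cm=0.5, sd_paired_diff=0.6)
        assert retrospective_power(spec, "wilcoxon") < retrospective_power(spec, "t")

    def test_invalid_spec(self):
        with pytest.raises(ValidationError):
            PowerSpec(delta_cm=-0.1)
        with pytest.raises(ValidationError):
            PowerSpec(alpha=1.5)


class TestModalityReport:
    def test_shared_border_null(self):
        distances, _ = simulate_cohort(CohortScenario(seed=0, n_cases=30))
        report = modality_comparison_report(distances)
        assert (report["p_value"] > 0.05).all()
        assert np.all(np.abs(report["median_a_cm"]) < 0.1)

    def test_builtin_offset_detected(self):
        detections = 0
        for seed in range(50):
            distances, _ = simulate_cohort(
                CohortScenario(seed=seed, n_cases=30, offsets_cm={"icg": 0.0, "recicg": 0.0, "sto2": 0.24})
            )
            report = modality_comparison_report(distances)
            row = report[report["modality_a"] == "sto2"].iloc[0]
            detections += row["p_value"] < 0.05
        assert detections >= 45

    def test_power_annotation_present(self):
        distances, _ = simulate_cohort(CohortScenario(seed=4, n_cases=18))
        report = modality_comparison_report(distances)
        assert ((report["power"] > 0) & (report["power"] <= 1)).all()

    def test_incomplete_cases_dropped(self):
        distances, _ = simulate_cohort(CohortScenario(seed=5, n_cases=10))
        distances.iloc[0, 0] = np.nan
        report = modality_comparison_report(distances)
        assert report["n_cases"].iloc[0] == 9
        assert report.attrs["n_dropped_cases"] == 1

    def test_two_cases_insufficient(self):
        distances, _ = simulate_cohort(CohortScenario(seed=6, n_cases=5))
        with pytest.raises(InsufficientCasesError):
            modality_comparison_report(distances.iloc[:2])
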