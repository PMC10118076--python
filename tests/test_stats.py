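import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ceboost.errors import DegenerateInputError
from ceboost.stats_report import (
    KappaResult,
    PairedSample,
    RatingTable,
    cohen_kappa,
    compare_report,
    interpret_kappa,
    normality_check,
    paired_t,
    wilcoxon_signed_rank,
)


def _ratings_from_table(table, categories=(4, 5)):
    """Long-format two-reader ratings realizing a given contingency table."""
    rows = []
    case = 0
    for i, ci in enumerate(categories):
        for j, cj in enumerate(categories):
            for _ in range(table[i][j]):
                rows.append({"case_id": case, "reader": "R1", "criterion": "overall", "score": ci})
                rows.append({"case_id": case, "reader": "R2", "criterion": "overall", "score": cj})
                case += 1
    return RatingTable(pd.DataFrame(rows))


class TestNormality:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gaussian_sample_not_rejected(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, 5000)
        _, p = normality_check(x, "shapiro_wilk")
        assert p > 0.01

    def test_linear_ramp_not_rejected_at_small_n(self):
        x = np.arange(1.0, 11.0)
        for method in ("shapiro_wilk", "kolmogorov_smirnov"):
            _, p = normality_check(x, method)
            assert p > 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            normality_check(np.full(10, 3.0))


class TestPairedT:
    def test_matches_hand_formula(self):
        a = np.array([1.0, 2, 3, 4, 10])
        b = np.array([2.0, 2, 4, 4, 9])
        t, df, p = paired_t(PairedSample(a, b))
        # independent oracle: one-sample t on the differences, by hand
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert abs(t - t_hand) < 1e-12
        assert df == 4

    def test_equals_one_sample_t_on_differences(self, rng):
        from scipy.stats import ttest_1samp

        a = rng.normal(10, 2, 25)
        b = rng.normal(9, 2, 25)
        t, _, p = paired_t(PairedSample(a, b))
        ref = ttest_1samp(a - b, 0.0)
        assert abs(t - ref.statistic) < 1e-10 and abs(p - ref.pvalue) < 1e-10

    def test_zero_variance_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t(PairedSample(np.arange(4.0), np.arange(4.0)))
        with pytest.raises(DegenerateInputError):
            paired_t(PairedSample(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5])))


def _brute_force_wilcoxon_p(d, alternative="two-sided"):
    """Literal enumeration of all 2^n sign assignments (midranked ties)."""
    from scipy.stats import rankdata

    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(ranks))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_differences_one_sided(self):
        a = np.array([2.0, 4, 6, 8, 10, 12])
        b = np.array([1.0, 2, 3, 4, 5, 6])
        w, p = wilcoxon_signed_rank(PairedSample(a, b), alternative="greater")
        assert w == 21.0  # full rank sum 1+..+6
        assert abs(p - 1 / 64) < 1e-12

    def test_symmetric_differences_near_one(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a + np.array([1.0, -1, 2, -2, 3, -3])
        w, p = wilcoxon_signed_rank(PairedSample(a, b))
        assert p > 0.9

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank(PairedSample(np.arange(5.0), np.arange(5.0)))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a = rng.integers(0, 6, n).astype(float)  # integer data forces ties/zeros
        b = rng.integers(0, 6, n).astype(float)
        if np.all(a == b):
            a[0] += 1
        sample = PairedSample(a, b) if n >= 3 else None
        for alt in ("two-sided", "greater", "less"):
            _, p = wilcoxon_signed_rank(sample, alternative=alt)
            assert abs(p - _brute_force_wilcoxon_p(a - b, alt)) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normal_approximation_close_at_n15(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 2.0, 15)
        b = rng.normal(0.0, 2.0, 15)
        sample = PairedSample(a, b)
        _, p_exact = wilcoxon_signed_rank(sample, exact_threshold=15)
        _, p_approx = wilcoxon_signed_rank(sample, exact_threshold=0)
        assert abs(p_exact - p_approx) < 0.02


class TestKappa:
    def test_perfect_agreement(self):
        table = [[10, 0], [0, 10]]
        res = cohen_kappa(_ratings_from_table(table))
        assert res.kappa == pytest.approx(1.0)
        assert res.interpretation == "excellent"

    def test_known_contingency_table(self):
        # po = 0.7, pe = 0.5 -> kappa = 0.4 ("fair")
        res = cohen_kappa(_ratings_from_table([[20, 5], [10, 15]]))
        po, pe = 35 / 50, (25 * 30 + 25 * 20) / 50**2
        assert abs(res.kappa - (po - pe) / (1 - pe)) < 1e-9
        assert res.interpretation == "fair"

    def test_interpretation_bins(self):
        assert interpret_kappa(0.58) == "moderate"
        assert interpret_kappa(0.90) == "excellent"
        assert interpret_kappa(0.70) == "substantial"
        assert interpret_kappa(0.30) == "fair"
        assert interpret_kappa(0.10) == "poor"
        with pytest.raises(DegenerateInputError):
            interpret_kappa(1.5)

    def test_relabeling_invariance(self):
        table = [[12, 3], [5, 10]]
        k1 = cohen_kappa(_ratings_from_table(table, categories=(1, 2))).kappa
        k2 = cohen_kappa(_ratings_from_table(table, categories=(4, 5))).kappa
        assert abs(k1 - k2) < 1e-12

    def test_single_category_undefined(self):
        with pytest.raises(DegenerateInputError):
            cohen_kappa(_ratings_from_table([[10, 0], [0, 0]]))

    def test_scores_outside_likert_rejected(self):
        df = pd.DataFrame(
            {"case_id": [0, 0], "reader": ["R1", "R2"], "criterion": ["q", "q"], "score": [6, 3]}
        )
        with pytest.raises(DegenerateInputError):
            RatingTable(df)


class TestCompareReport:
    def _records(self, n_cases=12, effect=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for case in range(n_cases):
            for segment in ("BA", "VA"):
                base = rng.normal(400, 10)
                rows.append({"case": case, "segment": segment, "variant": "conventional",
                             "attenuation_hu": base, "noise_hu": 8 + rng.normal(0, 0.5),
                             "snr": 50 + rng.normal(0, 3), "cnr": 45 + rng.normal(0, 3),
                             "fwhm_mm": 3.0 + rng.normal(0, 0.05)})
                rows.append({"case": case, "segment": segment, "variant": "boosted",
                             "attenuation_hu": base + 200 + rng.normal(0, 5),
                             "noise_hu": 6 + rng.normal(0, 0.5),
                             "snr": 50 + effect + rng.normal(0, 3),
                             "cnr": 45 + effect + rng.normal(0, 3),
                             "fwhm_mm": 2.9 + rng.normal(0, 0.05)})
        return pd.DataFrame(rows)

    def test_table_shape(self):
        rep = compare_report(self._records())["objective"]
        # 2 segments + 1 average row per metric, 5 metrics
        assert len(rep) == 3 * 5
        assert set(rep.segment) == {"BA", "VA", "average"}

    def test_means_match_direct_recomputation(self):
        df = self._records()
        rep = compare_report(df)["objective"]
        row = rep[(rep.metric == "snr") & (rep.segment == "BA")].iloc[0]
        raw = df[(df.segment == "BA") & (df.variant == "conventional")]["snr"]
        assert abs(row.conventional_mean - raw.mean()) < 1e-9
        assert abs(row.conventional_sd - raw.std(ddof=1)) < 1e-9

    def test_built_in_effect_detected(self):
        rep = compare_report(self._records(effect=8.0))["objective"]
        snr_avg = rep[(rep.metric == "snr") & (rep.segment == "average")].iloc[0]
        assert snr_avg.boosted_mean > snr_avg.conventional_mean
        assert snr_avg.p_value < 0.05
        fwhm_avg = rep[(rep.metric == "fwhm_mm") & (rep.segment == "average")].iloc[0]
        assert fwhm_avg.test == "wilcoxon"

    def test_unpaired_records_rejected(self):
        df = self._records()
        df = df[~((df["case"] == 0) & (df.variant == "boosted") & (df.segment == "BA"))]
        with pytest.raises(DegenerateInputError, match="unpaired"):
            compare_report(df)

    def test_agreement_table_included(self):
        ratings = _ratings_from_table([[20, 5], [10, 15]])
        tables = compare_report(self._records(), ratings)
        agree = tables["agreement"]
        assert "overall" in set(agree.criterion)
        assert set(agree.interpretation) <= {"poor", "fair", "moderate", "substantial", "excellent"}
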