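import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petratio.reliability import (
    PairedMeasurements,
    anova_oneway,
    build_reliability_report,
    cov_pct,
    error_variance_pct,
    icc_oneway,
    sem_pct,
    var_pct,
)

from .oracles import anova_first_principles


def pairs_of(test, retest):
    n = len(test)
    return PairedMeasurements(subjects=[f"s{i}" for i in range(n)],
                              test=np.asarray(test, float),
                              retest=np.asarray(retest, float))


class TestAnova:
    def test_zero_within_subject_variance(self):
        ms_b, ms_w = anova_oneway(pairs_of([1, 2, 3], [1, 2, 3]))
        assert ms_w == 0.0
        assert ms_b == pytest.approx(2.0)  # 2 · var([1,2,3])

    def test_matches_first_principles_decomposition(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            test = rng.normal(10, 2, size=6)
            retest = test + rng.normal(0, 1, size=6)
            ms_b, ms_w = anova_oneway(pairs_of(test, retest))
            oracle_b, oracle_w = anova_first_principles(test, retest)
            assert ms_b == pytest.approx(oracle_b, rel=1e-12)
            assert ms_w == pytest.approx(oracle_w, rel=1e-12)

    def test_exchangeable_within_subject(self):
        a = anova_oneway(pairs_of([1, 5, 2], [2, 4, 2.5]))
        b = anova_oneway(pairs_of([2, 4, 2], [1, 5, 2.5]))  # swap subjects 1, 2
        assert a == pytest.approx(b)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            pairs_of([1.0], [2.0])


class TestIcc:
    def test_perfect_reliability(self):
        assert icc_oneway(pairs_of([1, 2, 3], [1, 2, 3])) == 1.0

    def test_pure_within_subject_variance_floor(self):
        assert icc_oneway(pairs_of([1, 2], [2, 1])) == pytest.approx(-1.0)

    def test_all_identical_defined_as_one_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            assert icc_oneway(pairs_of([2, 2], [2, 2])) == 1.0

    def test_matches_variance_ratio_monte_carlo(self):
        # n = 10^4 pairs with σb = 2, σw = 1 → ICC → 4/5
        rng = np.random.default_rng(99)
        n = 10_000
        subject = rng.normal(10, 2, size=n)
        test = subject + rng.normal(0, 1, size=n)
        retest = subject + rng.normal(0, 1, size=n)
        icc = icc_oneway(pairs_of(test, retest))
        assert icc == pytest.approx(4.0 / 5.0, abs=0.01)


class TestErrorVariance:
    @pytest.mark.parametrize("icc,expected", [(0.89, 11.0), (0.93, 7.0), (1.0, 0.0)])
    def test_percent_error_variance(self, icc, expected):
        assert error_variance_pct(icc) == pytest.approx(expected)

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            error_variance_pct(1.2)


class TestCov:
    def test_all_equal_gives_zero(self):
        assert cov_pct(np.array([3.0, 3.0, 3.0])) == 0.0

    def test_hand_computed_example(self):
        # SD of {8, 12} is 2√2 (n−1), mean 10
        assert cov_pct(np.array([8.0, 12.0])) == pytest.approx(100 * 2 * np.sqrt(2) / 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        x = np.array([4.0, 5.0, 7.0, 9.0])
        assert cov_pct(c * x) == pytest.approx(cov_pct(x), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            cov_pct(np.array([-1.0, 1.0]))


class TestVar:
    def test_zero_when_test_equals_retest(self):
        assert var_pct(pairs_of([1, 2, 3], [1, 2, 3])) == 0.0

    def test_hand_computed_pair(self):
        # each pair (1.0, 1.2) contributes 200·0.2/2.2
        assert var_pct(pairs_of([1.0, 1.0], [1.2, 1.2])) == pytest.approx(200 * 0.2 / 2.2)

    def test_invariant_to_subjectwise_rescaling(self):
        base = pairs_of([1.0, 2.0, 4.0], [1.2, 1.9, 4.4])
        scaled = pairs_of([3.0, 10.0, 2.0], [3.6, 9.5, 2.2])  # × (3, 5, 0.5)
        assert var_pct(scaled) == pytest.approx(var_pct(base))

    def test_nonpositive_pair_sum_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            var_pct(pairs_of([0.0, 1.0], [0.0, 1.0]))


class TestSem:
    def test_zero_when_test_equals_retest(self):
        assert sem_pct(pairs_of([1, 2, 3], [1, 2, 3])) == 0.0

    def test_hand_computed_pair(self):
        # pairs {(9,11)} twice: MS_W = 2, grand mean 10 → 100·√2/10
        assert sem_pct(pairs_of([9.0, 9.0], [11.0, 11.0])) == pytest.approx(
            100 * np.sqrt(2) / 10)

    def test_estimates_within_subject_cov_monte_carlo(self):
        # multiplicative within-subject noise with CV w → SEM% ≈ 100·w
        rng = np.random.default_rng(17)
        n, w = 20_000, 0.08
        subject = rng.lognormal(0, 0.25, size=n) * 10
        test = subject * (1 + rng.normal(0, w, size=n))
        retest = subject * (1 + rng.normal(0, w, size=n))
        assert sem_pct(pairs_of(test, retest)) == pytest.approx(100 * w, rel=0.05)


@pytest.fixture(scope="module")
def synthetic_outcomes():
    # hand-built outcome table: 4 HAB + 4 MAB subjects, 2 scans
    rng = np.random.default_rng(3)
    rows = []
    for i in range(8):
        geno = "HAB" if i < 4 else "MAB"
        level = (4.0 if geno == "HAB" else 2.2) * (1 + 0.2 * rng.normal())
        for scan in (1, 2):
            for measure in ("VT", "SUV", "SUVR_WB", "SUVR_CBL",
                            "DVR_WB", "DVR_CBL"):
                noise = 1 + 0.05 * rng.normal()
                value = level * noise if measure in ("VT", "SUV") else noise
                rows.append({"subject": f"s{i}", "scan": scan,
                             "genotype": geno, "roi": "frontal_cortex",
                             "measure": measure, "value": value})
    return pd.DataFrame(rows)


class TestReport:
    def test_table_layout(self, synthetic_outcomes):
        report = build_reliability_report(synthetic_outcomes)
        assert len(report) == 16
        vt = report[report.measure == "VT"]
        assert sorted(vt.genotype) == ["HAB", "MAB"]  # no pooled V_T row
        for m, den in (("DVR", "CBL"), ("DVR", "WB"), ("SUVR", "CBL"), ("SUVR", "WB")):
            rows = report[(report.measure == m) & (report.denominator == den)]
            assert sorted(rows.genotype) == ["All", "HAB", "MAB"]

    def test_incomplete_subject_reduces_n_with_warning(self, synthetic_outcomes):
        trimmed = synthetic_outcomes[~((synthetic_outcomes.subject == "s0")
                                       & (synthetic_outcomes.scan == 2))]
        with pytest.warns(UserWarning, match="s0"):
            report = build_reliability_report(trimmed)
        vt_hab = report[(report.measure == "VT") & (report.genotype == "HAB")]
        assert int(vt_hab.n.iloc[0]) == 3

    def test_noiseless_cohort_gives_icc_one_throughout(self):
        rows = []
        for i in range(4):
            for scan in (1, 2):
                rows.append({"subject": f"s{i}", "scan": scan, "genotype": "HAB",
                             "roi": "frontal_cortex", "measure": "VT",
                             "value": 2.0 + i})
                rows.append({"subject": f"s{i}", "scan": scan, "genotype": "HAB",
                             "roi": "frontal_cortex", "measure": "SUV",
                             "value": 1.0 + i})
        df = pd.DataFrame(rows)
        df2 = df.copy()
        df2["genotype"] = "MAB"
        df2["subject"] = df2["subject"] + "m"
        report = build_reliability_report(pd.concat([df, df2]))
        assert np.allclose(report.icc, 1.0)
        assert np.allclose(report.sem_pct, 0.0)

    def test_metrics_permutation_invariant(self):
        a = pairs_of([1.0, 2.0, 3.0], [1.1, 2.2, 2.9])
        b = pairs_of([3.0, 1.0, 2.0], [2.9, 1.1, 2.2])
        assert icc_oneway(a) == pytest.approx(icc_oneway(b))
        assert var_pct(a) == pytest.approx(var_pct(b))
        assert sem_pct(a) == pytest.approx(sem_pct(b))
        assert cov_pct(a.pooled) == pytest.approx(cov_pct(b.pooled))
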