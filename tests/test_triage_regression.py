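import numpy as np
import pandas as pd
import pytest

from evotriage.errors import ConfigError, DataFormatError, EvoTriageError
from evotriage.triage_regression import (
    Thresholds,
    classify,
    corrected_fraction,
    fit_triage,
    frequently_mutated,
    mutation_fraction,
    mutation_fractions,
    score_cohort,
    standardized_residuals,
)

from conftest import make_record, ols_oracle, sample_for


class TestMutationFraction:
    def _cohort(self, n):
        return [f"TCGA-AA-{i:04d}" for i in range(1, n + 1)]

    def test_patient_counted_once_per_gene(self):
        records = [
            make_record("TLR4", sample=sample_for(1), hgvsp=f"p.A{i}V") for i in (10, 20, 30)
        ]
        n, f = mutation_fraction(records, self._cohort(10), "TLR4")
        assert (n, f) == (1, 0.1)

    def test_fraction_matches_hand_count(self):
        # 37 mutated patients in a 313-patient cohort -> f = 37/313 ~ 0.118
        records = [make_record("TLR4", sample=sample_for(i), hgvsp="p.A10V") for i in range(1, 38)]
        n, f = mutation_fraction(records, self._cohort(313), "TLR4")
        assert n == 37
        assert f == pytest.approx(37 / 313)
        assert f == pytest.approx(0.118, abs=5e-4)

    def test_absent_gene_is_zero(self):
        records = [make_record("TP53", sample=sample_for(1), hgvsp="p.R175H")]
        assert mutation_fraction(records, self._cohort(5), "TLR4") == (0, 0.0)

    def test_silent_mutations_do_not_count(self):
        records = [
            make_record("TLR4", sample=sample_for(1), classification="Silent", hgvsp="p.A10A"),
            make_record("TLR4", sample=sample_for(2), hgvsp="p.A10V"),
        ]
        table = mutation_fractions(records, self._cohort(10))
        assert int(table.loc["TLR4", "n_mutated"]) == 1

    def test_patients_outside_cohort_ignored(self):
        records = [make_record("TLR4", sample=sample_for(99), hgvsp="p.A10V")]
        assert mutation_fraction(records, self._cohort(5), "TLR4") == (0, 0.0)

    def test_empty_cohort_is_error(self):
        with pytest.raises(DataFormatError):
            mutation_fractions([], [])


class TestCorrectedFraction:
    @pytest.mark.parametrize("f,m,expected", [(0.10, 0.5, 0.20), (0.10, 1.0, 0.10), (0.0, 0.7, 0.0)])
    def test_arithmetic(self, f, m, expected):
        assert corrected_fraction(f, m) == pytest.approx(expected)

    def test_can_exceed_one(self):
        assert corrected_fraction(0.9, 0.5) == pytest.approx(1.8)

    def test_zero_coverage_is_error(self):
        with pytest.raises(DataFormatError):
            corrected_fraction(0.1, 0.0)


class TestFitTriage:
    def test_collinear_points_fit_exactly(self):
        x = np.array([10.0, 20.0, 30.0])
        y = 0.1 + 0.002 * x
        model = fit_triage(x, y)
        assert model.slope == pytest.approx(0.002, abs=1e-12)
        assert model.intercept == pytest.approx(0.1, abs=1e-12)
        assert model.residual_scale == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        x = np.sqrt(rng.uniform(300, 6000, 10))
        y = 0.01 + 0.004 * x + rng.normal(0, 0.02, 10)
        model = fit_triage(x, y)
        intercept, slope, scale, _ = ols_oracle(x, y)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.residual_scale == pytest.approx(scale, abs=1e-10)

    def test_duplicating_every_gene_keeps_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 80, 12)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 12)
        single = fit_triage(x, y)
        doubled = fit_triage(np.concatenate([x, x]), np.concatenate([y, y]))
        assert doubled.slope == pytest.approx(single.slope, abs=1e-12)
        assert doubled.intercept == pytest.approx(single.intercept, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DataFormatError):
            fit_triage([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataFormatError):
            fit_triage([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        with pytest.raises(ConfigError):
            fit_triage([1.0, 2.0, 3.0], [1.0, 2.0, 3.1], estimator="nope")

    def test_huber_resists_outliers_more_than_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(10, 80, 60)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.005, 60)
        y[:3] += 1.0  # gross over-mutation outliers
        clean_slope = fit_triage(x[3:], y[3:]).slope
        ols = fit_triage(x, y)
        huber = fit_triage(x, y, estimator="huber")
        assert abs(huber.slope - clean_slope) < abs(ols.slope - clean_slope)


class TestStandardizedResiduals:
    def test_gene_on_the_line_has_sr_zero(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(10, 80, 20)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 20)
        model = fit_triage(x, y)
        on_line = np.array([40.0])
        sr = standardized_residuals(model, on_line, model.predict(on_line))
        assert sr[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_toy_table(self):
        rng = np.random.default_rng(11)
        x = np.sqrt(rng.uniform(300, 6000, 10))
        y = 0.01 + 0.004 * x + rng.normal(0, 0.02, 10)
        model = fit_triage(x, y)
        sr = standardized_residuals(model, x, y)
        *_, sr_oracle = ols_oracle(x, y)
        np.testing.assert_allclose(sr, sr_oracle, atol=1e-10)

    def test_most_inflated_gene_attains_max_sr(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 80, 30)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.005, 30)
        y[17] += 0.5  # inflate one gene's corrected fraction
        model = fit_triage(x, y)
        sr = standardized_residuals(model, x, y)
        assert int(np.argmax(sr)) == 17

    def test_residuals_sum_to_zero_and_sr_mean_zero(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(10, 80, 200)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 200)
        model = fit_triage(x, y)
        resid = y - model.predict(x)
        assert abs(resid.sum()) < 1e-9 * len(x)
        sr = standardized_residuals(model, x, y)
        assert abs(sr.mean()) < 1e-9

    def test_affine_shift_moves_intercept_only(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(10, 80, 50)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 50)
        m0 = fit_triage(x, y)
        m1 = fit_triage(x, y + 0.7)
        assert m1.slope == pytest.approx(m0.slope, abs=1e-12)
        assert m1.intercept == pytest.approx(m0.intercept + 0.7, abs=1e-12)
        np.testing.assert_allclose(
            standardized_residuals(m0, x, y), standardized_residuals(m1, x, y + 0.7), atol=1e-10
        )

    def test_sr_strictly_increasing_in_corrected_fraction(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(10, 80, 30)
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 30)
        model = fit_triage(x, y)
        c_grid = np.linspace(0.01, 0.5, 10)
        sr = standardized_residuals(model, np.full(10, 40.0), np.sqrt(c_grid))
        assert np.all(np.diff(sr) > 0)

    def test_perfect_fit_raises(self):
        x = np.array([10.0, 20.0, 30.0])
        model = fit_triage(x, 0.1 + 0.002 * x)
        with pytest.raises(EvoTriageError, match="degenerate"):
            standardized_residuals(model, x, 0.1 + 0.002 * x)

    def test_studentized_inflates_high_leverage_points(self):
        rng = np.random.default_rng(23)
        x = np.concatenate([rng.uniform(10, 20, 20), [90.0]])
        y = 0.05 + 0.003 * x + rng.normal(0, 0.01, 21)
        model = fit_triage(x, y)
        plain = standardized_residuals(model, x, y)
        stud = standardized_residuals(model, x, y, studentized=True)
        assert abs(stud[-1]) > abs(plain[-1])


class TestClassify:
    @pytest.mark.parametrize(
        "sr,label,tier",
        [
            (-2.5, "conserved", "significant"),
            (-1.7, "conserved", "suggestive"),
            (-1.0, "conserved", "none"),
            (0.0, "background", "none"),
            (0.99, "background", "none"),
            (1.0, "over_mutated", "none"),
            (1.7, "over_mutated", "suggestive"),
            (2.0, "over_mutated", "significant"),
        ],
    )
    def test_labels_and_tiers(self, sr, label, tier):
        got_label, got_tier, p = classify(sr)
        assert (got_label, got_tier) == (label, tier)
        assert 0.0 <= p <= 1.0

    def test_p_value_reference_points(self):
        # the tier cutoffs correspond to two-sided normal p of ~0.10 and ~0.05
        assert classify(-1.65)[2] == pytest.approx(0.0989, abs=1e-3)
        assert classify(-1.96)[2] == pytest.approx(0.05, abs=1e-3)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            Thresholds(flag=2.0, suggestive=1.0, significant=2.5)


class TestFrequentlyMutated:
    def _scores(self, fs):
        return pd.DataFrame({"f": fs}, index=[f"G{i}" for i in range(len(fs))]).rename_axis("gene_symbol")

    def test_strictly_greater_than_cutoff(self):
        scores = self._scores([0.11, 0.10, 0.09])
        assert frequently_mutated(scores) == {"G0"}

    def test_empty_table(self):
        assert frequently_mutated(self._scores([])) == set()


class TestScoreCohort:
    def test_end_to_end_columns_and_consistency(self):
        rng = np.random.default_rng(29)
        genes = [f"G{i}" for i in range(40)]
        lengths = pd.Series(rng.uniform(500, 5000, 40), index=genes)
        cov = pd.Series(rng.uniform(0.8, 1.0, 40), index=genes)
        cohort = [f"TCGA-AA-{i:04d}" for i in range(1, 51)]
        records = []
        for i, g in enumerate(genes):
            for j in range(1, 1 + int(lengths[g] // 900)):
                records.append(make_record(g, sample=sample_for(j), hgvsp="p.A10V"))
        scores, model = score_cohort(records, cohort, lengths, cov, genes)
        assert list(scores.index) == sorted(genes)
        np.testing.assert_allclose(scores["f"], scores["n_mutated"] / 50)
        np.testing.assert_allclose(scores["c"], scores["f"] / scores["m"])
        # labels consistent with sr
        for _, row in scores.iterrows():
            if row["sr"] <= -1.0:
                assert row["label"] == "conserved"
            elif row["sr"] >= 1.0:
                assert row["label"] == "over_mutated"
            else:
                assert row["label"] == "background"

    def test_unmutated_kept_gene_scored_at_zero(self):
        genes = ["A", "B", "C", "D"]
        lengths = pd.Series([500.0, 1000.0, 2000.0, 4000.0], index=genes)
        cov = pd.Series([1.0, 1.0, 1.0, 1.0], index=genes)
        cohort = [f"TCGA-AA-{i:04d}" for i in range(1, 11)]
        records = [
            make_record("A", sample=sample_for(1), hgvsp="p.A10V"),
            make_record("B", sample=sample_for(2), hgvsp="p.A10V"),
            make_record("C", sample=sample_for(3), hgvsp="p.A10V"),
        ]
        scores, _ = score_cohort(records, cohort, lengths, cov, genes)
        assert scores.loc["D", "n_mutated"] == 0
        assert scores.loc["D", "f"] == 0.0
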