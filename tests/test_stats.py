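"""Normality gating, log policy, exact Mann-Whitney, Pearson, summaries."""

import numpy as np
import pandas as pd
import pytest

from renalsmi.errors import DegenerateInputError, ValidationError
from renalsmi.stats import (
    apply_log_policy,
    mann_whitney_exact,
    normality_gate,
    pearson_corr,
    summarize_cohort,
)

from mw_oracle import exact_two_sided_p


class TestNormalityGate:
    def test_level_on_normal_samples(self):
        flags = []
        for s in range(100):
            x = np.random.default_rng(s).normal(size=100)
            flags.append(normality_gate(x)[0] == "normal")
        assert np.mean(flags) >= 0.90

    def test_power_on_exponential_samples(self):
        flags = []
        for s in range(100):
            x = np.random.default_rng(s).exponential(size=100)
            flags.append(normality_gate(x)[0] == "non_normal")
        assert np.mean(flags) >= 0.90

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_gate(np.full(10, 3.0))

    def test_sample_size_bounds(self):
        with pytest.raises(ValidationError):
            normality_gate(np.array([1.0, 2.0]))


class TestLogPolicy:
    def test_log_of_e_is_one(self):
        table = pd.DataFrame({"cvp": np.full(10, np.e)})
        out, flags = apply_log_policy(table, ["cvp"], force=True)
        assert np.allclose(out["cvp"], 1.0)
        assert flags["cvp"]

    def test_normal_variable_left_unchanged(self):
        x = np.random.default_rng(0).normal(10, 1, 50)
        table = pd.DataFrame({"cvp": x})
        out, flags = apply_log_policy(table, ["cvp"], force=False)
        assert not flags["cvp"]
        assert np.array_equal(out["cvp"].to_numpy(), x)

    def test_lognormal_variable_passes_gate_after_log(self):
        passes = []
        for s in range(100):
            x = np.exp(np.random.default_rng(s).normal(1.0, 0.7, 100))
            table = pd.DataFrame({"rmp": x})
            out, flags = apply_log_policy(table, ["rmp"], force=False)
            if flags["rmp"]:
                passes.append(normality_gate(out["rmp"].to_numpy())[0] == "normal")
        assert np.mean(passes) >= 0.90

    def test_nonpositive_value_names_subject(self):
        table = pd.DataFrame({"id": ["a", "b"], "rmp": [1.0, -2.0]})
        with pytest.raises(ValidationError, match="b"):
            apply_log_policy(table, ["rmp"], force=True)


class TestMannWhitney:
    def test_agrees_with_enumeration_oracle(self, rng):
        # random tie-free samples across all small group-size combinations
        for n_x in range(2, 7):
            for n_y in range(2, 7):
                for _ in range(3):
                    pooled = rng.permutation(
                        np.arange(1.0, n_x + n_y + 1) + rng.normal(0, 0.01)
                    )
                    x, y = pooled[:n_x], pooled[n_x:]
                    _, p, method = mann_whitney_exact(x, y)
                    assert method == "exact"
                    assert p == pytest.approx(
                        exact_two_sided_p(x, y), abs=1e-12
                    ), (n_x, n_y)

    def test_fully_separated_5_vs_9(self):
        x = np.arange(1.0, 6.0)
        y = np.arange(6.0, 15.0)
        _, p, method = mann_whitney_exact(x, y)
        assert method == "exact"
        assert p == pytest.approx(2.0 / 2002.0, rel=1e-9)

    def test_small_interleaved_example(self):
        _, p, _ = mann_whitney_exact([1.0, 3.0], [2.0, 4.0])
        assert p == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_symmetry_under_sample_swap(self):
        x = [1.2, 5.3, 2.2]
        y = [0.7, 4.1, 9.0, 3.3]
        _, p_xy, _ = mann_whitney_exact(x, y)
        _, p_yx, _ = mann_whitney_exact(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-15)

    def test_ties_fall_back_to_asymptotic(self):
        _, _, method = mann_whitney_exact([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([], [1.0])


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, _ = pearson_corr(x, y)
        r2, _ = pearson_corr(5 * x + 3, 0.2 * y - 9)
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestSummarizeCohort:
    def test_mean_and_se_arithmetic(self):
        table = pd.DataFrame(
            {
                "group": ["control"] * 3 + ["HF"] * 3,
                "cvp": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        report = summarize_cohort(table, force_log=False, correlation_panel=())
        row = report.comparisons.iloc[0]
        assert row["mean_control"] == pytest.approx(2.0)
        assert row["se_control"] == pytest.approx(1.0 / np.sqrt(3))
        assert len(report.comparisons) == 1

    def test_report_matches_manual_recomputation(self):
        from renalsmi.simulate import CohortSpec, generate_cohort

        table, _ = generate_cohort(CohortSpec(seed=3))
        report = summarize_cohort(table)
        for _, row in report.comparisons.iterrows():
            raw = table.loc[table.group == "HF", row["variable"]].to_numpy()
            assert row["mean_hf"] == pytest.approx(raw.mean(), abs=1e-12)
            assert row["se_hf"] == pytest.approx(
                raw.std(ddof=1) / np.sqrt(len(raw)), abs=1e-12
            )

    def test_correlation_panel_uses_log_scale(self):
        from renalsmi.simulate import CohortSpec, generate_cohort

        table, _ = generate_cohort(CohortSpec(seed=4))
        report = summarize_cohort(table)
        row = report.correlations.query("y == 'rmp'").iloc[0]
        r_manual, _ = pearson_corr(
            table["irpi_interlobular"], np.log(table["rmp"])
        )
        assert row["r"] == pytest.approx(r_manual, abs=1e-12)
        assert row["y_log"]

    def test_type_one_error_controlled(self):
        # no planted difference: exact test rejects at most ~nominal rate
        rej = 0
        n_rep = 400
        g = np.random.default_rng(2024)
        for _ in range(n_rep):
            x = g.normal(size=5)
            y = g.normal(size=9)
            rej += mann_whitney_exact(x, y)[1] <= 0.05
        assert rej / n_rep <= 0.06
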