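"""Permutation regression, thresholds, demographics, lobar summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import design_matrix

from csfmarkers import (
    CohortSpec,
    bonferroni_thresholds,
    center_age,
    demographic_tests,
    generate_cohort,
    permutation_regression,
    run_marker_analysis,
    shapiro_screen,
    summarize_effects_by_lobe,
)
from csfmarkers.datasets import load_demographics_example, load_pvs_findings_example
from csfmarkers.stats import TERMS, _TERM_COLUMNS


class TestCenterAge:
    def test_arithmetic(self):
        t = pd.DataFrame({"age": [40.0, 50.0, 60.0]})
        out = center_age(t)
        assert out.age_centered.tolist() == [-10.0, 0.0, 10.0]

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"age": rng.uniform(30, 73, 50)})
        once = center_age(t)
        twice = center_age(once)
        assert abs(once.age_centered.mean()) < 1e-9
        assert np.allclose(once.age_centered, twice.age_centered, atol=1e-12)

    def test_missing_age_names_subject(self):
        t = pd.DataFrame({"age": [40.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            center_age(t)


class TestShapiroScreen:
    def test_heavy_tailed_flagged(self):
        flagged = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = pd.DataFrame({"y": rng.standard_cauchy(100)})
            if shapiro_screen(t, ["y"]).loc["y", "non_normal"]:
                flagged += 1
        assert flagged >= 0.95 * 200

    def test_gaussian_usually_not_flagged(self):
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = pd.DataFrame({"y": rng.normal(size=50)})
            ps.append(shapiro_screen(t, ["y"]).loc["y", "p"])
        assert np.median(ps) > 0.05

    def test_constant_column_degenerate(self):
        t = pd.DataFrame({"y": np.ones(10)})
        row = shapiro_screen(t, ["y"]).loc["y"]
        assert row["degenerate"]
        assert np.isnan(row["p"])


class TestBonferroniThresholds:
    def test_printed_lobe_thresholds(self):
        s = bonferroni_thresholds()
        assert s.display["frontal"] == 0.00227
        assert s.display["parietal"] == 0.00500
        assert s.display["temporal"] == 0.00313
        assert s.display["occipital"] == 0.00625
        assert s.display["lateral_ventricle"] == 0.025
        assert s.display["alps"] == 0.05

    def test_single_mask_no_correction(self):
        s = bonferroni_thresholds({"solo": 1})
        assert s.exact["solo"] == 0.05

    def test_strictly_decreasing_in_mask_count(self):
        s = bonferroni_thresholds({f"f{n}": n for n in range(1, 30)})
        vals = [s.exact[f"f{n}"] for n in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_exact_used_for_significance_not_display(self):
        s = bonferroni_thresholds({"temporal": 16})
        assert s.exact["temporal"] == pytest.approx(0.003125)
        assert s.display["temporal"] == 0.00313


class TestPermutationRegression:
    def test_exhaustive_matches_brute_force_oracle(self, tiny_design):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        y = rng.normal(size=6)
        x = design_matrix(tiny_design)
        results = permutation_regression(y, tiny_design, exhaustive=True)
        for r in results:
            j = _TERM_COLUMNS[r.term]
            xr = np.delete(x, j, axis=1)
            br = np.linalg.lstsq(xr, y, rcond=None)[0]
            mu, e = xr @ br, y - xr @ br
            t_obs = sm.OLS(y, x).fit().tvalues[j]
            count, total = 0, 0
            for perm in itertools.permutations(range(6)):
                t_star = sm.OLS(mu + e[list(perm)], x).fit().tvalues[j]
                total += 1
                count += abs(t_star) >= abs(t_obs) - 1e-12
            assert r.p_perm == pytest.approx(count / total, abs=1e-12)

    def test_observed_fit_matches_reference_ols(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        y = small_cohort.outcome.to_numpy()
        x = design_matrix(small_cohort)
        fit = sm.OLS(y, x).fit()
        for r in permutation_regression(y, small_cohort, n_permutations=10, seed=0):
            j = _TERM_COLUMNS[r.term]
            assert r.beta == pytest.approx(fit.params[j], rel=1e-10)
            assert r.se == pytest.approx(fit.bse[j], rel=1e-10)
            assert r.t == pytest.approx(fit.tvalues[j], rel=1e-10)

    def test_determinism_under_seed(self, small_cohort):
        a = permutation_regression(small_cohort.outcome, small_cohort, 199, seed=5)
        b = permutation_regression(small_cohort.outcome, small_cohort, 199, seed=5)
        assert [r.p_perm for r in a] == [r.p_perm for r in b]

    def test_zero_residual_fit_gives_minimum_p(self, small_cohort):
        x = design_matrix(small_cohort)
        y = x @ np.array([1.0, 0.5, 0.02, 0.01])  # exact full-model fit
        results = permutation_regression(y, small_cohort, n_permutations=99, seed=1)
        for r in results:
            assert r.p_perm == pytest.approx(1 / 100)

    def test_p_value_bounds(self, small_cohort):
        for r in permutation_regression(small_cohort.outcome, small_cohort, 199, seed=2):
            assert 1 / 200 <= r.p_perm <= 1.0

    def test_group_flip_flips_beta_sign(self, small_cohort):
        flipped = small_cohort.copy()
        flipped["group"] = 1 - flipped["group"]
        a = permutation_regression(small_cohort.outcome, small_cohort, 99, seed=3)
        b = permutation_regression(flipped.outcome, flipped, 99, seed=3)
        # reparametrization g -> 1-g negates the group and interaction betas
        for term in ("Group", "Group⋅Age"):
            ra = next(r for r in a if r.term == term)
            rb = next(r for r in b if r.term == term)
            assert rb.beta == pytest.approx(-ra.beta, rel=1e-9)
            assert abs(rb.t) == pytest.approx(abs(ra.t), rel=1e-9)

    def test_listwise_drop_of_missing_outcomes(self, small_cohort):
        y = small_cohort.outcome.copy().to_numpy()
        y[:5] = np.nan
        r = permutation_regression(y, small_cohort, 99, seed=0)[0]
        assert r.n == len(small_cohort) - 5

    def test_constant_outcome_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="constant"):
            permutation_regression(np.ones(len(small_cohort)), small_cohort, 99)


class TestDemographics:
    def test_printed_sex_table_chi_square(self):
        demo = load_demographics_example()
        table = pd.DataFrame(
            {
                "group": [1] * 49 + [0] * 61,
                "sex": ["M"] * 28 + ["F"] * 21 + ["M"] * 29 + ["F"] * 32,
            }
        )
        res = demographic_tests(table, categorical=["sex"])
        assert round(res.loc["sex", "statistic"], 2) == 1.00
        # manual expected-count oracle
        obs = demo["sex_table"].to_numpy(float)
        rowsum = obs.sum(1, keepdims=True)
        colsum = obs.sum(0, keepdims=True)
        exp = rowsum * colsum / obs.sum()
        assert res.loc["sex", "statistic"] == pytest.approx(
            ((obs - exp) ** 2 / exp).sum(), rel=1e-12
        )

    def test_identical_groups_zero_statistics(self):
        table = pd.DataFrame(
            {
                "group": [0] * 10 + [1] * 10,
                "age": list(range(10)) * 2,
                "sex": ["M", "F"] * 10,
            }
        )
        res = demographic_tests(table, continuous=["age"], categorical=["sex"])
        assert res.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["sex", "statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            demographic_tests(pd.DataFrame({"group": [0, 0], "age": [1.0, 2.0]}),
                              continuous=["age"])


def _cohort_with_outcomes(n_outcomes, seed=0, inject_interaction=None):
    """Null cohort plus independent noise outcomes named o000..;
    optionally one outcome with a real group x age interaction."""
    rng = np.random.default_rng(seed)
    base = generate_cohort(CohortSpec(seed=seed))
    table = center_age(base)
    cols = {}
    for i in range(n_outcomes):
        y = rng.normal(size=len(table))
        if inject_interaction is not None and i == inject_interaction[0]:
            y = y + inject_interaction[1] * table.group * table.age_centered
        cols[f"o{i:03d}"] = y
    names = list(cols)
    table = pd.concat([table, pd.DataFrame(cols, index=table.index)], axis=1)
    manifest = pd.DataFrame(
        {
            "outcome": names,
            "family": ["alps"] * n_outcomes,
        }
    )
    return table, manifest


class TestRunMarkerAnalysis:
    def test_row_count_173_models_519_terms(self):
        # one model per outcome, three terms per model
        table, manifest = _cohort_with_outcomes(173, seed=1)
        res = run_marker_analysis(table, manifest, n_permutations=29, seed=0)
        assert len(manifest) == 173
        assert len(res) == 519

    def test_injected_interaction_found_in_correct_outcome(self):
        table, manifest = _cohort_with_outcomes(
            12, seed=2, inject_interaction=(7, 0.08)
        )
        res = run_marker_analysis(table, manifest, n_permutations=499, seed=3)
        inter = res[res.term == "Group⋅Age"].set_index("outcome")
        assert inter.p_perm.idxmin() == "o007"

    def test_determinism(self):
        table, manifest = _cohort_with_outcomes(4, seed=4)
        a = run_marker_analysis(table, manifest, n_permutations=99, seed=7)
        b = run_marker_analysis(table, manifest, n_permutations=99, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unmapped_outcome_errors(self):
        table, manifest = _cohort_with_outcomes(3, seed=5)
        manifest.loc[manifest.index[-1], "outcome"] = "not_a_column"
        with pytest.raises(ValueError, match="not_a_column"):
            run_marker_analysis(table, manifest, n_permutations=29, seed=0)

    def test_significance_uses_family_threshold(self):
        table, manifest = _cohort_with_outcomes(2, seed=6)
        manifest["family"] = ["frontal", "alps"]
        res = run_marker_analysis(table, manifest, n_permutations=29, seed=0)
        assert set(res[res.family == "frontal"].threshold) == {0.05 / 22}
        assert set(res[res.family == "alps"].threshold) == {0.05}


class TestLobarSummary:
    def test_example_findings_reproduce_reported_percentages(self):
        table = load_pvs_findings_example()
        summary = summarize_effects_by_lobe(table, alpha=0.05)
        assert summary["Group"]["lobe_percent"] == {
            "frontal": 0.0, "parietal": 25.0, "temporal": 50.0, "occipital": 25.0,
        }
        assert summary["Group⋅Age"]["lobe_percent"] == {
            "frontal": 12.5, "parietal": 62.5, "temporal": 25.0, "occipital": 0.0,
        }
        assert summary["Age"]["lobe_percent"] == {
            "frontal": 55.6, "parietal": 22.2, "temporal": 18.5, "occipital": 3.7,
        }
        assert summary["Group⋅Age"]["hemisphere_counts"] == {"L": 8, "R": 0}

    def test_singleton_row_is_100_percent(self):
        table = pd.DataFrame(
            [{"term": "Group", "lobe": "temporal", "hemisphere": "L", "p_perm": 0.01}]
        )
        summary = summarize_effects_by_lobe(table)
        assert summary["Group"]["lobe_percent"]["temporal"] == 100.0
        assert summary["Age"]["n_significant"] == 0

    def test_all_terms_present(self):
        table = load_pvs_findings_example()
        assert set(summarize_effects_by_lobe(table)) == set(TERMS)
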