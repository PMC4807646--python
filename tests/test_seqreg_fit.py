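"""Least-squares core, model selection, within-box tests, interpretation."""

import numpy as np
import pandas as pd
import pytest

from seqreg.cohort_io import from_dataframe, log_transform
from seqreg.errors import CollinearityError, DomainError
from seqreg.graph_model import BlockOrdering, VariableSpec
from seqreg.seqreg_fit import (
    FitConfig,
    TermSpec,
    candidate_terms,
    fit_ols,
    fit_sequence,
    format_coefficient,
    interpret_coefficient,
    quadratic_turning_point,
    select_model,
    within_box_test,
)
from seqreg.synthetic_data import build_ordering, default_spec, simulate


def small_ordering(n_x=4):
    return BlockOrdering([
        [VariableSpec("y", 0)],
        [VariableSpec(f"x{i}", 1) for i in range(n_x)],
        [VariableSpec("age", 2, "context")],
    ])


def noise_table(rng, n, ordering):
    df = pd.DataFrame({v: np.exp(rng.standard_normal(n))
                       for v in ordering.names()})
    return from_dataframe(df, ordering)


class TestFitOls:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 8.0)
        m = fit_ols(x, pd.DataFrame({"x": x}))
        assert m["x"]["beta"] == pytest.approx(1.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        assert m.sigma == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_slope_and_intercept(self):
        # normal equations by hand: Sxy/Sxx = 10/10, intercept 3.2 - 3
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        x = np.arange(1.0, 6.0)
        m = fit_ols(y, pd.DataFrame({"x": x}))
        assert m["x"]["beta"] == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.2, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, k = 40, 4
            X = rng.standard_normal((n, k))
            y = X @ rng.standard_normal(k) + rng.standard_normal(n)
            m = fit_ols(y, pd.DataFrame(X, columns=[f"c{i}" for i in range(k)]))
            Xd = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            got = np.concatenate([[m.intercept], m.beta])
            assert np.allclose(got, beta, rtol=1e-10, atol=1e-12)

    def test_matches_statsmodels_inference(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n, k = 60, 3
        X = rng.standard_normal((n, k))
        y = X @ np.array([0.5, 0.0, -0.3]) + rng.standard_normal(n)
        m = fit_ols(y, pd.DataFrame(X, columns=list("abc")))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(m.beta, ref.params[1:], rtol=1e-10)
        assert np.allclose(m.p, ref.pvalues[1:], rtol=1e-8)
        ci = ref.conf_int(alpha=0.05)
        assert np.allclose(m.ci_low, ci[1:, 0], rtol=1e-8)
        assert np.allclose(m.ci_high, ci[1:, 1], rtol=1e-8)
        assert m.r_squared == pytest.approx(ref.rsquared, rel=1e-12)

    def test_collinearity_names_dependent_columns(self):
        x = np.arange(10.0)
        with pytest.raises(CollinearityError) as exc:
            fit_ols(x, pd.DataFrame({"a": x, "b": 2 * x}))
        assert "b" in str(exc.value)

    def test_elasticity_invariance_under_unit_rescaling(self):
        # multiplying an original-scale variable by any positive constant
        # shifts only its log intercept: slopes, p, R^2 are unchanged exactly
        rng = np.random.default_rng(9)
        n = 50
        x = np.exp(rng.standard_normal(n))
        z = np.exp(rng.standard_normal(n))
        y = 0.4 * np.log(x) - 0.2 * np.log(z) + 0.1 * rng.standard_normal(n)
        m1 = fit_ols(y, pd.DataFrame({"x": np.log(x), "z": np.log(z)}))
        m2 = fit_ols(y, pd.DataFrame({"x": np.log(1000.0 * x),
                                      "z": np.log(0.001 * z)}))
        assert np.allclose(m1.beta, m2.beta, atol=1e-10)
        assert np.allclose(m1.p, m2.p, atol=1e-10)
        assert m1.r_squared == pytest.approx(m2.r_squared, abs=1e-12)


class TestCandidateTerms:
    def test_bone_response_sees_habitus_biomarkers_age(self):
        o = build_ordering()
        labels = [t.label for t in candidate_terms("csa_dis", o)]
        assert labels == ["lean_mass", "fm_pct", "height", "leptin",
                          "adiponectin", "osteocalcin", "ucoc",
                          "phylloquinone", "age"]

    def test_biomarker_response_sees_only_age(self):
        o = build_ordering()
        assert [t.label for t in candidate_terms("leptin", o)] == ["age"]

    def test_habitus_response_sees_biomarkers_not_bone(self):
        o = build_ordering()
        labels = [t.label for t in candidate_terms("fm_pct", o)]
        assert "csa_dis" not in labels
        assert labels[:5] == ["leptin", "adiponectin", "osteocalcin", "ucoc",
                              "phylloquinone"]

    def test_context_variable_rejected(self):
        with pytest.raises(ValueError):
            candidate_terms("age", build_ordering())


class TestSelectModel:
    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(21)
        o = small_ordering()
        t = noise_table(rng, 500, o)
        logged = log_transform(t)
        logged.data["y"] = 0.8 * logged.data["x0"] + \
            0.1 * rng.standard_normal(500)
        cfg = FitConfig(screen_interactions=False, screen_quadratics=False)
        m = select_model(logged, "y", candidate_terms("y", o), cfg)
        assert "x0" in m.term_labels()
        assert m["x0"]["beta"] == pytest.approx(0.8, abs=0.05)
        for lab in m.term_labels():
            if lab != "x0":
                assert abs(m[lab]["beta"]) < 0.05

    def test_null_retention_rate_near_alpha(self):
        # pure-noise candidates: per-term retention from backward elimination
        # should sit near the nominal 5% level
        rng = np.random.default_rng(0)
        o = small_ordering()
        cfg = FitConfig(screen_interactions=False, screen_quadratics=False)
        cands = [TermSpec.main(f"x{i}") for i in range(4)]
        kept = total = 0
        for _ in range(1000):
            logged = log_transform(noise_table(rng, 100, o))
            m = select_model(logged, "y", cands, cfg)
            kept += len(m.terms)
            total += 4
        assert kept / total == pytest.approx(0.05, abs=0.015)

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(31)
        spec = default_spec(calibrate=False)
        t = log_transform(simulate(spec, 300, 8))
        cands = candidate_terms("csa_dis", spec.ordering)
        cfg = FitConfig()
        m1 = select_model(t, "csa_dis", cands, cfg)
        m2 = select_model(t, "csa_dis", cands[::-1], cfg)
        assert sorted(m1.term_labels()) == sorted(m2.term_labels())
        for lab in m1.term_labels():
            assert m1[lab]["beta"] == pytest.approx(m2[lab]["beta"], abs=1e-10)

    def test_no_candidates_gives_intercept_model(self):
        rng = np.random.default_rng(1)
        o = small_ordering()
        logged = log_transform(noise_table(rng, 30, o))
        m = select_model(logged, "y", [], FitConfig())
        assert m.terms == []
        assert m.n_used == 30

    def test_hierarchy_keeps_interaction_mains(self):
        # response built from a pure product of centred logs: once the
        # interaction enters, both mains stay even if weak
        rng = np.random.default_rng(41)
        o = small_ordering(3)
        t = noise_table(rng, 400, o)
        logged = log_transform(t)
        a = logged.data["x0"] - logged.data["x0"].mean()
        b = logged.data["x1"] - logged.data["x1"].mean()
        logged.data["y"] = 0.5 * (a * b) + 0.1 * rng.standard_normal(400)
        m = select_model(logged, "y", candidate_terms("y", o), FitConfig())
        assert "x0:x1" in m.term_labels()
        assert "x0" in m.term_labels() and "x1" in m.term_labels()


class TestWithinBoxTest:
    def test_same_variable_rejected(self):
        rng = np.random.default_rng(2)
        o = small_ordering()
        t = log_transform(noise_table(rng, 30, o))
        with pytest.raises(ValueError):
            within_box_test(t, "x0", "x0", set())

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        o = BlockOrdering([
            [VariableSpec("a", 0), VariableSpec("b", 0)],
            [VariableSpec("z", 1)],
        ])
        rejections = 0
        reps = 600
        for _ in range(reps):
            df = pd.DataFrame({
                "z": np.exp(rng.standard_normal(60)),
            })
            zlog = np.log(df["z"])
            df["a"] = np.exp(0.5 * zlog + 0.3 * rng.standard_normal(60))
            df["b"] = np.exp(-0.4 * zlog + 0.3 * rng.standard_normal(60))
            t = log_transform(from_dataframe(df, o))
            _, p = within_box_test(t, "a", "b", {"z"})
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)

    def test_correlated_errors_detected(self, calibrated_spec):
        # bone-box error correlation 0.5 between distal CSA and total vBMD
        t = log_transform(simulate(calibrated_spec, 70, 12))
        r, p = within_box_test(
            t, "csa_dis", "vbmd_dis",
            {"lean_mass", "height", "adiponectin", "ucoc", "phylloquinone"})
        assert p < 0.05
        assert r > 0


class TestFitSequence:
    def test_recovers_structural_arrows_at_large_n(self, calibrated_spec):
        t = simulate(calibrated_spec, 4000, 13)
        fit = fit_sequence(t, calibrated_spec.ordering)
        assert ("leptin", "fm_pct") in fit.graph.arrows
        assert ("osteocalcin", "lean_mass") in fit.graph.arrows
        assert ("lean_mass", "csa_dis") in fit.graph.arrows

    def test_noise_table_arrow_count_near_alpha_rate(self):
        rng = np.random.default_rng(4)
        o = small_ordering(4)
        cfg = FitConfig(screen_interactions=False, screen_quadratics=False)
        arrows = 0
        tests = 0
        for _ in range(120):
            fit = fit_sequence(noise_table(rng, 80, o), o, cfg)
            arrows += len(fit.graph.arrows)
            # y has 5 candidates; each x_i has 1 (age)
            tests += 5 + 4
        assert arrows / tests == pytest.approx(0.05, abs=0.02)

    def test_dropping_a_bone_response_leaves_other_models_unchanged(
            self, calibrated_spec):
        t = simulate(calibrated_spec, 1500, 14)
        full = fit_sequence(t, calibrated_spec.ordering)
        reduced_ordering = calibrated_spec.ordering.subset({"cort_vbmd"})
        reduced_t = from_dataframe(
            t.data.drop(columns="cort_vbmd"), reduced_ordering)
        reduced = fit_sequence(reduced_t, reduced_ordering)
        for resp, m in reduced.models.items():
            ref = full.models[resp]
            assert m.term_labels() == ref.term_labels()
            assert np.allclose(m.beta, ref.beta, atol=1e-12)

    def test_graph_mirrors_retained_terms_and_dashed_tests(self,
                                                           calibrated_spec):
        t = simulate(calibrated_spec, 300, 15)
        fit = fit_sequence(t, calibrated_spec.ordering)
        expected_arrows = {
            (v, resp)
            for resp, m in fit.models.items()
            for term in m.terms for v in term.variables
        }
        assert fit.graph.arrows == expected_arrows
        expected_dashed = {
            rec["pair"] for rec in fit.dashed_tests
            if rec["p"] < fit.config.alpha
        }
        assert fit.graph.dashed == expected_dashed


class TestInterpretation:
    def test_leptin_style_percent_reading(self):
        e = interpret_coefficient(-0.06, 10.0)
        assert e.linear == pytest.approx(-0.6)
        assert e.exact == pytest.approx(100 * (1.1 ** -0.06 - 1), rel=1e-12)

    def test_unit_elasticity_is_identity(self):
        assert interpret_coefficient(1.0, 7.3).linear == pytest.approx(7.3)

    def test_turning_point_of_published_quadratic(self):
        # diaphyseal-CSA osteocalcin profile: -1.1 x + 0.2 x^2
        tp = quadratic_turning_point(-1.1, 0.2)
        assert tp.log_location == pytest.approx(2.75)
        assert tp.kind == "minimum"
        # grid-search oracle on the original scale
        grid = np.linspace(5.0, 40.0, 200_001)
        f = -1.1 * np.log(grid) + 0.2 * np.log(grid) ** 2
        assert tp.original_scale == pytest.approx(grid[np.argmin(f)], rel=1e-4)

    def test_zero_curvature_rejected_and_sign_rule(self):
        with pytest.raises(DomainError):
            quadratic_turning_point(1.0, 0.0)
        assert quadratic_turning_point(0.0, 0.5).log_location == 0.0
        assert quadratic_turning_point(1.0, -0.5).kind == "maximum"

    def test_coefficient_formatting_two_sig_figs(self):
        assert format_coefficient(0.4612, 0.171, 0.757) == "0.46 (0.17, 0.76)"
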