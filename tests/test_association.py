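"""Circular encoding, Rubin pooling, ACAT, BH-FDR and the scan itself."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepatlas.association import (
    AssociationError,
    acat_combine,
    bh_fdr,
    build_design_matrix,
    encode_circular,
    rubin_pool,
    run_scan,
    _design_from_subjects,
)
from sleepatlas.association import test_circular as circular_assoc
from sleepatlas.association import test_linear as linear_assoc
from sleepatlas.preprocess import ImputationSet
from conftest import make_design


class TestEncodeCircular:
    def test_midnight_is_zero(self):
        enc = encode_circular(0.0)
        assert (enc.angle, enc.sin_term, enc.cos_term) == (0.0, 0.0, 1.0)

    def test_six_am_quarter_turn(self):
        enc = encode_circular(6.0)
        assert enc.angle == pytest.approx(math.pi / 2)
        assert enc.sin_term == pytest.approx(1.0)
        assert enc.cos_term == pytest.approx(0.0, abs=1e-12)

    def test_continuity_across_midnight(self):
        a = encode_circular(23 + 59 / 60)
        b = encode_circular(1 / 60)
        dist = math.hypot(a.sin_term - b.sin_term, a.cos_term - b.cos_term)
        assert dist < 0.01

    def test_out_of_range_errors(self):
        for bad in (-0.1, 24.0, 25.0):
            with pytest.raises(AssociationError):
                encode_circular(bad)

    def test_unit_circle_invariant(self):
        _, s, c = encode_circular(np.linspace(0, 23.99, 50))
        np.testing.assert_allclose(s**2 + c**2, 1.0, rtol=1e-12)


class TestRubinPool:
    def test_worked_arithmetic(self):
        est = rubin_pool([0.1, 0.2, 0.3], [0.04, 0.04, 0.04], complete_df=50)
        assert est.beta_bar == pytest.approx(0.2, abs=1e-12)
        assert est.W_bar == pytest.approx(0.04, abs=1e-12)
        assert est.B == pytest.approx(0.01, abs=1e-12)
        assert est.T == pytest.approx(0.04 + (4 / 3) * 0.01, abs=1e-12)

    def test_identical_imputations_no_between_variance(self):
        est = rubin_pool([0.3] * 5, [0.01] * 5, complete_df=30)
        assert est.B == 0.0
        assert est.T == pytest.approx(0.01)
        assert est.beta_bar == pytest.approx(0.3)
        assert est.df_adj == 30

    def test_m_one_passthrough(self):
        from scipy import stats

        est = rubin_pool([0.5], [0.04], complete_df=20)
        assert est.T == 0.04
        assert est.p == pytest.approx(2 * stats.t.sf(0.5 / 0.2, 20), rel=1e-12)

    def test_total_at_least_within(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b = rng.normal(size=4)
            v = rng.uniform(0.01, 1, size=4)
            est = rubin_pool(b, v, complete_df=25)
            assert est.T >= est.W_bar
            assert est.df_adj <= 25

    def test_length_mismatch_errors(self):
        with pytest.raises(AssociationError):
            rubin_pool([0.1, 0.2], [0.01], complete_df=10)


class TestACAT:
    def test_single_half_fixed_point(self):
        assert acat_combine([0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_identical_components_return_common_p(self):
        assert acat_combine([0.01] * 5) == pytest.approx(0.01, abs=1e-12)
        assert acat_combine([0.73] * 3) == pytest.approx(0.73, abs=1e-12)

    def test_matches_direct_formula(self):
        p = np.array([0.001, 0.9, 0.9, 0.9])
        T = np.mean(np.tan((0.5 - p) * np.pi))
        expected = 0.5 - math.atan(T) / math.pi
        assert acat_combine(p) == pytest.approx(expected, rel=1e-12)

    def test_single_component_identity(self):
        for p in (0.001, 0.2, 0.97):
            assert acat_combine([p]) == pytest.approx(p, rel=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-8, 1 - 1e-8), min_size=2, max_size=6),
        st.integers(0, 10_000),
    )
    def test_monotone_in_each_component(self, ps, salt):
        base = acat_combine(ps)
        i = salt % len(ps)
        smaller = list(ps)
        smaller[i] = ps[i] / 2
        assert acat_combine(smaller) <= base + 1e-12

    def test_tiny_p_uses_asymptote(self):
        out = acat_combine([1e-20, 0.5])
        assert 0 < out < 1e-15 * 10**6  # dominated by the tiny component
        assert np.isfinite(out)

    def test_invalid_p_errors(self):
        with pytest.raises(AssociationError):
            acat_combine([0.5, 1.5])
        with pytest.raises(AssociationError):
            acat_combine([])


def brute_force_bh(p):
    """Textbook step-up: sorted p * n/rank, right-to-left running minimum."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        adj_sorted[i] = running
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_fdr(p)
            np.testing.assert_array_equal(mine, brute_force_bh(p))
            np.testing.assert_allclose(
                mine, multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(AssociationError):
            bh_fdr([0.5, -0.1])


def _toy_imputation(y_list, subjects):
    datasets = []
    for y in y_list:
        d = pd.DataFrame({"subject_id": subjects["subject_id"], "batch": 1, "met": y})
        datasets.append(d)
    return ImputationSet(m=len(datasets), datasets=datasets,
                         method_tag={"met": "multiple_imputation"})


def _toy_subjects(n, seed=0, circular=False):
    rng = np.random.default_rng(seed)
    d = make_design(n, seed=seed)
    subjects = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "stratum": d.stratum, "psu": d.psu, "weight": d.weight,
        "age": rng.normal(45, 10, n), "sex": rng.binomial(1, 0.5, n),
        "bmi": rng.normal(28, 4, n),
    })
    if circular:
        subjects["tphen"] = rng.uniform(0, 24, n)
    else:
        subjects["xphen"] = rng.normal(size=n)
    return subjects


class TestPairTests:
    def test_linear_recovers_planted_slope(self):
        n = 1500
        subjects = _toy_subjects(n, seed=1)
        rng = np.random.default_rng(2)
        x = subjects["xphen"].to_numpy()
        ys = [0.5 * x + rng.normal(size=n) for _ in range(5)]
        imp = _toy_imputation(ys, subjects)
        design = _design_from_subjects(subjects)
        rec = linear_assoc("xphen", "met", imp, subjects, design, "Model1",
                          covariates=["age", "sex", "bmi"])
        pooled = rec["pooled"]
        assert abs(pooled.beta_bar - 0.5) < 3 * pooled.se

    def test_binary_phenotype_equals_group_difference_coding(self):
        n = 400
        subjects = _toy_subjects(n, seed=3)
        subjects["bphen"] = (subjects["xphen"] > 0).astype(int)
        rng = np.random.default_rng(4)
        y = 0.3 * subjects["bphen"].to_numpy() + rng.normal(size=n)
        imp = _toy_imputation([y], subjects)
        design = _design_from_subjects(subjects)
        rec01 = linear_assoc("bphen", "met", imp, subjects, design, "Model1",
                            covariates=["age"])
        # string-coded two-level factor gives the same contrast
        subjects2 = subjects.copy()
        subjects2["bphen"] = subjects2["bphen"].map({0: "no", 1: "yes"})
        from sleepatlas.design_glm import fit_weighted_lm

        X, names = build_design_matrix(subjects2, ["bphen", "age"])
        fit = fit_weighted_lm(y, X, design, names=names)
        assert rec01["effect"] == pytest.approx(fit.beta[names.index("bphen[yes]")], rel=1e-10)

    def test_constant_phenotype_errors(self):
        subjects = _toy_subjects(50, seed=5)
        subjects["xphen"] = 1.0
        imp = _toy_imputation([np.random.default_rng(0).normal(size=50)], subjects)
        with pytest.raises(AssociationError, match="constant"):
            linear_assoc("xphen", "met", imp, subjects,
                        _design_from_subjects(subjects), "Model1", covariates=["age"])

    def test_circular_m1_equals_single_wald_p(self):
        n = 600
        subjects = _toy_subjects(n, seed=6, circular=True)
        rng = np.random.default_rng(7)
        ang = 2 * np.pi * subjects["tphen"] / 24
        y = 0.3 * np.cos(ang - 1.0) + rng.normal(size=n)
        imp = _toy_imputation([y], subjects)
        design = _design_from_subjects(subjects)
        rec = circular_assoc("tphen", "met", imp, subjects, design, "Model1",
                            covariates=["age", "sex"])
        from sleepatlas.design_glm import fit_weighted_lm, wald_test

        X, names = build_design_matrix(subjects, ["age", "sex"])
        Xc = np.column_stack([X[:, :1], np.sin(ang), np.cos(ang), X[:, 1:]])
        fit = fit_weighted_lm(y, Xc, design)
        expected = wald_test(fit, [1, 2]).p
        assert rec["p_raw"] == pytest.approx(expected, rel=1e-10)
        assert rec["test_df"] == 2

    def test_circular_origin_shift_invariance(self):
        """Rotating all clock-times leaves the 2-df Wald p unchanged (the
        sin/cos span is rotation-invariant)."""
        n = 500
        subjects = _toy_subjects(n, seed=8, circular=True)
        rng = np.random.default_rng(9)
        y = rng.normal(size=n) + 0.2 * np.sin(2 * np.pi * subjects["tphen"] / 24)
        imp = _toy_imputation([y], subjects)
        design = _design_from_subjects(subjects)
        p0 = circular_assoc("tphen", "met", imp, subjects, design, "Model1",
                           covariates=["age"])["p_raw"]
        shifted = subjects.copy()
        shifted["tphen"] = (shifted["tphen"] + 5.75) % 24
        p1 = circular_assoc("tphen", "met", imp, shifted, design, "Model1",
                           covariates=["age"])["p_raw"]
        assert p1 == pytest.approx(p0, abs=1e-8)


class TestRunScan:
    def test_cartesian_completeness(self, small_cohort, small_scan):
        res = small_scan
        n_phen = len(small_cohort["phenotypes"])
        n_met = small_cohort["annotation"].shape[0]
        assert len(res) == n_phen * n_met * 2
        assert set(res["model"]) == {"Model1", "Model2"}
        assert (res["p_fdr"] >= res["p_raw"] - 1e-15).all()
        assert not res.loc[res["model"] == "Model2", "significant"].any()

    def test_planted_effects_detected(self, small_scan):
        res = small_scan.set_index(["phenotype", "metabolite", "model"])
        assert res.loc[("hr_mean_sleep", "met005", "Model1"), "significant"]

    def test_subgroup_filter(self, small_cohort, small_imputation):
        imp, _ = small_imputation
        res = run_scan(
            small_cohort["subjects"], imp, small_cohort["phenotypes"][:3],
            small_cohort["annotation"], models=("Model1",), subgroup=("sex", 1),
        )
        n_met = small_cohort["annotation"].shape[0]
        assert len(res) == 3 * n_met

    def test_missing_covariate_errors(self, small_cohort, small_imputation):
        imp, _ = small_imputation
        subjects = small_cohort["subjects"].drop(columns=["bmi"])
        with pytest.raises(AssociationError, match="bmi"):
            run_scan(subjects, imp, small_cohort["phenotypes"],
                     small_cohort["annotation"])

    def test_deterministic_given_imputation_set(self, small_cohort, small_imputation):
        imp, _ = small_imputation
        kwargs = dict(models=("Model1",))
        a = run_scan(small_cohort["subjects"], imp, small_cohort["phenotypes"][:2],
                     small_cohort["annotation"], **kwargs)
        b = run_scan(small_cohort["subjects"], imp, small_cohort["phenotypes"][:2],
                     small_cohort["annotation"], **kwargs)
        pd.testing.assert_frame_equal(a, b)
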