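import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special

from rohped.inference import (
    SplineBasis,
    adjust_boundaries,
    build_inbreeding_table,
    depth_bias_analysis,
    fit_beta,
    paired_comparison,
    prepost_models,
    temporal_models,
)

from oracles import kendall_tau_b, welch_t_hand, wilcoxon_enum


class TestPairedComparison:
    def test_v_zero_when_genomic_always_higher(self, rng):
        fped = rng.uniform(0, 0.05, 30)
        froh = fped + rng.uniform(0.01, 0.2, 30)
        res = paired_comparison(fped, froh)
        assert res.wilcoxon_v == 0.0
        assert res.wilcoxon_p < 0.001

    def test_tau_one_for_identical_rankings(self):
        x = np.array([0.01, 0.02, 0.05, 0.07, 0.1])
        res = paired_comparison(x, x * 2)
        assert res.kendall_tau == pytest.approx(1.0)

    def test_six_pair_fixture_matches_enumeration(self):
        fped = np.array([0.0, 0.0, 0.125, 0.25, 0.0625, 0.02])
        froh = np.array([0.05, 0.11, 0.09, 0.31, 0.0625, 0.01])
        res = paired_comparison(fped, froh)
        v, p = wilcoxon_enum(fped - froh)
        assert res.wilcoxon_v == pytest.approx(v)
        assert res.wilcoxon_p == pytest.approx(p, abs=1e-9)
        assert res.kendall_tau == pytest.approx(kendall_tau_b(fped, froh), abs=1e-12)

    def test_random_small_n_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 9))
            a = np.round(rng.uniform(0, 0.3, n), 2)
            b = np.round(rng.uniform(0, 0.3, n), 2)
            if np.all(a - b == 0):
                continue
            res = paired_comparison(a, b)
            v, p = wilcoxon_enum(a - b)
            assert res.wilcoxon_v == pytest.approx(v)
            assert res.wilcoxon_p == pytest.approx(p, abs=1e-9)
            assert res.kendall_tau == pytest.approx(kendall_tau_b(a, b), abs=1e-12)

    def test_all_zero_differences_reported(self):
        x = np.array([0.1, 0.2, 0.3])
        res = paired_comparison(x, x)
        assert res.all_zero and np.isnan(res.wilcoxon_v)


class TestBoundaryAdjustment:
    def test_zeros_replaced(self):
        np.testing.assert_allclose(
            adjust_boundaries([0.0, 0.1]), [0.0005, 0.1]
        )

    def test_identity_without_zeros(self):
        y = np.array([0.01, 0.5])
        np.testing.assert_array_equal(adjust_boundaries(y), y)

    def test_replacement_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            adjust_boundaries([0.0], replacement=0.002)
        with pytest.raises(ValueError):
            adjust_boundaries([1.0])


class TestSplineBasis:
    def test_shape_rank_and_knots(self, rng):
        x = rng.uniform(1979, 2022, 200)
        basis = SplineBasis.from_data(x, df=3)
        np.testing.assert_allclose(
            basis.knots[1:-1], np.quantile(x, [1 / 3, 2 / 3])
        )
        B = basis.transform(x)
        assert B.shape == (200, 3)
        assert np.linalg.matrix_rank(np.column_stack([np.ones(200), B])) == 4

    def test_linear_beyond_boundary_knots(self, rng):
        x = rng.uniform(0, 10, 100)
        basis = SplineBasis.from_data(x, df=3)
        g = np.linspace(11, 30, 50)  # beyond the upper boundary knot
        B = basis.transform(g)
        for j in range(B.shape[1]):
            d2 = np.diff(B[:, j], 2)
            np.testing.assert_allclose(d2, 0, atol=1e-6)

    def test_matches_r_ns_fitted_values(self, tmp_path, rng):
        """OLS fits on this basis and on R's splines::ns span the same
        function space, so fitted values agree."""
        x = np.sort(rng.uniform(0, 1, 80))
        y = np.sin(3 * x) + rng.normal(0, 0.1, 80)
        basis = SplineBasis.from_data(x, df=3)
        X = np.column_stack([np.ones(80), basis.transform(x)])
        ours = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        df = pd.DataFrame({"x": x, "y": y})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "ns.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "f <- fitted(lm(y ~ splines::ns(x, df = 3), data = d))\n"
            'cat(jsonlite::toJSON(as.numeric(f), digits = 12))\n' % (tmp_path / "d.csv")
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        theirs = np.array(json.loads(out.stdout))
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestBetaRegression:
    def test_intercept_only_recovery(self, rng):
        y = rng.beta(0.3 * 20, 0.7 * 20, 500)
        fit = fit_beta(y, np.ones((500, 1)))
        assert special.expit(fit.params[0]) == pytest.approx(0.3, abs=0.03)
        assert fit.phi == pytest.approx(20, rel=0.3)

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.beta(2, 5, 50)
        X = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="rank"):
            fit_beta(y, X)

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError, match="adjust_boundaries"):
            fit_beta(np.array([0.0, 0.5]), np.ones((2, 1)))

    def test_mixed_reduces_to_fixed_when_no_group_variance(self, rng):
        n = 300
        x = rng.normal(size=n)
        mu = special.expit(-1 + 0.5 * x)
        y = rng.beta(mu * 30, (1 - mu) * 30)
        X = np.column_stack([np.ones(n), x])
        groups = rng.integers(0, 15, n)
        fixed = fit_beta(y, X)
        mixed = fit_beta(y, X, random_intercept_group=groups)
        assert mixed.sigma_re == pytest.approx(0.0, abs=0.05)
        np.testing.assert_allclose(mixed.params, fixed.params, atol=0.05)

    def test_mixed_recovers_group_variance(self, rng):
        n_groups, per = 30, 25
        u = rng.normal(0, 0.5, n_groups)
        groups = np.repeat(np.arange(n_groups), per)
        mu = special.expit(-1.2 + u[groups])
        y = rng.beta(mu * 40, (1 - mu) * 40)
        fit = fit_beta(y, np.ones((len(y), 1)), random_intercept_group=groups)
        assert fit.sigma_re == pytest.approx(0.5, abs=0.2)
        assert fit.params[0] == pytest.approx(-1.2, abs=0.2)

    def test_mixed_matches_glmmtmb(self, tmp_path, rng):
        """Laplace ML agrees with glmmTMB on a grouped beta regression."""
        n_groups, per = 12, 20
        u = rng.normal(0, 0.4, n_groups)
        groups = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=len(groups))
        mu = special.expit(-1.0 + 0.6 * x + u[groups])
        y = rng.beta(mu * 25, (1 - mu) * 25)
        X = np.column_stack([np.ones(len(y)), x])
        ours = fit_beta(y, X, random_intercept_group=groups)
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "tmb.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "suppressMessages(library(glmmTMB))\n"
            "m <- glmmTMB(y ~ x + (1 | g), family = beta_family(), data = d)\n"
            "out <- list(beta = as.numeric(fixef(m)$cond),\n"
            "            sigma = sqrt(as.numeric(VarCorr(m)$cond$g[1])))\n"
            "cat(jsonlite::toJSON(out, digits = 10))\n" % (tmp_path / "d.csv")
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        np.testing.assert_allclose(ours.params, ref["beta"], atol=0.03)
        assert ours.sigma_re == pytest.approx(ref["sigma"][0], abs=0.05)


def make_table(rng, n=300, pre_mu=0.145, post_mu=0.110, phi=12, sigma_year=0.15,
               years=(1985, 2020), era_cut=2002):
    year = rng.integers(years[0], years[1] + 1, n)
    era = np.where(year <= era_cut, "pre", "post")
    uy = {y: rng.normal(0, sigma_year) for y in np.unique(year)}
    eta = special.logit(np.where(era == "pre", pre_mu, post_mu))
    eta = eta + np.array([uy[y] for y in year])
    mu = special.expit(eta)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return pd.DataFrame({"year": year, "era": era, "froh_total": y})


class TestPrePost:
    def test_era_assignment_rules(self):
        ptab = pd.DataFrame(
            {
                "id": ["a", "b", "t"],
                "sire": ["", "", ""],
                "dam": ["", "", ""],
                "birth_year": [2000, 2005, 1999],
                "sex": ["female"] * 3,
                "translocated": [False, False, True],
                "intro_year": [None, None, 2003],
                "fped": [0.0, 0.1, 0.0],
                "cge": [2.0, 3.0, 0.0],
                "known_grandparents": [4, 4, 0],
                "retained": [True, True, True],
                "reason": ["x", "x", "translocated"],
            }
        )
        t = build_inbreeding_table(ptab).set_index("individual")
        assert t.loc["a", "era"] == "pre"
        assert t.loc["b", "era"] == "post"
        # translocated born 1999 -> post group, year = introduction year
        assert t.loc["t", "era"] == "post"
        assert t.loc["t", "year"] == 2003

    def test_percent_change_recovery(self, rng):
        """Simulated 24% drop in F_ROH (0.145 -> 0.110) is recovered."""
        table = make_table(rng, n=400)
        res = prepost_models(table, responses=("froh_total",))["froh_total"]
        assert res.percent_change == pytest.approx(-24.1, abs=6)
        assert res.fit.params[1] < 0
        # percent change consistent with back-transformed coefficients
        m_pre = special.expit(res.fit.params[0])
        m_post = special.expit(res.fit.params[0] + res.fit.params[1])
        assert res.percent_change == pytest.approx(100 * (m_post - m_pre) / m_pre)

    def test_null_has_small_change(self, rng):
        table = make_table(rng, n=400, pre_mu=0.12, post_mu=0.12)
        res = prepost_models(table, responses=("froh_total",))["froh_total"]
        assert abs(res.percent_change) < 20

    def test_single_era_rejected(self, rng):
        table = make_table(rng, n=50, years=(2005, 2020))
        with pytest.raises(ValueError, match="era"):
            prepost_models(table, responses=("froh_total",))


class TestTemporal:
    def test_constant_response_flat_curve(self, rng):
        n = 200
        table = pd.DataFrame(
            {
                "year": rng.integers(1980, 2020, n),
                "froh_total": rng.beta(0.1 * 300, 0.9 * 300, n),
            }
        )
        out = temporal_models(table, responses=("froh_total",))
        curve = out["froh_total"]["curve"]
        assert curve["mean"].max() - curve["mean"].min() < 0.03

    def test_monotone_decline_tracked(self, rng):
        n = 400
        year = rng.integers(1980, 2020, n)
        mu = special.expit(-1 - 0.05 * (year - 1980))
        table = pd.DataFrame(
            {"year": year, "froh_total": rng.beta(mu * 60, (1 - mu) * 60)}
        )
        out = temporal_models(table, responses=("froh_total",))
        curve = out["froh_total"]["curve"]["mean"].to_numpy()
        assert (np.diff(curve) < 1e-4).all()
        assert curve[0] > curve[-1]

    def test_too_few_years_rejected(self, rng):
        table = pd.DataFrame({"year": [2000] * 30, "froh_total": rng.beta(2, 5, 30)})
        with pytest.raises(ValueError):
            temporal_models(table, responses=("froh_total",))


class TestDepthBias:
    def test_welch_hand_fixture(self):
        a = np.array([1.8, 2.1, 2.5, 2.2])
        b = np.array([3.0, 3.4, 2.9, 3.3])
        table = pd.DataFrame(
            {
                "era": ["pre"] * 4 + ["post"] * 4,
                "cge": np.concatenate([a, b]),
                "fped": [0.01, 0.02, 0.05, 0.0, 0.06, 0.1, 0.04, 0.08],
                "year": [1995, 1996, 1997, 1998, 2005, 2006, 2007, 2008],
            }
        )
        res = depth_bias_analysis(table)
        t_hand, df_hand = welch_t_hand(a, b)
        assert res.welch_t == pytest.approx(t_hand)
        assert res.welch_df == pytest.approx(df_hand)
        assert res.mean_cge_pre == pytest.approx(a.mean())

    def test_equal_variance_agreement_with_student(self, rng):
        from scipy import stats

        a = rng.normal(2.5, 0.4, 200)
        b = rng.normal(2.5, 0.4, 200)
        welch = stats.ttest_ind(a, b, equal_var=False)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(student.statistic, abs=1e-6)
        assert welch.pvalue == pytest.approx(student.pvalue, abs=1e-4)

    def test_low_cge_excluded_from_regression(self, rng):
        n = 120
        cge = rng.uniform(0, 4, n)
        table = pd.DataFrame(
            {
                "era": np.where(rng.random(n) < 0.5, "pre", "post"),
                "cge": cge,
                "fped": rng.beta(2, 30, n),
                "year": rng.integers(1990, 2020, n),
            }
        )
        res = depth_bias_analysis(table)
        assert res.n_regression == int((cge > 1).sum())
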