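"""Count-regression engine: closed forms, AIC identity, GLR, Kruskal-Wallis."""

import math

import numpy as np
import pandas as pd
import pytest

from mitosub import PredictorSpec, fit_count_glm, glr_test, kruskal_wallis
from mitosub.glm import build_design


def _frame(counts, **cols):
    return pd.DataFrame({"count": counts, **cols})


class TestFitCountGlm:
    def test_intercept_only_poisson_closed_form(self):
        df = _frame([2, 2, 2])
        fit = fit_count_glm(df, "count", PredictorSpec(), family="poisson")
        assert math.exp(fit.coefficients["Intercept"]) == pytest.approx(2.0, rel=1e-8)
        expected_llf = sum(-2 + 2 * math.log(2) - math.log(math.factorial(2)) for _ in range(3))
        assert fit.log_likelihood == pytest.approx(expected_llf, rel=1e-8)

    def test_rate_with_offset_is_counts_over_exposure(self):
        rng = np.random.default_rng(0)
        exposure = rng.uniform(0.5, 4.0, 40)
        counts = rng.poisson(1.7 * exposure)
        df = _frame(counts)
        fit = fit_count_glm(
            df, "count", PredictorSpec(), offset=np.log(exposure), family="poisson"
        )
        assert math.exp(fit.coefficients["Intercept"]) == pytest.approx(
            counts.sum() / exposure.sum(), rel=1e-8
        )

    def test_aic_identity(self):
        rng = np.random.default_rng(1)
        df = _frame(rng.poisson(2, 50), g=rng.choice(list("ab"), 50))
        for family in ("poisson", "negbin"):
            fit = fit_count_glm(
                df, "count", PredictorSpec(categorical=["g"]), family=family
            )
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.log_likelihood
            )
            expected_k = 2 + (1 if family == "negbin" else 0)
            assert fit.n_params == expected_k

    def test_negbin_on_equidispersed_matches_poisson(self):
        rng = np.random.default_rng(2)
        df = _frame(rng.poisson(3, 400))
        po = fit_count_glm(df, "count", PredictorSpec(), family="poisson")
        nb = fit_count_glm(df, "count", PredictorSpec(), family="negbin")
        assert nb.converged
        assert nb.log_likelihood == pytest.approx(po.log_likelihood, abs=1e-3)

    def test_negbin_recovers_dispersion(self):
        rng = np.random.default_rng(3)
        mu, alpha = 2.0, 0.8
        lam = rng.gamma(1 / alpha, alpha * mu, 3000)
        df = _frame(rng.poisson(lam))
        nb = fit_count_glm(df, "count", PredictorSpec(), family="negbin")
        assert nb.alpha == pytest.approx(alpha, rel=0.25)

    def test_collinear_column_dropped_and_recorded(self):
        rng = np.random.default_rng(4)
        g = rng.choice(list("ab"), 60)
        df = _frame(rng.poisson(2, 60), g=g, h=g)  # h duplicates g
        fit = fit_count_glm(
            df, "count", PredictorSpec(categorical=["g", "h"]), family="poisson"
        )
        assert fit.converged
        assert fit.dropped_columns == ["h[b]"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_count_glm(_frame([]), "count", PredictorSpec())


class TestBuildDesign:
    def test_dummy_coding_reference_and_order(self):
        df = pd.DataFrame(
            {"g": ["b", "a", "c", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0, 2.5]}
        )
        X, dropped = build_design(df, PredictorSpec(categorical=["g"], numeric=["x"]))
        assert list(X.columns) == ["Intercept", "g[b]", "g[c]", "x"]
        assert dropped == []
        assert X["g[b]"].tolist() == [1.0, 0.0, 0.0, 0.0, 1.0]


class TestGlrTest:
    def test_identical_fits_give_p_one(self):
        df = _frame([1, 2, 3, 4])
        fit = fit_count_glm(df, "count", PredictorSpec(), family="poisson")
        assert glr_test(fit, fit) == 1.0

    def test_chi_square_tail_oracle(self):
        from mitosub.glm import FitResult

        null = FitResult("poisson", pd.Series(dtype=float), -10.0, 1, 22.0, True, 5)
        alt = FitResult(
            "poisson", pd.Series(dtype=float), -10.0 + 6.635 / 2, 2, 0.0, True, 5
        )
        assert glr_test(null, alt) == pytest.approx(0.01, rel=5e-3)

    def test_non_nested_negative_statistic_rejected(self):
        from mitosub.glm import FitResult

        null = FitResult("poisson", pd.Series(dtype=float), -5.0, 1, 0.0, True, 5)
        alt = FitResult("poisson", pd.Series(dtype=float), -9.0, 2, 0.0, True, 5)
        with pytest.raises(ValueError, match="not nested"):
            glr_test(null, alt)

    def test_detects_real_group_difference(self):
        rng = np.random.default_rng(6)
        g = np.repeat(["a", "b"], 150)
        counts = rng.poisson(np.where(g == "a", 1.0, 3.0))
        df = _frame(counts, g=g)
        null = fit_count_glm(df, "count", PredictorSpec(), family="poisson")
        alt = fit_count_glm(df, "count", PredictorSpec(categorical=["g"]), family="poisson")
        assert glr_test(null, alt) < 1e-6


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        assert kruskal_wallis([[1, 2, 3], [1, 2, 3]]) == 1.0

    def test_all_values_identical_degenerate(self):
        assert kruskal_wallis([[2, 2, 2], [2, 2]]) == 1.0

    def test_hand_rank_oracle(self):
        # groups {1,2,3} and {4,5,6}: ranks 1..6, no ties;
        # H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2 = 12/42 * (2*(1.5)^2*3)...
        # computed by hand: rank sums 6 and 15, H = 12/(6*7)*(6^2/3+15^2/3)-3*7
        H = 12 / 42 * (36 / 3 + 225 / 3) - 21
        from scipy import stats

        expected = float(stats.chi2.sf(H, 1))
        assert kruskal_wallis([[1, 2, 3], [4, 5, 6]]) == pytest.approx(expected)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = [
            kruskal_wallis([rng.poisson(2, 80), rng.poisson(2, 80)])
            for _ in range(300)
        ]
        from scipy import stats

        # discrete counts make p slightly conservative; a loose KS check
        assert stats.kstest(ps, "uniform").statistic < 0.2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
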