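"""Climate-cline association tests: Pearson and OLS against from-scratch
sum-formula / normal-equations oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepcline.core import ALL_COVARIATES, MISSING, ClimateTable
from sweepcline.climate import (
    ClineAssociation,
    correlate_climate,
    derived_allele_frequency,
    fit_multiple_regression,
)

from conftest import make_matrix


def climate_from(values: dict[str, np.ndarray], pops: list[str]) -> ClimateTable:
    frame = pd.DataFrame({c: values.get(c, np.zeros(len(pops))) for c in ALL_COVARIATES},
                         index=pd.Index(pops, name="population"))
    # keep unrelated covariates non-degenerate
    rng = np.random.default_rng(99)
    for c in ALL_COVARIATES:
        if c not in values:
            frame[c] = rng.normal(size=len(pops))
    return ClimateTable(frame)


def pearson_oracle(x, y):
    """Plain sum-formula Pearson r and its two-sided t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x ** 2).sum() - sx ** 2) * np.sqrt(n * (y ** 2).sum() - sy ** 2)
    r = num / den
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestDaf:
    def test_all_derived(self):
        m = make_matrix([[1, 0], [1, 0], [1, 1]])
        assert derived_allele_frequency(m, "rs0", "pop1") == (1.0, 3)

    def test_fractional(self):
        alleles = np.zeros((10, 1), dtype=np.int8)
        alleles[:3, 0] = 1
        m = make_matrix(alleles)
        daf, n = derived_allele_frequency(m, "rs0", "pop1")
        assert daf == pytest.approx(0.3) and n == 10

    def test_missing_excluded_from_denominator(self):
        alleles = np.zeros((10, 1), dtype=np.int8)
        alleles[:3, 0] = 1
        alleles[9, 0] = MISSING
        m = make_matrix(alleles)
        daf, n = derived_allele_frequency(m, "rs0", "pop1")
        assert daf == pytest.approx(1 / 3) and n == 9

    def test_all_missing_is_an_error(self):
        m = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="pop1"):
            derived_allele_frequency(m, "rs0", "pop1")


class TestCorrelation:
    def test_perfect_linear_and_negative_affine(self):
        pops = [f"p{i}" for i in range(8)]
        x = np.arange(8, dtype=float)
        clim = climate_from({"precipitation": x}, pops)
        daf = dict(zip(pops, 0.1 + 0.05 * x))
        assert correlate_climate(daf, clim, "precipitation").r == pytest.approx(1.0)
        daf_neg = dict(zip(pops, 0.9 - 0.05 * x))
        assert correlate_climate(daf_neg, clim, "precipitation").r == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        pops = [f"p{i}" for i in range(5)]
        x = np.array([1.0, 2.5, 3.1, 4.9, 6.2])
        y = np.array([0.2, 0.33, 0.28, 0.5, 0.61])
        res = correlate_climate(dict(zip(pops, y)),
                                climate_from({"uv": x}, pops), "uv")
        r_exp, p_exp = pearson_oracle(x, y)
        assert res.r == pytest.approx(r_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)
        assert res.p_adjusted == pytest.approx(min(1.0, p_exp * 4))

    def test_affine_invariance_with_sign_flip(self):
        rng = np.random.default_rng(17)
        pops = [f"p{i}" for i in range(12)]
        x = rng.normal(size=12)
        y = rng.uniform(0.1, 0.9, 12)
        base = correlate_climate(dict(zip(pops, y)),
                                 climate_from({"temperature": x}, pops), "temperature")
        scaled = correlate_climate(dict(zip(pops, y)),
                                   climate_from({"temperature": -3.0 * x + 7}, pops),
                                   "temperature")
        assert scaled.r == pytest.approx(-base.r, abs=1e-12)
        assert scaled.p == pytest.approx(base.p, abs=1e-12)

    def test_zero_variance_flagged(self):
        pops = [f"p{i}" for i in range(5)]
        clim = climate_from({"sunshine": np.full(5, 3.3)}, pops)
        res = correlate_climate(dict(zip(pops, [0.1, 0.2, 0.3, 0.4, 0.5])),
                                clim, "sunshine")
        assert "zero_variance" in res.flags and np.isnan(res.r)

    def test_too_few_shared_populations(self):
        clim = climate_from({}, ["a", "b", "c"])
        with pytest.raises(ValueError):
            correlate_climate({"a": 0.5, "b": 0.6}, clim, "uv")


class TestRegression:
    def test_noiseless_recovery(self):
        pops = [f"p{i}" for i in range(30)]
        rng = np.random.default_rng(23)
        precip = rng.normal(size=30)
        clim = climate_from({"precipitation": precip}, pops)
        y = 2.0 * precip + 1.0
        res = fit_multiple_regression(dict(zip(pops, y)), clim,
                                      covariates=("precipitation",))
        assert res.coef("precipitation") == pytest.approx(2.0)
        assert res.coef("intercept") == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_response_gives_null_fit(self):
        rng = np.random.default_rng(29)
        pops = [f"p{i}" for i in range(40)]
        clim = climate_from({}, pops)
        x = np.column_stack([np.ones(40)] + [clim.covariate(c).to_numpy()
                                             for c in ALL_COVARIATES])
        y = rng.normal(size=40)
        # project out the design: the residual is exactly orthogonal
        y_orth = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        res = fit_multiple_regression(dict(zip(pops, y_orth)), clim)
        np.testing.assert_allclose(res.coefficients, 0, atol=1e-10)
        assert res.r_squared == pytest.approx(0.0, abs=1e-10)
        assert np.all(res.p_values[1:] > 0.999)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(31)
        pops = [f"p{i}" for i in range(30)]
        clim = climate_from({}, pops)
        covs = ("sunshine", "temperature", "uv", "precipitation")
        y = rng.normal(size=30)
        res = fit_multiple_regression(dict(zip(pops, y)), clim, covariates=covs)
        x = np.column_stack([np.ones(30)] + [clim.covariate(c).to_numpy() for c in covs])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-8)

    def test_single_covariate_p_equals_correlation_p(self):
        rng = np.random.default_rng(37)
        pops = [f"p{i}" for i in range(25)]
        x = rng.normal(size=25)
        clim = climate_from({"temperature": x}, pops)
        y = 0.3 * x + rng.normal(scale=0.5, size=25)
        daf = dict(zip(pops, y))
        corr = correlate_climate(daf, clim, "temperature")
        reg = fit_multiple_regression(daf, clim, covariates=("temperature",))
        assert reg.p_values[1] == pytest.approx(corr.p, abs=1e-10)

    def test_too_few_populations_rejected(self):
        clim = climate_from({}, [f"p{i}" for i in range(6)])
        with pytest.raises(ValueError):
            fit_multiple_regression({f"p{i}": 0.5 for i in range(6)}, clim)


class TestClineAssociationModel:
    def test_fit_reports_all_climate_covariates_and_best(self):
        rng = np.random.default_rng(41)
        pops = [f"p{i}" for i in range(20)]
        precip = rng.normal(size=20)
        clim = climate_from({"precipitation": precip}, pops)
        daf = dict(zip(pops, np.clip(0.5 + 0.12 * precip + rng.normal(0, 0.02, 20),
                                     0.01, 0.99)))
        res = ClineAssociation(daf, clim).fit()
        assert list(res.frame["covariate"]) == ["sunshine", "temperature", "uv",
                                                "precipitation"]
        assert res.best_covariate().covariate == "precipitation"
        assert res.regression is not None
        assert "precipitation" in res.summary()

    def test_population_intersection_used(self):
        pops = [f"p{i}" for i in range(10)]
        clim = climate_from({}, pops)
        daf = {p: 0.1 + 0.05 * i for i, p in enumerate(pops)}
        daf["extra_pop"] = 0.5  # not in the climate table
        res = correlate_climate(daf, clim, "uv")
        assert res.n == 10

    def test_cline_scatter_plot_written(self, tmp_path):
        rng = np.random.default_rng(43)
        pops = [f"p{i}" for i in range(12)]
        clim = climate_from({}, pops)
        daf = dict(zip(pops, rng.uniform(0.2, 0.8, 12)))
        res = ClineAssociation(daf, clim).fit()
        out = tmp_path / "cline.png"
        res.plot("precipitation", path=str(out))
        assert out.stat().st_size > 0

    def test_transforms_preserve_monotone_association(self):
        pops = [f"p{i}" for i in range(15)]
        x = np.linspace(-2, 2, 15)
        clim = climate_from({"uv": x}, pops)
        daf = dict(zip(pops, np.clip(0.5 + 0.1 * x, 0.02, 0.98)))
        r_raw = correlate_climate(daf, clim, "uv").r
        r_logit = correlate_climate(daf, clim, "uv", transform="logit").r
        r_asin = correlate_climate(daf, clim, "uv", transform="arcsine").r
        assert r_raw > 0.99 and r_logit > 0.99 and r_asin > 0.99
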