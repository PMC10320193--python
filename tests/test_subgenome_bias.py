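"""Haploid-fraction statistics, the per-sample 2n-vs-1n regression with
prediction-interval outliers, consistency calls and paired tests."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from subbias.data_io import CountMatrix, OrthologMap, SampleTable
from subbias.subgenome_bias import test_fraction_excess as fraction_excess_ztest
from subbias.subgenome_bias import (
    RegressionFit,
    consistent_bias,
    fit_sample_regression,
    haploid_fraction,
    holm_adjust,
    paired_subgenome_test,
    population_bias_analysis,
    prediction_outliers,
    sample_bias_calls,
)


def _pair_setup(c2_col, c1_col):
    genes = [f"g{i}" for i in range(len(c2_col))]
    idx = pd.Index(genes, name="gene_id")
    c2 = CountMatrix(pd.DataFrame({"s": c2_col}, index=idx), "2n")
    c1 = CountMatrix(pd.DataFrame({"s": c1_col}, index=idx), "1n")
    omap = OrthologMap({"P": {g: f"{g}@P" for g in genes}})
    return c2, c1, omap


# ---------------------------------------------------------------------------
# haploid fraction & z-test


def test_haploid_fraction_one_third():
    c2, c1, omap = _pair_setup([20, 80, 100], [10, 40, 50])
    assert haploid_fraction(c2, c1, omap, "s", "P") == pytest.approx(1 / 3)


def test_haploid_fraction_matches_sums(rng):
    a = rng.integers(0, 200, 50)
    b = rng.integers(0, 200, 50)
    c2, c1, omap = _pair_setup(a, b)
    assert haploid_fraction(c2, c1, omap, "s", "P") == pytest.approx(
        b.sum() / (a.sum() + b.sum())
    )


def test_haploid_fraction_zero_reads_errors():
    c2, c1, omap = _pair_setup([0, 0], [0, 0])
    with pytest.raises(ValueError, match="no reads"):
        haploid_fraction(c2, c1, omap, "s", "P")


def test_fraction_excess_at_expectation():
    z, p = fraction_excess_ztest([1 / 3, 1 / 3, 1 / 3])
    assert (z, p) == (0.0, 0.5)


def test_fraction_excess_closed_form():
    f = np.array([0.40, 0.42, 0.38, 0.41])
    z, p = fraction_excess_ztest(f)
    se = f.std(ddof=1) / math.sqrt(4)
    z_oracle = (f.mean() - 1 / 3) / se
    assert z == pytest.approx(z_oracle)
    assert p == pytest.approx(stats.norm.sf(z_oracle))


def test_fraction_excess_strong_rejection(rng):
    """Thirty samples at a true 40% share reject the one-third null hard."""
    f = rng.normal(0.40, 0.02, 30)
    _, p = fraction_excess_ztest(f)
    assert p < 1e-10


# ---------------------------------------------------------------------------
# regression


def test_regression_exact_line():
    counts = (2 ** np.arange(1, 11) - 1).astype(int)  # log2(c+1) = 1..10
    c2, c1, omap = _pair_setup(counts, counts)
    fit = fit_sample_regression(c2, c1, omap, "s", "P")
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
    assert fit.n_pairs == 10


def test_regression_matches_ols_oracle(rng):
    a = rng.integers(1, 2000, 50)
    b = rng.integers(1, 2000, 50)
    c2, c1, omap = _pair_setup(a, b)
    fit = fit_sample_regression(c2, c1, omap, "s", "P")
    x = np.log2(a + 1.0)
    y = np.log2(b + 1.0)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.intercept == pytest.approx(ols.params[0])
    assert fit.slope == pytest.approx(ols.params[1])
    assert fit.residual_sd == pytest.approx(np.sqrt(ols.mse_resid))


def test_regression_null_simulation_slope_one_intercept_minus_one(
    null_allotriploid_dataset,
):
    """Equal per-copy expression: 1n is half of 2n, so on the log2 scale the
    fitted line has slope ~1 and intercept ~log2(1/2) = -1."""
    d = null_allotriploid_dataset
    slopes, intercepts = [], []
    for sid in d.samples.samples_in("Allo"):
        fit = fit_sample_regression(d.counts_2n, d.counts_1n, d.ortholog_maps, sid, "Allo")
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
    assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)
    assert np.mean(intercepts) == pytest.approx(-1.0, abs=0.15)


def test_regression_degenerate_inputs():
    c2, c1, omap = _pair_setup([5, 5, 5], [1, 2, 3])
    with pytest.raises(ValueError, match="zero variance"):
        fit_sample_regression(c2, c1, omap, "s", "P")
    c2, c1, omap = _pair_setup([1, 2], [1, 2])
    with pytest.raises(ValueError, match=">=3"):
        fit_sample_regression(c2, c1, omap, "s", "P")


# ---------------------------------------------------------------------------
# prediction-interval outliers


def test_point_on_line_is_within():
    counts = (2 ** np.arange(1, 11) - 1).astype(int)
    c2, c1, omap = _pair_setup(counts, counts)
    calls = sample_bias_calls(c2, c1, omap, "s", "P")
    assert (calls["direction"] == "within").all()


def test_prediction_interval_matches_textbook_formula(rng):
    """Bounds equal the simple-regression prediction-interval formula and
    the independent statsmodels implementation, point by point."""
    x = rng.normal(8, 2, 10)
    y = 0.9 * x - 1 + rng.normal(0, 0.5, 10)
    n = 10
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    slope = ((x - xb) * (y - yb)).sum() / sxx
    inter = yb - slope * xb
    resid = y - (inter + slope * x)
    s = math.sqrt((resid**2).sum() / (n - 2))
    fit = RegressionFit("s", slope, inter, s, n, xb, sxx)
    calls = prediction_outliers(fit, [f"g{i}" for i in range(n)], x, y, level=0.95)
    tq = stats.t.ppf(0.975, n - 2)
    for i in range(n):
        half = tq * s * math.sqrt(1 + 1 / n + (x[i] - xb) ** 2 / sxx)
        pred = inter + slope * x[i]
        assert calls["lower"].iloc[i] == pytest.approx(pred - half)
        assert calls["upper"].iloc[i] == pytest.approx(pred + half)
    # independent oracle: statsmodels observation prediction interval
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    frame = ols.get_prediction(sm.add_constant(x)).summary_frame(alpha=0.05)
    np.testing.assert_allclose(calls["lower"], frame["obs_ci_lower"], rtol=1e-10)
    np.testing.assert_allclose(calls["upper"], frame["obs_ci_upper"], rtol=1e-10)


def test_outlier_directions_consistent_with_bounds(rng):
    x = rng.normal(6, 2, 40)
    y = x + rng.normal(0, 1, 40)
    fit_args = dict(zip("abc", [0, 0, 0]))
    xb = x.mean()
    sxx = ((x - xb) ** 2).sum()
    slope = ((x - xb) * (y - y.mean())).sum() / sxx
    inter = y.mean() - slope * xb
    s = math.sqrt(((y - inter - slope * x) ** 2).sum() / 38)
    fit = RegressionFit("s", slope, inter, s, 40, xb, sxx)
    calls = prediction_outliers(fit, [f"g{i}" for i in range(40)], x, y, level=0.5)
    above = calls["direction"] == "above"
    below = calls["direction"] == "below"
    assert (calls.loc[above, "observed_1n"] > calls.loc[above, "upper"]).all()
    assert (calls.loc[below, "observed_1n"] < calls.loc[below, "lower"]).all()
    within = calls["direction"] == "within"
    assert (
        (calls.loc[within, "observed_1n"] >= calls.loc[within, "lower"])
        & (calls.loc[within, "observed_1n"] <= calls.loc[within, "upper"])
    ).all()


# ---------------------------------------------------------------------------
# consistency calls


def _calls_frame(n_samples, n_above, n_below, gene="gX"):
    rows = []
    for i in range(n_samples):
        direction = (
            "above" if i < n_above else "below" if i < n_above + n_below else "within"
        )
        rows.append({"gene_id": gene, "sample_id": f"s{i}", "direction": direction})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "n_above,n_below,expected",
    [(26, 0, "1n_over"), (25, 0, "1n_over"), (24, 0, "none"), (13, 13, "none"), (0, 25, "1n_under")],
)
def test_consistency_threshold_30_samples(n_above, n_below, expected):
    """25-of-30 same-direction threshold; opposite deviations do not pool."""
    out = consistent_bias(_calls_frame(30, n_above, n_below), "Beer", n_samples=30)
    assert out.loc["gX", "call"] == expected


@pytest.mark.parametrize("n,thr", [(30, 25), (9, 7), (6, 5), (20, 17), (12, 10)])
def test_consistency_thresholds_by_population_size(n, thr):
    over = consistent_bias(_calls_frame(n, thr, 0), "P", n_samples=n)
    under_thr = consistent_bias(_calls_frame(n, thr - 1, 0), "P", n_samples=n)
    assert over.loc["gX", "call"] == "1n_over"
    assert under_thr.loc["gX", "call"] == "none"
    assert over.loc["gX", "threshold"] == thr


# ---------------------------------------------------------------------------
# paired tests and Holm


def test_paired_test_identical_vectors():
    idx = pd.Index(["g"], name="gene_id")
    a = pd.DataFrame([[1.0, 2.0, 3.0]], index=idx, columns=["s1", "s2", "s3"])
    t, p = paired_subgenome_test(a, a.copy(), "g", ["s1", "s2", "s3"])
    assert (t, p) == (0.0, 1.0)


def test_paired_test_matches_textbook_formula(rng):
    a = rng.normal(10, 2, 6)
    b = a + rng.normal(1, 0.5, 6)
    idx = pd.Index(["g"], name="gene_id")
    cols = [f"s{i}" for i in range(6)]
    t, p = paired_subgenome_test(
        pd.DataFrame([a], index=idx, columns=cols),
        pd.DataFrame([b], index=idx, columns=cols),
        "g",
        cols,
    )
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(6))
    assert t == pytest.approx(t_oracle)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_oracle), 5))


def test_holm_step_down_example():
    np.testing.assert_allclose(
        holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
    )


def test_holm_matches_statsmodels(rng):
    for _ in range(100):
        p = rng.uniform(0, 1, rng.integers(1, 15))
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj, rtol=1e-12)


# ---------------------------------------------------------------------------
# end-to-end per-population workflow


def test_population_analysis_recovers_biased_genes(demo_dataset):
    """Genes simulated at 0.6 haploid allocation are called 1n_over in the
    large (30-sample) population; null genes essentially never are."""
    d = demo_dataset
    _, consistent = population_bias_analysis(
        d.counts_2n, d.counts_1n, d.ortholog_maps, d.samples, "Beer"
    )
    truth_bias = set(d.truth.index[d.truth["is_1n_biased"]])
    called_over = set(consistent.index[consistent["call"] == "1n_over"])
    assert len(called_over & truth_bias) >= 0.7 * len(truth_bias)
    null_called = called_over - truth_bias
    assert len(null_called) <= 2
    # Holm-adjusted paired p small for recovered bias genes
    rec = consistent.loc[sorted(called_over & truth_bias)]
    assert (rec["paired_p_holm"] < 0.05).mean() > 0.8
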