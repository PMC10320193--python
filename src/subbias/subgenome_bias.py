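"""Homeolog expression bias between the primary diploid (2n) and acquired
haploid (1n) subgenomes of allotriploid samples.

Under equal per-copy expression, one-third of an ortholog pair's reads
should come from the single acquired haploid copy and two-thirds from the
two primary copies.  This module implements:

* the per-sample haploid read fraction over ortholog pairs, and a one-sample
  z-test for its excess over 1/3 across samples of a population;
* a per-sample ordinary least-squares regression of (transformed) 1n counts
  on 2n counts over ortholog pairs, with gene-level outlier calls from the
  simple-regression prediction interval — genes that do not follow the
  sample's own 2n-vs-1n trend;
* consolidation of per-sample outlier calls into per-population
  "consistently biased" gene sets using same-direction sample-count
  thresholds, plus paired t-tests (Holm-corrected) comparing
  library-corrected 2n and 1n expression per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountMatrix, OrthologMap, SampleTable
from .normalization import shared_core_normalize

__all__ = [
    "RegressionFit",
    "haploid_fraction",
    "test_fraction_excess",
    "fit_sample_regression",
    "prediction_outliers",
    "consistent_bias",
    "paired_subgenome_test",
    "holm_adjust",
    "CONSISTENCY_THRESHOLDS",
    "DEFAULT_MIN_FRACTION",
]

#: exact per-population sample-count thresholds for a consistent call,
#: keyed by population size (30 Beer, 9 Teq/EtOH, 6 Wine 1 in the design
#: being emulated); other sizes use ceil(DEFAULT_MIN_FRACTION * n)
CONSISTENCY_THRESHOLDS: dict[int, int] = {30: 25, 9: 7, 6: 5}
DEFAULT_MIN_FRACTION = 25.0 / 30.0


@dataclass
class RegressionFit:
    """OLS fit of transformed 1n counts on transformed 2n counts for one
    sample, with the sufficient statistics needed for prediction intervals."""

    sample_id: str
    slope: float
    intercept: float
    residual_sd: float  # sqrt(RSS / (n - 2))
    n_pairs: int
    x_mean: float
    sxx: float  # sum of squared predictor deviations
    scale: str = "log2p1"  # "log2p1" or "raw"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _pair_arrays(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    sample_id: str,
    population: str,
    drop_absent: bool = True,
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Ortholog-pair count vectors (2n, 1n) for one sample.

    Pairs with zero reads in both compartments are treated as not expressed
    in that sample and dropped when ``drop_absent``.
    """
    df2 = counts_2n.df if isinstance(counts_2n, CountMatrix) else counts_2n
    df1 = counts_1n.df if isinstance(counts_1n, CountMatrix) else counts_1n
    if population not in ortholog_maps:
        raise KeyError(f"no ortholog map for population {population!r}")
    paired = pd.Index(ortholog_maps[population].keys())
    paired = paired.intersection(df2.index).intersection(df1.index)
    x = df2.loc[paired, sample_id].to_numpy(dtype=float)
    y = df1.loc[paired, sample_id].to_numpy(dtype=float)
    if drop_absent:
        keep = (x > 0) | (y > 0)
        return paired[keep], x[keep], y[keep]
    return paired, x, y


def haploid_fraction(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    sample_id: str,
    population: str,
) -> float:
    """Share of ortholog-pair reads assigned to the acquired 1n subgenome.

    Computed over genes present on both subgenomes; 1/3 under equal
    per-copy expression.
    """
    _, x, y = _pair_arrays(counts_2n, counts_1n, ortholog_maps, sample_id, population)
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError(f"sample {sample_id!r}: no reads over ortholog pairs")
    return float(y.sum() / denom)


def test_fraction_excess(
    fractions: np.ndarray | list[float], expected: float = 1.0 / 3.0
) -> tuple[float, float]:
    """One-sample z-test of the mean haploid fraction against ``expected``.

    Returns (z, one-sided upper-tail p).  z uses the sample standard
    deviation of the per-sample fractions over sqrt(n).
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two samples")
    sd = f.std(ddof=1)
    if sd == 0:
        if np.isclose(f.mean(), expected):
            return 0.0, 0.5  # exactly at expectation: no evidence either way
        raise ValueError("zero spread across samples; z-test degenerate")
    z = (f.mean() - expected) / (sd / math.sqrt(f.size))
    return float(z), float(stats.norm.sf(z))


def fit_sample_regression(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    sample_id: str,
    population: str,
    scale: str = "log2p1",
) -> RegressionFit:
    """OLS of 1n on 2n counts over the sample's expressed ortholog pairs.

    ``scale="log2p1"`` (default) regresses log2(count + 1) values; raw
    counts via ``scale="raw"``.  Pairs unexpressed in both compartments are
    excluded.  Residual SD uses n - 2 degrees of freedom.
    """
    genes, x, y = _pair_arrays(
        counts_2n, counts_1n, ortholog_maps, sample_id, population
    )
    if scale == "log2p1":
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    n = x.size
    if n < 3:
        raise ValueError(f"sample {sample_id!r}: need >=3 ortholog pairs, got {n}")
    x_mean = x.mean()
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0:
        raise ValueError(f"sample {sample_id!r}: zero variance in 2n predictor")
    slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    residual_sd = math.sqrt(float((resid**2).sum()) / (n - 2))
    return RegressionFit(
        sample_id=sample_id,
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        n_pairs=n,
        x_mean=float(x_mean),
        sxx=sxx,
        scale=scale,
    )


def prediction_outliers(
    fit: RegressionFit,
    genes: pd.Index | list[str],
    x: np.ndarray,
    y: np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Classify each ortholog pair against the regression prediction interval.

    For a new observation at predictor value x the two-sided interval at
    ``level`` is  ŷ ± t_{1-(1-level)/2, n-2} · s · sqrt(1 + 1/n + (x - x̄)²/Sxx)
    with s the residual SD.  Genes above the upper bound are expressed more
    from the 1n copy than the sample-wide trend predicts, genes below less.

    ``x`` and ``y`` must already be on the fit's scale.  Returns one row per
    gene: observed, predicted, lower, upper, direction.
    """
    if fit.n_pairs < 3:
        raise ValueError("need >=3 pairs in the fit")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pred = fit.predict(x)
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.n_pairs - 2)
    half = tq * fit.residual_sd * np.sqrt(
        1.0 + 1.0 / fit.n_pairs + (x - fit.x_mean) ** 2 / fit.sxx
    )
    lower = pred - half
    upper = pred + half
    direction = np.where(y > upper, "above", np.where(y < lower, "below", "within"))
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "sample_id": fit.sample_id,
            "observed_1n": y,
            "predicted_1n": pred,
            "lower": lower,
            "upper": upper,
            "direction": direction,
        }
    )


def sample_bias_calls(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    sample_id: str,
    population: str,
    level: float = 0.95,
    scale: str = "log2p1",
) -> pd.DataFrame:
    """Regression plus outlier classification for one sample (convenience)."""
    genes, x, y = _pair_arrays(
        counts_2n, counts_1n, ortholog_maps, sample_id, population
    )
    if scale == "log2p1":
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    fit = fit_sample_regression(
        counts_2n, counts_1n, ortholog_maps, sample_id, population, scale=scale
    )
    return prediction_outliers(fit, genes, x, y, level=level)


def _threshold_for(n_samples: int, min_fraction: float | None) -> int:
    if min_fraction is None and n_samples in CONSISTENCY_THRESHOLDS:
        return CONSISTENCY_THRESHOLDS[n_samples]
    frac = DEFAULT_MIN_FRACTION if min_fraction is None else min_fraction
    return math.ceil(frac * n_samples)


def consistent_bias(
    calls: pd.DataFrame,
    population: str,
    n_samples: int | None = None,
    min_fraction: float | None = None,
) -> pd.DataFrame:
    """Per-population consolidation of per-sample deviation calls.

    A gene is called ``1n_over`` (``1n_under``) if it falls above (below)
    the prediction interval in at least the threshold number of samples —
    deviations must share a direction.  Thresholds are the design's exact
    values for population sizes 30, 9 and 6 (25, 7 and 5 samples) and
    ceil(min_fraction · n) otherwise.

    ``calls`` concatenates ``sample_bias_calls`` rows for every sample of
    the population; a gene's evaluable count is the number of samples in
    which it appears (i.e. was expressed and paired).
    """
    if calls.empty:
        raise ValueError(f"no calls supplied for population {population!r}")
    n = n_samples if n_samples is not None else calls["sample_id"].nunique()
    thr = _threshold_for(n, min_fraction)
    grp = calls.groupby("gene_id")["direction"]
    n_above = grp.apply(lambda s: int((s == "above").sum()))
    n_below = grp.apply(lambda s: int((s == "below").sum()))
    n_eval = grp.size()
    call = np.where(
        n_above >= thr, "1n_over", np.where(n_below >= thr, "1n_under", "none")
    )
    return pd.DataFrame(
        {
            "population": population,
            "n_above": n_above,
            "n_below": n_below,
            "n_samples_evaluable": n_eval,
            "threshold": thr,
            "call": call,
        }
    )


def paired_subgenome_test(
    corrected_2n: pd.DataFrame,
    corrected_1n: pd.DataFrame,
    gene: str,
    sample_ids: list[str],
) -> tuple[float, float]:
    """Paired t-test of a gene's library-corrected 2n vs 1n expression.

    Expression should be corrected per subgenome by the shared-ortholog
    library totals (``shared_core_normalize``) so the per-sample difference
    reflects allocation, not depth.  Returns (t, two-sided p).
    """
    a = corrected_2n.loc[gene, sample_ids].to_numpy(dtype=float)
    b = corrected_1n.loc[gene, sample_ids].to_numpy(dtype=float)
    if a.size < 2:
        raise ValueError("need >=2 paired samples")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        raise ValueError(f"gene {gene!r}: zero-variance nonzero differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def holm_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def population_bias_analysis(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    samples: SampleTable,
    population: str,
    level: float = 0.95,
    scale: str = "log2p1",
    min_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-population bias workflow.

    Runs the per-sample regression/outlier step for every sample of the
    population, consolidates consistent calls, and attaches paired-test p
    (Holm-adjusted across the population's evaluable genes).  Returns
    (per-sample calls, consistent-bias table).
    """
    sids = samples.samples_in(population)
    calls = pd.concat(
        [
            sample_bias_calls(
                counts_2n, counts_1n, ortholog_maps, sid, population,
                level=level, scale=scale,
            )
            for sid in sids
        ],
        ignore_index=True,
    )
    consistent = consistent_bias(
        calls, population, n_samples=len(sids), min_fraction=min_fraction
    )

    # paired tests on shared-core-corrected expression across the
    # population's samples, for every gene with paired presence
    paired = list(ortholog_maps[population].keys())
    df2 = counts_2n.df if isinstance(counts_2n, CountMatrix) else counts_2n
    df1 = counts_1n.df if isinstance(counts_1n, CountMatrix) else counts_1n
    corr2 = shared_core_normalize(df2[sids], paired)
    corr1 = shared_core_normalize(df1[sids], paired)
    tvals, pvals, genes_tested = [], [], []
    for g in consistent.index:
        if g not in corr2.index:
            continue
        try:
            t, p = paired_subgenome_test(corr2, corr1, g, sids)
        except ValueError:
            continue
        genes_tested.append(g)
        tvals.append(t)
        pvals.append(p)
    adj = holm_adjust(pvals)
    tests = pd.DataFrame(
        {"paired_t": tvals, "paired_p": pvals, "paired_p_holm": adj},
        index=pd.Index(genes_tested, name="gene_id"),
    )
    consistent = consistent.join(tests)
    return calls, consistent
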