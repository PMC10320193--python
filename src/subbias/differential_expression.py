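"""One-vs-rest negative-binomial Wald differential expression, DE calling
and population "transcriptomic signature" calling.

The engine is a deliberately minimal NB Wald test: median-of-ratios size
factors, gene-wise method-of-moments dispersion, a two-group NB GLM with a
log link, Wald z on the group coefficient and Benjamini–Hochberg control
across genes.  No dispersion shrinkage toward a mean–dispersion trend, no
fold-change shrinkage and no independent filtering: the focus is the
one-population-versus-rest contrast design and the downstream thresholds,
and the simplified engine is calibration-tested under null simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import CountMatrix, SampleTable
from .normalization import size_factors_median_of_ratios

__all__ = [
    "nb_wald_de",
    "call_de",
    "call_signatures",
    "welch_t_test",
    "bh_adjust",
    "DEFAULT_FDR",
    "DEFAULT_MIN_ABS_LFC",
    "SIGNATURE_MIN_ABS_LFC",
]

LN2 = np.log(2.0)

DEFAULT_FDR = 0.05
DEFAULT_MIN_ABS_LFC = 1.0  # >= 2-fold
SIGNATURE_MIN_ABS_LFC = 1.6  # >= 3-fold
DISPERSION_FLOOR = 1e-8


def _moment_dispersion(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments on normalized counts.

    Within-group means and variances are pooled so a true group difference
    does not masquerade as dispersion; alpha solves
    var = mu + alpha * mu^2 and is floored at a small positive value.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    weight = 0.0
    alphas = np.zeros(n_genes)
    total_w = 0.0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        w = sub.shape[1] - 1
        alphas += w * np.nan_to_num(a)
        total_w += w
    if total_w > 0:
        alphas /= total_w
    return np.maximum(alphas, DISPERSION_FLOOR)


def _fit_gene(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[float, float] | None:
    """NB GLM fit for one gene; returns (log2fc, se) or None on failure."""
    fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
        coef = res.params[1]
        se = res.bse[1]
    except Exception:
        return None
    if not np.isfinite(coef) or not np.isfinite(se) or se <= 0:
        return None
    return float(coef / LN2), float(se / LN2)


def nb_wald_de(
    counts: CountMatrix | pd.DataFrame,
    samples: SampleTable,
    focal_population: str,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald DE, focal population versus all the rest.

    Per gene: counts are normalized by median-of-ratios size factors,
    gene-wise dispersion is estimated by within-group method of moments,
    and an NB GLM with log link and group indicator is fitted with the
    size factors as offsets.  Wald z = log2fc / se, two-sided normal p,
    BH adjustment across testable genes.  All-zero genes are reported with
    missing statistics and excluded from the BH family.

    Returns one row per gene: base_mean, log2fc, se, wald_z, p, padj,
    contrast.
    """
    df = counts.df if isinstance(counts, CountMatrix) else counts
    sids = [s for s in samples.sample_ids if s in df.columns]
    if focal_population not in samples.populations:
        raise KeyError(f"unknown population {focal_population!r}")
    focal = np.array(
        [samples.population_of(s) == focal_population for s in sids], dtype=bool
    )
    if focal.sum() < 2 or (~focal).sum() < 2:
        raise ValueError("focal and rest groups each need >=2 samples")

    mat = df[sids].to_numpy(dtype=float)
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(df[sids])
    sf = size_factors.loc[sids].to_numpy(dtype=float)
    norm = mat / sf

    alphas = _moment_dispersion(norm, focal.astype(int))
    design = np.column_stack([np.ones(len(sids)), focal.astype(float)])
    offset = np.log(sf)

    base_mean = norm.mean(axis=1)
    n_genes = mat.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)

    for i in range(n_genes):
        y = mat[i]
        if y.sum() == 0:
            continue
        fit = _fit_gene(y, design, offset, float(alphas[i]))
        if fit is None:
            continue
        log2fc[i], se[i] = fit
        z = log2fc[i] / se[i]
        pvals[i] = 2.0 * stats.norm.sf(abs(z))

    with np.errstate(invalid="ignore"):
        wald_z = log2fc / se
    padj = np.full(n_genes, np.nan)
    testable = np.isfinite(pvals)
    if testable.any():
        padj[testable] = bh_adjust(pvals[testable])
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_z": wald_z,
            "p": pvals,
            "padj": padj,
            "contrast": f"{focal_population}_vs_rest",
        },
        index=df.index.copy(),
    )


def call_de(
    de: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> pd.DataFrame:
    """Differentially expressed genes: padj < fdr and |log2fc| > min_abs_lfc.

    Returns the DE rows with a ``direction`` column (up/down in the focal
    population).
    """
    sel = (de["padj"] < fdr) & (de["log2fc"].abs() > min_abs_lfc)
    out = de.loc[sel.fillna(False)].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def call_signatures(
    de: pd.DataFrame,
    de_called: pd.DataFrame,
    min_abs_lfc: float = SIGNATURE_MIN_ABS_LFC,
) -> pd.DataFrame:
    """Transcriptomic signatures: strong, high-confidence DE genes.

    Within each direction (up/down) of the called DE set, keep genes whose
    |log2fc| exceeds ``min_abs_lfc`` (>= 3-fold by default) and whose
    adjusted p is strictly below the direction's median adjusted p
    (strict top-half; ties at the median are excluded).
    """
    keep = []
    for direction, sub in de_called.groupby("direction"):
        med = sub["padj"].median()
        strong = sub.loc[
            (sub["log2fc"].abs() > min_abs_lfc) & (sub["padj"] < med)
        ]
        keep.append(strong)
    if not keep:
        return de_called.iloc[0:0].copy()
    return pd.concat(keep).sort_index()


def welch_t_test(
    group_a: np.ndarray | list[float], group_b: np.ndarray | list[float]
) -> tuple[float, float]:
    """Two-sample t-test assuming unequal variances (Satterthwaite dof)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj
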