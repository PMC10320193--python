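"""Functional enrichment of DE gene sets, plus the ordination summaries
(PCA, Spearman correlation matrix) used to compare expression profiles.

The enrichment score of a term is the ratio of the proportion of DE genes
annotated with the term to the proportion of genes in the gene universe so
annotated; significance is a hypergeometric upper-tail test, BH-corrected
within each GO category (BP/MF/CC), significant at adjusted p < 0.1.  The
test is a plain hypergeometric — no gene-length bias weighting — which is
appropriate for data without length-dependent detection bias.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .data_io import GeneAnnotation
from .differential_expression import bh_adjust

__all__ = ["enrich", "pca", "spearman_matrix", "ENRICHMENT_PADJ_CUTOFF"]

ENRICHMENT_PADJ_CUTOFF = 0.1


def enrich(
    de_genes: Iterable[str],
    annotation: GeneAnnotation,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a DE gene set.

    For each GO term with at least one annotated gene in the universe:
    the upper-tail hypergeometric p of drawing the observed overlap or
    more, and the enrichment score
    (n_de_with_term / n_de) / (n_universe_with_term / n_universe).
    BH adjustment is applied within each category; ``significant`` marks
    adjusted p below 0.1.
    """
    universe = set(universe)
    de = set(de_genes) & universe
    if set(de_genes) - universe:
        extra = sorted(set(de_genes) - universe)
        raise ValueError(f"DE genes outside the universe: {extra[:5]}")
    rows = []
    if not de:
        return pd.DataFrame(
            columns=[
                "term", "category", "n_de_with_term", "n_de",
                "n_genome_with_term", "n_genome", "enrichment_score",
                "p", "padj", "significant",
            ]
        )
    n_universe = len(universe)
    n_de = len(de)
    for category in annotation.CATEGORIES:
        cat_rows = []
        for term in annotation.terms_in(category):
            with_term = annotation.genes_with(term) & universe
            if not with_term:
                continue
            overlap = len(with_term & de)
            k = len(with_term)
            # P(X >= overlap), X ~ Hypergeom(N=n_universe, K=k, n=n_de)
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, k, n_de))
            score = (overlap / n_de) / (k / n_universe)
            cat_rows.append(
                {
                    "term": term,
                    "category": category,
                    "n_de_with_term": overlap,
                    "n_de": n_de,
                    "n_genome_with_term": k,
                    "n_genome": n_universe,
                    "enrichment_score": score,
                    "p": p,
                }
            )
        if cat_rows:
            cat_df = pd.DataFrame(cat_rows)
            cat_df["padj"] = bh_adjust(cat_df["p"].to_numpy())
            rows.append(cat_df)
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "category", "n_de_with_term", "n_de",
                "n_genome_with_term", "n_genome", "enrichment_score",
                "p", "padj", "significant",
            ]
        )
    out = pd.concat(rows, ignore_index=True)
    out["significant"] = out["padj"] < ENRICHMENT_PADJ_CUTOFF
    return out.sort_values(["category", "padj", "term"]).reset_index(drop=True)


def pca(
    log_matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples from a gene × sample (log-scale) expression matrix.

    Genes are features (centered per gene), samples are observations.
    Returns (scores: sample × PC, loadings: gene × PC, variance_explained).
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    X = log_matrix.to_numpy(dtype=float).T  # samples × genes
    n_comp = n_components or min(X.shape)
    model = PCA(n_components=n_comp)
    scores = model.fit_transform(X)
    loadings = model.components_.T  # genes × PCs
    # fix signs so results do not depend on SVD implementation details
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    pcs = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=log_matrix.columns, columns=pcs),
        pd.DataFrame(loadings, index=log_matrix.index, columns=pcs),
        model.explained_variance_,
    )


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Spearman correlation of expression profiles.

    Columns are samples; ties get average ranks.  The result is symmetric
    with a unit diagonal.
    """
    return matrix.corr(method="spearman")
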