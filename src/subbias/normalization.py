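"""Count transformations used before any between-sample comparison.

Subgenome-restricted library normalization (counts per million within one
compartment), shared-ortholog-core normalization, collapsing of homeolog
pairs into a single per-gene total, median-of-ratios size factors, TPM and
the log2 transform.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .data_io import CountMatrix, OrthologMap, SampleTable

__all__ = [
    "CPM_SCALE",
    "subgenome_library_normalize",
    "shared_core_normalize",
    "collapse_counts",
    "size_factors_median_of_ratios",
    "tpm",
    "log_transform",
]

CPM_SCALE = 1e6


def _as_df(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.df if isinstance(counts, CountMatrix) else counts


def subgenome_library_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by its compartment-restricted total, to CPM.

    Reads restricted to one subgenome are normalized by the total number of
    reads assigned to that subgenome in the same sample, so samples become
    comparable despite differing subgenome read fractions.
    """
    df = _as_df(counts)
    totals = df.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero compartment total for sample {zero[0]!r}")
    return df / totals * CPM_SCALE


def shared_core_normalize(
    counts: CountMatrix | pd.DataFrame, shared_genes: Iterable[str]
) -> pd.DataFrame:
    """Restrict to the shared ortholog core and normalize within it.

    Used for acquired-subgenome expression: only genes present on every
    acquired subgenome are kept, and each sample is scaled by the reads
    assigned to exactly that gene set, removing both gene-content and
    mapping-fraction differences between populations.
    """
    genes = pd.Index(shared_genes)
    if len(genes) == 0:
        raise ValueError("shared gene set is empty")
    df = _as_df(counts)
    missing = genes.difference(df.index)
    if len(missing):
        raise KeyError(f"shared genes missing from matrix: {missing[:5].tolist()}")
    sub = df.loc[genes]
    sub.index.name = df.index.name
    return subgenome_library_normalize(sub)


def collapse_counts(
    counts_2n: CountMatrix | pd.DataFrame,
    counts_1n: CountMatrix | pd.DataFrame,
    ortholog_maps: OrthologMap,
    samples: SampleTable,
) -> CountMatrix:
    """Sum homeolog pairs into one count per primary gene and sample.

    For each allotriploid sample, reads mapped to an acquired-subgenome
    gene are added to the reads of its primary-genome ortholog; genes with
    no retained ortholog keep their 2n count.  The gene universe stays the
    primary genome, making allotriploid samples directly comparable with
    diploid and autotriploid ones.

    The 1n matrix is indexed by primary gene IDs (annotation-transfer
    convention); a nonzero 1n count at a gene outside the sample's
    population map is rejected.
    """
    df2 = _as_df(counts_2n)
    df1 = _as_df(counts_1n)
    if not df2.index.equals(df1.index):
        raise ValueError("2n and 1n matrices must share the same gene universe")
    out = df2.copy()
    for sid in df2.columns:
        pop = samples.population_of(sid)
        if pop not in ortholog_maps:
            raise KeyError(f"no ortholog map for population {pop!r}")
        paired = pd.Index(ortholog_maps[pop].keys())
        col1 = df1[sid]
        stray = col1.index[(col1 > 0) & ~col1.index.isin(paired)]
        if len(stray):
            raise ValueError(
                f"sample {sid!r}: 1n counts at gene {stray[0]!r} which has no "
                f"primary partner in the {pop!r} map"
            )
        out.loc[paired.intersection(out.index), sid] += col1.loc[
            paired.intersection(out.index)
        ]
    return CountMatrix(out, "total")


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample the factor is the median, over genes with positive
    counts in every sample, of the ratio of that gene's count to its
    geometric mean across samples — the default library-size normalization
    of negative-binomial DE frameworks.
    """
    df = _as_df(counts).astype(float)
    all_pos = (df > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    ref = df.loc[all_pos]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    factors = ref.div(geo_mean, axis=0).median(axis=0)
    factors.name = "size_factor"
    return factors


def tpm(
    counts: CountMatrix | pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6/column."""
    df = _as_df(counts)
    missing = df.index.difference(gene_lengths.index)
    if len(missing):
        raise KeyError(f"missing gene length for {missing[:5].tolist()}")
    lengths = gene_lengths.loc[df.index].astype(float)
    rate = df.div(lengths, axis=0)
    return rate / rate.sum(axis=0) * CPM_SCALE


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount)."""
    return np.log2(matrix + pseudocount)
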