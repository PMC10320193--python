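"""Tabular input/output and the ortholog-transfer hit filter.

All on-disk formats are plain TSV with a header row.  Count matrices are
gene × sample integer tables; the subgenome compartment a matrix belongs to
(primary diploid ``2n``, acquired haploid ``1n``, or ``total``) travels with
the in-memory object, not the file.  BLAST tabular hit files (``-outfmt 7``
style, ``#`` comment lines) are supported for the annotation-transfer step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "OrthologMap",
    "GeneAnnotation",
    "ParseError",
    "COMPARTMENTS",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_annotation",
    "write_annotation",
    "read_hits",
    "filter_ortholog_hits",
]

COMPARTMENTS = ("2n", "1n", "total")

#: ploidy classes a sample may carry
PLOIDY_CLASSES = ("diploid", "autotriploid", "allotriploid")


class ParseError(ValueError):
    """A malformed input table; the message names the offending line or cell."""


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer read counts.

    Parameters
    ----------
    df :
        Rows indexed by gene ID, columns by sample ID, integer dtype.
    compartment :
        Which subgenome the reads were assigned to: ``"2n"`` (primary
        diploid), ``"1n"`` (acquired haploid) or ``"total"``.
    """

    df: pd.DataFrame
    compartment: str = "total"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene IDs: {dups[:5]}")
        if self.df.columns.has_duplicates:
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dups[:5]}")
        if self.df.isna().any().any():
            raise ParseError("count matrix contains missing cells")
        if (self.df.to_numpy() < 0).any():
            r, c = np.argwhere(self.df.to_numpy() < 0)[0]
            raise ParseError(
                f"negative count at gene {self.df.index[r]!r}, "
                f"sample {self.df.columns[c]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def samples(self) -> pd.Index:
        return self.df.columns

    def restrict(self, genes: Iterable[str]) -> "CountMatrix":
        """Row-subset to ``genes`` (order preserved from the argument)."""
        idx = pd.Index(genes)
        missing = idx.difference(self.df.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {missing[:5].tolist()}")
        return CountMatrix(self.df.loc[idx], self.compartment)


@dataclass
class SampleTable:
    """Per-sample metadata: population, ploidy class and, for allotriploids,
    the identifier of the acquired-subgenome reference assembly."""

    df: pd.DataFrame  # columns: sample_id, population, ploidy_class, subgenome_ref

    REQUIRED = ("sample_id", "population", "ploidy_class", "subgenome_ref")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ParseError(f"sample table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise ParseError(f"duplicate sample IDs: {dups.tolist()[:5]}")
        bad = ~self.df["ploidy_class"].isin(PLOIDY_CLASSES)
        if bad.any():
            raise ParseError(
                f"unknown ploidy class {self.df.loc[bad, 'ploidy_class'].iloc[0]!r}"
            )
        # allotriploid <=> subgenome_ref present
        is_allo = self.df["ploidy_class"] == "allotriploid"
        has_ref = self.df["subgenome_ref"].notna() & (self.df["subgenome_ref"] != "")
        if (is_allo != has_ref).any():
            sid = self.df.loc[is_allo != has_ref, "sample_id"].iloc[0]
            raise ParseError(
                f"sample {sid!r}: subgenome_ref must be present exactly for "
                "allotriploid samples"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def population_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return row["population"].iloc[0]

    def samples_in(self, population: str) -> list[str]:
        return self.df.loc[self.df["population"] == population, "sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population"]))

    def allotriploid_populations(self) -> list[str]:
        sel = self.df["ploidy_class"] == "allotriploid"
        return list(dict.fromkeys(self.df.loc[sel, "population"]))


@dataclass
class OrthologMap:
    """Per-population pairing of primary-genome gene IDs with acquired
    (haploid) subgenome gene IDs.

    The pairing is partial — loss-of-heterozygosity removes genes from
    acquired subgenomes — and injective in both directions within each
    population.
    """

    pairs: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, mapping in self.pairs.items():
            targets = list(mapping.values())
            if len(set(targets)) != len(targets):
                raise ParseError(f"population {pop!r}: acquired gene mapped twice")

    def populations(self) -> list[str]:
        return list(self.pairs)

    def primary_genes(self, population: str) -> list[str]:
        return list(self.pairs[population])

    def shared_core(self, populations: Iterable[str] | None = None) -> list[str]:
        """Primary genes retained in every listed population (all by default)."""
        pops = list(populations) if populations is not None else list(self.pairs)
        if not pops:
            return []
        core = set(self.pairs[pops[0]])
        for pop in pops[1:]:
            core &= set(self.pairs[pop])
        return sorted(core)

    def __getitem__(self, population: str) -> dict[str, str]:
        return self.pairs[population]

    def __contains__(self, population: str) -> bool:
        return population in self.pairs


@dataclass
class GeneAnnotation:
    """Gene lengths (bp) and GO-term assignments (categories BP/MF/CC)."""

    lengths: pd.Series  # gene_id -> length
    go: pd.DataFrame  # columns: gene_id, term, category

    CATEGORIES = ("BP", "MF", "CC")

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            g = self.lengths.index[self.lengths <= 0][0]
            raise ParseError(f"gene {g!r}: non-positive length")
        bad = ~self.go["category"].isin(self.CATEGORIES)
        if bad.any():
            raise ParseError(
                f"unknown GO category {self.go.loc[bad, 'category'].iloc[0]!r}"
            )

    def terms_in(self, category: str) -> list[str]:
        sel = self.go["category"] == category
        return sorted(self.go.loc[sel, "term"].unique())

    def genes_with(self, term: str) -> set[str]:
        return set(self.go.loc[self.go["term"] == term, "gene_id"])


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc


def read_counts(path: str | Path, compartment: str = "total") -> CountMatrix:
    """Read a gene × sample count TSV (first column = gene IDs)."""
    raw = _read_tsv(path)
    if raw.empty or raw.shape[1] < 2:
        raise ParseError(f"{path}: expected gene column plus >=1 sample column")
    gene_col = raw.columns[0]
    df = raw.set_index(gene_col)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            g = df.index[converted.isna()][0]
            raise ParseError(f"{path}: non-numeric count at gene {g!r}, sample {col!r}")
        if (converted < 0).any():
            g = df.index[converted < 0][0]
            raise ParseError(f"{path}: negative count at gene {g!r}, sample {col!r}")
        if (converted % 1 != 0).any():
            g = df.index[converted % 1 != 0][0]
            raise ParseError(f"{path}: non-integer count at gene {g!r}, sample {col!r}")
        df[col] = converted.astype(np.int64)
    df.index.name = "gene_id"
    return CountMatrix(df, compartment)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_samples(path: str | Path) -> SampleTable:
    df = _read_tsv(path)
    if "subgenome_ref" in df.columns:
        df["subgenome_ref"] = df["subgenome_ref"].where(df["subgenome_ref"].notna(), None)
    return SampleTable(df)


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """TSV with columns population, primary_gene, acquired_gene."""
    df = _read_tsv(path)
    for col in ("population", "primary_gene", "acquired_gene"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    pairs: dict[str, dict[str, str]] = {}
    for pop, sub in df.groupby("population", sort=False):
        if sub["primary_gene"].duplicated().any():
            g = sub.loc[sub["primary_gene"].duplicated(), "primary_gene"].iloc[0]
            raise ParseError(f"{path}: primary gene {g!r} mapped twice in {pop!r}")
        pairs[str(pop)] = dict(zip(sub["primary_gene"], sub["acquired_gene"]))
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    rows = [
        {"population": pop, "primary_gene": p, "acquired_gene": a}
        for pop, mapping in omap.pairs.items()
        for p, a in mapping.items()
    ]
    pd.DataFrame(rows, columns=["population", "primary_gene", "acquired_gene"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_annotation(length_path: str | Path, go_path: str | Path) -> GeneAnnotation:
    lengths_df = _read_tsv(length_path)
    for col in ("gene_id", "length"):
        if col not in lengths_df.columns:
            raise ParseError(f"{length_path}: missing column {col!r}")
    if lengths_df["gene_id"].duplicated().any():
        g = lengths_df.loc[lengths_df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{length_path}: duplicate gene {g!r}")
    lengths = pd.Series(
        pd.to_numeric(lengths_df["length"]).to_numpy(),
        index=lengths_df["gene_id"],
        name="length",
    )
    go = _read_tsv(go_path)
    for col in ("gene_id", "term", "category"):
        if col not in go.columns:
            raise ParseError(f"{go_path}: missing column {col!r}")
    return GeneAnnotation(lengths, go[["gene_id", "term", "category"]])


def write_annotation(ann: GeneAnnotation, length_path: str | Path, go_path: str | Path) -> None:
    ann.lengths.rename_axis("gene_id").reset_index().to_csv(
        length_path, sep="\t", index=False, lineterminator="\n"
    )
    ann.go.to_csv(go_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# BLAST tabular hits and the transfer filter

#: canonical column names for a hit table
HIT_COLUMNS = (
    "query_id",
    "target_id",
    "percent_identity",
    "alignment_length",
    "query_length",
    "e_value",
    "bit_score",
)

# names used by BLAST "# Fields:" comment lines -> canonical names
_BLAST_FIELD_ALIASES = {
    "query id": "query_id",
    "query acc.": "query_id",
    "query acc.ver": "query_id",
    "subject id": "target_id",
    "subject acc.": "target_id",
    "subject acc.ver": "target_id",
    "% identity": "percent_identity",
    "alignment length": "alignment_length",
    "query length": "query_length",
    "evalue": "e_value",
    "bit score": "bit_score",
}


def read_hits(path: str | Path) -> pd.DataFrame:
    """Parse a hit table: headered TSV or BLAST ``-outfmt 7`` with comments.

    For BLAST output the column layout is taken from the ``# Fields:`` line;
    ``qlen`` must have been requested (query length is needed for the
    coverage filter).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    field_names: list[str] | None = None
    data_lines: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            if ln.lower().startswith("# fields:"):
                raw = ln.split(":", 1)[1]
                field_names = [f.strip() for f in raw.split(",")]
            continue
        if ln.strip():
            data_lines.append(ln)

    if field_names is not None:
        cols = [_BLAST_FIELD_ALIASES.get(f.lower(), f) for f in field_names]
        rows = [ln.split("\t") for ln in data_lines]
        df = pd.DataFrame(rows, columns=cols)
    else:
        # headered TSV
        if not data_lines:
            return pd.DataFrame(columns=HIT_COLUMNS)
        header = data_lines[0].split("\t")
        rows = [ln.split("\t") for ln in data_lines[1:]]
        df = pd.DataFrame(rows, columns=header)

    if "query_length" not in df.columns:
        raise ParseError(
            f"{path}: missing query_length column — cannot evaluate query coverage"
        )
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing hit columns: {missing}")
    df = df[list(HIT_COLUMNS)].copy()
    for col in ("percent_identity", "alignment_length", "query_length", "e_value", "bit_score"):
        df[col] = pd.to_numeric(df[col])
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise ParseError(f"{path}: percent_identity outside [0, 100]")
    if (df["query_length"] <= 0).any() or (df["alignment_length"] <= 0).any():
        raise ParseError(f"{path}: non-positive alignment or query length")
    return df


def filter_ortholog_hits(
    hits: pd.DataFrame,
    min_identity: float = 85.0,
    min_query_coverage: float = 0.95,
    population: str = "population",
) -> OrthologMap:
    """Stringency filter turning raw similarity hits into an ortholog map.

    A hit survives if it is at least ``min_identity`` percent identical to
    the query and the alignment covers strictly more than
    ``min_query_coverage`` of the query length.  Per query the single best
    surviving hit (highest bit score; ties broken by lexicographic target
    ID) is kept, and the result is made injective on targets: when two
    queries claim one target the higher bit score wins and the loser is
    dropped.
    """
    if "query_length" not in hits.columns:
        raise ParseError("hit table lacks query_length — cannot evaluate coverage")
    if hits.empty:
        return OrthologMap({population: {}})

    surviving = hits.loc[
        (hits["percent_identity"] >= min_identity)
        & (hits["alignment_length"] > min_query_coverage * hits["query_length"])
    ]
    # best hit per query: max bit score, tie -> lexicographically smallest target
    best: dict[str, tuple[float, str]] = {}
    for row in surviving.itertuples(index=False):
        key = (row.bit_score, row.target_id)
        cur = best.get(row.query_id)
        if cur is None or key[0] > cur[0] or (key[0] == cur[0] and key[1] < cur[1]):
            best[row.query_id] = key
    # injectivity on targets: higher bit score wins, tie -> smaller query id
    by_target: dict[str, tuple[float, str]] = {}
    for query in sorted(best):
        score, target = best[query]
        cur = by_target.get(target)
        if cur is None or score > cur[0]:
            by_target[target] = (score, query)
    mapping = {query: target for target, (_, query) in by_target.items()}
    return OrthologMap({population: dict(sorted(mapping.items()))})
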