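"""Simulation of allopolyploid RNA-seq count data with known ground truth.

The generator emulates the structure of a *Brettanomyces bruxellensis*
transcriptome survey: six populations — three allotriploid (2n + 1n), one
autotriploid, two diploid — with fixed per-population sample counts, a
primary-genome gene universe, per-population loss of acquired-subgenome
orthologs, and negative-binomial read counts.  For allotriploid samples a
gene's reads are split between the primary diploid (2n) and acquired
haploid (1n) compartments by binomial thinning of the gene's total count,
so compartment totals are exactly consistent with the collapsed total.

Ground truth (which genes carry a haplotype-allocation bias, which are
population-differentially expressed, and which are present on each acquired
subgenome) is returned alongside the counts so that detection methods can
be benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CountMatrix, OrthologMap, SampleTable, GeneAnnotation

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_ortholog_loss",
    "simulate_counts",
    "simulate_dataset",
    "simulate_annotation",
    "DEFAULT_POPULATIONS",
    "DEFAULT_RETENTION",
]

#: the expected share of an allotriploid gene's reads coming from the single
#: acquired haploid copy when all three haplotypes are expressed equally
NULL_HAPLOID_SHARE = 1.0 / 3.0


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    ploidy_class: str  # diploid | autotriploid | allotriploid
    n_samples: int


# The study design being emulated: 45 allotriploid samples across three
# independent hybridization lineages, 9 autotriploid and 33 diploid samples.
DEFAULT_POPULATIONS: tuple[PopulationSpec, ...] = (
    PopulationSpec("Teq/EtOH", "allotriploid", 9),
    PopulationSpec("Beer", "allotriploid", 30),
    PopulationSpec("Wine 1", "allotriploid", 6),
    PopulationSpec("Wine 2", "autotriploid", 9),
    PopulationSpec("Wine 3", "diploid", 26),
    PopulationSpec("Kombucha", "diploid", 7),
)

#: fraction of primary genes recovered on each acquired subgenome assembly
DEFAULT_RETENTION: Mapping[str, float] = {
    "Teq/EtOH": 0.88,
    "Beer": 0.70,
    "Wine 1": 0.75,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Attributes
    ----------
    populations :
        Population layout; defaults to the six-population study design.
    n_genes :
        Primary-genome gene universe.  The reduced default (500) keeps test
        runs fast; ``full_scale()`` gives the 5,206-gene universe.
    ortholog_retention :
        Per allotriploid population, the probability that a primary gene
        has a retained ortholog on the acquired subgenome (LOH removes the
        rest).
    baseline_log_mean, baseline_log_sd :
        Natural-log-scale location/spread of per-gene relative expression.
    dispersion :
        NB dispersion alpha (variance = mu + alpha * mu^2), scalar or
        per-gene array.  ``0`` switches to deterministic expectation mode
        (counts equal rounded means; no sampling noise).
    haploid_allocation :
        Expected fraction of an allotriploid gene's reads originating from
        the 1n copy when the ortholog is present.  1/3 is the equal
        per-copy-expression null.
    n_bias_genes, bias_allocation :
        Number of genes (drawn from the shared ortholog core) whose
        allocation is set to ``bias_allocation`` instead — the truth set
        for haplotype-bias detection.
    n_de_genes, de_log2fc :
        Number of genes given a population-specific expression shift of
        ``±de_log2fc`` log2 units (populations cycled, signs alternated) —
        the truth set for differential-expression detection.
    library_size :
        Expected total reads per sample.
    library_log_sd :
        Log-normal spread of per-sample library depth around library_size.
    autotriploid_scale :
        Optional global expression multiplier for autotriploid samples.
    seed :
        Base seed for all randomness.
    """

    populations: tuple[PopulationSpec, ...] = DEFAULT_POPULATIONS
    n_genes: int = 500
    ortholog_retention: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION)
    )
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    dispersion: float | Sequence[float] = 0.05
    haploid_allocation: float = NULL_HAPLOID_SHARE
    n_bias_genes: int = 0
    bias_allocation: float = 0.6
    n_de_genes: int = 0
    de_log2fc: float = 2.0
    library_size: float = 2e5
    library_log_sd: float = 0.1
    autotriploid_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for pop in self.populations:
            if pop.n_samples < 2:
                raise ValueError(f"population {pop.name!r}: need >=2 samples")
            if pop.ploidy_class not in ("diploid", "autotriploid", "allotriploid"):
                raise ValueError(f"unknown ploidy class {pop.ploidy_class!r}")
        allo = {p.name for p in self.populations if p.ploidy_class == "allotriploid"}
        for name in allo:
            if name not in self.ortholog_retention:
                raise ValueError(f"no ortholog retention given for {name!r}")
            r = self.ortholog_retention[name]
            if not (0.0 < r <= 1.0):
                raise ValueError(f"retention for {name!r} must be in (0, 1], got {r}")
        if not (0.0 < self.haploid_allocation < 1.0):
            raise ValueError("haploid_allocation must be in (0, 1)")
        if self.n_bias_genes and not (0.0 < self.bias_allocation < 1.0):
            raise ValueError("bias_allocation must be in (0, 1)")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")
        alpha = np.asarray(self.dispersion, dtype=float)
        if (alpha < 0).any():
            raise ValueError("dispersion must be >= 0")

    def allotriploid_populations(self) -> list[PopulationSpec]:
        return [p for p in self.populations if p.ploidy_class == "allotriploid"]

    def full_scale(self) -> "SimulationConfig":
        """The full 5,206-gene universe at deeper sequencing."""
        return replace(self, n_genes=5206, library_size=2e6)


@dataclass
class SimulatedDataset:
    """Counts, metadata and ground truth of one simulation run."""

    counts_2n: CountMatrix  # allotriploid samples only
    counts_1n: CountMatrix  # allotriploid samples only
    counts_total: CountMatrix  # every sample
    samples: SampleTable
    ortholog_maps: OrthologMap
    truth: pd.DataFrame  # one row per gene


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"BBgene{i:0{width}d}" for i in range(1, n + 1)]


def _acquired_id(gene: str, population: str) -> str:
    tag = population.replace(" ", "").replace("/", "-")
    return f"{gene}@{tag}"


def simulate_ortholog_loss(
    config: SimulationConfig, seed: int | None = None
) -> OrthologMap:
    """Draw per-population ortholog retention (independent LOH model).

    Each primary gene is independently retained on a population's acquired
    subgenome with that population's retention probability.  Returns an
    injective primary -> acquired map per allotriploid population; the
    shared core is the intersection across populations
    (``OrthologMap.shared_core``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = _gene_ids(config.n_genes)
    pairs: dict[str, dict[str, str]] = {}
    for pop in config.allotriploid_populations():
        r = config.ortholog_retention[pop.name]
        kept = rng.random(config.n_genes) < r
        pairs[pop.name] = {
            g: _acquired_id(g, pop.name) for g, k in zip(genes, kept) if k
        }
    return OrthologMap(pairs)


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mean, alpha) draws; alpha == 0 -> deterministic rounded mean."""
    out = np.empty(mean.shape, dtype=np.int64)
    det = alpha == 0
    if det.any():
        out[det] = np.rint(mean[det]).astype(np.int64)
    stoch = ~det
    if stoch.any():
        r = 1.0 / alpha[stoch]
        p = r / (r + mean[stoch])
        out[stoch] = rng.negative_binomial(r, p)
    return out


def _thin(
    rng: np.random.Generator, total: np.ndarray, p: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Binomial split of totals; deterministic share when alpha == 0."""
    out = np.empty(total.shape, dtype=np.int64)
    det = alpha == 0
    if det.any():
        out[det] = np.rint(total[det] * p[det]).astype(np.int64)
    stoch = ~det
    if stoch.any():
        out[stoch] = rng.binomial(total[stoch], p[stoch])
    return out


def simulate_counts(
    config: SimulationConfig,
    ortholog_maps: OrthologMap,
    seed: int | None = None,
) -> SimulatedDataset:
    """Generate count matrices, sample table and truth table.

    Allotriploid samples receive 2n and 1n compartment counts whose sum is
    the total; other samples only a total.  A gene's total count is NB with
    the configured dispersion around its expected expression; when a 1n
    ortholog exists the total is thinned binomially with the gene's
    allocation fraction (1/3 under the null), otherwise all reads fall on
    the 2n compartment.  The 1n matrix is indexed by primary-genome gene
    IDs, mirroring annotation transfer, with structural zeros where the
    ortholog is lost.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = _gene_ids(config.n_genes)
    n_genes = config.n_genes
    alpha = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float), (n_genes,)
    ).copy()

    # per-gene relative abundance -> expected reads at the configured depth
    abundance = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    )
    base_prop = abundance / abundance.sum()

    # truth assignment: bias genes from the shared ortholog core, DE genes
    # from the remainder (disjoint, so each truth label is unambiguous)
    allo_pops = [p.name for p in config.allotriploid_populations()]
    core = ortholog_maps.shared_core(allo_pops) if allo_pops else list(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    if config.n_bias_genes > len(core):
        raise ValueError(
            f"n_bias_genes={config.n_bias_genes} exceeds shared ortholog core "
            f"({len(core)} genes)"
        )
    bias_genes = sorted(
        rng.choice(core, size=config.n_bias_genes, replace=False).tolist()
    )
    allocation = np.full(n_genes, config.haploid_allocation)
    for g in bias_genes:
        allocation[gene_pos[g]] = config.bias_allocation

    non_bias = [g for g in genes if g not in set(bias_genes)]
    if config.n_de_genes > len(non_bias):
        raise ValueError("n_de_genes exceeds available (non-bias) genes")
    de_genes = sorted(
        rng.choice(non_bias, size=config.n_de_genes, replace=False).tolist()
    )
    pop_names = [p.name for p in config.populations]
    de_pop = {g: pop_names[i % len(pop_names)] for i, g in enumerate(de_genes)}
    de_sign = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(de_genes)}

    # sample bookkeeping
    sample_rows = []
    for pop in config.populations:
        tag = pop.name.replace(" ", "").replace("/", "-")
        for k in range(1, pop.n_samples + 1):
            sample_rows.append(
                {
                    "sample_id": f"{tag}_{k:02d}",
                    "population": pop.name,
                    "ploidy_class": pop.ploidy_class,
                    "subgenome_ref": (
                        f"1n-{tag}" if pop.ploidy_class == "allotriploid" else None
                    ),
                }
            )
    samples = SampleTable(pd.DataFrame(sample_rows))

    allo_sample_ids = [
        r["sample_id"] for r in sample_rows if r["ploidy_class"] == "allotriploid"
    ]
    total_mat = np.zeros((n_genes, len(sample_rows)), dtype=np.int64)
    c1n = np.zeros((n_genes, len(allo_sample_ids)), dtype=np.int64)
    c2n = np.zeros((n_genes, len(allo_sample_ids)), dtype=np.int64)
    allo_col = {s: j for j, s in enumerate(allo_sample_ids)}

    presence: dict[str, np.ndarray] = {}
    for pop_name in allo_pops:
        mask = np.zeros(n_genes, dtype=bool)
        for g in ortholog_maps[pop_name]:
            mask[gene_pos[g]] = True
        presence[pop_name] = mask

    for j, row in enumerate(sample_rows):
        pop_name = row["population"]
        lam = base_prop * config.library_size
        if config.library_log_sd > 0:
            lam = lam * np.exp(rng.normal(0.0, config.library_log_sd))
        if row["ploidy_class"] == "autotriploid":
            lam = lam * config.autotriploid_scale
        # population-DE effects
        for g in de_genes:
            if de_pop[g] == pop_name:
                lam[gene_pos[g]] *= 2.0 ** (de_sign[g] * config.de_log2fc)

        total = _draw_counts(rng, lam, alpha)
        total_mat[:, j] = total

        if row["ploidy_class"] == "allotriploid":
            p_eff = np.where(presence[pop_name], allocation, 0.0)
            ones = _thin(rng, total, p_eff, alpha)
            col = allo_col[row["sample_id"]]
            c1n[:, col] = ones
            c2n[:, col] = total - ones

    gene_index = pd.Index(genes, name="gene_id")
    counts_total = CountMatrix(
        pd.DataFrame(total_mat, index=gene_index, columns=[r["sample_id"] for r in sample_rows]),
        "total",
    )
    counts_1n = CountMatrix(
        pd.DataFrame(c1n, index=gene_index, columns=allo_sample_ids), "1n"
    )
    counts_2n = CountMatrix(
        pd.DataFrame(c2n, index=gene_index, columns=allo_sample_ids), "2n"
    )

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_allocation": allocation,
            "is_1n_biased": [g in set(bias_genes) for g in genes],
            "bias_direction": [
                (
                    "over"
                    if g in set(bias_genes) and config.bias_allocation > NULL_HAPLOID_SHARE
                    else "under" if g in set(bias_genes) else "none"
                )
                for g in genes
            ],
            "is_de": [g in de_pop for g in genes],
            "de_population": [de_pop.get(g, "") for g in genes],
            "de_log2fc": [
                de_sign.get(g, 0) * config.de_log2fc if g in de_pop else 0.0
                for g in genes
            ],
        }
    )
    for pop_name in allo_pops:
        tag = pop_name.replace(" ", "").replace("/", "-")
        truth[f"present_in_1n_{tag}"] = presence[pop_name]
    truth = truth.set_index("gene_id")

    return SimulatedDataset(
        counts_2n=counts_2n,
        counts_1n=counts_1n,
        counts_total=counts_total,
        samples=samples,
        ortholog_maps=ortholog_maps,
        truth=truth,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Ortholog loss followed by count generation, from one base seed."""
    # derived seeds keep loss and counts independent but reproducible
    omap = simulate_ortholog_loss(config, seed=config.seed)
    return simulate_counts(config, omap, seed=config.seed + 1)


def simulate_annotation(
    genes: Sequence[str],
    n_terms_per_category: int = 8,
    mean_terms_per_gene: float = 1.5,
    length_log_mean: float = 7.0,
    length_log_sd: float = 0.4,
    enriched_term: str | None = None,
    enriched_genes: Sequence[str] = (),
    seed: int = 0,
) -> GeneAnnotation:
    """Random gene lengths and GO assignments for enrichment testing.

    Lengths are log-normal (median ~1.1 kb by default).  Terms are assigned
    independently per category with geometric-ish popularity.  When
    ``enriched_term`` is given, every gene in ``enriched_genes`` is
    additionally annotated with it (category BP), creating a known
    enrichment signal.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    lengths = pd.Series(
        np.maximum(150, np.rint(np.exp(rng.normal(length_log_mean, length_log_sd, len(genes))))).astype(int),
        index=pd.Index(genes, name="gene_id"),
        name="length",
    )
    rows = []
    for cat in ("BP", "MF", "CC"):
        terms = [f"GO:{cat}:{i:04d}" for i in range(1, n_terms_per_category + 1)]
        # earlier terms more popular, so term sizes vary
        weights = 1.0 / np.arange(1, n_terms_per_category + 1)
        probs = weights / weights.sum() * mean_terms_per_gene
        probs = np.clip(probs, 0, 1)
        for g in genes:
            hit = rng.random(n_terms_per_category) < probs
            for t, h in zip(terms, hit):
                if h:
                    rows.append({"gene_id": g, "term": t, "category": cat})
    if enriched_term is not None:
        existing = {(r["gene_id"], r["term"]) for r in rows}
        for g in enriched_genes:
            if (g, enriched_term) not in existing:
                rows.append({"gene_id": g, "term": enriched_term, "category": "BP"})
    go = pd.DataFrame(rows, columns=["gene_id", "term", "category"])
    return GeneAnnotation(lengths, go)
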