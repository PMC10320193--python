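"""Config-driven end-to-end run of the subgenome expression analysis.

A single structured (YAML) config drives: simulation (or loading) of the
count data, ortholog handling, haploid-fraction tests, per-sample
2n-vs-1n regression with prediction-interval outliers and per-population
consistency calls, homeolog collapsing, one-vs-rest NB Wald differential
expression, signature calling, GO enrichment and ordination summaries.
Every stage writes TSV artifacts into the output directory and a JSON
manifest records the seed, thresholds and SHA-256 of each artifact, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    CountMatrix,
    OrthologMap,
    read_annotation,
    read_counts,
    read_hits,
    read_ortholog_map,
    read_samples,
    filter_ortholog_hits,
    write_annotation,
    write_counts,
    write_ortholog_map,
    write_samples,
)
from .differential_expression import (
    DEFAULT_FDR,
    DEFAULT_MIN_ABS_LFC,
    SIGNATURE_MIN_ABS_LFC,
    call_de,
    call_signatures,
    nb_wald_de,
)
from .enrichment_summaries import enrich, pca, spearman_matrix
from .normalization import (
    collapse_counts,
    log_transform,
    shared_core_normalize,
    subgenome_library_normalize,
)
from .subgenome_bias import (
    haploid_fraction,
    population_bias_analysis,
    test_fraction_excess,
)
from .synthetic_data import (
    PopulationSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
)

__all__ = ["run_pipeline", "load_config", "DEFAULT_THRESHOLDS"]

log = logging.getLogger("subbias.pipeline")

#: analysis thresholds, all overridable from the config's `thresholds` block
DEFAULT_THRESHOLDS: dict[str, float | None] = {
    "de_fdr": DEFAULT_FDR,
    "de_min_abs_lfc": DEFAULT_MIN_ABS_LFC,
    "signature_min_abs_lfc": SIGNATURE_MIN_ABS_LFC,
    "prediction_level": 0.95,
    "consistency_min_fraction": None,  # None -> design-size thresholds
    "enrichment_padj": 0.1,
    "transfer_min_identity": 85.0,
    "transfer_min_qcov": 0.95,
}


class PipelineConfigError(ValueError):
    """The config is invalid; raised before any stage runs."""


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    return cfg


def _simulation_config(cfg: dict[str, Any]) -> SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    if "seed" not in cfg:
        raise PipelineConfigError("config field 'seed' is mandatory in simulate mode")
    pops = sim.pop("populations", None)
    kwargs: dict[str, Any] = {"seed": int(cfg["seed"])}
    if pops is not None:
        kwargs["populations"] = tuple(
            PopulationSpec(p["name"], p["ploidy_class"], int(p["n_samples"]))
            for p in pops
        )
    for key, value in sim.items():
        kwargs[key] = value
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid simulate block: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config_file: str | Path, outdir: str | Path) -> Path:
    """Run every stage described by the config; returns the output directory.

    The config is validated up front (missing inputs fail before any stage
    runs); if a later stage fails, files written so far are removed.
    """
    t0 = time.monotonic()
    cfg = load_config(config_file)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    mode = cfg.get("mode", "simulate")
    if mode not in ("simulate", "load"):
        raise PipelineConfigError(f"unknown mode {mode!r}")

    # ---- validate everything needed before touching the filesystem
    if mode == "simulate":
        sim_config = _simulation_config(cfg)
    else:
        inputs = cfg.get("inputs", {})
        needed = ["counts_2n", "counts_1n", "counts_total", "samples"]
        if "hits" not in inputs and "orthologs" not in inputs:
            raise PipelineConfigError(
                "load mode requires inputs.orthologs or inputs.hits"
            )
        missing = [k for k in needed if k not in inputs]
        if missing:
            raise PipelineConfigError(f"load mode missing inputs: {missing}")
        for key, p in inputs.items():
            if not Path(p).exists():
                raise PipelineConfigError(f"inputs.{key}: no such file {p!r}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = outdir / name
        _write_tsv(df, path, index=index)
        written.append(path)
        return path

    try:
        # ---- stage: data ------------------------------------------------
        if mode == "simulate":
            log.info("stage=simulate seed=%d n_genes=%d", sim_config.seed, sim_config.n_genes)
            data = simulate_dataset(sim_config)
            omap = data.ortholog_maps
            write_counts(data.counts_2n, outdir / "counts_2n.tsv")
            write_counts(data.counts_1n, outdir / "counts_1n.tsv")
            write_counts(data.counts_total, outdir / "counts_total.tsv")
            write_samples(data.samples, outdir / "samples.tsv")
            write_ortholog_map(omap, outdir / "ortholog_map.tsv")
            emit(data.truth, "truth.tsv")
            written += [
                outdir / n
                for n in (
                    "counts_2n.tsv", "counts_1n.tsv", "counts_total.tsv",
                    "samples.tsv", "ortholog_map.tsv",
                )
            ]
            counts_2n, counts_1n = data.counts_2n, data.counts_1n
            counts_total, samples = data.counts_total, data.samples
            ann_cfg = cfg.get("annotation", {})
            de_truth_genes = data.truth.index[data.truth["is_de"]].tolist()
            annotation = simulate_annotation(
                list(counts_total.genes),
                n_terms_per_category=int(ann_cfg.get("n_terms_per_category", 8)),
                enriched_term=("GO:BP:demo-signal" if ann_cfg.get("enrich_de_term", True) and de_truth_genes else None),
                enriched_genes=de_truth_genes,
                seed=sim_config.seed + 2,
            )
            write_annotation(
                annotation, outdir / "gene_lengths.tsv", outdir / "gene_go.tsv"
            )
            written += [outdir / "gene_lengths.tsv", outdir / "gene_go.tsv"]
        else:
            inputs = cfg["inputs"]
            counts_2n = read_counts(inputs["counts_2n"], "2n")
            counts_1n = read_counts(inputs["counts_1n"], "1n")
            counts_total = read_counts(inputs["counts_total"], "total")
            samples = read_samples(inputs["samples"])
            if "orthologs" in inputs:
                omap = read_ortholog_map(inputs["orthologs"])
            else:
                log.info("stage=transfer-filter hits=%s", inputs["hits"])
                omap = filter_ortholog_hits(
                    read_hits(inputs["hits"]),
                    min_identity=thresholds["transfer_min_identity"],
                    min_query_coverage=thresholds["transfer_min_qcov"],
                )
                write_ortholog_map(omap, outdir / "ortholog_map.tsv")
                written.append(outdir / "ortholog_map.tsv")
            annotation = None
            if "gene_lengths" in inputs and "gene_go" in inputs:
                annotation = read_annotation(inputs["gene_lengths"], inputs["gene_go"])

        allo_pops = [p for p in samples.allotriploid_populations() if p in omap]
        shared = omap.shared_core(allo_pops)
        log.info("stage=orthologs populations=%d shared_core=%d", len(allo_pops), len(shared))

        # ---- stage: haploid fractions -----------------------------------
        frac_rows = []
        for pop in allo_pops:
            for sid in samples.samples_in(pop):
                frac_rows.append(
                    {
                        "sample_id": sid,
                        "population": pop,
                        "haploid_fraction": haploid_fraction(
                            counts_2n, counts_1n, omap, sid, pop
                        ),
                    }
                )
        fractions = pd.DataFrame(frac_rows)
        emit(fractions, "haploid_fractions.tsv", index=False)

        ztest_rows = []
        for pop in allo_pops:
            f = fractions.loc[fractions["population"] == pop, "haploid_fraction"]
            z, p = test_fraction_excess(f.to_numpy())
            ztest_rows.append({"population": pop, "z": z, "p_one_sided": p})
        emit(pd.DataFrame(ztest_rows), "fraction_excess_tests.tsv", index=False)

        # ---- stage: per-sample regression & consistent bias --------------
        consistent_tables = []
        call_tables = []
        for pop in allo_pops:
            calls, consistent = population_bias_analysis(
                counts_2n, counts_1n, omap, samples, pop,
                level=float(thresholds["prediction_level"]),
                min_fraction=thresholds["consistency_min_fraction"],
            )
            call_tables.append(calls)
            consistent_tables.append(consistent)
        if call_tables:
            emit(pd.concat(call_tables, ignore_index=True), "bias_calls.tsv", index=False)
            emit(pd.concat(consistent_tables), "consistent_bias.tsv")
            n_called = sum((t["call"] != "none").sum() for t in consistent_tables)
            log.info("stage=bias consistent_calls=%d", int(n_called))

        # ---- stage: collapse + DE + signatures ----------------------------
        allo_samples = [s for p in allo_pops for s in samples.samples_in(p)]
        collapsed = collapse_counts(
            CountMatrix(counts_2n.df[allo_samples], "2n"),
            CountMatrix(counts_1n.df[allo_samples], "1n"),
            omap,
            samples,
        )
        other_samples = [s for s in samples.sample_ids if s not in allo_samples]
        combined = pd.concat(
            [collapsed.df, counts_total.df[other_samples]], axis=1
        )[samples.sample_ids]
        emit(combined, "counts_collapsed.tsv")

        de_tables = {}
        sig_tables = []
        de_summary = []
        for pop in samples.populations:
            de = nb_wald_de(combined, samples, pop)
            de_tables[pop] = de
            tag = pop.replace(" ", "").replace("/", "-")
            emit(de, f"de_{tag}.tsv")
            called = call_de(
                de,
                fdr=float(thresholds["de_fdr"]),
                min_abs_lfc=float(thresholds["de_min_abs_lfc"]),
            )
            sigs = call_signatures(
                de, called, min_abs_lfc=float(thresholds["signature_min_abs_lfc"])
            )
            sigs = sigs.assign(population=pop)
            sig_tables.append(sigs)
            de_summary.append(
                {"population": pop, "n_de": len(called), "n_signatures": len(sigs)}
            )
            log.info("stage=de population=%s n_de=%d n_signatures=%d", pop, len(called), len(sigs))
        emit(pd.DataFrame(de_summary), "de_summary.tsv", index=False)
        emit(pd.concat(sig_tables), "signatures.tsv")

        # ---- stage: enrichment -------------------------------------------
        if annotation is not None:
            universe = list(combined.index)
            enr_tables = []
            for pop in samples.populations:
                called = call_de(
                    de_tables[pop],
                    fdr=float(thresholds["de_fdr"]),
                    min_abs_lfc=float(thresholds["de_min_abs_lfc"]),
                )
                enr = enrich(called.index.tolist(), annotation, universe)
                enr_tables.append(enr.assign(population=pop))
            emit(pd.concat(enr_tables, ignore_index=True), "enrichment.tsv", index=False)

        # ---- stage: ordination -------------------------------------------
        if shared and allo_samples:
            acq = shared_core_normalize(counts_1n.df[allo_samples], shared)
            scores, _, var = pca(log_transform(acq))
            scores["variance_explained"] = np.nan
            scores.iloc[: len(var), scores.columns.get_loc("variance_explained")] = var
            emit(scores, "pca_acquired_scores.tsv")
        cpm = subgenome_library_normalize(combined)
        scores_all, _, var_all = pca(log_transform(cpm))
        scores_all["variance_explained"] = np.nan
        scores_all.iloc[: len(var_all), scores_all.columns.get_loc("variance_explained")] = var_all
        emit(scores_all, "pca_collapsed_scores.tsv")
        emit(spearman_matrix(cpm), "spearman_collapsed.tsv")

        # ---- manifest -----------------------------------------------------
        manifest = {
            "package": "subbias",
            "version": __version__,
            "seed": cfg.get("seed"),
            "mode": mode,
            "thresholds": thresholds,
            "outputs": {
                p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
                for p in sorted(set(written))
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        log.info("pipeline done in %.1fs, %d artifacts", time.monotonic() - t0, len(written))
        return outdir
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (outdir / "manifest.json").unlink(missing_ok=True)
        raise
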