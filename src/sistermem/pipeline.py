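"""End-to-end workflows: generation-1 qPCR, generation-1/2 RNA-seq and the
all-synthetic demonstration run.

Each workflow writes a report bundle to the output directory: the
serialized configuration, pair counts, per-pair distances with their
relation class, distance summaries, subsampling null distributions, the
memory-gene table, a negative-control summary and a machine-readable run
log.  Optional plots mirror the standard figures (distance boxplots, null
histograms, ICC densities, abundance ECDFs).  All randomness derives from
the single config seed, so re-running a workflow with the same config and
inputs reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import distances as dist
from . import io as smio
from . import lineage, memory, qpcr, rnaseq
from .simulate import (
    SimulationConfig,
    simulate_ct_table,
    simulate_expression,
    simulate_fluorescence,
    simulate_pedigree,
)

logger = logging.getLogger(__name__)

WORKFLOWS = ("gen1_qpcr", "gen1_rnaseq", "gen2_rnaseq", "synthetic_demo")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    workflow: str
    outdir: str
    seed: int = 0
    metrics: tuple[str, ...] = ("manhattan", "euclidean")
    B: int = 1000
    alpha: float = 0.05
    plots: bool = False
    # file inputs (per workflow; unused ones stay None)
    ct_prefix: str | None = None
    counts_path: str | None = None
    pedigree_path: str | None = None
    fluorescence_path: str | None = None
    covariates_path: str | None = None
    covariates: tuple[str, ...] = ()
    normalize: bool = True
    # synthetic_demo
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"workflow must be one of {WORKFLOWS}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(log: list, name: str, fn, *args, **kw):
    try:
        result = fn(*args, **kw)
    except Exception as exc:
        log.append({"stage": name, "status": "failed", "error": str(exc)})
        raise StageError(name, exc) from exc
    log.append({"stage": name, "status": "ok"})
    return result


def run_workflow(cfg: RunConfig) -> dict:
    """Execute a workflow and write its report bundle.

    Returns a dictionary of the in-memory results (pair counts, distance
    summaries, nulls, memory-gene table, ...).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []

    serializable = dataclasses.asdict(cfg)
    (outdir / "config.yaml").write_text(yaml.safe_dump(serializable))

    if cfg.workflow == "synthetic_demo":
        adata, ped, counts_layer = _stage(run_log, "simulate", _synthetic_inputs, cfg)
    elif cfg.workflow == "gen1_qpcr":
        adata, ped, counts_layer = _stage(run_log, "qpcr_preprocess", _qpcr_inputs, cfg)
    elif cfg.workflow == "gen1_rnaseq":
        adata, ped, counts_layer = _stage(
            run_log, "rnaseq_preprocess", _rnaseq_inputs, cfg, generation=1
        )
    else:  # gen2_rnaseq
        adata, ped, counts_layer = _stage(
            run_log, "lineage_and_preprocess", _gen2_inputs, cfg
        )

    results = _stage(run_log, "analysis", _analyze, cfg, adata, ped, counts_layer)
    _stage(run_log, "report", _write_report, cfg, outdir, results, adata)
    if cfg.plots:
        _stage(run_log, "plots", _write_plots, outdir, results)

    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return results


# -- input stages -----------------------------------------------------------

def _synthetic_inputs(cfg: RunConfig):
    sim = cfg.sim.with_(seed=cfg.sim.seed if cfg.sim.seed else cfg.seed)
    ped = simulate_pedigree(sim)
    adata = simulate_expression(ped, sim)
    counts = None
    if sim.count_model == "negative_binomial":
        counts = adata.copy()
        adata = ad.AnnData(X=adata.layers["latent"], obs=adata.obs, var=adata.var)
    return adata, ped, counts


def _qpcr_inputs(cfg: RunConfig):
    if cfg.ct_prefix is None or cfg.pedigree_path is None:
        raise ValueError("gen1_qpcr needs ct_prefix and pedigree_path")
    table = smio.read_ct_csv(cfg.ct_prefix)
    ped = smio.read_pedigree_tsv(cfg.pedigree_path)
    table = qpcr.qc_filter_ct(table)
    adata = qpcr.normalize_ct(table)
    adata = adata[adata.obs_names.isin(ped["cell_id"])].copy()
    adata = rnaseq.remove_orphans(adata, ped)  # spike failures can orphan a cell
    ped = ped.loc[ped["cell_id"].isin(adata.obs_names)]
    adata.obs = adata.obs.join(ped.drop(columns=["cell_id"]))
    adata.obs["cell_id"] = adata.obs_names
    return adata, ped, None


def _read_counts(cfg: RunConfig) -> ad.AnnData:
    path = Path(cfg.counts_path)
    if path.is_dir():
        return smio.read_expression_mtx(path)
    return smio.read_expression_tsv(path)


def _rnaseq_inputs(cfg: RunConfig, generation: int, ped: pd.DataFrame | None = None):
    if cfg.counts_path is None:
        raise ValueError("rnaseq workflows need counts_path")
    adata = _read_counts(cfg)
    if ped is None:
        if cfg.pedigree_path is None:
            raise ValueError("gen1_rnaseq needs pedigree_path")
        ped = smio.read_pedigree_tsv(cfg.pedigree_path)
    if cfg.covariates_path:
        cov = smio.read_covariates_csv(cfg.covariates_path)
        adata.obs = adata.obs.join(cov)

    metrics = rnaseq.compute_cell_qc_metrics(adata)
    qc = rnaseq.cell_qc_thresholds(metrics)
    adata = adata[qc.keep].copy()
    adata = adata[adata.obs_names.isin(ped["cell_id"])].copy()
    adata = rnaseq.remove_orphans(adata, ped)
    kept_genes = rnaseq.filter_genes_mean_expression(adata)
    adata = adata[:, kept_genes].copy()
    counts = adata.copy()
    if cfg.normalize:
        adata = rnaseq.normalize_counts(adata, covariates=list(cfg.covariates))
    ped = ped.loc[ped["cell_id"].isin(adata.obs_names)]
    for col in ped.columns:
        if col not in adata.obs:
            adata.obs[col] = ped.loc[adata.obs_names, col]
    return adata, ped, counts


def _gen2_inputs(cfg: RunConfig):
    if cfg.fluorescence_path is None:
        raise ValueError("gen2_rnaseq needs fluorescence_path")
    fluo = smio.read_fluorescence_csv(cfg.fluorescence_path)
    assignments = lineage.infer_lineage(fluo, seed=cfg.seed)
    retained = assignments[assignments["retained"]]
    ped = pd.DataFrame(
        {
            "cell_id": retained["cell_id"],
            "family_id": retained["inferred_family_id"],
            "sister_pair_id": retained["inferred_sister_pair_id"],
            "generation": 2,
        }
    )
    if cfg.covariates_path:
        cov = smio.read_covariates_csv(cfg.covariates_path)
        ped = ped.join(cov[["condition"]], on="cell_id")
    elif cfg.pedigree_path:
        true_ped = smio.read_pedigree_tsv(cfg.pedigree_path)
        ped["condition"] = true_ped.reindex(ped.index)["condition"]
    else:
        ped["condition"] = "self_renewing"
    return _rnaseq_inputs(cfg, generation=2, ped=ped)


# -- analysis ---------------------------------------------------------------

def _conditions_with_pairs(ped: pd.DataFrame) -> list[str]:
    out = []
    for cond in pd.unique(ped["condition"]):
        counts = dist.count_pairs(ped, cond)
        if counts["sister"] >= 3 and counts["non_related"] >= counts["sister"]:
            out.append(cond)
    return out


def _analyze(cfg: RunConfig, adata: ad.AnnData, ped: pd.DataFrame, counts) -> dict:
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)
    pairwise_complete = bool(np.isnan(np.asarray(adata.X, dtype=float)).any())

    pair_counts = {c: dist.count_pairs(ped, c) for c in pd.unique(ped["condition"])}
    relations = [r for r in dist.RELATIONS if any(
        pc[r] > 0 for pc in pair_counts.values()
    )]

    summaries, comparisons, nulls, pair_tables = [], [], {}, {}
    for cond in _conditions_with_pairs(ped):
        cells = ped.loc[ped["condition"] == cond, "cell_id"]
        sub = adata[adata.obs_names.isin(cells)]
        for metric in cfg.metrics:
            dm = dist.pairwise_distances(
                sub, metric=metric, pairwise_complete=pairwise_complete
            )
            per_relation = {}
            for rel in relations:
                if pair_counts[cond][rel] == 0:
                    continue
                rd = dist.mean_distance_by_relation(dm, ped, rel, cond, metric)
                per_relation[rel] = rd
                summaries.append(
                    {
                        "condition": cond,
                        "metric": metric,
                        "relation": rel,
                        "mean": rd.mean,
                        "median": rd.median,
                        "n": rd.n,
                    }
                )
            pair_tables[(cond, metric)] = pd.concat(
                [
                    rd.pairs.assign(relation=rel, condition=cond, metric=metric)
                    for rel, rd in per_relation.items()
                ]
            )
            for rel in ("sister", "cousin"):
                if rel not in per_relation:
                    continue
                cmp_res = dist.compare_means(
                    per_relation[rel].distances,
                    per_relation["non_related"].distances,
                    alpha=cfg.alpha,
                )
                comparisons.append(
                    {
                        "condition": cond,
                        "metric": metric,
                        "relation": rel,
                        "test": cmp_res.test,
                        "statistic": cmp_res.statistic,
                        "pvalue": cmp_res.pvalue,
                        "mean_related": cmp_res.mean_a,
                        "mean_non_related": cmp_res.mean_b,
                    }
                )
                null = dist.subsample_null(
                    dm,
                    ped,
                    relation_observed=rel,
                    condition=cond,
                    B=cfg.B,
                    seed=int(seeds[0]),
                )
                nulls[(cond, metric, rel)] = null

    memory_table = memory.detect_memory_genes(adata, alpha=cfg.alpha)
    _, n_detected_random = memory.negative_control_random_pairing(
        adata, seed=int(seeds[1]), alpha=cfg.alpha
    )

    abundance = None
    memory_set = memory_table.index[memory_table["memory"]]
    if counts is not None and 0 < len(memory_set) < counts.n_vars:
        abundance = memory.abundance_enrichment(memory_set, counts)

    return {
        "pair_counts": pair_counts,
        "summaries": pd.DataFrame(summaries),
        "comparisons": pd.DataFrame(comparisons),
        "nulls": nulls,
        "pair_tables": pair_tables,
        "memory_genes": memory_table,
        "n_memory": int(memory_table["memory"].sum()),
        "n_memory_random_pairing": n_detected_random,
        "abundance": abundance,
    }


# -- report -----------------------------------------------------------------

def _write_report(cfg: RunConfig, outdir: Path, results: dict, adata) -> None:
    pd.DataFrame(results["pair_counts"]).T.rename_axis("condition").to_csv(
        outdir / "pair_counts.csv"
    )
    results["summaries"].to_csv(outdir / "distance_summary.csv", index=False)
    results["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    results["memory_genes"].to_csv(outdir / "memory_genes.csv", index=False)
    for (cond, metric), table in results["pair_tables"].items():
        table.to_csv(outdir / f"distances_{metric}_{cond}.csv", index=False)
    null_rows = []
    for (cond, metric, rel), null in results["nulls"].items():
        pd.DataFrame({"mean_distance": null.mean_distances}).to_csv(
            outdir / f"null_{metric}_{cond}_{rel}.csv", index=False
        )
        null_rows.append(
            {
                "condition": cond,
                "metric": metric,
                "relation": rel,
                "observed_mean": null.observed_mean,
                "empirical_p": null.empirical_p,
                "B": null.B,
                "subsample_size": null.subsample_size,
            }
        )
    pd.DataFrame(null_rows).to_csv(outdir / "subsample_nulls.csv", index=False)
    summary = {
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "n_memory_genes": results["n_memory"],
        "n_memory_random_pairing": results["n_memory_random_pairing"],
    }
    if results["abundance"] is not None:
        summary["abundance_ks_p"] = results["abundance"]["ks_p"]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _write_plots(outdir: Path, results: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir = outdir / "plots"
    plotdir.mkdir(exist_ok=True)

    for (cond, metric), table in results["pair_tables"].items():
        fig, axis = plt.subplots(figsize=(4, 3))
        groups = [g["distance"].to_numpy() for _, g in table.groupby("relation")]
        labels = [str(r) for r, _ in table.groupby("relation")]
        axis.boxplot(groups, tick_labels=labels)
        axis.set_ylabel(f"{metric} distance")
        axis.set_title(cond)
        fig.tight_layout()
        fig.savefig(plotdir / f"boxplot_{metric}_{cond}.png", dpi=100)
        plt.close(fig)

    for (cond, metric, rel), null in results["nulls"].items():
        fig, axis = plt.subplots(figsize=(4, 3))
        axis.hist(null.mean_distances, bins=40, color="seagreen")
        axis.axvline(null.observed_mean, color="darkorange")
        axis.set_xlabel(f"mean {metric} distance ({cond}, {rel}-matched)")
        fig.tight_layout()
        fig.savefig(plotdir / f"null_{metric}_{cond}_{rel}.png", dpi=100)
        plt.close(fig)

    table = results["memory_genes"]
    fig, axis = plt.subplots(figsize=(4, 3))
    axis.hist(table["icc"], bins=40, density=True, color="darkseagreen")
    axis.set_xlabel("intraclass correlation")
    fig.tight_layout()
    fig.savefig(plotdir / "icc_density.png", dpi=100)
    plt.close(fig)

    if results["abundance"] is not None:
        ab = results["abundance"]
        fig, axis = plt.subplots(figsize=(4, 3))
        for key, label in (("ecdf_memory", "memory"), ("ecdf_all", "all")):
            x = ab[key]
            axis.step(np.sort(x), np.arange(1, len(x) + 1) / len(x), label=label)
        axis.set_xscale("log")
        axis.set_xlabel("total abundance")
        axis.legend()
        fig.tight_layout()
        fig.savefig(plotdir / "abundance_ecdf.png", dpi=100)
        plt.close(fig)
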