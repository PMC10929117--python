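"""Readers and writers for the pipeline's on-disk formats.

Expression goes to MTX (with genes/cells TSV sidecars) or dense TSV;
fluorescence and Ct tables to CSV; pedigrees to TSV; configs to YAML.
All formats are plain text.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import CtParams, CtTable, DyeParams, SimulationConfig

PEDIGREE_COLUMNS = ["cell_id", "family_id", "sister_pair_id", "generation", "condition"]


# -- pedigree ---------------------------------------------------------------

def write_pedigree_tsv(ped: pd.DataFrame, path) -> None:
    ped[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"generation": int})
    ped = ped.set_index("cell_id", drop=False)
    ped.index.name = None
    return ped


# -- expression -------------------------------------------------------------

def write_expression_mtx(adata: ad.AnnData, outdir) -> None:
    """MTX matrix (cells x genes) plus cells.tsv / genes.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(np.asarray(adata.X)))
    pd.Series(adata.obs_names).to_csv(
        outdir / "cells.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")


def read_expression_mtx(outdir) -> ad.AnnData:
    outdir = Path(outdir)
    X = np.asarray(spio.mmread(outdir / "matrix.mtx").todense())
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t", header=None)[0]
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(cells, name=None).astype(str))
    meta = outdir / "cell_metadata.tsv"
    if meta.exists():
        obs = pd.read_csv(meta, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name=None).astype(str))
    )


def write_expression_tsv(adata: ad.AnnData, path) -> None:
    """Dense cells x genes TSV with header row of gene names."""
    pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    ).to_csv(path, sep="\t")


def read_expression_tsv(path) -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ad.AnnData(
        X=df.to_numpy(dtype=float),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


# -- fluorescence -----------------------------------------------------------

def write_fluorescence_csv(fluo: pd.DataFrame, path) -> None:
    fluo[["cell_id", "cfse", "cty", "ctv", "ctfr", "well"]].to_csv(path, index=False)


def read_fluorescence_csv(path) -> pd.DataFrame:
    fluo = pd.read_csv(path, float_precision="round_trip").set_index(
        "cell_id", drop=False
    )
    fluo.index.name = None
    return fluo


# -- Ct tables --------------------------------------------------------------

def write_ct_csv(t: CtTable, prefix) -> None:
    """Write <prefix>_ct.csv, <prefix>_flags.csv and (if present)
    <prefix>_negctrl.csv.  First column gene name, header row of cell ids;
    spike rows are named ``spike1``/``spike4``."""
    prefix = str(prefix)
    t.values.to_csv(prefix + "_ct.csv", index_label="gene")
    t.flags.to_csv(prefix + "_flags.csv", index_label="gene")
    if t.negative_controls is not None:
        t.negative_controls.to_csv(prefix + "_negctrl.csv", index_label="gene")


def read_ct_csv(prefix) -> CtTable:
    prefix = str(prefix)
    values = pd.read_csv(
        prefix + "_ct.csv", index_col="gene", float_precision="round_trip"
    )
    flags = pd.read_csv(prefix + "_flags.csv", index_col="gene")
    neg_path = Path(prefix + "_negctrl.csv")
    neg = (
        pd.read_csv(neg_path, index_col="gene", float_precision="round_trip")
        if neg_path.exists()
        else None
    )
    return CtTable(values=values, flags=flags, negative_controls=neg)


# -- covariates -------------------------------------------------------------

def read_covariates_csv(path) -> pd.DataFrame:
    """Per-cell covariate table (batch, day, medium, depth ...) keyed by cell_id."""
    cov = pd.read_csv(path)
    if "cell_id" not in cov.columns:
        raise ValueError("covariate CSV needs a 'cell_id' column")
    return cov.set_index("cell_id")


# -- config -----------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def config_from_yaml(path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "dye_params" in raw and isinstance(raw["dye_params"], dict):
        dye = dict(raw["dye_params"])
        if "cfse_levels" in dye:
            dye["cfse_levels"] = tuple(dye["cfse_levels"])
        raw["dye_params"] = DyeParams(**dye)
    if "ct_params" in raw and isinstance(raw["ct_params"], dict):
        raw["ct_params"] = CtParams(**raw["ct_params"])
    if "conditions" in raw:
        raw["conditions"] = tuple(raw["conditions"])
    return SimulationConfig(**raw)
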