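"""Cell/gene filtering and normalization of UMI count matrices.

Cells are filtered on reads, detected genes, total counts and ERCC
spike-in content using mean - 3*sd cutoffs (upper cutoff for the ERCC
fraction, where *high* values indicate poor-quality cells); orphan cells
whose sister (or any cousin of the quartet) dropped out are removed so the
pedigree stays complete.  Genes are kept when their total UMI count is at
least the number of cells.  Normalization regresses each gene's counts on
log sequencing depth and the experimental covariates with a regularized
negative-binomial model and returns clipped Pearson residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import validate_pedigree

logger = logging.getLogger(__name__)

ERCC_PREFIX = "ERCC-"
QC_METRICS = ("reads", "genes", "counts", "ercc_frac")


def compute_cell_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC metrics from a raw count matrix.

    ``reads`` is taken from ``obs["reads"]`` when the mapping pipeline
    provided it, otherwise it falls back to total counts.  ERCC spike-in
    genes are recognized by the ``ERCC-`` name prefix.
    """
    X = np.asarray(adata.X, dtype=float)
    is_ercc = adata.var_names.str.startswith(ERCC_PREFIX)
    total = X.sum(axis=1)
    ercc = X[:, is_ercc].sum(axis=1) if is_ercc.any() else np.zeros(len(X))
    metrics = pd.DataFrame(
        {
            "reads": adata.obs["reads"].to_numpy(dtype=float)
            if "reads" in adata.obs
            else total,
            "genes": (X > 0).sum(axis=1).astype(float),
            "counts": total,
            "ercc_frac": np.divide(
                ercc, total, out=np.zeros_like(ercc), where=total > 0
            ),
        },
        index=adata.obs_names,
    )
    return metrics


@dataclass
class CellQC:
    """Result of the mean - 3*sd cell filter."""

    cutoffs: dict[str, float]
    keep: pd.Series
    #: per cell and metric, True where the cell fails that criterion
    reasons: pd.DataFrame


def cell_qc_thresholds(
    metrics: pd.DataFrame, ercc_upper: bool = True
) -> CellQC:
    """Compute mean - 3*sd cutoffs and apply them.

    Cells below the cutoff on reads, detected genes or total counts are
    removed.  The ERCC fraction is by default filtered with an *upper*
    cutoff mean + 3*sd (high spike fraction = degraded cell); pass
    ``ercc_upper=False`` for the literal lower-cutoff reading.  Every
    removal decision is recorded in ``reasons``.
    """
    if len(metrics) < 2:
        raise ValueError("cell QC needs at least 2 cells (sd undefined)")
    cutoffs: dict[str, float] = {}
    reasons = pd.DataFrame(False, index=metrics.index, columns=list(QC_METRICS))
    for m in ("reads", "genes", "counts"):
        cut = metrics[m].mean() - 3.0 * metrics[m].std(ddof=1)
        cutoffs[m] = float(cut)
        reasons[m] = metrics[m] < cut
    if ercc_upper:
        cut = metrics["ercc_frac"].mean() + 3.0 * metrics["ercc_frac"].std(ddof=1)
        reasons["ercc_frac"] = metrics["ercc_frac"] > cut
    else:
        cut = metrics["ercc_frac"].mean() - 3.0 * metrics["ercc_frac"].std(ddof=1)
        reasons["ercc_frac"] = metrics["ercc_frac"] < cut
    cutoffs["ercc_frac"] = float(cut)
    keep = ~reasons.any(axis=1)
    for cell in metrics.index[~keep]:
        failed = [m for m in QC_METRICS if reasons.at[cell, m]]
        logger.info("cell %s removed by QC (%s)", cell, ", ".join(failed))
    return CellQC(cutoffs=cutoffs, keep=keep, reasons=reasons)


def remove_orphans(adata: ad.AnnData, ped: pd.DataFrame) -> ad.AnnData:
    """Drop cells whose relatives did not survive filtering.

    Generation 1: keep only complete sister pairs.  Generation 2: keep
    only complete 4-cell cousin families.  The pedigree must cover every
    cell of ``adata``.
    """
    validate_pedigree(ped)
    missing = set(adata.obs_names) - set(ped["cell_id"])
    if missing:
        raise ValueError(f"pedigree does not cover cells {sorted(missing)[:5]} ...")
    sub = ped.loc[ped["cell_id"].isin(adata.obs_names)]
    generation = int(sub["generation"].iloc[0])
    if generation == 1:
        sizes = sub.groupby("sister_pair_id")["cell_id"].transform("size")
        keep_cells = sub.loc[sizes == 2, "cell_id"]
    else:
        sizes = sub.groupby("family_id")["cell_id"].transform("size")
        keep_cells = sub.loc[sizes == 4, "cell_id"]
    dropped = len(sub) - len(keep_cells)
    if dropped:
        logger.info("removed %d orphan cells", dropped)
    return adata[adata.obs_names.isin(keep_cells)].copy()


def filter_genes_mean_expression(adata: ad.AnnData) -> pd.Index:
    """Genes expressed on average at least once per cell.

    Keeps gene g iff its total UMI count is at least the number of cells
    (e.g. with 100 cells the threshold is 100 UMIs).  Returns the kept
    gene index; subset with ``adata[:, kept]``.
    """
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=0)
    kept = adata.var_names[totals >= adata.n_obs]
    logger.info(
        "gene filter: kept %d of %d genes (threshold %d UMIs)",
        len(kept),
        adata.n_vars,
        adata.n_obs,
    )
    return kept


def _design_matrix(
    obs: pd.DataFrame, covariates: list[str], depth: np.ndarray
) -> np.ndarray:
    cols = [np.ones(len(obs)), np.log(depth)]
    for cov in covariates:
        values = obs[cov]
        if pd.api.types.is_numeric_dtype(values):
            cols.append(values.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(values, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def normalize_counts(
    adata: ad.AnnData,
    covariates: list[str] | None = None,
    clip: float | None = None,
) -> ad.AnnData:
    """Covariate-corrected variance-stabilizing normalization.

    Per gene, counts are regressed on log total depth plus the given
    categorical/numeric covariates with a Poisson GLM; the per-gene
    negative-binomial dispersion is then estimated by moments and
    regularized by lowess smoothing against log10 mean expression, and the
    output is the NB Pearson residual (y - mu) / sqrt(mu + mu^2/theta),
    clipped at +/- sqrt(n_cells).

    Residuals of a well-specified gene have approximately zero mean, unit
    variance and no linear dependence on the regressed covariates.  Genes
    whose fit fails (constant counts, covariate spanning the gene's whole
    support) get residuals 0 and are logged.
    """
    covariates = covariates or []
    Y = np.asarray(adata.X, dtype=float)
    n, G = Y.shape
    depth = Y.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("cells with zero total counts; filter cells first")
    X = _design_matrix(adata.obs, covariates, depth)
    clip = float(np.sqrt(n)) if clip is None else clip

    mu = np.zeros_like(Y)
    ok = np.zeros(G, dtype=bool)
    for j in range(G):
        y = Y[:, j]
        if y.max() == y.min():
            continue
        try:
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite GLM coefficients")
            mu[:, j] = fit.mu
            ok[j] = True
        except Exception as exc:  # confounded / separated genes
            logger.info("normalization failed for gene %s: %s", adata.var_names[j], exc)

    # moment estimate of the NB dispersion, regularized across genes
    resid2 = (Y - mu) ** 2
    denom = (resid2 - mu).sum(axis=0)
    num = (mu**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom > 0, num / denom, np.inf)
    theta_reg = _regularize_theta(theta, Y.mean(axis=0), ok)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom_var = mu + mu**2 / theta_reg[None, :]
        resid = np.where(denom_var > 0, (Y - mu) / np.sqrt(denom_var), 0.0)
    resid[:, ~ok] = 0.0
    resid = np.clip(resid, -clip, clip)

    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = resid
    out.var["nb_theta"] = theta_reg
    out.var["normalization_ok"] = ok
    return out


def _regularize_theta(
    theta: np.ndarray, gene_mean: np.ndarray, ok: np.ndarray
) -> np.ndarray:
    """Smooth log dispersion against log mean expression across genes."""
    finite = ok & np.isfinite(theta) & (theta > 0)
    if finite.sum() < 10:
        return theta
    x = np.log10(gene_mean[finite])
    z = np.log10(np.clip(theta[finite], 1e-8, 1e8))
    smoothed = lowess(z, x, frac=0.5, return_sorted=False)
    out = theta.copy()
    out[finite] = 10.0 ** smoothed
    # genes with an infinite raw estimate (under-dispersed): interpolate on
    # the smoothed trend
    needs = ok & ~finite
    if needs.any():
        order = np.argsort(x)
        out[needs] = 10.0 ** np.interp(
            np.log10(np.maximum(gene_mean[needs], 1e-12)), x[order],
            smoothed[order],
        )
    return out
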