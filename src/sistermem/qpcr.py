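"""Quality control and spike-based normalization of scRT-qPCR Ct tables.

Readings flagged "failed" by the instrument software are blanked; genes
that amplify in any water-only negative-control well are removed.
Expression is then the spike geometric mean minus the gene Ct, floored at
-22 (the conventional null-signal value for this assay).
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

from .simulate import CtTable

logger = logging.getLogger(__name__)

#: differential Ct assigned to null signal
NULL_SIGNAL = -22.0


def qc_filter_ct(t: CtTable) -> CtTable:
    """Apply instrument QC to a Ct table.

    Failed readings become missing (NaN) and keep flowing as missing
    through normalization.  Any gene with amplification (a finite Ct) in
    at least one negative-control well is removed entirely.  If the table
    carries no negative-control annotation the gene-removal step is
    skipped with a warning.
    """
    out = t.copy()
    failed = out.flags == "failed"
    n_failed = int(failed.to_numpy().sum())
    if n_failed:
        out.values = out.values.mask(failed)
        logger.info("blanked %d failed readings", n_failed)

    if out.negative_controls is None:
        logger.warning(
            "no negative-control wells annotated; skipping contamination "
            "gene removal"
        )
        return out

    genes = out.gene_names()
    amplified = out.negative_controls.loc[genes].notna().any(axis=1)
    bad_genes = amplified[amplified].index.tolist()
    if bad_genes:
        logger.info(
            "removing %d genes amplifying in negative controls: %s",
            len(bad_genes),
            bad_genes,
        )
        keep = [g for g in out.values.index if g not in bad_genes]
        out.values = out.values.loc[keep]
        out.flags = out.flags.loc[keep]
        out.negative_controls = out.negative_controls.loc[keep]
    return out


def normalize_ct(t: CtTable, floor: float = NULL_SIGNAL) -> ad.AnnData:
    """Spike-normalize a Ct table into expression values.

    For each cell, expression(g) = geomean(Ct_spike1, Ct_spike4) - Ct_g,
    with values below ``floor`` (default -22) set to the floor.  Missing
    readings stay missing.  The geometric mean is taken of the Ct values
    themselves, so nonpositive spike Cts are rejected.

    Returns an AnnData of cells x genes (spike rows dropped).
    """
    for s in CtTable.SPIKE_ROWS:
        if s not in t.values.index:
            raise ValueError(f"spike row {s!r} missing from Ct table")
    spikes = t.values.loc[list(CtTable.SPIKE_ROWS)].to_numpy(dtype=float)
    if np.any(spikes[np.isfinite(spikes)] <= 0):
        raise ValueError(
            "spike Ct values must be positive for the geometric mean"
        )
    usable = np.isfinite(spikes).all(axis=0)
    if not usable.all():
        dropped = list(t.values.columns[~usable])
        logger.warning(
            "dropping %d cells with failed/missing spike readings: %s",
            len(dropped),
            dropped,
        )
    t = CtTable(
        values=t.values.loc[:, usable],
        flags=t.flags.loc[:, usable],
        negative_controls=t.negative_controls,
    )
    spikes = spikes[:, usable]
    geomean = np.exp(np.mean(np.log(spikes), axis=0))  # per cell

    genes = t.gene_names()
    ct = t.values.loc[genes].to_numpy(dtype=float)
    expr = geomean[None, :] - ct
    expr = np.where(np.isnan(expr), np.nan, np.maximum(expr, floor))

    adata = ad.AnnData(
        X=expr.T,
        obs=pd.DataFrame(index=t.values.columns),
        var=pd.DataFrame(index=pd.Index(genes, name=None)),
    )
    adata.obs["spike_geomean"] = geomean
    return adata
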