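"""Gene-wise mixed-model detection of memory genes.

A memory gene varies across sister pairs but is correlated within them.
Per gene the model is

    y = X beta + b_pair + eps,   b_pair ~ N(0, sigma_b^2),  eps ~ N(0, sigma_e^2)

with an intercept (plus a condition fixed effect when both conditions are
present) and a pair-level random intercept — the "sorority effect".  The
model is estimated by REML; testing sigma_b^2 = 0 is a likelihood ratio
test of the restricted likelihoods of the full model and the null model
with identical fixed effects, referred to chi-square(1) by default (the
50:50 chi0/chi1 boundary mixture is available as an option).  Gene-wise
p-values are Benjamini-Hochberg adjusted and a gene is called "memory"
when its adjusted p-value falls below alpha.

For the balanced design of exactly two cells per pair with pair-constant
fixed effects the REML solution is available in closed form: transforming
each pair to its scaled sum s = (y1+y2)/sqrt(2) and difference
d = (y1-y2)/sqrt(2) diagonalizes the covariance (var(s) = sigma_e^2 +
2 sigma_b^2, var(d) = sigma_e^2), giving sigma_e^2 = RSS_d / q and
sigma_e^2 + 2 sigma_b^2 = RSS_s / (q - p) truncated at the sigma_b^2 = 0
boundary — which for the no-covariate case is exactly the one-way ANOVA
estimator sigma_b^2 = max(0, (MSB - MSW)/2), sigma_e^2 = MSW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MemoryFit:
    """REML fit of the pair random-intercept model for one gene."""

    beta: np.ndarray  # fixed effects (intercept [, condition])
    sigma_b2: float
    sigma_e2: float
    icc: float
    loglik: float  # restricted log-likelihood
    n: int
    n_pairs: int
    p_fixed: int
    has_condition: bool


def _prepare_design(
    pair_ids, condition=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Order observations by pair and build the per-pair design matrix."""
    pair_ids = pd.Series(np.asarray(pair_ids))
    counts = pair_ids.value_counts()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()
        raise ValueError(f"every pair must have exactly 2 cells; offending: {bad[:5]}")
    if len(counts) < 3:
        raise ValueError("need at least 3 pairs to fit the mixed model")
    codes, uniques = pd.factorize(pair_ids)
    order = np.argsort(codes, kind="stable")
    i1 = order[0::2]
    i2 = order[1::2]

    has_condition = False
    if condition is not None:
        condition = pd.Series(np.asarray(condition))
        levels = pd.unique(condition)
        if len(levels) > 2:
            raise ValueError("condition must have at most 2 levels")
        if len(levels) == 2:
            c1 = condition.to_numpy()[i1]
            c2 = condition.to_numpy()[i2]
            if (c1 != c2).any():
                raise ValueError("condition must be constant within a sister pair")
            dummy = (c1 == sorted(map(str, levels))[-1]).astype(float)
            has_condition = True
    q = len(i1)
    X_pair = np.ones((q, 1))
    if has_condition:
        X_pair = np.column_stack([X_pair, dummy])
    return i1, i2, X_pair, has_condition


def _reml_closed_form(
    S: np.ndarray, D: np.ndarray, X_pair: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized closed-form REML for (q x G) sum/difference matrices."""
    q, G = S.shape
    n = 2 * q
    Xs = np.sqrt(2.0) * X_pair
    p = np.linalg.matrix_rank(Xs)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ S)  # p x G
    resid_s = S - Xs @ beta
    rss_s = (resid_s**2).sum(axis=0)
    rss_d = (D**2).sum(axis=0)

    u = rss_d / q  # sigma_e^2 candidate
    w = rss_s / (q - p)  # sigma_e^2 + 2 sigma_b^2 candidate
    boundary = w <= u
    sigma_e2 = np.where(boundary, (rss_s + rss_d) / (n - p), u)
    w_hat = np.where(boundary, sigma_e2, w)
    sigma_b2 = np.maximum(0.0, (w_hat - sigma_e2) / 2.0)

    sign, logdet_xtx = np.linalg.slogdet(XtX)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = -0.5 * (
            (n - p) * _LOG2PI
            + q * np.log(w_hat)
            + q * np.log(sigma_e2)
            + (logdet_xtx - p * np.log(w_hat))
            + rss_s / w_hat
            + rss_d / sigma_e2
        )
    # OLS-REML of the null model (no random effect), same fixed effects
    s2_null = (rss_s + rss_d) / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik_null = -0.5 * (
            (n - p) * _LOG2PI
            + (n - p) * np.log(s2_null)
            + logdet_xtx
            + (n - p)
        )
    return {
        "beta": beta,
        "sigma_b2": sigma_b2,
        "sigma_e2": sigma_e2,
        "loglik": loglik,
        "loglik_null": loglik_null,
        "s2_null": s2_null,
        "p_fixed": p,
    }


def _sum_diff(Y: np.ndarray, i1: np.ndarray, i2: np.ndarray):
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return (Y[i1] + Y[i2]) * inv_sqrt2, (Y[i1] - Y[i2]) * inv_sqrt2


def fit_memory_model(y, pair_ids, condition=None) -> MemoryFit:
    """REML fit of the pair random-intercept model for one gene.

    ``y`` is the per-cell expression (two observations per pair);
    ``condition`` (optional) adds the differentiation fixed effect, which
    must be constant within pairs.  Returns variance components, ICC and
    the restricted log-likelihood needed for the LRT.
    """
    y = np.asarray(y, dtype=float)
    i1, i2, X_pair, has_condition = _prepare_design(pair_ids, condition)
    S, D = _sum_diff(y[:, None], i1, i2)
    res = _reml_closed_form(S, D, X_pair)
    sb2, se2 = float(res["sigma_b2"][0]), float(res["sigma_e2"][0])
    return MemoryFit(
        beta=res["beta"][:, 0],
        sigma_b2=sb2,
        sigma_e2=se2,
        icc=sb2 / (sb2 + se2) if sb2 + se2 > 0 else 0.0,
        loglik=float(res["loglik"][0]),
        n=len(y),
        n_pairs=len(i1),
        p_fixed=int(res["p_fixed"]),
        has_condition=has_condition,
    )


def fit_null_model(y, pair_ids, condition=None) -> MemoryFit:
    """The null model: identical fixed effects, no pair random effect."""
    y = np.asarray(y, dtype=float)
    i1, i2, X_pair, has_condition = _prepare_design(pair_ids, condition)
    S, D = _sum_diff(y[:, None], i1, i2)
    res = _reml_closed_form(S, D, X_pair)
    se2 = float(res["s2_null"][0])
    return MemoryFit(
        beta=res["beta"][:, 0],
        sigma_b2=0.0,
        sigma_e2=se2,
        icc=0.0,
        loglik=float(res["loglik_null"][0]),
        n=len(y),
        n_pairs=len(i1),
        p_fixed=int(res["p_fixed"]),
        has_condition=has_condition,
    )


def lrt_memory(fit_full: MemoryFit, fit_null: MemoryFit, boundary: bool = False) -> dict:
    """Likelihood ratio test of the pair random effect.

    stat = 2 (ll_full - ll_null), clamped at zero.  The default reference
    is chi-square(1) (conservative at the sigma_b^2 = 0 boundary); with
    ``boundary=True`` the 50:50 chi0/chi1 mixture p-value is returned.
    """
    if (fit_full.p_fixed, fit_full.has_condition) != (
        fit_null.p_fixed,
        fit_null.has_condition,
    ):
        raise ValueError("full and null fits must share the fixed-effect structure")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-8 * max(1.0, abs(fit_null.loglik)):
        raise RuntimeError(
            "full-model restricted likelihood below the null likelihood"
        )
    stat = max(0.0, stat)
    if boundary:
        p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return {"stat": stat, "p": p}


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def detect_memory_genes(
    adata: ad.AnnData,
    alpha: float = 0.05,
    boundary: bool = False,
    pair_key: str = "sister_pair_id",
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Run the memory-gene test on every gene of an expression matrix.

    Expects per-cell pair labels in ``obs[pair_key]``; a condition fixed
    effect is included automatically when ``obs[condition_key]`` has two
    levels (the single-condition variant Y = p2 + e omits it).  All genes
    are fit at once through the closed-form REML.

    Returns a per-gene table with variance components, ICC, the LRT
    statistic, raw and BH-adjusted p-values and the memory flag
    (p_bh < alpha).
    """
    condition = (
        adata.obs[condition_key]
        if condition_key in adata.obs and adata.obs[condition_key].nunique() > 1
        else None
    )
    Y = np.asarray(adata.X, dtype=float)
    if np.isnan(Y).any():
        return _detect_memory_genes_incomplete(
            adata, Y, condition, alpha, boundary, pair_key
        )
    i1, i2, X_pair, has_condition = _prepare_design(
        adata.obs[pair_key], condition
    )
    S, D = _sum_diff(Y, i1, i2)
    res = _reml_closed_form(S, D, X_pair)

    stat = np.maximum(0.0, 2.0 * (res["loglik"] - res["loglik_null"]))
    if boundary:
        p_raw = np.where(stat == 0.0, 1.0, 0.5 * stats.chi2.sf(stat, df=1))
    else:
        p_raw = stats.chi2.sf(stat, df=1)
    p_bh = adjust_bh(p_raw)
    sb2, se2 = res["sigma_b2"], res["sigma_e2"]
    with np.errstate(invalid="ignore"):
        icc = np.where(sb2 + se2 > 0, sb2 / (sb2 + se2), 0.0)
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "beta_condition": res["beta"][1] if has_condition else np.nan,
            "sigma_b2": sb2,
            "sigma_e2": se2,
            "icc": icc,
            "lrt_stat": stat,
            "p_raw": p_raw,
            "p_bh": p_bh,
            "memory": p_bh < alpha,
        }
    ).set_index("gene", drop=False)
    out.index.name = None
    return out


def _detect_memory_genes_incomplete(
    adata, Y, condition, alpha, boundary, pair_key
) -> pd.DataFrame:
    """Per-gene complete-pair analysis for matrices with missing readings.

    QC-failed qPCR readings propagate as missing; each gene is fit on the
    pairs where both cells were observed.  Genes left with fewer than 3
    complete pairs get a missing result (never flagged memory).
    """
    pair_ids = adata.obs[pair_key].to_numpy()
    cond = None if condition is None else np.asarray(condition)
    rows = []
    for j, gene in enumerate(adata.var_names):
        y = Y[:, j]
        present = ~np.isnan(y)
        pair_sizes = pd.Series(pair_ids[present]).value_counts()
        complete = set(pair_sizes[pair_sizes == 2].index)
        mask = present & np.isin(pair_ids, list(complete))
        row = {
            "gene": gene,
            "beta_condition": np.nan,
            "sigma_b2": np.nan,
            "sigma_e2": np.nan,
            "icc": np.nan,
            "lrt_stat": np.nan,
            "p_raw": np.nan,
            "p_bh": np.nan,
            "memory": False,
            "n_pairs_used": int(mask.sum() // 2),
        }
        sub_cond = None
        if cond is not None and len(pd.unique(cond[mask])) > 1:
            sub_cond = cond[mask]
        try:
            full = fit_memory_model(y[mask], pair_ids[mask], sub_cond)
            null = fit_null_model(y[mask], pair_ids[mask], sub_cond)
            lrt = lrt_memory(full, null, boundary=boundary)
            row.update(
                beta_condition=full.beta[1] if full.has_condition else np.nan,
                sigma_b2=full.sigma_b2,
                sigma_e2=full.sigma_e2,
                icc=full.icc,
                lrt_stat=lrt["stat"],
                p_raw=lrt["p"],
            )
        except ValueError as exc:
            logger.info("gene %s skipped: %s", gene, exc)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene", drop=False)
    out.index.name = None
    tested = out["p_raw"].notna()
    if tested.any():
        out.loc[tested, "p_bh"] = adjust_bh(out.loc[tested, "p_raw"].to_numpy())
        out["memory"] = out["p_bh"] < alpha
    return out


def negative_control_random_pairing(
    adata: ad.AnnData,
    seed: int = 0,
    alpha: float = 0.05,
    boundary: bool = False,
    condition_key: str = "condition",
) -> tuple[pd.DataFrame, int]:
    """Re-run the memory-gene detection on randomly paired cells.

    True sister-pair labels are replaced by a random perfect matching of
    the cells within each condition; on data with genuine memory this
    negative control should detect (close to) nothing.  Returns the
    per-gene result table under randomized pairing and the detected count.
    """
    rng = np.random.default_rng(seed)
    obs = adata.obs.copy()
    new_pairs = pd.Series(index=obs.index, dtype=object)
    groups = (
        obs.groupby(condition_key, observed=True).groups
        if condition_key in obs
        else {"all": obs.index}
    )
    keep = []
    for g, cells in groups.items():
        cells = list(cells)
        rng.shuffle(cells)
        if len(cells) % 2 == 1:
            dropped = cells.pop()
            logger.warning(
                "odd cell count in condition %s; dropping cell %s", g, dropped
            )
        for k in range(0, len(cells), 2):
            pair = f"rand_{g}_{k // 2}"
            new_pairs[cells[k]] = pair
            new_pairs[cells[k + 1]] = pair
            keep.extend([cells[k], cells[k + 1]])
    sub = adata[keep].copy()
    sub.obs["sister_pair_id"] = new_pairs.loc[keep].to_numpy()
    results = detect_memory_genes(
        sub, alpha=alpha, boundary=boundary, condition_key=condition_key
    )
    return results, int(results["memory"].sum())


def abundance_enrichment(memory_set, counts) -> dict:
    """Transcript-abundance comparison of memory genes vs the whole panel.

    ``counts`` is the raw count matrix (AnnData) or a per-gene total
    abundance Series.  Returns the two empirical CDFs (as sorted abundance
    arrays) and the two-sample Kolmogorov-Smirnov test of the memory-gene
    abundances against all genes.
    """
    if isinstance(counts, ad.AnnData):
        totals = pd.Series(
            np.asarray(counts.X, dtype=float).sum(axis=0), index=counts.var_names
        )
    else:
        totals = pd.Series(counts)
    memory_set = pd.Index(memory_set)
    if len(memory_set) == 0:
        raise ValueError("memory gene set is empty")
    missing = memory_set.difference(totals.index)
    if len(missing):
        raise KeyError(f"memory genes absent from counts: {list(missing)[:5]}")
    if len(memory_set) >= len(totals.index.unique()):
        raise ValueError("memory set equals the whole gene panel; comparison degenerate")
    mem = totals.loc[memory_set].to_numpy()
    allg = totals.to_numpy()
    ks = stats.ks_2samp(mem, allg)
    return {
        "ecdf_memory": np.sort(mem),
        "ecdf_all": np.sort(allg),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def halflife_join(results: pd.DataFrame, halflife_table: pd.DataFrame) -> pd.DataFrame:
    """Attach external mRNA half-life measurements to memory-gene results.

    ``halflife_table`` must be keyed by unique gene ids (column ``gene``)
    with a ``halflife`` column; genes without a measurement keep a missing
    half-life.
    """
    if "gene" not in halflife_table.columns:
        raise ValueError("half-life table needs a 'gene' column")
    if halflife_table["gene"].duplicated().any():
        dup = halflife_table.loc[halflife_table["gene"].duplicated(), "gene"]
        raise ValueError(f"duplicate gene keys in half-life table: {list(dup)[:5]}")
    cols = [c for c in halflife_table.columns if c != "gene"]
    if not cols:
        halflife_table = halflife_table.assign(halflife=np.nan)
    joined = results.merge(halflife_table, how="left", on="gene")
    joined.index = results.index
    return joined
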