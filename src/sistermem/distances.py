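"""Pairwise transcriptome distances by lineage relation, with resampling nulls.

The central comparison of the pipeline: are sister (or cousin) cells
closer in expression space than non-related cells of the same condition?
Distances (Manhattan by default, Euclidean as confirmation) are computed
within condition; relation classes partition the unordered cell pairs
into sister / cousin / non-related.  Mean comparisons use a Shapiro-Wilk
gated t-test / Wilcoxon rank-sum test, and a size-matched subsampling
null quantifies how extreme the observed related-pair mean distance is
among random non-related draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .memory import adjust_bh

logger = logging.getLogger(__name__)

RELATIONS = ("sister", "cousin", "non_related")
METRICS = ("manhattan", "euclidean")


def _values_and_index(x) -> tuple[np.ndarray, pd.Index]:
    if isinstance(x, ad.AnnData):
        return np.asarray(x.X, dtype=float), x.obs_names
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), x.index
    arr = np.asarray(x, dtype=float)
    return arr, pd.RangeIndex(len(arr))


def pairwise_distances(
    x, metric: str = "manhattan", pairwise_complete: bool = False
) -> pd.DataFrame:
    """Cell x cell distance matrix.

    Manhattan: d(a, b) = sum_g |a_g - b_g|; Euclidean the usual L2 norm.
    With ``pairwise_complete=True`` (the qPCR branch, where QC-failed
    readings are missing) each pair is computed over the genes observed in
    both cells, and the per-pair gene counts are logged.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    V, index = _values_and_index(x)
    if V.shape[1] == 0:
        raise ValueError("distance computation requires at least one gene")
    if np.isnan(V).any():
        if not pairwise_complete:
            raise ValueError(
                "matrix contains missing values; use pairwise_complete=True"
            )
        diff = V[:, None, :] - V[None, :, :]
        valid = ~np.isnan(diff)
        counts = valid.sum(axis=2)
        logger.info(
            "pairwise-complete distances: gene count per pair min=%d median=%.0f",
            counts[np.triu_indices(len(V), 1)].min() if len(V) > 1 else 0,
            np.median(counts[np.triu_indices(len(V), 1)]) if len(V) > 1 else 0,
        )
        if metric == "manhattan":
            D = np.nansum(np.abs(diff), axis=2)
        else:
            D = np.sqrt(np.nansum(diff**2, axis=2))
        np.fill_diagonal(D, 0.0)
    else:
        sp_metric = "cityblock" if metric == "manhattan" else "euclidean"
        D = squareform(pdist(V, metric=sp_metric))
    return pd.DataFrame(D, index=index, columns=index)


def classify_pairs(ped: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """All unordered same-condition cell pairs with their relation class.

    Relations: ``sister`` (same sister pair), ``cousin`` (same family,
    different pair) and ``non_related`` (different families).  The three
    classes are disjoint and exhaustive within a condition.
    """
    sub = ped if condition is None else ped[ped["condition"] == condition]
    cells = sub["cell_id"].to_numpy()
    fam = sub["family_id"].to_numpy()
    pair = sub["sister_pair_id"].to_numpy()
    i, j = np.triu_indices(len(cells), k=1)
    same_pair = pair[i] == pair[j]
    same_fam = fam[i] == fam[j]
    relation = np.where(
        same_pair, "sister", np.where(same_fam, "cousin", "non_related")
    )
    return pd.DataFrame(
        {"cell_a": cells[i], "cell_b": cells[j], "relation": relation}
    )


def count_pairs(ped: pd.DataFrame, condition: str | None = None) -> dict[str, int]:
    """Pair counts per relation class within a condition.

    Conservation: sister + cousin + non_related = n(n-1)/2.
    """
    pairs = classify_pairs(ped, condition)
    counts = pairs["relation"].value_counts()
    n = len(ped if condition is None else ped[ped["condition"] == condition])
    out = {r: int(counts.get(r, 0)) for r in RELATIONS}
    out["total"] = n * (n - 1) // 2
    out["n_cells"] = n
    assert sum(out[r] for r in RELATIONS) == out["total"]
    return out


@dataclass
class RelationDistances:
    """Distances of one relation class within one condition."""

    relation: str
    condition: str | None
    metric: str | None
    pairs: pd.DataFrame  # cell_a, cell_b, distance
    mean: float
    median: float
    n: int

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance"].to_numpy()


def mean_distance_by_relation(
    dm: pd.DataFrame,
    ped: pd.DataFrame,
    relation: str,
    condition: str | None = None,
    metric: str | None = None,
) -> RelationDistances:
    """Extract and summarize one relation class from a distance matrix.

    The distance matrix must have been computed on same-condition cells
    (cross-condition distances are never pooled).
    """
    if relation not in RELATIONS:
        raise ValueError(f"relation must be one of {RELATIONS}")
    pairs = classify_pairs(ped, condition)
    pairs = pairs[pairs["relation"] == relation].copy()
    pairs = pairs[
        pairs["cell_a"].isin(dm.index) & pairs["cell_b"].isin(dm.index)
    ]
    if len(pairs) == 0:
        raise ValueError(f"no {relation!r} pairs in this condition")
    ia = dm.index.get_indexer(pairs["cell_a"])
    ib = dm.index.get_indexer(pairs["cell_b"])
    d = dm.to_numpy()[ia, ib]
    pairs["distance"] = d
    return RelationDistances(
        relation=relation,
        condition=condition,
        metric=metric,
        pairs=pairs.reset_index(drop=True),
        mean=float(np.mean(d)),
        median=float(np.median(d)),
        n=len(d),
    )


def mean_pair_distance_per_gene(x, pairs: list[tuple[str, str]]) -> pd.Series:
    """Per-gene mean within-pair absolute expression difference.

    For a single memory gene with sister pairs at values (1, 2) and
    (3, 4) this is (|1-2| + |3-4|) / 2 = 1.
    """
    V, index = _values_and_index(x)
    var_names = (
        x.var_names
        if isinstance(x, ad.AnnData)
        else (x.columns if isinstance(x, pd.DataFrame) else pd.RangeIndex(V.shape[1]))
    )
    ia = index.get_indexer([p[0] for p in pairs])
    ib = index.get_indexer([p[1] for p in pairs])
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("pair cell missing from expression matrix")
    d = np.abs(V[ia] - V[ib]).mean(axis=0)
    return pd.Series(d, index=var_names)


@dataclass
class ComparisonResult:
    """Shapiro-Wilk gated two-sample mean comparison."""

    test: str  # "t" or "wilcoxon"
    statistic: float
    pvalue: float
    shapiro_p: tuple[float, float]
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def compare_means(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Compare two samples' means the way the pipeline does everywhere.

    Each sample is tested for normality with Shapiro-Wilk; if neither
    rejects at ``alpha`` a two-sample t-test is used, otherwise the
    Wilcoxon rank-sum test.  Constant samples force the rank-sum branch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both samples need at least 3 values")

    def shapiro_p(v):
        if np.ptp(v) == 0:
            return np.nan
        return float(stats.shapiro(v).pvalue)

    pa, pb = shapiro_p(a), shapiro_p(b)
    normal = (
        not np.isnan(pa) and not np.isnan(pb) and pa >= alpha and pb >= alpha
    )
    if np.isnan(pa) or np.isnan(pb):
        logger.warning("constant sample; falling back to rank-sum test")
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon"
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        shapiro_p=(pa, pb),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class SubsampleNull:
    """Size-matched subsampling null for a related-pair mean distance."""

    B: int
    subsample_size: int
    mean_distances: np.ndarray
    observed_mean: float
    empirical_p: float
    seed: int


def subsample_null(
    dm: pd.DataFrame,
    ped: pd.DataFrame,
    relation_observed: str = "sister",
    condition: str | None = None,
    B: int = 1000,
    seed: int = 0,
    subsample_size: int | None = None,
) -> SubsampleNull:
    """Null distribution of mean non-related distance at matched sample size.

    ``B`` draws, each sampling (without replacement within a draw, with
    replacement across draws) as many non-related distances as there are
    observed related pairs; the empirical p for the "related cells are
    closer" direction is (1 + #{null means <= observed mean}) / (B + 1).
    """
    observed = mean_distance_by_relation(dm, ped, relation_observed, condition)
    pool = mean_distance_by_relation(dm, ped, "non_related", condition).distances
    size = subsample_size if subsample_size is not None else observed.n
    if size > len(pool):
        raise ValueError(
            f"subsample size {size} exceeds the non-related pool ({len(pool)})"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(B)
    for b in range(B):
        means[b] = pool[rng.choice(len(pool), size=size, replace=False)].mean()
    p = (1.0 + np.sum(means <= observed.mean)) / (B + 1.0)
    return SubsampleNull(
        B=B,
        subsample_size=size,
        mean_distances=means,
        observed_mean=observed.mean,
        empirical_p=float(p),
        seed=seed,
    )


def most_variable_genes(x, k: int) -> pd.Index:
    """The k genes with the largest variance of (normalized) expression.

    Ties are broken by gene id so the selection is deterministic.
    """
    V, _ = _values_and_index(x)
    var_names = (
        x.var_names if isinstance(x, ad.AnnData) else pd.Index(x.columns)
    )
    if k > len(var_names):
        raise ValueError(f"k={k} exceeds the {len(var_names)} available genes")
    variances = V.var(axis=0, ddof=1)
    order = np.lexsort((np.asarray(var_names), -variances))
    return pd.Index(var_names[order[:k]])


def distance_with_gene_subset(
    x,
    ped: pd.DataFrame,
    gene_set,
    metric: str = "manhattan",
    condition: str | None = None,
) -> dict:
    """Sister vs non-related comparison restricted to a gene set.

    Returns the comparison result together with the relation summaries;
    with ``gene_set`` equal to all genes this reduces to the full
    analysis.
    """
    gene_set = pd.Index(gene_set)
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    if isinstance(x, ad.AnnData):
        missing = gene_set.difference(x.var_names)
        sub = x[:, gene_set]
    else:
        missing = gene_set.difference(x.columns)
        sub = x[gene_set]
    if len(missing):
        raise KeyError(f"genes not in matrix: {list(missing)[:5]} ...")
    if condition is not None:
        cells = ped.loc[ped["condition"] == condition, "cell_id"]
        sub = sub[sub.obs_names.isin(cells)] if isinstance(sub, ad.AnnData) else sub.loc[sub.index.isin(cells)]
    dm = pairwise_distances(sub, metric=metric)
    sisters = mean_distance_by_relation(dm, ped, "sister", condition, metric)
    others = mean_distance_by_relation(dm, ped, "non_related", condition, metric)
    comparison = compare_means(sisters.distances, others.distances)
    return {
        "comparison": comparison,
        "sisters": sisters,
        "non_related": others,
        "n_genes": len(gene_set),
    }


def _pair_gene_absdiff(
    x, ped: pd.DataFrame, condition: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair per-gene |difference| for sister and non-related pairs."""
    V, index = _values_and_index(x)
    pairs = classify_pairs(ped, condition)
    pairs = pairs[pairs["cell_a"].isin(index) & pairs["cell_b"].isin(index)]
    out = {}
    for rel in ("sister", "non_related"):
        sub = pairs[pairs["relation"] == rel]
        ia = index.get_indexer(sub["cell_a"])
        ib = index.get_indexer(sub["cell_b"])
        out[rel] = np.abs(V[ia] - V[ib])
    return out["sister"], out["non_related"]


def gene_subsample_sensitivity(
    x,
    ped: pd.DataFrame,
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 2)),
    B: int = 1000,
    seed: int = 0,
    condition: str | None = None,
) -> dict[float, np.ndarray]:
    """Sensitivity of the sister vs non-related Manhattan comparison to gene-set size.

    For each fraction of the gene panel, ``B`` random gene draws are taken;
    each draw compares sister to non-related Manhattan distances on the
    restricted matrix.  The ``B`` p-values of a fraction are BH-adjusted
    and returned, one array per fraction.  Fractions yielding fewer than
    2 genes are skipped with a warning.
    """
    V, _ = _values_and_index(x)
    G = V.shape[1]
    if G < 10:
        raise ValueError("gene subsampling needs at least 10 genes")
    sis, non = _pair_gene_absdiff(x, ped, condition)
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for frac in fractions:
        size = int(round(frac * G))
        if size < 2:
            logger.warning("fraction %.2f yields <2 genes; skipped", frac)
            continue
        if size >= G:
            idx_draws = [np.arange(G)] * B
        else:
            idx_draws = [rng.choice(G, size=size, replace=False) for _ in range(B)]
        pvals = np.empty(B)
        for b, idx in enumerate(idx_draws):
            d_sis = sis[:, idx].sum(axis=1)
            d_non = non[:, idx].sum(axis=1)
            pvals[b] = compare_means(d_sis, d_non).pvalue
        out[float(frac)] = adjust_bh(pvals)
    return out
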