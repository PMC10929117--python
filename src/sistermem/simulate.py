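"""Synthetic data with the lineage structure of dye-barcoded dividing cells.

Generates the four kinds of inputs the analysis pipeline consumes:

* pedigrees — families of sister (generation 1) or cousin (generation 2)
  cells, each family descending from one observed mother cell;
* expression matrices — per-gene Gaussian (or negative-binomial count)
  values with a pair-level random intercept for "memory genes", so that
  sister cells are correlated at a known intraclass correlation (ICC);
* fluorescence tables — CFSE/CTY/CTV/CTFR dye intensities implementing
  heritable fluorescent barcodes that are diluted ~2-fold per division;
* Ct tables — scRT-qPCR cycle-threshold readings with spike-in rows,
  QC flags and negative-control wells.

Random streams are split per output (pedigree / expression / fluorescence /
Ct) from the single config seed, so requesting one output never perturbs
another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SELF_RENEWING = "self_renewing"
DIFFERENTIATING = "differentiating"

# substream indices for per-output RNG splitting
_STREAM_PEDIGREE = 0
_STREAM_EXPRESSION = 1
_STREAM_FLUORESCENCE = 2
_STREAM_CT = 3

#: number of distinct CFSE x CTY barcodes available within one plate group
N_BARCODES = 6


@dataclass(frozen=True)
class DyeParams:
    """Fluorescent-barcode parameters.

    Intensities are in arbitrary fluorescence units.  ``cfse_levels``
    mirrors the three staining concentrations (5, 2.187 and 0.312 uM)
    used to build barcodes; combined with CTY on/off this yields six
    distinguishable barcodes per plate group.
    """

    cfse_levels: tuple[float, ...] = (5000.0, 2187.0, 312.0)
    cty_level: float = 10000.0
    ctv_level: float = 5000.0
    ctfr_level: float = 1000.0
    background: float = 30.0
    #: per-cell multiplicative staining noise (lognormal CV)
    staining_cv: float = 0.05
    #: mother-to-mother dye-uptake variability (lognormal CV); must stay
    #: well below the ~2.3-fold spacing of the CFSE barcode levels for the
    #: barcodes to remain identifiable after two divisions
    uptake_cv: float = 0.15
    #: fraction of dye inherited by each daughter at division
    dilution: float = 0.5
    #: lognormal sigma of the deliberately heterogeneous CTFR staining
    ctfr_het_sd: float = 0.8


@dataclass(frozen=True)
class CtParams:
    """scRT-qPCR layer parameters (cycle-threshold units)."""

    spike_ct: float = 8.0
    spike_sd: float = 0.05
    noise_sd: float = 0.25
    failed_frac: float = 0.0
    #: probability that a gene spuriously amplifies in a negative-control well
    negctrl_amplify_frac: float = 0.0
    n_negative_controls: int = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults emulate the generation-1 scRNA-seq design: ~30 families
    (sister pairs), 1000 genes of which 10% are memory genes with a true
    sister ICC of 0.6, and both culture conditions represented.
    """

    n_families: int = 30
    generation: int = 1
    n_genes: int = 1000
    frac_memory: float = 0.1
    icc_memory: float = 0.6
    condition_effect: float = 0.5
    base_mean: float = 0.0
    sigma_total: float = 1.0
    count_model: str = "gaussian"
    nb_dispersion: float = 2.0
    #: for generation-2 pedigrees, fraction of the memory variance shared at
    #: the family level (cousin correlation = icc_memory * family_share)
    family_share: float = 0.5
    conditions: tuple[str, ...] = (SELF_RENEWING, DIFFERENTIATING)
    dye_params: DyeParams = field(default_factory=DyeParams)
    ct_params: CtParams = field(default_factory=CtParams)
    n_feeder: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generation not in (1, 2):
            raise ValueError(
                f"generation must be 1 or 2, got {self.generation!r}"
            )
        if not 0.0 <= self.frac_memory <= 1.0:
            raise ValueError("frac_memory must lie in [0, 1]")
        if not 0.0 <= self.icc_memory < 1.0:
            raise ValueError(
                "icc_memory must lie in [0, 1); icc_memory = 1 leaves no "
                "residual variance and is degenerate (in particular for the "
                "count layer)"
            )
        if not 0.0 < self.dye_params.dilution <= 1.0:
            raise ValueError("dye dilution factor must lie in (0, 1]")
        if self.count_model not in ("gaussian", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    def with_(self, **kw) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Build the lineage-label table.

    Generation 1 gives two sister cells per family; generation 2 gives a
    quartet of cousins per family, split into two sister pairs.  Families
    alternate over ``config.conditions`` so both media are represented.

    Returns
    -------
    DataFrame with columns ``cell_id, family_id, sister_pair_id,
    generation, condition``, one row per cell, indexed by ``cell_id``.
    """
    rows = []
    n_pairs = 1 if config.generation == 1 else 2
    for f in range(config.n_families):
        fam = f"fam{f:03d}"
        condition = config.conditions[f % len(config.conditions)]
        for p in range(n_pairs):
            pair = f"{fam}.p{p}"
            for c in "ab":
                rows.append(
                    {
                        "cell_id": f"{pair}.{c}",
                        "family_id": fam,
                        "sister_pair_id": pair,
                        "generation": config.generation,
                        "condition": condition,
                    }
                )
    ped = pd.DataFrame(rows).set_index("cell_id", drop=False)
    ped.index.name = None
    return ped


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Raise if a pedigree violates its structural invariants."""
    required = {"cell_id", "family_id", "sister_pair_id", "generation", "condition"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree misses columns {sorted(missing)}")
    pair_sizes = ped.groupby("sister_pair_id").size()
    if not (pair_sizes == 2).all():
        bad = pair_sizes[pair_sizes != 2].index.tolist()
        raise ValueError(f"sister pairs without exactly 2 cells: {bad}")
    fam_of_pair = ped.groupby("sister_pair_id")["family_id"].nunique()
    if not (fam_of_pair == 1).all():
        raise ValueError("a sister pair spans more than one family")
    gen2 = ped[ped["generation"] == 2]
    if len(gen2):
        fam_sizes = gen2.groupby("family_id").size()
        if not (fam_sizes == 4).all():
            raise ValueError("generation-2 families must contain exactly 4 cells")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(ped: pd.DataFrame, config: SimulationConfig) -> ad.AnnData:
    """Simulate lineage-structured expression for every cell of a pedigree.

    Each gene g follows

        y_cg = mu_g + beta_g * 1[differentiating] + b_pair(c),g + eps_cg

    where for memory genes the pair-level random intercept has variance
    sigma_b^2 = icc_memory * sigma_total^2 and the residual
    sigma_e^2 = (1 - icc_memory) * sigma_total^2; non-memory genes have
    sigma_b^2 = 0.  On generation-2 pedigrees the memory variance is split
    between a family-level and a pair-level component
    (``config.family_share``), so cousins are correlated too, at
    icc_memory * family_share.

    With ``count_model="negative_binomial"`` an integer count layer is
    drawn with log-mean y_cg (gamma-Poisson with size ``nb_dispersion``);
    the latent Gaussian values are kept in ``layers["latent"]``.

    Returns an AnnData (cells x genes); ground-truth memory labels are in
    ``var["is_memory"]`` and the per-gene true ICC in ``var["true_icc"]``.
    """
    if len(ped) == 0:
        raise ValueError("pedigree is empty")
    validate_pedigree(ped)
    rng = _rng(config, _STREAM_EXPRESSION)

    n_cells = len(ped)
    G = config.n_genes
    n_memory = int(round(config.frac_memory * G))
    is_memory = np.zeros(G, dtype=bool)
    is_memory[rng.choice(G, size=n_memory, replace=False)] = True

    sigma_b2 = np.where(is_memory, config.icc_memory, 0.0) * config.sigma_total**2
    sigma_e2 = config.sigma_total**2 - sigma_b2

    beta = (
        rng.normal(0.0, config.condition_effect, size=G)
        if config.condition_effect > 0 and len(config.conditions) > 1
        else np.zeros(G)
    )

    pair_codes, pairs = pd.factorize(ped["sister_pair_id"])
    fam_codes, fams = pd.factorize(ped["family_id"])
    is_diff = (ped["condition"] == DIFFERENTIATING).to_numpy()

    # split the pair-level variance across family and pair for generation 2
    if config.generation == 2:
        share_fam = config.family_share
    else:
        share_fam = 0.0
    b_fam = rng.normal(size=(len(fams), G)) * np.sqrt(share_fam * sigma_b2)
    b_pair = rng.normal(size=(len(pairs), G)) * np.sqrt((1.0 - share_fam) * sigma_b2)
    eps = rng.normal(size=(n_cells, G)) * np.sqrt(sigma_e2)

    y = (
        config.base_mean
        + beta * is_diff[:, None]
        + b_fam[fam_codes]
        + b_pair[pair_codes]
        + eps
    )

    var = pd.DataFrame(
        {
            "is_memory": is_memory,
            "true_icc": np.where(is_memory, config.icc_memory, 0.0),
            "beta_condition": beta,
        },
        index=[f"g{j:04d}" for j in range(G)],
    )
    adata = ad.AnnData(X=y, obs=ped.copy(), var=var)

    if config.count_model == "negative_binomial":
        mu = np.exp(y)
        r = config.nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam).astype(np.float64)
        adata.layers["latent"] = adata.X
        adata.X = counts
    return adata


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_fluorescence(ped: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the dye-intensity table recorded at the final sort.

    Generation 2 (the barcoding design): each family carries one of the
    six CFSE-level x CTY+/- barcodes, unique within its plate group of up
    to six families.  A descendant's stained-dye intensity is the mother
    intensity times ``dilution ** divisions`` times per-cell lognormal
    staining noise.  CTFR is applied after the first division with strong
    per-daughter heterogeneity and is inherited (x dilution) by her two
    daughters, so the two sister pairs of a family are separable by CTFR.
    CTV is applied to mothers only and reflects division count.

    Generation 1: mothers are stained with CFSE only; CTY/CTFR stay at
    autofluorescence background.

    Feeder (decoy) cells carry every barcode dye at background level and
    are excluded downstream by the CTV-positivity gate.
    """
    validate_pedigree(ped)
    dye = config.dye_params
    rng = _rng(config, _STREAM_FLUORESCENCE)

    fams = ped["family_id"].unique()
    fam_index = {f: i for i, f in enumerate(fams)}
    divisions = int(ped["generation"].iloc[0])

    if divisions == 2:
        # barcode per family, unique within a plate group of six
        cfse_level = np.array(
            [dye.cfse_levels[fam_index[f] % len(dye.cfse_levels)] for f in fams]
        )
        cty_on = np.array(
            [(fam_index[f] // len(dye.cfse_levels)) % 2 == 0 for f in fams]
        )
    else:
        cfse_level = np.full(len(fams), dye.cfse_levels[0])
        cty_on = np.zeros(len(fams), dtype=bool)

    # mother staining (day 1)
    n_fam = len(fams)
    cfse_mother = cfse_level * _lognoise(rng, dye.uptake_cv, n_fam)
    cty_mother = np.where(cty_on, dye.cty_level, 0.0) * _lognoise(
        rng, dye.uptake_cv, n_fam
    )
    ctv_mother = dye.ctv_level * _lognoise(rng, dye.uptake_cv, n_fam)

    # CTFR staining of the two generation-1 daughters (day 2), deliberately
    # heterogeneous; in generation-1 mode CTFR is never applied
    pairs = ped["sister_pair_id"].unique()
    ctfr_daughter = {
        p: dye.ctfr_level * rng.lognormal(0.0, dye.ctfr_het_sd) for p in pairs
    }

    rows = []
    for i, (cell_id, row) in enumerate(ped.iterrows()):
        fi = fam_index[row["family_id"]]
        dil = dye.dilution**divisions
        noise = _lognoise(rng, dye.staining_cv, 3)
        cfse = cfse_mother[fi] * dil * noise[0]
        cty = (
            cty_mother[fi] * dil * noise[1]
            if cty_mother[fi] > 0
            else dye.background * noise[1]
        )
        ctv = ctv_mother[fi] * dil * noise[2]
        if divisions == 2:
            ctfr = (
                ctfr_daughter[row["sister_pair_id"]]
                * dye.dilution
                * _lognoise(rng, dye.staining_cv, 1)[0]
            )
        else:
            ctfr = dye.background
        plate = fi // N_BARCODES
        rows.append(
            {
                "cell_id": cell_id,
                "cfse": cfse,
                "cty": cty,
                "ctv": ctv,
                "ctfr": ctfr,
                "well": f"p{plate}_w{i:03d}",
            }
        )

    n_cells = len(rows)
    for j in range(config.n_feeder):
        noise = _lognoise(rng, dye.staining_cv, 4)
        rows.append(
            {
                "cell_id": f"feeder{j:04d}",
                "cfse": dye.background * noise[0],
                "cty": dye.background * noise[1],
                "ctv": dye.background * noise[2],
                "ctfr": dye.background * noise[3],
                "well": f"p0_w{n_cells + j:03d}",
            }
        )

    fluo = pd.DataFrame(rows).set_index("cell_id", drop=False)
    fluo.index.name = None
    return fluo


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """A qPCR chip readout.

    ``values``: genes (+ ``spike1``/``spike4`` rows) x cells, Ct units
    (lower Ct = more template).  ``flags``: same shape, ``"ok"`` or
    ``"failed"``.  ``negative_controls``: same rows x water-only wells,
    NaN where nothing amplified.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    negative_controls: pd.DataFrame | None = None

    SPIKE_ROWS = ("spike1", "spike4")

    def gene_names(self) -> list[str]:
        return [g for g in self.values.index if g not in self.SPIKE_ROWS]

    def copy(self) -> "CtTable":
        return CtTable(
            self.values.copy(),
            self.flags.copy(),
            None if self.negative_controls is None else self.negative_controls.copy(),
        )


def simulate_ct_table(
    ped: pd.DataFrame,
    config: SimulationConfig,
    expression: ad.AnnData | None = None,
) -> CtTable:
    """Simulate a Fluidigm-style Ct table for a pedigree.

    Gene Ct values are derived from a (lineage-structured) expression
    simulation via ``Ct = geomean(spike Cts) - expression``, so the
    spike-based normalization recovers the latent expression up to
    measurement noise (``ct_params.noise_sd``).  Set ``base_mean`` around
    -17 to obtain Ct values in the realistic mid-20s range.
    """
    ct = config.ct_params
    rng = _rng(config, _STREAM_CT)
    if expression is None:
        expression = simulate_expression(ped, config)
    expr = np.asarray(expression.X, dtype=float)  # cells x genes
    genes = list(expression.var_names)
    cells = list(expression.obs_names)

    spikes = ct.spike_ct + rng.normal(0.0, ct.spike_sd, size=(2, len(cells)))
    spike_geomean = np.exp(np.mean(np.log(spikes), axis=0))
    ct_values = spike_geomean[None, :] - expr.T  # genes x cells
    if ct.noise_sd > 0:
        ct_values = ct_values + rng.normal(0.0, ct.noise_sd, size=ct_values.shape)

    index = genes + list(CtTable.SPIKE_ROWS)
    values = pd.DataFrame(
        np.vstack([ct_values, spikes]), index=index, columns=cells
    )
    failed = rng.random(size=values.shape) < ct.failed_frac
    flags = pd.DataFrame(
        np.where(failed, "failed", "ok"), index=index, columns=cells
    )

    neg_cols = [f"neg{k}" for k in range(ct.n_negative_controls)]
    neg = pd.DataFrame(np.nan, index=index, columns=neg_cols)
    if ct.negctrl_amplify_frac > 0:
        spurious = rng.random(size=(len(genes), len(neg_cols))) < ct.negctrl_amplify_frac
        neg.iloc[: len(genes), :] = np.where(
            spurious, ct.spike_ct + 20.0 + rng.normal(0, 1, spurious.shape), np.nan
        )
    return CtTable(values=values, flags=flags, negative_controls=neg)
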