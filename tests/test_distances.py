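"""Distance computation, relation classes, mean tests and resampling nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sistermem as sm


def brute_force_distances(V, metric):
    n = len(V)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = V[i] - V[j]
            D[i, j] = np.abs(d).sum() if metric == "manhattan" else np.sqrt((d**2).sum())
    return D


@pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
def test_matches_brute_force_oracle(metric, rng):
    V = rng.normal(size=(50, 20))
    dm = sm.pairwise_distances(pd.DataFrame(V), metric=metric)
    np.testing.assert_allclose(dm.to_numpy(), brute_force_distances(V, metric),
                               atol=1e-10)


@pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
def test_metric_axioms(metric, rng):
    V = rng.normal(size=(15, 8))
    D = sm.pairwise_distances(pd.DataFrame(V), metric=metric).to_numpy()
    np.testing.assert_allclose(D, D.T)
    np.testing.assert_allclose(np.diag(D), 0.0)
    assert (D >= 0).all()
    for i in range(15):
        for j in range(15):
            for k in range(15):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


def test_identical_vectors_zero_distance():
    V = np.tile([1.0, 2.0, 3.0], (4, 1))
    dm = sm.pairwise_distances(pd.DataFrame(V))
    np.testing.assert_allclose(dm.to_numpy(), 0.0)


def test_zero_genes_rejected():
    with pytest.raises(ValueError):
        sm.pairwise_distances(pd.DataFrame(np.empty((3, 0))))


def test_pairwise_complete_handles_missing(rng):
    V = rng.normal(size=(6, 10))
    V[0, 3] = np.nan
    with pytest.raises(ValueError):
        sm.pairwise_distances(pd.DataFrame(V))
    dm = sm.pairwise_distances(pd.DataFrame(V), pairwise_complete=True)
    expect = np.nansum(np.abs(V[0] - V[1])[~np.isnan(V[0] - V[1])])
    assert dm.iloc[0, 1] == pytest.approx(expect)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 8))
def test_manhattan_gene_additivity(seed, n_split):
    """Manhattan over a gene set equals the sum of per-gene contributions."""
    r = np.random.default_rng(seed)
    V = pd.DataFrame(r.normal(size=(6, 12)),
                     columns=[f"g{j}" for j in range(12)])
    full = sm.pairwise_distances(V).to_numpy()
    parts = np.array_split(np.arange(12), n_split)
    total = sum(sm.pairwise_distances(V.iloc[:, p]).to_numpy() for p in parts)
    np.testing.assert_allclose(full, total, atol=1e-9)


def test_single_gene_sister_example():
    """One memory gene, sister values (1, 2) and (3, 4): mean distance 1."""
    x = pd.DataFrame({"memory_gene": [1.0, 2.0, 3.0, 4.0]},
                     index=["s1", "s2", "s3", "s4"])
    d = sm.mean_pair_distance_per_gene(x, [("s1", "s2"), ("s3", "s4")])
    assert d["memory_gene"] == pytest.approx(1.0)
    dm = sm.pairwise_distances(x)
    assert dm.loc["s1", "s2"] == pytest.approx(1.0)


class TestCountPairs:
    @staticmethod
    def pedigree(n_pairs, condition="c"):
        cfg = sm.SimulationConfig(n_families=n_pairs, generation=1, n_genes=1,
                                  conditions=(condition,))
        return sm.simulate_pedigree(cfg)

    @pytest.mark.parametrize(
        "n_pairs, non_related",
        [(43, 3612), (30, 1740), (32, 1984), (1, 0)],
    )
    def test_generation1_cohorts(self, n_pairs, non_related):
        counts = sm.count_pairs(self.pedigree(n_pairs))
        assert counts["sister"] == n_pairs
        assert counts["non_related"] == non_related
        assert counts["cousin"] == 0

    def test_generation2_quartets(self):
        cfg = sm.SimulationConfig(n_families=8, generation=2, n_genes=1,
                                  conditions=("sr",))
        counts = sm.count_pairs(sm.simulate_pedigree(cfg))
        assert (counts["sister"], counts["cousin"], counts["non_related"]) == (
            16, 32, 448)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(1, 12), st.integers(1, 2))
    def test_conservation(self, n_families, generation):
        cfg = sm.SimulationConfig(n_families=n_families, generation=generation,
                                  n_genes=1, conditions=("sr",))
        counts = sm.count_pairs(sm.simulate_pedigree(cfg), "sr")
        n = counts["n_cells"]
        assert (counts["sister"] + counts["cousin"] + counts["non_related"]
                == n * (n - 1) // 2)


class TestCompareMeans:
    def test_identical_samples_p_near_one(self, rng):
        a = rng.normal(size=30)
        res = sm.compare_means(a, a.copy())
        assert res.pvalue > 0.9

    def test_normal_shift_uses_t_and_rejects(self):
        r = np.random.default_rng(0)
        res = sm.compare_means(r.normal(0, 1, 50), r.normal(2, 1, 50))
        assert res.test == "t"
        assert res.pvalue < 1e-6

    def test_skewed_samples_use_wilcoxon(self):
        r = np.random.default_rng(1)
        res = sm.compare_means(r.lognormal(0, 2, 80), r.lognormal(0.2, 2, 80))
        assert res.test == "wilcoxon"

    def test_constant_sample_falls_back_to_ranksum(self, caplog):
        res = sm.compare_means(np.ones(10), np.arange(10.0))
        assert res.test == "wilcoxon"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            sm.compare_means([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSubsampleNull:
    @pytest.fixture()
    def memory_setup(self):
        cfg = sm.SimulationConfig(n_families=40, generation=1, n_genes=600,
                                  frac_memory=0.1, icc_memory=0.8, seed=3,
                                  conditions=("self_renewing",))
        ped = sm.simulate_pedigree(cfg)
        x = sm.simulate_expression(ped, cfg)
        return ped, sm.pairwise_distances(x)

    def test_strong_memory_below_every_null_mean(self, memory_setup):
        ped, dm = memory_setup
        null = sm.subsample_null(dm, ped, "sister", "self_renewing", B=1000, seed=0)
        assert null.observed_mean < null.mean_distances.min()
        assert null.empirical_p == pytest.approx(1 / 1001)

    def test_reproducible_bit_exact(self, memory_setup):
        ped, dm = memory_setup
        a = sm.subsample_null(dm, ped, "sister", "self_renewing", B=1, seed=7)
        b = sm.subsample_null(dm, ped, "sister", "self_renewing", B=1, seed=7)
        np.testing.assert_array_equal(a.mean_distances, b.mean_distances)
        assert a.empirical_p == b.empirical_p

    def test_oversized_subsample_rejected(self, memory_setup):
        ped, dm = memory_setup
        with pytest.raises(ValueError):
            sm.subsample_null(dm, ped, "sister", "self_renewing", B=10, seed=0,
                              subsample_size=10**6)


@pytest.fixture(scope="module")
def memory_data():
    cfg = sm.SimulationConfig(n_families=30, generation=1, n_genes=400,
                              frac_memory=0.15, icc_memory=0.6, seed=2,
                              conditions=("self_renewing",))
    ped = sm.simulate_pedigree(cfg)
    return ped, sm.simulate_expression(ped, cfg)


class TestGeneSubsets:
    def test_full_fraction_reproduces_full_p(self, memory_data):
        ped, x = memory_data
        out = sm.gene_subsample_sensitivity(x, ped, fractions=(1.0,), B=5, seed=0,
                                            condition="self_renewing")
        full_p = sm.distance_with_gene_subset(
            x, ped, x.var_names, condition="self_renewing"
        )["comparison"].pvalue
        assert np.allclose(out[1.0], full_p)

    def test_significance_improves_with_gene_fraction(self, memory_data):
        from scipy.stats import spearmanr
        ped, x = memory_data
        out = sm.gene_subsample_sensitivity(
            x, ped, fractions=(0.1, 0.3, 0.5, 0.7, 0.9), B=60, seed=1,
            condition="self_renewing")
        fracs = sorted(out)
        sig = [np.mean(out[f] < 0.05) for f in fracs]
        rho = spearmanr(fracs, sig).statistic
        assert rho > 0

    def test_null_data_calibrated(self):
        cfg = sm.SimulationConfig(n_families=30, generation=1, n_genes=200,
                                  frac_memory=0.0, seed=9,
                                  conditions=("self_renewing",))
        ped = sm.simulate_pedigree(cfg)
        x = sm.simulate_expression(ped, cfg)
        out = sm.gene_subsample_sensitivity(x, ped, fractions=(0.5,), B=100,
                                            seed=4, condition="self_renewing")
        # BH-adjusted p-values under the null: few draws significant
        assert np.mean(out[0.5] < 0.05) <= 0.1

    def test_memory_subset_sharper_than_all_genes(self, memory_data):
        ped, x = memory_data
        subset = x.var_names[x.var["is_memory"]]
        p_sub = sm.distance_with_gene_subset(
            x, ped, subset, condition="self_renewing")["comparison"].pvalue
        p_all = sm.distance_with_gene_subset(
            x, ped, x.var_names, condition="self_renewing")["comparison"].pvalue
        assert p_sub < p_all

    def test_empty_gene_set_rejected(self, memory_data):
        ped, x = memory_data
        with pytest.raises(ValueError):
            sm.distance_with_gene_subset(x, ped, [], condition="self_renewing")

    def test_most_variable_genes_match_brute_force(self, rng):
        V = pd.DataFrame(rng.normal(0, rng.uniform(0.5, 3.0, 30), size=(40, 30)),
                         columns=[f"g{j:02d}" for j in range(30)])
        got = sm.most_variable_genes(V, 7)
        order = sorted(V.columns, key=lambda g: (-V[g].var(ddof=1), g))
        assert list(got) == order[:7]


def test_mean_distance_scales_with_gene_count(rng):
    """On i.i.d. data, doubling the gene count doubles mean Manhattan distance."""
    V = rng.normal(size=(30, 1000))
    d1 = sm.pairwise_distances(pd.DataFrame(V[:, :500])).to_numpy()
    d2 = sm.pairwise_distances(pd.DataFrame(V)).to_numpy()
    iu = np.triu_indices(30, 1)
    ratio = d2[iu].mean() / d1[iu].mean()
    assert abs(ratio - 2.0) < 0.1
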