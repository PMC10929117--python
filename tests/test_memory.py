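"""Mixed-model memory-gene detection: REML, LRT, BH, controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import anndata as ad
import sistermem as sm
from conftest import make_paired_gaussian


def anova_estimator(y, q):
    """Balanced one-way ANOVA closed form, computed independently."""
    a = np.asarray(y).reshape(q, 2)
    msb = 2 * np.sum((a.mean(axis=1) - a.mean()) ** 2) / (q - 1)
    msw = np.sum((a[:, 0] - a[:, 1]) ** 2) / 2 / q
    return max(0.0, (msb - msw) / 2), msw if msb > msw else (
        np.sum((a - a.mean()) ** 2) / (2 * q - 1))


class TestReml:
    def test_agrees_with_anova_closed_form_100_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = int(rng.integers(3, 40))
            icc = rng.uniform(0, 0.9)
            y, pairs = make_paired_gaussian(q, icc, rng)
            fit = sm.fit_memory_model(y, pairs)
            sb2, se2 = anova_estimator(y, q)
            assert fit.sigma_b2 == pytest.approx(sb2, abs=1e-6)
            assert fit.sigma_e2 == pytest.approx(se2, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent REML oracle: statsmodels MixedLM on the same data."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        y, pairs = make_paired_gaussian(25, 0.5, rng)
        fit = sm.fit_memory_model(y, pairs)
        ref = smf.mixedlm("y ~ 1", pd.DataFrame({"y": y, "pair": pairs}),
                          groups="pair").fit(reml=True)
        assert fit.sigma_b2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(float(ref.scale), abs=1e-4)
        assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-6)

    def test_within_pair_identical_values_icc_one(self):
        y = np.repeat([1.0, 5.0, 9.0, 2.0], 2)
        pairs = np.repeat(list("abcd"), 2)
        fit = sm.fit_memory_model(y, pairs)
        assert fit.sigma_e2 == pytest.approx(0.0)
        assert fit.icc == pytest.approx(1.0)

    def test_iid_data_hits_zero_boundary_mostly(self):
        rng = np.random.default_rng(8)
        at_zero = sum(
            sm.fit_memory_model(*make_paired_gaussian(20, 0.0, rng)).sigma_b2 == 0.0
            for _ in range(40)
        )
        assert at_zero > 20

    def test_icc_recovery_500_pairs(self):
        rng = np.random.default_rng(5)
        y, pairs = make_paired_gaussian(500, 0.6, rng)
        fit = sm.fit_memory_model(y, pairs)
        assert fit.icc == pytest.approx(0.6, abs=0.05)

    def test_icc_recovery_operating_curve_30_pairs(self):
        rng = np.random.default_rng(12)
        errors = [
            abs(sm.fit_memory_model(*make_paired_gaussian(30, 0.6, rng)).icc - 0.6)
            for _ in range(50)
        ]
        assert np.median(errors) <= 0.15

    def test_condition_effect_estimated(self):
        rng = np.random.default_rng(6)
        q = 100
        cond = np.repeat(np.tile(["self_renewing", "differentiating"], q // 2), 2)
        y, pairs = make_paired_gaussian(q, 0.4, rng, condition=cond, beta=1.5)
        fit = sm.fit_memory_model(y, pairs, cond)
        assert fit.has_condition
        # dummy codes the lexicographically later level
        assert fit.beta[1] == pytest.approx(-1.5, abs=0.5)

    def test_condition_varying_within_pair_rejected(self):
        y = np.arange(8.0)
        pairs = np.repeat(list("abcd"), 2)
        cond = np.tile(["x", "y"], 4)
        with pytest.raises(ValueError):
            sm.fit_memory_model(y, pairs, cond)

    @pytest.mark.parametrize("bad_pairs", [
        ["a", "a", "a", "b", "b", "c"],          # triple + singleton
        ["a", "a", "b", "b"],                     # only 2 pairs
    ])
    def test_bad_structure_rejected(self, bad_pairs):
        with pytest.raises(ValueError):
            sm.fit_memory_model(np.arange(float(len(bad_pairs))), bad_pairs)


class TestLrt:
    def test_zero_stat_gives_p_one(self):
        rng = np.random.default_rng(1)
        # strong within-pair disagreement pushes sigma_b2 to the boundary
        y = rng.normal(size=20)
        pairs = np.repeat([f"p{i}" for i in range(10)], 2)
        full = sm.fit_memory_model(y, pairs)
        null = sm.fit_null_model(y, pairs)
        lrt = sm.lrt_memory(full, null)
        if lrt["stat"] == 0.0:
            assert lrt["p"] == 1.0

    def test_boundary_mixture_halves_p(self):
        rng = np.random.default_rng(2)
        y, pairs = make_paired_gaussian(50, 0.5, rng)
        full, null = sm.fit_memory_model(y, pairs), sm.fit_null_model(y, pairs)
        default = sm.lrt_memory(full, null)
        mixture = sm.lrt_memory(full, null, boundary=True)
        assert default["stat"] > 0
        assert mixture["p"] == pytest.approx(default["p"] / 2)

    def test_mismatched_fixed_effects_rejected(self):
        rng = np.random.default_rng(3)
        q = 20
        cond = np.repeat(np.tile(["a", "b"], q // 2), 2)
        y, pairs = make_paired_gaussian(q, 0.3, rng)
        full = sm.fit_memory_model(y, pairs, cond)
        null = sm.fit_null_model(y, pairs)
        with pytest.raises(ValueError):
            sm.lrt_memory(full, null)

    def test_type_i_error_controlled_under_global_null(self):
        """Raw p stochastically >= uniform (boundary-conservative);
        BH detections essentially absent."""
        rates, raw_rates = [], []
        for s in range(10):
            cfg = sm.SimulationConfig(n_families=30, generation=1, n_genes=1000,
                                      frac_memory=0.0, seed=4000 + s)
            ped = sm.simulate_pedigree(cfg)
            x = sm.simulate_expression(ped, cfg)
            res = sm.detect_memory_genes(x)
            rates.append(res["memory"].mean())
            raw_rates.append((res["p_raw"] < 0.05).mean())
        assert max(rates) <= 0.05
        assert np.mean(raw_rates) <= 0.05


class TestBH:
    def test_single_p_unchanged(self):
        assert sm.adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(sm.adjust_bh([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @staticmethod
    def reference_step_up(p):
        """Independent BH implementation: literal step-up rule."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * m / rank)
            adj[i] = running_min
        return adj

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_independent_reference(self, pvals):
        np.testing.assert_allclose(sm.adjust_bh(pvals),
                                   self.reference_step_up(pvals), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.adjust_bh([0.5, 1.2])


class TestDetection:
    def test_power_and_fdr_on_planted_memory(self):
        """10% memory genes at ICC 0.6, 30 pairs: BH recovers >= 80% of the
        planted genes on average with FDR <= 0.1, over 20 seeds."""
        recalls, fdrs = [], []
        for s in range(20):
            cfg = sm.SimulationConfig(n_families=30, generation=1, n_genes=1000,
                                      frac_memory=0.1, icc_memory=0.6, seed=s)
            ped = sm.simulate_pedigree(cfg)
            x = sm.simulate_expression(ped, cfg)
            det = sm.detect_memory_genes(x)["memory"].to_numpy()
            true = x.var["is_memory"].to_numpy()
            recalls.append((det & true).sum() / true.sum())
            fdrs.append((det & ~true).sum() / max(1, det.sum()))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.1

    def test_label_invariance(self, gen1_memory_data):
        ped, x = gen1_memory_data
        base = sm.detect_memory_genes(x)
        rng = np.random.default_rng(0)
        gperm = rng.permutation(x.n_vars)
        cperm = rng.permutation(x.n_obs)
        shuffled = x[cperm, gperm].copy()
        res = sm.detect_memory_genes(shuffled)
        np.testing.assert_allclose(res["icc"].to_numpy(),
                                   base["icc"].to_numpy()[gperm], atol=1e-10)
        # boundary genes (stat exactly 0 vs ~1e-14) allow float-level jitter
        np.testing.assert_allclose(res["p_raw"].to_numpy(),
                                   base["p_raw"].to_numpy()[gperm], atol=1e-6)

    def test_condition_encoding_invariance(self):
        cfg = sm.SimulationConfig(n_families=20, generation=1, n_genes=50,
                                  frac_memory=0.2, icc_memory=0.5, seed=13)
        ped = sm.simulate_pedigree(cfg)
        x = sm.simulate_expression(ped, cfg)
        base = sm.detect_memory_genes(x)
        renamed = x.copy()
        renamed.obs["condition"] = renamed.obs["condition"].map(
            {"self_renewing": "zzz_sr", "differentiating": "aaa_diff"}
        )
        res = sm.detect_memory_genes(renamed)
        np.testing.assert_allclose(res["icc"], base["icc"], atol=1e-10)
        np.testing.assert_allclose(res["lrt_stat"], base["lrt_stat"], atol=1e-8)
        # the dummy coding flips, so only the magnitude of beta is invariant
        np.testing.assert_allclose(np.abs(res["beta_condition"]),
                                   np.abs(base["beta_condition"]), atol=1e-10)

    def test_missing_value_path_agrees_with_vectorized(self, gen1_memory_data):
        ped, x = gen1_memory_data
        base = sm.detect_memory_genes(x)
        nanned = x.copy()
        X = np.asarray(nanned.X, dtype=float).copy()
        X[0, 0] = np.nan  # gene g0000 loses one pair; others untouched
        nanned.X = X
        res = sm.detect_memory_genes(nanned)
        clean = res.index[1:]
        np.testing.assert_allclose(res.loc[clean, "p_raw"].astype(float),
                                   base.loc[clean, "p_raw"].astype(float),
                                   atol=1e-6)
        assert res["n_pairs_used"].iloc[0] == 29


@pytest.fixture(scope="module")
def memory_data():
    cfg = sm.SimulationConfig(n_families=30, generation=1, n_genes=500,
                              frac_memory=0.1, icc_memory=0.6, seed=77)
    ped = sm.simulate_pedigree(cfg)
    return sm.simulate_expression(ped, cfg)


class TestNegativeControl:
    def test_random_pairing_detects_nothing(self, memory_data):
        detected = [
            sm.negative_control_random_pairing(memory_data, seed=s)[1]
            for s in range(20)
        ]
        assert np.median(detected) == 0
        true_detected = int(sm.detect_memory_genes(memory_data)["memory"].sum())
        assert true_detected > 0
        assert np.mean([d <= true_detected for d in detected]) >= 0.95

    def test_matching_reproducible(self, memory_data):
        r1, n1 = sm.negative_control_random_pairing(memory_data, seed=9)
        r2, n2 = sm.negative_control_random_pairing(memory_data, seed=9)
        assert n1 == n2
        np.testing.assert_allclose(r1["p_raw"].to_numpy(), r2["p_raw"].to_numpy())

    def test_odd_cell_count_drops_one(self, memory_data, caplog):
        sub = memory_data[:-1].copy()
        res, _ = sm.negative_control_random_pairing(sub, seed=0)
        assert len(res) == sub.n_vars


class TestAbundance:
    def test_random_memory_set_ks_not_extreme(self, rng):
        totals = pd.Series(rng.lognormal(5, 1, 400),
                           index=[f"g{j}" for j in range(400)])
        ps = [
            sm.abundance_enrichment(
                totals.sample(50, random_state=s).index, totals)["ks_p"]
            for s in range(20)
        ]
        # under the null the KS p-values should not pile up at zero
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_top_decile_enrichment_detected(self, rng):
        totals = pd.Series(rng.lognormal(5, 1, 400),
                           index=[f"g{j}" for j in range(400)])
        top = totals.nlargest(40).index
        out = sm.abundance_enrichment(top, totals)
        assert out["ks_p"] < 0.05

    def test_degenerate_whole_panel_rejected(self):
        totals = pd.Series([1.0], index=["g"])
        with pytest.raises(ValueError):
            sm.abundance_enrichment(["g"], totals)


class TestHalflifeJoin:
    @pytest.fixture()
    def results(self, gen1_memory_data):
        _, x = gen1_memory_data
        return sm.detect_memory_genes(x)

    def test_empty_table_adds_missing_column(self, results):
        out = sm.halflife_join(results, pd.DataFrame({"gene": []}))
        assert "halflife" in out.columns
        assert out["halflife"].isna().all()
        assert len(out) == len(results)

    def test_six_gene_overlap_cardinality(self, results):
        table = pd.DataFrame({
            "gene": [f"g{j:04d}" for j in range(6)] + ["absent1", "absent2"],
            "halflife": np.arange(8.0),
        })
        out = sm.halflife_join(results, table)
        assert out["halflife"].notna().sum() == 6

    def test_round_trip_preserves_results(self, results):
        table = pd.DataFrame({"gene": ["g0001"], "halflife": [3.0]})
        out = sm.halflife_join(results, table)
        pd.testing.assert_frame_equal(out[results.columns], results)

    def test_duplicate_keys_rejected(self, results):
        table = pd.DataFrame({"gene": ["g0001", "g0001"], "halflife": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sm.halflife_join(results, table)
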