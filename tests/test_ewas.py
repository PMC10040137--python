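"""Design construction arithmetic, the likelihood-ratio test against an
independent Gaussian log-likelihood oracle, Wald/F equivalence, BH-FDR
against brute force, and EWAS power/enrichment behaviour on simulated data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from duomethyl.config import CohortConfig
from duomethyl.ewas import bh_fdr, build_designs, encode_covariates, fit_site, run_site_ewas
from duomethyl.qc import inverse_normal_transform
from duomethyl.simulate import simulate_cohort


def _gaussian_loglik(y, x):
    """Independent oracle: maximised Gaussian log-likelihood of an OLS fit."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    n = len(y)
    sigma2 = (resid @ resid) / n
    return float(np.sum(stats.norm.logpdf(resid, scale=np.sqrt(sigma2))))


@pytest.fixture()
def site_data(rng):
    n = 120
    pairs = pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(n)],
            "mother_id": [f"M{i}" for i in range(n)],
            "newborn_id": [f"C{i}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "maternal_age": rng.uniform(18, 40, n),
            "race": np.where(rng.random(n) < 0.6, "Black", "non-Black"),
            "smoking": np.where(rng.random(n) < 0.2, "yes", "no"),
            "preterm": np.where(rng.random(n) < 0.15, "yes", "no"),
            "delivery": np.where(rng.random(n) < 0.3, "C-section", "vaginal"),
            "parity": rng.integers(1, 4, n),
        }
    )
    maternal = inverse_normal_transform(rng.uniform(0, 1, n))
    return pairs, maternal


class TestBuildDesigns:
    def test_full_adds_seven_columns_with_five_covariates(self, site_data):
        pairs, maternal = site_data
        svs = pd.DataFrame(np.random.default_rng(0).standard_normal((len(pairs), 3)),
                           columns=["sv_1", "sv_2", "sv_3"])
        full, reduced, dropped = build_designs(pairs, svs, maternal)
        # 1 maternal main + 1 maternal:sex + 5 maternal:covariate
        assert full.shape[1] == reduced.shape[1] + 7
        assert dropped == 0
        assert "maternal:sex_male" in full.columns
        assert not any(c.startswith("maternal:sv") for c in full.columns)

    def test_no_svs_designs_contain_only_clinical_terms(self, site_data):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal)
        assert list(reduced.columns) == [
            "intercept", "sex_male", "maternal_age", "race_black",
            "smoking_yes", "preterm_yes", "csection",
        ]
        assert full.shape[1] == reduced.shape[1] + 7

    def test_parity_toggle_adds_main_and_interaction(self, site_data):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal, include_parity=True)
        assert "parity" in reduced.columns
        assert "maternal:parity" in full.columns
        assert full.shape[1] == reduced.shape[1] + 8

    def test_single_level_covariate_dropped_with_warning(self, site_data):
        pairs, maternal = site_data
        pairs = pairs.assign(smoking="no")
        with pytest.warns(UserWarning, match="smoking"):
            full, reduced, _ = build_designs(pairs, None, maternal)
        assert "smoking_yes" not in reduced.columns
        assert full.shape[1] == reduced.shape[1] + 6

    def test_missing_covariates_dropped_listwise(self, site_data):
        pairs, maternal = site_data
        pairs = pairs.copy()
        pairs.loc[0, "maternal_age"] = np.nan
        full, reduced, dropped = build_designs(pairs, None, maternal)
        assert dropped == 1
        assert len(full) == len(pairs) - 1


class TestFitSite:
    def test_lrt_equals_twice_loglik_difference(self, site_data, rng):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal)
        y = rng.standard_normal(len(full))
        res = fit_site(y, full, reduced)
        oracle = 2 * (_gaussian_loglik(y, full.to_numpy()) - _gaussian_loglik(y, reduced.to_numpy()))
        assert res["lrt_stat"] == pytest.approx(oracle, abs=1e-8)

    def test_exact_reduced_fit_gives_zero_statistic(self, site_data):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal)
        y = reduced.to_numpy() @ np.arange(1.0, reduced.shape[1] + 1)
        res = fit_site(y, full, reduced)
        assert res["lrt_stat"] == pytest.approx(0.0, abs=1e-6)
        assert res["p_lrt"] == pytest.approx(1.0, abs=1e-6)

    def test_lrt_invariant_to_affine_covariate_rescaling(self, site_data, rng):
        pairs, maternal = site_data
        y = rng.standard_normal(len(pairs))
        full, reduced, _ = build_designs(pairs, None, maternal)
        base = fit_site(y, full, reduced)
        pairs2 = pairs.assign(maternal_age=pairs["maternal_age"] * 10 + 5)
        full2, reduced2, _ = build_designs(pairs2, None, maternal)
        scaled = fit_site(y, full2, reduced2)
        assert scaled["lrt_stat"] == pytest.approx(base["lrt_stat"], abs=1e-8)
        assert scaled["p_interaction"] == pytest.approx(base["p_interaction"], abs=1e-8)

    def test_wald_t_matches_single_constraint_f(self, site_data, rng):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal)
        y = rng.standard_normal(len(full))
        res = fit_site(y, full, reduced)
        # F test dropping only the interaction column
        xf = full.to_numpy()
        xr = full.drop(columns="maternal:sex_male").to_numpy()
        rss_f = np.sum((y - xf @ np.linalg.lstsq(xf, y, rcond=None)[0]) ** 2)
        rss_r = np.sum((y - xr @ np.linalg.lstsq(xr, y, rcond=None)[0]) ** 2)
        df2 = len(y) - xf.shape[1]
        f = (rss_r - rss_f) / (rss_f / df2)
        t2 = (res["beta_interaction"] / res["se_interaction"]) ** 2
        assert t2 == pytest.approx(f, abs=1e-10)
        assert res["p_interaction"] == pytest.approx(float(stats.f.sf(f, 1, df2)), abs=1e-10)

    def test_rank_deficient_design_flagged_not_fatal(self, site_data, rng):
        pairs, maternal = site_data
        full, reduced, _ = build_designs(pairs, None, maternal)
        full = full.assign(dup=full["sex_male"])
        res = fit_site(rng.standard_normal(len(full)), full, reduced)
        assert res["flag"] == "rank_deficient"
        assert np.isnan(res["p_lrt"])


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels_over_random_draws(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_nan_ignored_and_propagated(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))


class TestRunSiteEwas:
    def test_heritable_sites_rank_ahead_of_null_sites(self):
        cfg = CohortConfig(
            n_pairs=200, n_auto_sites=400, n_x_sites=1, n_latent_factors=0,
            frac_sex_differential=0.0, seed=41,
        )
        co = simulate_cohort(cfg)
        res = run_site_ewas(co.maternal, co.neonatal, co.pairs)
        h2 = co.truth.site_params.set_index("site_id")["h2"]
        merged = res.merge(h2, left_on="site_id", right_index=True)
        high = merged.loc[merged["h2"] >= 0.6, "p_lrt"].median()
        low = merged.loc[merged["h2"] <= 0.05, "p_lrt"].median()
        assert high < low
        sig = merged.loc[merged["significant_lrt"], "h2"]
        assert sig.mean() > merged["h2"].mean()

    def test_injected_sex_interaction_recovered(self, rng):
        # male slope 0, female slope 0.5 on 20 signal sites; 180 null sites
        n = 400
        sexes = np.array(["female", "male"])[rng.integers(0, 2, n)]
        pairs = pd.DataFrame(
            {"pair_id": [f"P{i}" for i in range(n)],
             "mother_id": [f"M{i}" for i in range(n)],
             "newborn_id": [f"C{i}" for i in range(n)],
             "sex": sexes,
             "maternal_age": rng.uniform(18, 40, n),
             "race": np.where(rng.random(n) < 0.6, "Black", "non-Black"),
             "smoking": np.where(rng.random(n) < 0.2, "yes", "no"),
             "preterm": np.where(rng.random(n) < 0.15, "yes", "no"),
             "delivery": np.where(rng.random(n) < 0.3, "C-section", "vaginal")}
        )
        female = (sexes == "female").astype(float)
        n_sites, n_signal = 200, 20
        sites = [f"cg{i:05d}" for i in range(n_sites)]
        lat_m = rng.standard_normal((n_sites, n))
        noise = rng.standard_normal((n_sites, n))
        slope = np.zeros((n_sites, 1))
        slope[:n_signal] = 0.5
        lat_c = slope * lat_m * female[None, :] + noise
        from scipy.special import expit
        maternal = pd.DataFrame(expit(lat_m), index=sites, columns=pairs["mother_id"].tolist())
        neonatal = pd.DataFrame(expit(lat_c), index=sites, columns=pairs["newborn_id"].tolist())
        res = run_site_ewas(maternal, neonatal, pairs, fdr_threshold=0.1)
        hits = res.iloc[:n_signal]["fdr_interaction"] < 0.1
        assert hits.sum() >= 15

    def test_column_permutation_invariance(self, cohort_null):
        res = run_site_ewas(cohort_null.maternal, cohort_null.neonatal, cohort_null.pairs)
        perm = np.random.default_rng(0).permutation(len(cohort_null.pairs))
        pairs_p = cohort_null.pairs.iloc[perm].reset_index(drop=True)
        res_p = run_site_ewas(cohort_null.maternal, cohort_null.neonatal, pairs_p)
        np.testing.assert_allclose(res["p_lrt"], res_p["p_lrt"], atol=1e-8)

    def test_constant_site_flagged(self, cohort_null):
        maternal = cohort_null.maternal.copy()
        maternal.iloc[0] = 0.5
        res = run_site_ewas(maternal.iloc[:10], cohort_null.neonatal.iloc[:10], cohort_null.pairs)
        assert res.iloc[0]["flag"] == "constant"
        assert np.isnan(res.iloc[0]["p_lrt"])


class TestEncodeCovariates:
    def test_sex_coding_female_zero_male_one(self, toy_pairs):
        enc = encode_covariates(toy_pairs)
        np.testing.assert_array_equal(enc["sex_male"], [0, 1, 0, 1, 0, 1])
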