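"""Per-pair Spearman correlations, the derangement-based permutation null,
and the matched-vs-background / between-sex t comparisons."""

import numpy as np
import pandas as pd
import pytest

from duomethyl.config import CohortConfig, H2Mixture
from duomethyl.paircorr import (
    compare_by_sex,
    compare_matched_vs_background,
    pair_spearman,
    permutation_background,
)
from duomethyl.simulate import simulate_cohort


def _tiny(maternal_vals, neonatal_vals, chrom="1"):
    """One-pair cohort with explicit site values."""
    n = len(maternal_vals)
    sites = [f"cg{i}" for i in range(n)]
    maternal = pd.DataFrame({"M0": maternal_vals}, index=sites)
    neonatal = pd.DataFrame({"C0": neonatal_vals}, index=sites)
    pairs = pd.DataFrame(
        {"pair_id": ["P0"], "mother_id": ["M0"], "newborn_id": ["C0"], "sex": ["female"]}
    )
    annotation = pd.DataFrame({"site_id": sites, "chromosome": [chrom] * n})
    return maternal, neonatal, pairs, annotation


class TestPairSpearman:
    def test_identical_vectors_give_rho_one(self, cohort_default):
        res = pair_spearman(
            cohort_default.maternal,
            cohort_default.maternal.set_axis(cohort_default.pairs["newborn_id"].tolist(), axis=1),
            cohort_default.pairs,
            cohort_default.annotation,
        )
        for col in ("rho_all", "rho_auto", "rho_x"):
            np.testing.assert_allclose(res[col], 1.0, atol=1e-12)

    def test_closed_form_five_point_example(self):
        # d = (0, 1, -1, 1, -1), sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        m, c, pairs, ann = _tiny([0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.3, 0.2, 0.5, 0.4])
        res = pair_spearman(m, c, pairs, ann)
        assert res["rho_all"].iloc[0] == pytest.approx(0.8, abs=1e-12)
        assert res["rho_auto"].iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_rank_reversal_gives_minus_one(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        m, c, pairs, ann = _tiny(vals, [1 - v for v in vals])
        assert pair_spearman(m, c, pairs, ann)["rho_all"].iloc[0] == pytest.approx(-1.0)

    def test_unresolvable_sample_errors_with_pair_name(self, cohort_default):
        pairs = cohort_default.pairs.copy()
        pairs.loc[0, "mother_id"] = "NOPE"
        with pytest.raises(ValueError, match=pairs.loc[0, "pair_id"]):
            pair_spearman(cohort_default.maternal, cohort_default.neonatal, pairs, cohort_default.annotation)

    def test_missing_values_dropped_pairwise(self):
        m, c, pairs, ann = _tiny([0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.3, 0.2, 0.5, 0.4])
        m_miss = m.copy()
        m_miss.iloc[0, 0] = np.nan
        res = pair_spearman(m_miss, c, pairs, ann)
        # remaining 4 points: neonatal ranks (2,1,4,3) vs maternal (1,2,3,4)
        d2 = 1 + 1 + 1 + 1
        expected = 1 - 6 * d2 / (4 * 15)
        assert res["rho_all"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_mixture_consistency_of_subsets(self, cohort_default):
        res = pair_spearman(
            cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs, cohort_default.annotation
        )
        ann = cohort_default.annotation
        w_x = (ann["chromosome"] == "X").mean()
        interp = (1 - w_x) * res["rho_auto"] + w_x * res["rho_x"]
        assert (np.abs(res["rho_all"] - interp) < 0.1).all()


class TestPermutationBackground:
    def test_two_pairs_forces_the_swap(self):
        sites = [f"cg{i}" for i in range(6)]
        rngv = np.random.default_rng(0).uniform(0.1, 0.9, (6, 2))
        maternal = pd.DataFrame(rngv, index=sites, columns=["M0", "M1"])
        neonatal = pd.DataFrame(rngv[::-1], index=sites, columns=["C0", "C1"])
        pairs = pd.DataFrame(
            {"pair_id": ["P0", "P1"], "mother_id": ["M0", "M1"],
             "newborn_id": ["C0", "C1"], "sex": ["male", "male"]}
        )
        ann = pd.DataFrame({"site_id": sites, "chromosome": ["1"] * 6})
        bg = permutation_background(maternal, neonatal, pairs, ann, n_iter=4, seed=5)
        matched_swap = pair_spearman(
            maternal.set_axis(["M1", "M0"], axis=1), neonatal, pairs, ann
        )
        np.testing.assert_allclose(bg["rho_all"], matched_swap["rho_all"], atol=1e-12)

    def test_seeded_determinism(self, cohort_default):
        args = (cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs, cohort_default.annotation)
        a = permutation_background(*args, n_iter=3, seed=42)
        b = permutation_background(*args, n_iter=3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_cohort_background_matches_matched(self, cohort_null):
        matched = pair_spearman(cohort_null.maternal, cohort_null.neonatal, cohort_null.pairs, cohort_null.annotation)
        bg = permutation_background(
            cohort_null.maternal, cohort_null.neonatal, cohort_null.pairs, cohort_null.annotation,
            n_iter=10, seed=0,
        )
        res = compare_matched_vs_background(matched, bg)
        assert res["p"] > 0.05

    def test_stratum_of_one_errors(self, cohort_default):
        pairs = cohort_default.pairs.copy()
        female_idx = pairs.index[pairs["sex"] == "female"]
        pairs = pairs.drop(female_idx[1:])
        with pytest.raises(ValueError, match="derangement"):
            permutation_background(
                cohort_default.maternal, cohort_default.neonatal, pairs, cohort_default.annotation,
                n_iter=1, seed=0,
            )

    def test_zero_iterations_errors(self, cohort_default):
        with pytest.raises(ValueError, match="n_iter"):
            permutation_background(
                cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs,
                cohort_default.annotation, n_iter=0, seed=0,
            )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matched_exceeds_background_with_heritability(self, seed):
        cfg = CohortConfig(
            n_pairs=100, n_auto_sites=500, n_x_sites=50, n_latent_factors=0,
            h2_distribution=H2Mixture(frac_low=0.5, low_range=(0.0, 0.05), high_range=(0.3, 0.9)),
            seed=seed,
        )
        co = simulate_cohort(cfg)
        matched = pair_spearman(co.maternal, co.neonatal, co.pairs, co.annotation)
        bg = permutation_background(co.maternal, co.neonatal, co.pairs, co.annotation, n_iter=5, seed=seed)
        assert matched["rho_all"].mean() > bg["rho_all"].mean()


class TestComparisons:
    def test_degenerate_identical_sets_flagged(self, cohort_default):
        matched = pair_spearman(
            cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs, cohort_default.annotation
        )
        res = compare_matched_vs_background(matched, matched.assign(source="background"))
        assert res["p"] == 1.0
        assert "degenerate_variance" in res["flags"]

    def test_uniform_shift_moves_t_by_known_amount(self, rng):
        n = 50
        rho_m = rng.uniform(0.7, 0.95, n)
        rho_b = rho_m - rng.uniform(0.01, 0.1, n)
        base = pd.DataFrame({"pair_id": [f"P{i}" for i in range(n)], "newborn_sex": "female"})
        matched = base.assign(rho_all=rho_m, source="matched")
        bg = base.assign(rho_all=rho_b, source="background")
        t0 = compare_matched_vs_background(matched, bg)["statistic"]
        c = 0.03
        t1 = compare_matched_vs_background(matched, bg.assign(rho_all=rho_b + c))["statistic"]
        sd = np.std(rho_m - rho_b, ddof=1)
        assert t1 == pytest.approx(t0 - c * np.sqrt(n) / sd, rel=1e-10)

    def test_signal_cohort_matched_beats_background(self):
        cfg = CohortConfig(
            n_pairs=200, n_auto_sites=600, n_x_sites=60, n_latent_factors=0,
            h2_distribution=H2Mixture.point_mass(0.4), seed=31,
        )
        co = simulate_cohort(cfg)
        matched = pair_spearman(co.maternal, co.neonatal, co.pairs, co.annotation)
        bg = permutation_background(co.maternal, co.neonatal, co.pairs, co.annotation, n_iter=5, seed=31)
        res = compare_matched_vs_background(matched, bg)
        assert res["group_means"]["matched"] > res["group_means"]["background"]
        assert res["p"] < 0.01

    def test_identical_sex_distributions_give_p_one(self):
        rho = np.tile(np.linspace(0.8, 0.95, 10), 2)
        df = pd.DataFrame(
            {"pair_id": [f"P{i}" for i in range(20)],
             "newborn_sex": ["female"] * 10 + ["male"] * 10,
             "rho_all": rho, "source": "matched"}
        )
        res = compare_by_sex(df)
        assert res["p"] == pytest.approx(1.0)
        assert res["group_means"]["female"] == pytest.approx(res["group_means"]["male"])

    def test_xci_cohort_female_x_rho_higher(self, cohort_default):
        matched = pair_spearman(
            cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs, cohort_default.annotation
        )
        res = compare_by_sex(matched, subset="x")
        assert res["group_means"]["female"] > res["group_means"]["male"]
        assert res["p"] < 0.01

    def test_single_sex_cohort_errors(self, cohort_default):
        matched = pair_spearman(
            cohort_default.maternal, cohort_default.neonatal, cohort_default.pairs, cohort_default.annotation
        )
        with pytest.raises(ValueError, match="both sexes"):
            compare_by_sex(matched.loc[matched["newborn_sex"] == "female"])
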