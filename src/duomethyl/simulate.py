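"""Paired mother-newborn methylome simulator.

Generates maternal and neonatal beta-value matrices with the statistical
structure the downstream analysis assumes, together with a truth table, so
every stage of the pipeline can be exercised against known answers.

Generative model (logit scale, per site j and pair i):

    logit(beta_maternal) = mu_j + age_slope_j * (age_i - age_mid)
                           + g_m + sum_k loading_jk * L_ik + eps

with Var(g_m) = h2_j * sigma_tot_j^2 and eps ~ N(0, noise_sd^2), where
sigma_tot_j^2 = noise_sd^2 / (1 - h2_j) so that h2_j is the additive-genetic
fraction of the (age- and batch-free) variance. The newborn's genetic value
is g_c = 0.5 * g_m + e with Var(e) = 0.75 * Var(g_m): paternal genomes are
unobserved, and this additive model yields the canonical parent-offspring
correlation of h2/2 on the latent scale.

X-inactivated sites follow a balanced-XCI allele-average model: mothers and
female newborns emit beta = 0.5 * (inv-logit(active draw) + inv-logit(inactive
draw centred at mu_inactive)), where the inactive-X allele is predominantly
methylated (mu_inactive high); male newborns are hemizygous and emit the
single active-allele draw. This is the mechanism that makes mother-male
methylation differences on the X negative while mother-female differences
centre on zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig, ConfigError
from ._util import derive_seed

BETA_EPS = 1e-6
H2_CAP = 0.98

CHROM_AUTOSOME = "autosome"
CHROM_X_ESCAPE = "X_escape"
CHROM_X_INACTIVATED = "X_inactivated"

_FUNCTIONAL_REGIONS = ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"]
_ISLAND_RELATIONS = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]

# sampling weights loosely shaped like array manifests: gene bodies dominate
# genome-wide, XCI-subject sites skew toward island promoters
_REGION_W_AUTO = [0.14, 0.08, 0.09, 0.05, 0.40, 0.05, 0.19]
_REGION_W_XCI = [0.25, 0.18, 0.12, 0.08, 0.27, 0.03, 0.07]
_ISLAND_W_AUTO = [0.30, 0.12, 0.12, 0.05, 0.05, 0.36]
_ISLAND_W_XCI = [0.62, 0.15, 0.13, 0.02, 0.02, 0.06]


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort: per-site parameters, per-sample
    latent factor scores, and the latent genetic values actually drawn."""

    site_params: pd.DataFrame
    latent_maternal: pd.DataFrame
    latent_neonatal: pd.DataFrame
    genetic_maternal: pd.DataFrame
    genetic_neonatal: pd.DataFrame


@dataclass
class SimulatedCohort:
    maternal: pd.DataFrame  # sites x mother samples, beta values
    neonatal: pd.DataFrame  # sites x newborn samples, beta values
    pairs: pd.DataFrame
    annotation: pd.DataFrame
    truth: TruthTable

    def __iter__(self):
        return iter((self.maternal, self.neonatal, self.pairs, self.annotation, self.truth))


def simulate_site_params(config: CohortConfig) -> pd.DataFrame:
    """Draw per-site generative parameters.

    Returns a DataFrame with one row per site: chromosome class, baseline
    logit mean, heritability, sex effect (autosomal sex-differential sites),
    maternal age slope, latent-factor loadings, and the inactive-allele mean
    for X-inactivated sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_auto, n_x = config.n_auto_sites, config.n_x_sites
    n_sites = n_auto + n_x
    n_xci = int(round(config.frac_x_inactivated * n_x))

    chrom_class = np.array(
        [CHROM_AUTOSOME] * n_auto + [CHROM_X_INACTIVATED] * n_xci + [CHROM_X_ESCAPE] * (n_x - n_xci)
    )
    site_id = np.array([f"cg{j:08d}" for j in range(1, n_sites + 1)])

    # baseline means: autosomes/escape bimodal (hypo/hyper), XCI active allele
    # low (island-promoter-like), inactive allele high
    mu = np.empty(n_sites)
    non_xci = chrom_class != CHROM_X_INACTIVATED
    n_non = int(non_xci.sum())
    comp = rng.choice(3, size=n_non, p=[0.4, 0.4, 0.2])
    mu_non = np.where(
        comp == 0,
        rng.normal(-2.5, 0.8, n_non),
        np.where(comp == 1, rng.normal(2.5, 0.8, n_non), rng.normal(0.0, 1.0, n_non)),
    )
    mu[non_xci] = mu_non
    mu[~non_xci] = rng.normal(-2.0, 0.7, n_sites - n_non)

    mu_inactive = np.full(n_sites, np.nan)
    mu_inactive[~non_xci] = rng.normal(2.0, 0.7, n_sites - n_non)

    h2 = np.minimum(config.h2_distribution.draw(rng, n_sites), H2_CAP)

    sex_effect = np.zeros(n_sites)
    is_auto = chrom_class == CHROM_AUTOSOME
    flagged = is_auto & (rng.random(n_sites) < config.frac_sex_differential)
    sex_effect[flagged] = rng.normal(0.0, config.sex_effect_sd, int(flagged.sum()))

    age_slope = rng.normal(0.0, config.age_slope_sd, n_sites) if config.age_slope_sd > 0 else np.zeros(n_sites)

    params = pd.DataFrame(
        {
            "site_id": site_id,
            "chrom_class": chrom_class,
            "mu": mu,
            "h2": h2,
            "sex_effect": sex_effect,
            "age_slope": age_slope,
            "mu_inactive": mu_inactive,
        }
    )
    for k in range(config.n_latent_factors):
        loaded = rng.random(n_sites) < config.frac_loaded
        if config.fixed_loading is not None:
            vals = np.where(loaded, config.fixed_loading, 0.0)
        else:
            vals = np.where(loaded, rng.normal(0.0, config.loading_sd, n_sites), 0.0)
        params[f"loading_{k + 1}"] = vals
    return params


def _draw_latent_scores(rng, n, k, binary):
    if binary:
        return (rng.random((n, k)) < 0.5).astype(float) - 0.5
    return rng.standard_normal((n, k))


def _sample_sheet(rng, config: CohortConfig) -> pd.DataFrame:
    n = config.n_pairs
    sex = np.where(rng.random(n) < config.frac_male, "male", "female")
    lo, hi = config.maternal_age_range
    age = rng.uniform(lo, hi, n)
    race = np.where(rng.random(n) < 0.655, "Black", "non-Black")
    smoking = np.where(rng.random(n) < 0.11, "yes", "no")
    # preterm is more frequent among male newborns, as birth-cohort tables show
    p_pre = np.where(sex == "male", 0.208, 0.111)
    preterm = np.where(rng.random(n) < p_pre, "yes", "no")
    delivery = np.where(rng.random(n) < 0.30, "C-section", "vaginal")
    parity = rng.choice([1, 2, 3], size=n, p=[0.46, 0.26, 0.28])
    return pd.DataFrame(
        {
            "pair_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "mother_id": [f"M{i:04d}" for i in range(1, n + 1)],
            "newborn_id": [f"C{i:04d}" for i in range(1, n + 1)],
            "sex": sex,
            "maternal_age": age,
            "race": race,
            "smoking": smoking,
            "preterm": preterm,
            "delivery": delivery,
            "parity": parity,
        }
    )


def _annotation(rng, params: pd.DataFrame) -> pd.DataFrame:
    n_sites = len(params)
    is_x = (params["chrom_class"] != CHROM_AUTOSOME).to_numpy()
    is_xci = (params["chrom_class"] == CHROM_X_INACTIVATED).to_numpy()

    chrom = np.where(is_x, "X", rng.integers(1, 23, n_sites).astype(str))
    position = rng.integers(1, 150_000_000, n_sites)

    n_genes = max(3, n_sites // 3)
    gene_pool = np.array([f"GENE{g:05d}" for g in range(1, n_genes + 1)])
    auto_genes = gene_pool[: max(2, int(n_genes * 0.8))]
    x_genes = gene_pool[max(2, int(n_genes * 0.8)):]
    if len(x_genes) == 0:
        x_genes = gene_pool[-1:]

    genes = []
    u = rng.random(n_sites)
    for j in range(n_sites):
        pool = x_genes if is_x[j] else auto_genes
        if u[j] < 0.15:
            genes.append("")  # intergenic
        elif u[j] < 0.25:
            picks = rng.choice(pool, size=min(2, len(pool)), replace=False)
            genes.append(";".join(sorted(picks)))
        else:
            genes.append(str(rng.choice(pool)))

    region = np.empty(n_sites, dtype=object)
    island = np.empty(n_sites, dtype=object)
    for mask, rw, iw in ((is_xci, _REGION_W_XCI, _ISLAND_W_XCI), (~is_xci, _REGION_W_AUTO, _ISLAND_W_AUTO)):
        m = int(mask.sum())
        if m:
            region[mask] = rng.choice(_FUNCTIONAL_REGIONS, size=m, p=rw)
            island[mask] = rng.choice(_ISLAND_RELATIONS, size=m, p=iw)
    # sites annotated intergenic in the gene column stay consistent
    region[np.array([g == "" for g in genes])] = "intergenic"

    h2 = params["h2"].to_numpy().copy()
    h2[is_x] = np.nan  # heritability catalogues cover autosomes only

    return pd.DataFrame(
        {
            "site_id": params["site_id"].to_numpy(),
            "chromosome": chrom,
            "position": position,
            "genes": genes,
            "functional_region": region,
            "island_relation": island,
            "h2": h2,
        }
    )


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a paired maternal/neonatal methylome cohort.

    Returns beta matrices (sites x samples), the pair/sample sheet, a
    manifest-style site annotation table, and the full ground truth.
    Deterministic given ``config.seed``; all betas lie strictly inside (0,1).
    """
    config.validate()
    if config.noise_sd <= 0:
        raise ConfigError(f"noise_sd must be > 0, got {config.noise_sd}")

    params = simulate_site_params(config)
    rng = np.random.default_rng(derive_seed(config.seed, "cohort-samples"))

    pairs = _sample_sheet(rng, config)
    n, s = config.n_pairs, len(params)
    k = config.n_latent_factors

    h2 = params["h2"].to_numpy()
    mu = params["mu"].to_numpy()
    sigma_tot2 = config.noise_sd**2 / (1.0 - h2)
    sd_g = np.sqrt(h2 * sigma_tot2)

    g_m = sd_g[:, None] * rng.standard_normal((s, n))
    g_c = 0.5 * g_m + np.sqrt(0.75) * sd_g[:, None] * rng.standard_normal((s, n))

    loadings = (
        params[[f"loading_{j + 1}" for j in range(k)]].to_numpy() if k else np.zeros((s, 0))
    )
    l_m = _draw_latent_scores(rng, n, k, config.latent_binary)
    l_c = l_m if config.share_latent_within_pair else _draw_latent_scores(rng, n, k, config.latent_binary)
    if config.latent_newborn_only:
        # e.g. cord-blood plates distinct from maternal plates: the latent
        # structure hits only the newborn samples
        l_m = np.zeros_like(l_m)

    age_mid = 0.5 * (config.maternal_age_range[0] + config.maternal_age_range[1])
    age_term = params["age_slope"].to_numpy()[:, None] * (pairs["maternal_age"].to_numpy() - age_mid)[None, :]

    male = (pairs["sex"] == "male").to_numpy()
    sex_term = params["sex_effect"].to_numpy()[:, None] * male[None, :]

    logit_m = mu[:, None] + age_term + g_m + loadings @ l_m.T + rng.normal(0, config.noise_sd, (s, n))
    logit_c = mu[:, None] + g_c + loadings @ l_c.T + sex_term + rng.normal(0, config.noise_sd, (s, n))

    beta_m = expit(logit_m)
    beta_c = expit(logit_c)

    # XCI allele-average model for mothers and female newborns
    xci = (params["chrom_class"] == CHROM_X_INACTIVATED).to_numpy()
    if xci.any():
        mu_in = params.loc[xci, "mu_inactive"].to_numpy()[:, None]
        inact_m = expit(mu_in + rng.normal(0, config.noise_sd, (int(xci.sum()), n)))
        inact_c = expit(mu_in + rng.normal(0, config.noise_sd, (int(xci.sum()), n)))
        beta_m[xci] = 0.5 * (beta_m[xci] + inact_m)
        female = ~male
        mixed = 0.5 * (beta_c[xci] + inact_c)
        beta_c[np.ix_(xci, female)] = mixed[:, female]
        # males keep the single active-allele draw

    beta_m = np.clip(beta_m, BETA_EPS, 1 - BETA_EPS)
    beta_c = np.clip(beta_c, BETA_EPS, 1 - BETA_EPS)

    site_index = pd.Index(params["site_id"], name="site_id")
    maternal = pd.DataFrame(beta_m, index=site_index, columns=pairs["mother_id"].to_numpy())
    neonatal = pd.DataFrame(beta_c, index=site_index, columns=pairs["newborn_id"].to_numpy())
    annotation = _annotation(rng, params)
    truth = TruthTable(
        site_params=params,
        latent_maternal=pd.DataFrame(l_m, index=pairs["mother_id"], columns=[f"factor_{j + 1}" for j in range(k)]),
        latent_neonatal=pd.DataFrame(l_c, index=pairs["newborn_id"], columns=[f"factor_{j + 1}" for j in range(k)]),
        genetic_maternal=pd.DataFrame(g_m, index=site_index, columns=pairs["mother_id"].to_numpy()),
        genetic_neonatal=pd.DataFrame(g_c, index=site_index, columns=pairs["newborn_id"].to_numpy()),
    )
    return SimulatedCohort(maternal, neonatal, pairs, annotation, truth)
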