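"""Per-pair genome-wide Spearman correlations and the sex-matched permutation null.

Each mother-newborn pair gets a Spearman rho over all shared sites and over
the autosomal and X-chromosomal subsets. The null ("background") distribution
is built by repeatedly reassigning newborns to unrelated mothers within the
same newborn-sex stratum via a derangement (no newborn ever keeps its own
mother), and averaging each newborn's rho over iterations. A paired t test
compares matched against background; a Welch two-sample t compares rho
between newborn sexes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

SUBSETS = ("all", "auto", "x")


def _aligned_matrices(maternal, neonatal, pairs):
    shared = maternal.index.intersection(neonatal.index)
    if len(shared) == 0:
        raise ValueError("maternal and neonatal matrices share no sites")
    missing_m = set(pairs["mother_id"]) - set(maternal.columns)
    missing_c = set(pairs["newborn_id"]) - set(neonatal.columns)
    if missing_m or missing_c:
        bad = pairs.loc[
            pairs["mother_id"].isin(missing_m) | pairs["newborn_id"].isin(missing_c), "pair_id"
        ].tolist()
        raise ValueError(f"unresolvable sample IDs for pairs: {bad}")
    m = maternal.loc[shared, pairs["mother_id"]].to_numpy(dtype=float)
    c = neonatal.loc[shared, pairs["newborn_id"]].to_numpy(dtype=float)
    return shared, m, c


def _subset_masks(site_index, annotation):
    ann = annotation.set_index("site_id")["chromosome"].astype(str)
    chrom = ann.reindex(site_index)
    if chrom.isna().any():
        raise ValueError("annotation does not cover all matrix sites")
    is_x = (chrom == "X").to_numpy()
    return {"all": np.ones(len(site_index), bool), "auto": ~is_x, "x": is_x}


def _columnwise_spearman(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Spearman rho between corresponding columns (no missing values)."""
    rm = rankdata(m, method="average", axis=0)
    rc = rankdata(c, method="average", axis=0)
    rm = rm - rm.mean(axis=0)
    rc = rc - rc.mean(axis=0)
    denom = np.sqrt((rm**2).sum(axis=0) * (rc**2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        return (rm * rc).sum(axis=0) / denom


def _rank_columns(a: np.ndarray) -> np.ndarray:
    r = rankdata(a, method="average", axis=0)
    return r - r.mean(axis=0)


def _pairwise_spearman_missing(m, c):
    out = np.empty(m.shape[1])
    for i in range(m.shape[1]):
        ok = np.isfinite(m[:, i]) & np.isfinite(c[:, i])
        if ok.sum() < 2:
            out[i] = np.nan
        else:
            out[i] = stats.spearmanr(m[ok, i], c[ok, i]).statistic
    return out


def pair_spearman(
    maternal: pd.DataFrame,
    neonatal: pd.DataFrame,
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Matched per-pair Spearman correlations over all/autosomal/X site subsets.

    Missing betas are dropped pairwise within each pair.
    """
    shared, m, c = _aligned_matrices(maternal, neonatal, pairs)
    masks = _subset_masks(shared, annotation)
    has_nan = np.isnan(m).any() or np.isnan(c).any()
    out = {"pair_id": pairs["pair_id"].to_numpy(), "newborn_sex": pairs["sex"].to_numpy()}
    for name in SUBSETS:
        sel = masks[name]
        if sel.sum() < 2:
            out[f"rho_{name}"] = np.full(len(pairs), np.nan)
        elif has_nan:
            out[f"rho_{name}"] = _pairwise_spearman_missing(m[sel], c[sel])
        else:
            out[f"rho_{name}"] = _columnwise_spearman(m[sel], c[sel])
    res = pd.DataFrame(out)
    res["source"] = "matched"
    return res


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random derangement of range(n) by rejection sampling."""
    if n < 2:
        raise ValueError("no derangement exists for a stratum of size 1")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def permutation_background(
    maternal: pd.DataFrame,
    neonatal: pd.DataFrame,
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    n_iter: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sex-matched permutation null of the per-pair correlations.

    Each iteration reassigns every newborn to an unrelated mother of a
    same-sex pair (a derangement within the sex stratum); the background rho
    recorded for a newborn is its mean over ``n_iter`` iterations.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    shared, m, c = _aligned_matrices(maternal, neonatal, pairs)
    if np.isnan(m).any() or np.isnan(c).any():
        raise ValueError("permutation background requires complete matrices (run QC first)")
    masks = _subset_masks(shared, annotation)
    rng = np.random.default_rng(seed)

    sex = pairs["sex"].to_numpy()
    strata = {s: np.flatnonzero(sex == s) for s in np.unique(sex)}
    for s, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"sex stratum {s!r} has fewer than 2 pairs; no derangement exists")

    ranks = {}
    for name in SUBSETS:
        sel = masks[name]
        if sel.sum() >= 2:
            ranks[name] = (_rank_columns(m[sel]), _rank_columns(c[sel]))

    acc = {name: np.zeros(len(pairs)) for name in ranks}
    for _ in range(n_iter):
        assign = np.arange(len(pairs))
        for idx in strata.values():
            assign[idx] = idx[_derangement(rng, len(idx))]
        assert not np.any(assign == np.arange(len(pairs))), "derangement produced a true pair"
        for name, (rm, rc) in ranks.items():
            rm_p = rm[:, assign]  # mother assigned to each newborn
            denom = np.sqrt((rm_p**2).sum(axis=0) * (rc**2).sum(axis=0))
            acc[name] += (rm_p * rc).sum(axis=0) / denom

    out = {"pair_id": pairs["pair_id"].to_numpy(), "newborn_sex": sex}
    for name in SUBSETS:
        out[f"rho_{name}"] = acc[name] / n_iter if name in acc else np.full(len(pairs), np.nan)
    res = pd.DataFrame(out)
    res["source"] = "background"
    return res


def compare_matched_vs_background(
    matched: pd.DataFrame, background: pd.DataFrame, subset: str = "all"
) -> dict:
    """Paired t test of matched vs background rho for the same newborns."""
    col = f"rho_{subset}"
    merged = matched.merge(background, on="pair_id", suffixes=("_matched", "_background"))
    if len(merged) != len(matched):
        raise ValueError("matched and background sets do not cover the same pairs")
    a = merged[f"{col}_matched"].to_numpy()
    b = merged[f"{col}_background"].to_numpy()
    diff = a - b
    flags = []
    if np.allclose(diff.std(ddof=1), 0.0):
        stat, p = 0.0, 1.0
        flags.append("degenerate_variance")
    else:
        res = stats.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "test": "paired_t",
        "subset": subset,
        "statistic": stat,
        "p": p,
        "n": int(len(merged)),
        "group_means": {"matched": float(np.mean(a)), "background": float(np.mean(b))},
        "flags": flags,
    }


def compare_by_sex(matched: pd.DataFrame, subset: str = "all") -> dict:
    """Welch two-sample t test of per-pair rho by newborn sex."""
    col = f"rho_{subset}"
    female = matched.loc[matched["newborn_sex"] == "female", col].dropna().to_numpy()
    male = matched.loc[matched["newborn_sex"] == "male", col].dropna().to_numpy()
    if len(female) == 0 or len(male) == 0:
        raise ValueError("both sexes must be represented to compare correlations by sex")
    res = stats.ttest_ind(female, male, equal_var=False)
    return {
        "test": "welch_t",
        "subset": subset,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(len(female) + len(male)),
        "group_means": {"female": float(female.mean()), "male": float(male.mean())},
        "flags": [],
    }
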