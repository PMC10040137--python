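"""Mother-newborn methylation differences (delta = neonatal - maternal) and
their association with newborn sex.

Raw-scale deltas are summarised descriptively by newborn sex and chromosome
class; for testing, each site's delta vector is rank-inverse-normalised and
regressed on sex (0 = female, 1 = male) with clinical covariates and
surrogate variables. A positive sex coefficient means the mother-male
difference exceeds the mother-female difference at that site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr, encode_covariates
from .qc import int_rows, inverse_normal_transform


def compute_delta(maternal: pd.DataFrame, neonatal: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Elementwise neonatal - maternal beta per pair (columns keyed by pair_id).

    Missing if either member is missing. Raises when a pair's samples cannot
    be resolved in the matrices.
    """
    shared = maternal.index.intersection(neonatal.index)
    if len(shared) == 0:
        raise ValueError("maternal and neonatal matrices share no sites")
    bad = pairs.loc[
        ~pairs["mother_id"].isin(maternal.columns) | ~pairs["newborn_id"].isin(neonatal.columns), "pair_id"
    ].tolist()
    if bad:
        raise ValueError(f"unmatched pairs: {bad}")
    delta = (
        neonatal.loc[shared, pairs["newborn_id"]].to_numpy(dtype=float)
        - maternal.loc[shared, pairs["mother_id"]].to_numpy(dtype=float)
    )
    return pd.DataFrame(delta, index=shared, columns=pairs["pair_id"].to_numpy())


def summarize_delta(delta: pd.DataFrame, pairs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Pooled mean/SD of raw delta by newborn sex and chromosome group.

    Pooled over all site x pair observations within each group (not averaged
    per site first).
    """
    chrom = annotation.set_index("site_id")["chromosome"].astype(str).reindex(delta.index)
    if chrom.isna().any():
        raise ValueError("annotation does not cover all delta sites")
    is_x = (chrom == "X").to_numpy()
    sex = pairs.set_index("pair_id")["sex"].reindex(delta.columns).to_numpy()
    vals = delta.to_numpy(dtype=float)

    rows = []
    for sex_label in ("female", "male"):
        cols = sex == sex_label
        for group, mask in (("autosome", ~is_x), ("X", is_x)):
            block = vals[np.ix_(mask, cols)]
            block = block[np.isfinite(block)]
            rows.append(
                {
                    "sex": sex_label,
                    "chrom_group": group,
                    "mean": float(block.mean()) if block.size else np.nan,
                    "sd": float(block.std(ddof=1)) if block.size > 1 else np.nan,
                    "n_obs": int(block.size),
                }
            )
    return pd.DataFrame(rows)


def run_delta_ewas(
    delta: pd.DataFrame,
    pairs: pd.DataFrame,
    svs: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    include_parity: bool = False,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-site regression of INT(delta) on newborn sex with covariates and SVs.

    Sites with constant delta (INT undefined) are reported with missing
    statistics and a flag rather than dropped. FDR is Benjamini-Hochberg over
    all tested sites jointly.
    """
    enc = encode_covariates(pairs.reset_index(drop=True), include_parity=include_parity)
    x_parts = [pd.Series(1.0, index=enc.index, name="intercept"), enc]
    if svs is not None and svs.shape[1] > 0:
        sv_block = svs.reset_index(drop=True)
        sv_block.index = enc.index
        x_parts.append(sv_block)
    design = pd.concat(x_parts, axis=1)
    valid_rows = design.notna().all(axis=1).to_numpy()
    x = design.to_numpy(dtype=float)[valid_rows]
    sex_j = list(design.columns).index("sex_male")
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("delta design is rank-deficient")

    vals = delta.to_numpy(dtype=float)[:, valid_rows]
    site_ids = delta.index.to_numpy()
    s = vals.shape[0]

    beta = np.full(s, np.nan)
    se = np.full(s, np.nan)
    pv = np.full(s, np.nan)
    n_used = np.full(s, 0, dtype=int)
    flags = np.array([""] * s, dtype=object)

    complete = np.isfinite(vals).all(axis=1)
    constant = np.all(vals == vals[:, :1], axis=1)
    fast = complete & ~constant

    if fast.any():
        y = int_rows(vals[fast])
        still_ok = ~np.isnan(y).any(axis=1)
        xtx_inv = np.linalg.inv(x.T @ x)
        coef = xtx_inv @ x.T @ y[still_ok].T
        resid = y[still_ok].T - x @ coef
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / (n - p)
        se_fast = np.sqrt(sigma2 * xtx_inv[sex_j, sex_j])
        b_fast = coef[sex_j]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b_fast / se_fast
        p_fast = 2 * stats.t.sf(np.abs(t), n - p)
        idx = np.flatnonzero(fast)[still_ok]
        beta[idx], se[idx], pv[idx] = b_fast, se_fast, p_fast
        n_used[idx] = n
        bad = np.flatnonzero(fast)[~still_ok]
        flags[bad] = "constant"

    # slow path: sites with missing values, listwise per site
    for i in np.flatnonzero(~complete):
        ok = np.isfinite(vals[i])
        if ok.sum() <= p or len(np.unique(vals[i][ok])) < 2:
            flags[i] = "constant" if len(np.unique(vals[i][ok])) < 2 else "insufficient"
            continue
        yi = inverse_normal_transform(vals[i][ok])
        xi = x[ok]
        if np.linalg.matrix_rank(xi) < p:
            flags[i] = "rank_deficient"
            continue
        xtx_inv_i = np.linalg.inv(xi.T @ xi)
        coef_i = xtx_inv_i @ xi.T @ yi
        rss_i = float(((yi - xi @ coef_i) ** 2).sum())
        sig2 = rss_i / (ok.sum() - p)
        se[i] = float(np.sqrt(sig2 * xtx_inv_i[sex_j, sex_j]))
        beta[i] = float(coef_i[sex_j])
        pv[i] = float(2 * stats.t.sf(abs(beta[i] / se[i]), ok.sum() - p))
        n_used[i] = int(ok.sum())

    flags[constant] = "constant"
    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "beta_sex": beta,
            "se": se,
            "p": pv,
            "fdr": bh_fdr(pv),
            "direction": np.sign(beta),
            "n_used": n_used,
            "flag": flags,
        }
    )
    table["significant"] = table["fdr"] < fdr_threshold
    if annotation is not None:
        chrom = annotation.set_index("site_id")["chromosome"].astype(str)
        table["chromosome"] = chrom.reindex(table["site_id"]).to_numpy()
    return table
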