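"""Per-site mother-newborn association testing.

For every methylation site, the neonatal level (rank-inverse-normalised) is
regressed on the maternal level under two nested OLS models:

    full:    neonatal ~ maternal + sex + maternal:sex + covariates
                        + maternal:covariates + SVs
    reduced: neonatal ~ sex + covariates + SVs

The mother-newborn association is tested by a likelihood-ratio statistic
n * log(RSS_reduced / RSS_full) on a chi-square with df equal to the number
of extra full-model columns; the maternal-by-sex interaction is tested by
the Wald t of its coefficient in the full model. Newborn sex is coded
0 = female, 1 = male, so a positive interaction means a steeper
mother-newborn slope in males. FDR is Benjamini-Hochberg, computed jointly
over all tested sites (autosomes and X together).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .qc import int_rows, inverse_normal_transform

CLINICAL_COVARIATES = ["maternal_age", "race", "smoking", "preterm", "delivery"]


def encode_covariates(pairs: pd.DataFrame, include_parity: bool = False) -> pd.DataFrame:
    """Numeric covariate encoding from the pair/sample sheet.

    Sex coded 0=female / 1=male; binary covariates as 0/1 indicators
    (race: Black=1, smoking yes=1, preterm yes=1, delivery C-section=1);
    maternal age in years; parity numeric when requested. Covariates with a
    single observed level are dropped with a warning.
    """
    enc = pd.DataFrame(index=pairs.index)
    enc["sex_male"] = (pairs["sex"] == "male").astype(float)
    enc["maternal_age"] = pd.to_numeric(pairs["maternal_age"], errors="coerce")
    enc["race_black"] = (pairs["race"] == "Black").astype(float).where(pairs["race"].notna())
    enc["smoking_yes"] = (pairs["smoking"] == "yes").astype(float).where(pairs["smoking"].notna())
    enc["preterm_yes"] = (pairs["preterm"] == "yes").astype(float).where(pairs["preterm"].notna())
    enc["csection"] = (pairs["delivery"] == "C-section").astype(float).where(pairs["delivery"].notna())
    if include_parity:
        enc["parity"] = pd.to_numeric(pairs["parity"], errors="coerce")
    for col in list(enc.columns):
        if col == "sex_male":
            continue
        if enc[col].nunique(dropna=True) < 2:
            warnings.warn(f"covariate {col!r} has a single level and was dropped", UserWarning)
            enc = enc.drop(columns=col)
    return enc


def build_designs(
    pairs: pd.DataFrame,
    svs: pd.DataFrame | None,
    maternal_site: np.ndarray,
    include_parity: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Full and reduced per-site design matrices.

    The full design adds, relative to the reduced: the maternal main effect,
    maternal x sex, and maternal x each clinical covariate. SVs enter both
    designs as main effects only. Rows with missing covariates or missing
    maternal values are dropped listwise; the count dropped is returned.
    """
    enc = encode_covariates(pairs, include_parity=include_parity)
    mat = pd.Series(np.asarray(maternal_site, float), index=pairs.index, name="maternal")

    reduced = pd.DataFrame({"intercept": 1.0}, index=pairs.index)
    reduced = pd.concat([reduced, enc], axis=1)
    if svs is not None and svs.shape[1] > 0:
        sv_block = svs.reset_index(drop=True)
        sv_block.index = pairs.index
        reduced = pd.concat([reduced, sv_block], axis=1)

    full = reduced.copy()
    full["maternal"] = mat
    full["maternal:sex_male"] = mat * enc["sex_male"]
    for col in enc.columns:
        if col == "sex_male":
            continue
        if svs is not None and col in getattr(svs, "columns", []):
            continue
        full[f"maternal:{col}"] = mat * enc[col]

    valid = full.notna().all(axis=1)
    n_dropped = int((~valid).sum())
    return full.loc[valid], reduced.loc[valid], n_dropped


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return coef, float(resid @ resid)


def fit_site(neonatal_site, full_design, reduced_design, interaction_col: str = "maternal:sex_male") -> dict:
    """LRT of the nested models plus the Wald test of the maternal x sex term.

    ``neonatal_site`` must already be inverse-normal transformed and aligned
    with the design rows. Rank-deficient designs yield a flagged result with
    missing p-values rather than an exception.
    """
    xf = full_design.to_numpy(dtype=float) if hasattr(full_design, "to_numpy") else np.asarray(full_design, float)
    xr = reduced_design.to_numpy(dtype=float) if hasattr(reduced_design, "to_numpy") else np.asarray(reduced_design, float)
    y = np.asarray(neonatal_site, dtype=float)
    n, p_full = xf.shape
    p_red = xr.shape[1]
    out = {
        "beta_interaction": np.nan, "se_interaction": np.nan, "p_interaction": np.nan,
        "lrt_stat": np.nan, "p_lrt": np.nan, "n_used": n, "r2_full": np.nan,
        "df_resid": n - p_full, "flag": "",
    }
    if n <= p_full or np.linalg.matrix_rank(xf) < p_full:
        out["flag"] = "rank_deficient"
        return out

    coef_f, rss_f = _ols_rss(xf, y)
    _, rss_r = _ols_rss(xr, y)
    rss_f = max(rss_f, 1e-300)
    lrt = n * np.log(max(rss_r, 1e-300) / rss_f)
    df = p_full - p_red
    out["lrt_stat"] = float(max(lrt, 0.0))
    out["p_lrt"] = float(stats.chi2.sf(max(lrt, 0.0), df))

    cols = list(full_design.columns) if hasattr(full_design, "columns") else None
    j = cols.index(interaction_col) if cols is not None else p_red + 1
    sigma2 = rss_f / (n - p_full)
    xtx_inv = np.linalg.inv(xf.T @ xf)
    se = float(np.sqrt(sigma2 * xtx_inv[j, j]))
    b = float(coef_f[j])
    t = b / se if se > 0 else np.nan
    out["beta_interaction"] = b
    out["se_interaction"] = se
    out["p_interaction"] = float(2 * stats.t.sf(abs(t), n - p_full)) if np.isfinite(t) else np.nan
    tss = float(((y - y.mean()) ** 2).sum())
    out["r2_full"] = 1.0 - rss_f / tss if tss > 0 else np.nan
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values are ignored and
    returned as NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def _fit_site_arrays(y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray, interaction_j: int, site) -> dict:
    """Numpy-only per-site fit used by the complete-data fast path."""
    n, p_full = x_full.shape
    out = {
        "site_id": site, "beta_interaction": np.nan, "se_interaction": np.nan,
        "p_interaction": np.nan, "lrt_stat": np.nan, "p_lrt": np.nan,
        "n_used": n, "r2_full": np.nan, "df_resid": n - p_full, "flag": "",
    }
    coef_f, res_f, rank_f, _ = np.linalg.lstsq(x_full, y, rcond=None)
    if rank_f < p_full or n <= p_full:
        out["flag"] = "rank_deficient"
        return out
    rss_f = max(float(((y - x_full @ coef_f) ** 2).sum()), 1e-300)
    coef_r, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    rss_r = max(float(((y - x_red @ coef_r) ** 2).sum()), 1e-300)
    lrt = max(n * np.log(rss_r / rss_f), 0.0)
    out["lrt_stat"] = float(lrt)
    out["p_lrt"] = float(stats.chi2.sf(lrt, p_full - x_red.shape[1]))
    sigma2 = rss_f / (n - p_full)
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    se = float(np.sqrt(sigma2 * xtx_inv[interaction_j, interaction_j]))
    b = float(coef_f[interaction_j])
    out["beta_interaction"] = b
    out["se_interaction"] = se
    if se > 0:
        out["p_interaction"] = float(2 * stats.t.sf(abs(b / se), n - p_full))
    tss = float(((y - y.mean()) ** 2).sum())
    out["r2_full"] = 1.0 - rss_f / tss if tss > 0 else np.nan
    return out


def _finish_table(records, annotation, fdr_threshold) -> pd.DataFrame:
    table = pd.DataFrame.from_records(records)
    table["fdr_lrt"] = bh_fdr(table.get("p_lrt"))
    table["fdr_interaction"] = bh_fdr(table.get("p_interaction"))
    table["significant_lrt"] = table["fdr_lrt"] < fdr_threshold
    table["significant_interaction"] = table["fdr_interaction"] < fdr_threshold
    if annotation is not None:
        chrom = annotation.set_index("site_id")["chromosome"].astype(str)
        table["chromosome"] = chrom.reindex(table["site_id"]).to_numpy()
    cols = ["site_id", "beta_interaction", "se_interaction", "p_interaction", "fdr_interaction",
            "lrt_stat", "p_lrt", "fdr_lrt", "significant_lrt", "significant_interaction",
            "n_used", "r2_full", "df_resid", "flag"]
    cols = [c_ for c_ in cols if c_ in table.columns] + [c_ for c_ in table.columns if c_ not in cols]
    return table[cols]


def run_site_ewas(
    maternal: pd.DataFrame,
    neonatal: pd.DataFrame,
    pairs: pd.DataFrame,
    svs: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    include_parity: bool = False,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-site full/reduced regression over all sites shared by both matrices.

    Maternal and neonatal vectors are inverse-normal transformed separately
    per site; FDR is computed jointly over all tested sites. Complete
    matrices take a vectorised path that builds the shared reduced design
    once; matrices with missing betas fall back to per-site listwise
    deletion.
    """
    shared = maternal.index.intersection(neonatal.index)
    if len(shared) == 0:
        raise ValueError("maternal and neonatal matrices share no sites")
    m = maternal.loc[shared, pairs["mother_id"]].to_numpy(dtype=float)
    c = neonatal.loc[shared, pairs["newborn_id"]].to_numpy(dtype=float)

    enc = encode_covariates(pairs.reset_index(drop=True), include_parity=include_parity)
    complete = not (np.isnan(m).any() or np.isnan(c).any() or enc.isna().any().any())

    records = []
    if complete:
        m_int = int_rows(m)
        c_int = int_rows(c)
        n = len(pairs)
        x_red_parts = [np.ones((n, 1)), enc.to_numpy(float)]
        if svs is not None and svs.shape[1] > 0:
            x_red_parts.append(np.asarray(svs, float))
        x_red = np.column_stack(x_red_parts)
        # full design appends maternal * [1, covariates]; the sex interaction
        # sits right after the maternal main effect column
        inter_block = np.column_stack([np.ones(n), enc.to_numpy(float)])
        interaction_j = x_red.shape[1] + 1 + list(enc.columns).index("sex_male")
        for i, site in enumerate(shared):
            mv, cv = m_int[i], c_int[i]
            if np.isnan(mv).any() or np.isnan(cv).any():
                records.append({"site_id": site, "flag": "constant", "n_used": 0})
                continue
            x_full = np.column_stack([x_red, mv[:, None] * inter_block])
            records.append(_fit_site_arrays(cv, x_full, x_red, interaction_j, site))
        return _finish_table(records, annotation, fdr_threshold)

    for i, site in enumerate(shared):
        ok = np.isfinite(m[i]) & np.isfinite(c[i])
        if ok.sum() < 3 or len(np.unique(m[i][ok])) < 2 or len(np.unique(c[i][ok])) < 2:
            records.append({"site_id": site, "flag": "constant", "n_used": int(ok.sum())})
            continue
        mv = np.full(len(pairs), np.nan)
        cv = np.full(len(pairs), np.nan)
        mv[ok] = inverse_normal_transform(m[i][ok])
        cv[ok] = inverse_normal_transform(c[i][ok])
        full, reduced, _ = build_designs(pairs.reset_index(drop=True), svs, mv, include_parity=include_parity)
        y = cv[full.index.to_numpy()]
        keep = np.isfinite(y)
        res = fit_site(y[keep], full.iloc[keep], reduced.iloc[keep])
        res["site_id"] = site
        records.append(res)
    return _finish_table(records, annotation, fdr_threshold)
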