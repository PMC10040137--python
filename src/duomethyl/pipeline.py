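"""End-to-end orchestration: QC, paired correlations, SVA, both EWAS stages,
summaries and optional replication/enrichment, from a single RunConfig.

One global seed fans out to per-stage seeds derived by hashing the stage
name, so stages are independently re-runnable yet reproducible; a manifest
records software version, config hash, per-stage outputs with checksums and
seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from . import io as dio
from ._util import derive_seed, round_half_up, sha256_file
from .config import RunConfig
from .delta import compute_delta, run_delta_ewas, summarize_delta
from .enrichment import heritability_strata, hypergeometric_ora, map_sites_to_genes
from .ewas import encode_covariates, run_site_ewas
from .paircorr import compare_by_sex, compare_matched_vs_background, pair_spearman, permutation_background
from .qc import check_sex_consistency, filter_samples, filter_sites
from .replication import concordance_summary, overlap_results
from .simulate import simulate_cohort
from .sva import SurrogateVariableAnalysis


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def summarize_pairs(pairs: pd.DataFrame, by_sex: bool = True) -> pd.DataFrame:
    """Cohort characteristics table: counts and percentages per categorical
    covariate (percentages half-up to 1 decimal, within sex column when
    stratified), median (range) maternal age, and a p-value per contrast
    (chi-square for categoricals, Welch t for age)."""
    if pairs.empty:
        raise ValueError("empty pair table")
    categoricals = [c for c in ("delivery", "preterm", "smoking", "race", "parity") if c in pairs.columns]

    if by_sex:
        sexes = sorted(pairs["sex"].unique())
        if len(sexes) < 2:
            raise ValueError("by-sex summary needs both sexes present")
        groups = {s: pairs.loc[pairs["sex"] == s] for s in sexes}
    else:
        groups = {"all": pairs}

    rows = [{"characteristic": "total_n", "level": "",
             **{f"{g}_n": len(df) for g, df in groups.items()}, "p": np.nan}]

    if "maternal_age" in pairs.columns:
        row = {"characteristic": "maternal_age", "level": "median (range)"}
        for g, df in groups.items():
            a = df["maternal_age"].dropna()
            row[f"{g}_summary"] = f"{round_half_up(a.median(), 1)} ({round_half_up(a.min(), 1)}-{round_half_up(a.max(), 1)})"
        if by_sex:
            a, b = (groups[s]["maternal_age"].dropna() for s in sexes[:2])
            row["p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(row)

    for cov in categoricals:
        levels = sorted(pairs[cov].dropna().astype(str).unique())
        p = np.nan
        if by_sex:
            table = pd.crosstab(pairs[cov].astype(str), pairs["sex"])
            if table.shape[0] > 1 and (table.to_numpy().sum(axis=0) > 0).all():
                p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        for i, level in enumerate(levels):
            row = {"characteristic": cov, "level": level, "p": p if i == 0 else np.nan}
            for g, df in groups.items():
                n = int((df[cov].astype(str) == level).sum())
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = round_half_up(100.0 * n / len(df), 1) if len(df) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _sva_design(pairs: pd.DataFrame, include_parity: bool) -> pd.DataFrame:
    """Known-covariate design for SV estimation: intercept + newborn sex +
    clinical covariates.

    Sex is kept in the design so the surrogate variables are estimated from
    structure beyond the exposure of interest — otherwise the leading SV of
    the delta outcome would simply reconstruct the male X-methylation
    deficit and absorb the very signal the EWAS tests."""
    enc = encode_covariates(pairs.reset_index(drop=True), include_parity=include_parity)
    design = pd.concat([pd.Series(1.0, index=enc.index, name="intercept"), enc], axis=1)
    return design.fillna(design.mean(numeric_only=True))


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute QC -> paired correlations (+permutation null) -> SVA ->
    site EWAS -> delta EWAS -> summaries (-> replication/enrichment when
    configured); returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, t0: float, seed: int | None, files: dict[str, Path], **info):
        manifest["stages"][stage] = {
            "seed": seed,
            "wall_s": round(time.time() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": sha256_file(p)} for k, p in files.items()},
            **info,
        }

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                return fn(t0)
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise PipelineError(name, exc, manifest) from exc
        return wrap

    # ---- inputs -----------------------------------------------------------
    @stage("input")
    def _input(t0):
        if config.simulate:
            cohort_cfg = config.cohort
            cohort_cfg.seed = derive_seed(config.seed, "simulate")
            cohort = simulate_cohort(cohort_cfg)
            maternal, neonatal, pairs, annotation = cohort.maternal, cohort.neonatal, cohort.pairs, cohort.annotation
            files = {}
            for name, df, writer in (
                ("maternal", maternal, dio.write_matrix),
                ("neonatal", neonatal, dio.write_matrix),
            ):
                p = out / f"{name}.tsv"
                writer(df, p)
                files[name] = p
            p = out / "pairs.tsv"
            dio.write_pairs(pairs, p)
            files["pairs"] = p
            p = out / "annotation.tsv"
            dio.write_annotation(annotation, p)
            files["annotation"] = p
            p = out / "truth_site_params.tsv"
            dio.write_table(cohort.truth.site_params, p)
            files["truth_site_params"] = p
            record("input", t0, cohort_cfg.seed, files, simulated=True)
            return maternal, neonatal, pairs, annotation
        maternal = dio.read_matrix(config.maternal_path)
        neonatal = dio.read_matrix(config.neonatal_path)
        pairs = dio.read_pairs(config.pairs_path)
        annotation = dio.read_annotation(config.annotation_path)
        record("input", t0, None, {}, simulated=False)
        return maternal, neonatal, pairs, annotation

    maternal, neonatal, pairs, annotation = _input

    # ---- QC ---------------------------------------------------------------
    @stage("qc")
    def _qc(t0):
        mask = dio.read_mask(config.mask_path) if config.mask_path else set()
        m1, rep_m = filter_sites(maternal, mask_ids=mask)
        c1, rep_c = filter_sites(neonatal, mask_ids=mask)
        m2, rep_ms = filter_samples(m1, config.max_missing_fraction)
        c2, rep_cs = filter_samples(c1, config.max_missing_fraction)
        flagged: list[str] = []
        sex_thr = None
        if (annotation["chromosome"].astype(str) == "X").sum() >= 50:
            recorded = pairs.set_index("newborn_id")["sex"]
            flagged, rep_sex = check_sex_consistency(c2, annotation, recorded)
            sex_thr = rep_sex.sex_threshold
            c2 = c2.drop(columns=flagged)
        keep = pairs["mother_id"].isin(m2.columns) & pairs["newborn_id"].isin(c2.columns)
        pairs_q = pairs.loc[keep].reset_index(drop=True)
        shared = m2.index.intersection(c2.index)
        m3 = m2.loc[shared, pairs_q["mother_id"]]
        c3 = c2.loc[shared, pairs_q["newborn_id"]]
        report = {
            "sites_in": int(maternal.shape[0]),
            "sites_removed_mask": rep_m.sites_removed_mask,
            "sites_retained": int(len(shared)),
            "samples_removed_missing": rep_ms.samples_removed_missing + rep_cs.samples_removed_missing,
            "samples_removed_sex": len(flagged),
            "sex_threshold": sex_thr,
            "pairs_retained": int(len(pairs_q)),
        }
        p = out / "qc_report.json"
        p.write_text(json.dumps(report, indent=2))
        record("qc", t0, None, {"qc_report": p}, **report)
        return m3, c3, pairs_q

    maternal_q, neonatal_q, pairs_q = _qc

    # ---- paired correlations ---------------------------------------------
    @stage("pairs_corr")
    def _pairs(t0):
        seed = derive_seed(config.seed, "pairs_corr")
        matched = pair_spearman(maternal_q, neonatal_q, pairs_q, annotation)
        background = permutation_background(
            maternal_q, neonatal_q, pairs_q, annotation, n_iter=config.n_iter_permutation, seed=seed
        )
        tests = {
            "matched_vs_background": compare_matched_vs_background(matched, background),
            "by_sex": {s: compare_by_sex(matched, s) for s in ("all", "auto", "x")},
            "n_iter": config.n_iter_permutation,
        }
        files = {}
        p = out / "pair_correlations.tsv"
        dio.write_table(pd.concat([matched, background], ignore_index=True), p)
        files["pair_correlations"] = p
        p = out / "pair_correlation_tests.json"
        p.write_text(json.dumps(tests, indent=2))
        files["pair_correlation_tests"] = p
        record("pairs_corr", t0, seed, files)
        return matched, background

    _pairs

    # ---- SVA (neonatal outcome) + site EWAS -------------------------------
    @stage("sva_neonatal")
    def _sva_neo(t0):
        seed = derive_seed(config.seed, "sva_neonatal")
        design = _sva_design(pairs_q, config.include_parity)
        sva = SurrogateVariableAnalysis(
            n_sv=config.n_sv if config.n_sv is not None else "auto",
            n_perm=config.n_perm_sv, random_state=seed,
        ).fit(neonatal_q.dropna(axis=0), design)
        p = out / "svs_neonatal.tsv"
        dio.write_table(sva.svs_, p, index=True)
        record("sva_neonatal", t0, seed, {"svs_neonatal": p}, n_sv=sva.n_sv_, converged=bool(sva.converged_))
        return sva.svs_

    svs_neo = _sva_neo

    @stage("site_ewas")
    def _site(t0):
        res = run_site_ewas(
            maternal_q, neonatal_q, pairs_q, svs=svs_neo, annotation=annotation,
            include_parity=config.include_parity, fdr_threshold=config.fdr_threshold,
        )
        files = {}
        p = out / "site_association.tsv"
        dio.write_table(res, p)
        files["site_association"] = p
        ann = annotation.set_index("site_id")
        man = pd.DataFrame({
            "site_id": res["site_id"],
            "chromosome": ann["chromosome"].reindex(res["site_id"]).to_numpy(),
            "position": ann["position"].reindex(res["site_id"]).to_numpy(),
            "minus_log10_p": -np.log10(np.clip(res["p_lrt"].to_numpy(float), 1e-300, None)),
        })
        p = out / "site_association_manhattan.tsv"
        dio.write_table(man, p)
        files["manhattan"] = p
        info = {"n_significant_lrt": int(res["significant_lrt"].sum()),
                "n_significant_interaction": int(res["significant_interaction"].sum()),
                "interaction_fdr_scope": "joint over all tested sites",
                "parity_adjusted": config.include_parity}
        record("site_ewas", t0, None, files, **info)
        return res

    site_res = _site

    # ---- delta ------------------------------------------------------------
    @stage("delta_ewas")
    def _delta(t0):
        seed = derive_seed(config.seed, "sva_delta")
        delta = compute_delta(maternal_q, neonatal_q, pairs_q)
        summary = summarize_delta(delta, pairs_q, annotation)
        design = _sva_design(pairs_q, config.include_parity)
        sva = SurrogateVariableAnalysis(
            n_sv=config.n_sv if config.n_sv is not None else "auto",
            n_perm=config.n_perm_sv, random_state=seed,
        ).fit(delta.dropna(axis=0), design)
        res = run_delta_ewas(
            delta, pairs_q, svs=sva.svs_, annotation=annotation,
            include_parity=config.include_parity, fdr_threshold=config.fdr_threshold,
        )
        files = {}
        p = out / "svs_delta.tsv"
        dio.write_table(sva.svs_, p, index=True)
        files["svs_delta"] = p
        p = out / "delta_summary.json"
        p.write_text(summary.to_json(orient="records", indent=2))
        files["delta_summary"] = p
        p = out / "delta_association.tsv"
        dio.write_table(res, p)
        files["delta_association"] = p
        record("delta_ewas", t0, seed, files, n_sv=sva.n_sv_,
               n_significant=int(res["significant"].sum()), parity_adjusted=config.include_parity)
        return delta, summary, res

    _delta_out = _delta
    delta_res = _delta_out[2]

    # ---- cohort summary ----------------------------------------------------
    @stage("summarize_pairs")
    def _summary(t0):
        tbl = summarize_pairs(pairs_q, by_sex=pairs_q["sex"].nunique() > 1)
        p = out / "pair_characteristics.tsv"
        dio.write_table(tbl, p)
        record("summarize_pairs", t0, None, {"pair_characteristics": p})
        return tbl

    _summary

    # ---- heritability strata ----------------------------------------------
    if annotation.get("h2") is not None and annotation["h2"].notna().sum() >= 100:
        @stage("heritability")
        def _h2(t0):
            strata = heritability_strata(site_res, annotation, top_n=min(100, int(annotation["h2"].notna().sum())))
            p = out / "heritability_strata.json"
            p.write_text(json.dumps(strata, indent=2))
            record("heritability", t0, None, {"heritability_strata": p})
            return strata
        _h2

    # ---- optional replication ---------------------------------------------
    if config.replication_results_path:
        @stage("replication")
        def _repl(t0):
            repl = pd.read_csv(config.replication_results_path, sep="\t")
            joined = overlap_results(delta_res, repl, discovery_fdr_threshold=config.fdr_threshold)
            summary = concordance_summary(joined, replication_fdr_threshold=config.fdr_threshold)
            files = {}
            p = out / "replication_joined.tsv"
            dio.write_table(joined, p)
            files["replication_joined"] = p
            p = out / "replication_concordance.json"
            p.write_text(json.dumps(asdict(summary), indent=2))
            files["replication_concordance"] = p
            record("replication", t0, None, files)
            return summary
        _repl

    # ---- optional enrichment ----------------------------------------------
    if config.gmt_path:
        @stage("enrichment")
        def _enrich(t0):
            pathways = dio.read_gmt(config.gmt_path)
            universe = map_sites_to_genes(delta_res["site_id"], annotation)
            sig_sites = delta_res.loc[delta_res["significant"], "site_id"]
            genes = map_sites_to_genes(sig_sites, annotation)
            table = hypergeometric_ora(genes, pathways, universe)
            p = out / "pathway_enrichment.tsv"
            dio.write_table(table, p)
            record("enrichment", t0, None, {"pathway_enrichment": p},
                   n_genes=len(genes), n_universe=len(universe))
            return table
        _enrich

    manifest["completed"] = True
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
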