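"""Site-to-gene mapping, annotation-category comparisons, heritability
strata, and hypergeometric pathway over-representation analysis.

Multi-gene site annotations follow the array-manifest semicolon convention
("GENEA;GENEB" contributes both symbols); intergenic sites contribute none.
The over-representation test is the one-sided hypergeometric upper tail of
the pathway/gene-set overlap given the chosen universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr


def split_genes(field: str) -> list[str]:
    if field is None or (isinstance(field, float) and np.isnan(field)) or field == "":
        return []
    return [g for g in str(field).split(";") if g]


def map_sites_to_genes(site_ids, annotation: pd.DataFrame) -> set[str]:
    """Union of gene symbols annotated to the given sites.

    Unknown site IDs raise, listing the offenders.
    """
    ann = annotation.set_index("site_id")
    idx = pd.Index(site_ids)
    unknown = idx.difference(ann.index)
    if len(unknown):
        raise KeyError(f"unknown site IDs: {sorted(unknown)[:10]}{'...' if len(unknown) > 10 else ''}")
    genes: set[str] = set()
    for field in ann.loc[idx, "genes"]:
        genes.update(split_genes(field))
    return genes


def category_distribution(site_ids, annotation: pd.DataFrame, which: str) -> pd.DataFrame:
    """Counts and proportions of a categorical annotation over the sites.

    ``which`` is "functional_region" or "island_relation".
    """
    if which not in ("functional_region", "island_relation"):
        raise ValueError(f"which must be functional_region or island_relation, got {which!r}")
    idx = pd.Index(site_ids)
    if len(idx) == 0:
        raise ValueError("empty site list")
    ann = annotation.set_index("site_id")
    cats = ann.loc[idx, which]
    counts = cats.value_counts()
    out = pd.DataFrame({"category": counts.index, "count": counts.to_numpy()})
    out["proportion"] = out["count"] / out["count"].sum()
    return out


def compare_category_distributions(group_a: pd.DataFrame, group_b: pd.DataFrame) -> dict:
    """Pearson chi-square on the 2 x C contingency table of category counts.

    Categories with zero pooled count are dropped; the reported df is the
    number of retained categories minus 1.
    """
    a = group_a.set_index("category")["count"]
    b = group_b.set_index("category")["count"]
    cats = a.index.union(b.index)
    a = a.reindex(cats, fill_value=0).to_numpy(dtype=float)
    b = b.reindex(cats, fill_value=0).to_numpy(dtype=float)
    pooled = a + b
    keep = pooled > 0
    a, b = a[keep], b[keep]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups need nonzero total counts")
    table = np.vstack([a, b])
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(stat), "p": float(p), "df": int(dof), "n_categories": int(keep.sum())}


def heritability_strata(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    top_n: int = 100,
    p_col: str = "p_lrt",
) -> dict:
    """Median h2 of the top-N autosomal sites (by ascending p) vs all
    annotated autosomal sites.

    Only autosomal sites with an h2 annotation participate (heritability
    catalogues typically cover autosomes only).
    """
    ann = annotation.set_index("site_id")
    merged = results.drop(columns=[c for c in ("chromosome", "h2") if c in results.columns]).merge(
        ann[["chromosome", "h2"]], left_on="site_id", right_index=True, how="inner"
    )
    auto = merged.loc[(merged["chromosome"].astype(str) != "X") & merged["h2"].notna() & merged[p_col].notna()]
    if len(auto) < top_n:
        raise ValueError(f"need >= {top_n} annotated autosomal sites with h2, found {len(auto)}")
    top = auto.nsmallest(top_n, p_col, keep="first")
    return {
        "top_n": int(top_n),
        "median_h2_top": float(top["h2"].median()),
        "median_h2_genomewide": float(auto["h2"].median()),
        "n_genomewide": int(len(auto)),
    }


def hypergeometric_ora(
    gene_set: set[str],
    pathway_db: dict[str, tuple[str, frozenset]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene set in pathways.

    Pathways are intersected with the universe; p is the upper-tail
    probability of the observed-or-larger overlap; FDR is BH across pathways.
    """
    if not universe:
        raise ValueError("empty gene universe")
    extra = set(gene_set) - set(universe)
    if extra:
        raise ValueError(f"gene_set contains genes outside the universe: {sorted(extra)[:10]}")
    m = len(universe)
    n_draw = len(gene_set)
    rows = []
    for name, (_desc, genes) in pathway_db.items():
        in_univ = set(genes) & set(universe)
        k_path = len(in_univ)
        if k_path == 0:
            continue
        overlap = len(in_univ & set(gene_set))
        p = float(stats.hypergeom.sf(overlap - 1, m, k_path, n_draw))
        rows.append(
            {"pathway_id": name, "n_in_map": k_path, "n_in_data": overlap, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["pathway_id", "n_in_map", "n_in_data", "p"])
    out["fdr"] = bh_fdr(out["p"]) if len(out) else np.nan
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
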