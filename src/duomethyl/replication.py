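"""Cross-cohort replication: overlap of significant sites, direction
concordance with a chi-square test, and printed-proportion arithmetic.

The concordance test treats the (consistent, inconsistent) direction counts
among replication-significant sites as a 1-df goodness-of-fit against a
50:50 split - the null of no shared direction information between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr
from ._util import round_half_up


@dataclass
class ConcordanceSummary:
    n_overlap: int
    n_sig_replication: int
    n_consistent_direction: int
    pct_consistent: float  # percent, 1 decimal, NaN when nothing significant
    chisq_stat: float
    p: float
    note: str = "chi-square goodness of fit of direction counts against 50:50, 1 df"


def overlap_results(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    discovery_fdr_threshold: float = 0.05,
    fdr_col: str = "fdr",
) -> pd.DataFrame:
    """Inner join of discovery-significant sites with the replication table.

    Both tables need site_id, a beta column (beta_sex or beta_interaction),
    p and FDR columns; the join is restricted to discovery sites with
    FDR < threshold. Raises on empty overlap.
    """
    disc_sig = discovery.loc[discovery[fdr_col] < discovery_fdr_threshold]
    joined = disc_sig.merge(replication, on="site_id", suffixes=("_discovery", "_replication"))
    if joined.empty:
        raise ValueError("no overlap between discovery-significant sites and the replication table")
    return joined


def concordance_summary(
    joined: pd.DataFrame,
    replication_fdr_threshold: float = 0.05,
    beta_col: str = "beta_sex",
) -> ConcordanceSummary:
    """Direction concordance among replication-significant overlapping sites.

    Replication significance is re-assessed by BH-FDR within the overlapping
    sites. The percentage is half-up rounded to 1 decimal, matching printed
    convention.
    """
    b_disc = joined[f"{beta_col}_discovery"].to_numpy(dtype=float)
    b_repl = joined[f"{beta_col}_replication"].to_numpy(dtype=float)
    p_repl = joined["p_replication"].to_numpy(dtype=float)

    fdr_repl = bh_fdr(p_repl)
    sig = fdr_repl < replication_fdr_threshold
    n_sig = int(sig.sum())
    consistent = np.sign(b_disc[sig]) == np.sign(b_repl[sig])
    n_cons = int(consistent.sum())
    if n_sig == 0:
        return ConcordanceSummary(len(joined), 0, 0, float("nan"), float("nan"), float("nan"))
    pct = round_half_up(100.0 * n_cons / n_sig, 1)
    res = stats.chisquare([n_cons, n_sig - n_cons], f_exp=[n_sig / 2, n_sig / 2])
    return ConcordanceSummary(len(joined), n_sig, n_cons, pct, float(res.statistic), float(res.pvalue))


def direction_concordance(n_consistent: int, n_significant: int) -> ConcordanceSummary:
    """Concordance summary directly from direction counts (for published
    tables where only the counts are available)."""
    if not 0 <= n_consistent <= n_significant:
        raise ValueError("need 0 <= n_consistent <= n_significant")
    if n_significant == 0:
        return ConcordanceSummary(0, 0, 0, float("nan"), float("nan"), float("nan"))
    pct = round_half_up(100.0 * n_consistent / n_significant, 1)
    res = stats.chisquare(
        [n_consistent, n_significant - n_consistent],
        f_exp=[n_significant / 2, n_significant / 2],
    )
    return ConcordanceSummary(n_significant, n_significant, n_consistent, pct, float(res.statistic), float(res.pvalue))


def proportion_significant(n_significant: int, n_tested: int) -> float:
    """100 * n_significant / n_tested, half-up rounded to 1 decimal."""
    if n_tested <= 0:
        raise ValueError(f"n_tested must be > 0, got {n_tested}")
    if not 0 <= n_significant <= n_tested:
        raise ValueError("need 0 <= n_significant <= n_tested")
    return round_half_up(100.0 * n_significant / n_tested, 1)
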