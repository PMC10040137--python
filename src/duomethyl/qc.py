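"""Quality-control filters and the rank-based inverse normal transformation.

Site filters follow the usual EWAS conventions: a probe is dropped when its
detection p-value exceeds the threshold in strictly more than the allowed
fraction of samples, or when it appears on a supplied mask of SNP-overlapping
or cross-hybridising probes. Samples are dropped when missing strictly more
than the allowed fraction of sites, or when methylation-predicted sex
contradicts the recorded sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class QcReport:
    """Counts of removed/retained sites and samples, by reason."""

    sites_in: int = 0
    samples_in: int = 0
    sites_removed_detection: int = 0
    sites_removed_mask: int = 0
    samples_removed_missing: int = 0
    samples_removed_sex: int = 0
    sites_retained: int = 0
    samples_retained: int = 0
    sex_threshold: float | None = None
    details: dict = field(default_factory=dict)


def filter_sites(
    matrix: pd.DataFrame,
    mask_ids: set[str] | None = None,
    detection_p: pd.DataFrame | None = None,
    detection_threshold: float | None = None,
    sample_fraction: float = 0.05,
) -> tuple[pd.DataFrame, QcReport]:
    """Remove failing or masked sites.

    A site is removed when detection_p > detection_threshold in strictly more
    than ``sample_fraction`` of samples ("over" the fraction, so a site failing
    in exactly that fraction is retained), or when listed in ``mask_ids``.
    Passing a ``detection_threshold`` without a ``detection_p`` matrix is an
    error rather than a silent no-op.
    """
    if detection_threshold is not None and detection_p is None:
        raise ValueError("detection p-value filtering requested but no detection_p matrix supplied")
    if detection_threshold is not None and not 0 < detection_threshold < 1:
        raise ValueError(f"detection_threshold must be in (0,1), got {detection_threshold}")
    if not 0 < sample_fraction < 1:
        raise ValueError(f"sample_fraction must be in (0,1), got {sample_fraction}")

    report = QcReport(sites_in=matrix.shape[0], samples_in=matrix.shape[1])
    mask_ids = mask_ids or set()

    bad_detection = pd.Series(False, index=matrix.index)
    if detection_p is not None:
        thr = 0.01 if detection_threshold is None else detection_threshold
        dp = detection_p.reindex(index=matrix.index, columns=matrix.columns)
        fail_frac = (dp > thr).sum(axis=1) / matrix.shape[1]
        bad_detection = fail_frac > sample_fraction

    in_mask = matrix.index.isin(mask_ids)
    report.sites_removed_detection = int(bad_detection.sum())
    report.sites_removed_mask = int((in_mask & ~bad_detection.to_numpy()).sum())
    keep = ~bad_detection.to_numpy() & ~in_mask
    out = matrix.loc[keep]
    report.sites_retained = out.shape[0]
    report.samples_retained = out.shape[1]
    return out, report


def filter_samples(matrix: pd.DataFrame, max_missing_fraction: float = 0.02) -> tuple[pd.DataFrame, QcReport]:
    """Remove samples missing strictly more than ``max_missing_fraction`` of sites."""
    if not 0 < max_missing_fraction < 1:
        raise ValueError(f"max_missing_fraction must be in (0,1), got {max_missing_fraction}")
    report = QcReport(sites_in=matrix.shape[0], samples_in=matrix.shape[1])
    miss = matrix.isna().sum(axis=0) / matrix.shape[0]
    keep = miss <= max_missing_fraction
    out = matrix.loc[:, keep]
    report.samples_removed_missing = int((~keep).sum())
    report.sites_retained = out.shape[0]
    report.samples_retained = out.shape[1]
    return out, report


def check_sex_consistency(
    newborn_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    recorded_sex: pd.Series,
    min_x_sites: int = 50,
) -> tuple[list[str], QcReport]:
    """Flag samples whose methylation-predicted sex disagrees with the records.

    Prediction uses a one-dimensional two-means split of each sample's mean
    beta over X-chromosomal sites: under balanced X inactivation with the
    inactive allele predominantly methylated, females average near 0.5 at
    XCI-subject island sites while hemizygous males sit near the unmethylated
    active-allele level, so the higher cluster is called female.
    """
    x_sites = annotation.loc[annotation["chromosome"].astype(str) == "X", "site_id"]
    x_sites = [s for s in x_sites if s in newborn_matrix.index]
    if len(x_sites) < min_x_sites:
        raise ValueError(f"need >= {min_x_sites} X-chromosomal sites for sex prediction, found {len(x_sites)}")
    if newborn_matrix.shape[1] < 2:
        raise ValueError("cannot form two clusters from fewer than 2 samples")

    mean_x = newborn_matrix.loc[x_sites].mean(axis=0)
    order = np.sort(mean_x.to_numpy())
    # exact 1-D two-means: best split minimises within-cluster sum of squares
    best_cut, best_ss = None, np.inf
    csum = np.cumsum(order)
    csum2 = np.cumsum(order**2)
    n = len(order)
    for i in range(1, n):
        ss_lo = csum2[i - 1] - csum[i - 1] ** 2 / i
        ss_hi = (csum2[-1] - csum2[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        if ss_lo + ss_hi < best_ss:
            best_ss, best_cut = ss_lo + ss_hi, 0.5 * (order[i - 1] + order[i])
    predicted = pd.Series(np.where(mean_x > best_cut, "female", "male"), index=mean_x.index)

    recorded = recorded_sex.reindex(mean_x.index)
    flagged = list(predicted.index[predicted != recorded])
    report = QcReport(
        sites_in=newborn_matrix.shape[0],
        samples_in=newborn_matrix.shape[1],
        samples_removed_sex=len(flagged),
        sites_retained=newborn_matrix.shape[0],
        samples_retained=newborn_matrix.shape[1] - len(flagged),
        sex_threshold=float(best_cut),
    )
    return flagged, report


def inverse_normal_transform(values) -> np.ndarray:
    """Blom rank-based inverse normal transform: Phi^-1((r - 3/8) / (n + 1/4)).

    Ties receive average ranks. Requires >= 2 finite values and at least two
    distinct values; NaNs are returned as NaN in place.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 2:
        raise ValueError(f"inverse normal transform needs >= 2 finite values, got {n}")
    xv = x[finite]
    if np.all(xv == xv[0]):
        raise ValueError("inverse normal transform undefined for a constant vector")
    ranks = rankdata(xv, method="average")
    out = np.full_like(x, np.nan)
    out[finite] = norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def int_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise Blom transform of a sites x samples matrix (no missing values).

    Rows with all-equal values come back as NaN rather than raising, so
    degenerate sites can be flagged instead of aborting a whole EWAS.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[1]
    ranks = rankdata(m, method="average", axis=1)
    out = norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    constant = np.all(m == m[:, :1], axis=1)
    out[constant] = np.nan
    return out
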