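"""Multiple-comparison corrections over the timepoint axis.

Three families, matching common practice for time-series EEG statistics:

* false discovery rate (Benjamini–Hochberg step-up, or the
  Benjamini–Yekutieli variant for arbitrary dependence);
* permutation maximum-statistic correction on the absolute GFP
  difference (strong FWER control);
* cluster-size correction: maximal runs of consecutive timepoints with
  uncorrected p below an inclusion criterion, referred to the
  permutation null distribution of maximum run lengths.

The permutation-based corrections re-use the null distribution retained
on a :class:`~gfpperm.permutation.PermutationResult`; the same label
shuffle is shared across timepoints within a resample, which is what
makes row-wise maxima and run lengths meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import GfppermError
from .permutation import PermutationResult


@dataclass
class CorrectionResult:
    """Rejection mask after one correction method plus method-specific
    detail (critical value, cluster table, threshold rank...)."""

    method: str
    reject: np.ndarray
    detail: dict[str, Any]


def fdr_correct(p_values: np.ndarray, q: float = 0.05, variant: str = "bh") -> CorrectionResult:
    """Step-up FDR control at level ``q``.

    BH compares the i-th smallest p against i*q/m; BY additionally
    divides q by sum(1/i).  All p-values up to the largest passing rank
    are rejected.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    method = {"bh": "fdr_bh", "by": "fdr_by"}.get(variant)
    if method is None:
        raise ValueError("variant must be 'bh' or 'by'")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=method)
    return CorrectionResult(
        method=f"fdr_{variant}",
        reject=reject,
        detail={"threshold_rank": int(reject.sum()), "p_adjusted": p_adj, "q": q},
    )


def max_stat_correct(result: PermutationResult, alpha: float = 0.05) -> CorrectionResult:
    """Maximum-statistic FWER correction on the absolute GFP difference.

    For every null row (the observed row included) take the maximum of
    |dGFP| over timepoints.  A timepoint's adjusted p is the share of
    row maxima at least as large as its |observed dGFP|; it is rejected
    when that share is <= alpha (equivalently, when |observed dGFP|
    clears the empirical (1 - alpha) quantile of the maxima, reported as
    ``detail["critical_value"]``).
    """
    if result.null_distribution is None:
        raise GfppermError("max_stat_correct requires the retained null distribution")
    maxima = np.abs(result.null_distribution).max(axis=1)
    critical = float(np.quantile(maxima, 1 - alpha, method="higher"))
    abs_obs = np.abs(result.observed)
    # adjusted p per timepoint: share of row maxima at least as large;
    # rejecting on p_adj <= alpha makes the S=1 degeneracy coincide with
    # the uncorrected two-tailed decision on symmetric nulls
    p_adj = (maxima[None, :] >= abs_obs[:, None]).mean(axis=1)
    return CorrectionResult(
        method="max_stat",
        reject=p_adj <= alpha,
        detail={"critical_value": critical, "p_adjusted": p_adj, "alpha": alpha},
    )


def _max_run_length(mask: np.ndarray) -> int:
    """Length of the longest run of True values in a 1-D boolean mask."""
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[::2]))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2], edges[1::2]))


def null_row_p_values(null: np.ndarray) -> np.ndarray:
    """Two-tailed p of every null row against the full null, column-wise.

    Row r is treated exactly as the observed row is: its p at timepoint
    s is 2*min(#rows <= value, #rows >= value)/R, capped at 1.  Row 0
    therefore reproduces the result's own p-values.
    """
    R = null.shape[0]
    n_le = rankdata(null, method="max", axis=0)
    n_ge = R - rankdata(null, method="min", axis=0) + 1
    return np.minimum(1.0, 2.0 * np.minimum(n_le, n_ge) / R)


def cluster_size_correct(
    result: PermutationResult, inclusion_alpha: float = 0.05, alpha: float = 0.05
) -> CorrectionResult:
    """Cluster-size correction with a sub-threshold inclusion criterion.

    Observed clusters are maximal runs of consecutive timepoints with
    uncorrected p < ``inclusion_alpha``.  The null distribution of
    cluster sizes takes each null row in turn as the observed statistic
    (scored against the full null, itself included) and records its
    maximum sub-threshold run length.  A cluster's p-value is the
    proportion of null maxima at least as long as the cluster; clusters
    with p <= ``alpha`` are rejected.
    """
    if result.null_distribution is None:
        raise GfppermError("cluster_size_correct requires the retained null distribution")
    null = result.null_distribution
    R = null.shape[0]
    p_rows = null_row_p_values(null)
    sub = p_rows < inclusion_alpha
    null_max = np.array([_max_run_length(sub[r]) for r in range(R)])
    obs_mask = result.p_values < inclusion_alpha
    reject = np.zeros_like(obs_mask)
    clusters = []
    for start, stop in _runs(obs_mask):
        size = stop - start
        p_cluster = float(np.count_nonzero(null_max >= size) / R)
        significant = p_cluster <= alpha
        if significant:
            reject[start:stop] = True
        times = result.times
        clusters.append(
            {
                "start": int(start),
                "stop": int(stop),
                "start_s": float(times[start]) if times is not None else float(start),
                "end_s": float(times[stop - 1]) if times is not None else float(stop - 1),
                "size": int(size),
                "p": p_cluster,
                "significant": bool(significant),
            }
        )
    critical = float(np.quantile(null_max, 1 - alpha, method="higher")) if R else np.inf
    return CorrectionResult(
        method="cluster_size",
        reject=reject,
        detail={
            "clusters": clusters,
            "null_max_sizes": null_max,
            "critical_size": critical,
            "inclusion_alpha": inclusion_alpha,
            "alpha": alpha,
        },
    )


def cluster_table(correction: CorrectionResult) -> pd.DataFrame:
    """Cluster extents and p-values as a tidy table (start_s, end_s, size, p)."""
    if correction.method != "cluster_size":
        raise ValueError("cluster_table expects a cluster_size CorrectionResult")
    cols = ["start_s", "end_s", "size", "p", "significant"]
    return pd.DataFrame(correction.detail["clusters"], columns=cols)
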