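"""Per-timepoint tests for group GFP differences in paired designs.

Three tests operate on a multi-subject, two-condition, repeated-measures
design:

``unbalanced_paired_permutation_test``
    Reshuffles condition labels at the *single-trial* level within each
    subject, preserving each subject's per-condition trial counts, then
    re-averages, recomputes per-condition GFP traces and the group-mean
    GFP difference.  Because each null resample carries the same trial
    counts as the observed labelling, the trial-count bias of GFP is
    identical under the null and the observed statistic, making the test
    valid under arbitrary imbalance.

``conventional_paired_permutation_test``
    The classical subject-level paired permutation test on per-subject
    condition GFP traces: condition labels are flipped per subject
    (2^N possible flips), which ignores the trial-count bias and is
    anti-conservative on unbalanced data.

``paired_t_test``
    The classical two-tailed paired-samples T test on per-subject
    condition GFPs, df = N - 1; equally anti-conservative when
    unbalanced.

All permutation p-values follow the observed-in-null convention: the
statistic computed from the true labels is one entry of the null
distribution, and the two-tailed p-value is twice the smaller of the
lower/upper tail proportions, capped at 1, so the smallest attainable p
is 2 / n_resamples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import EpochedDataset, check_compatible
from .errors import GfppermError
from .gfp import gfp_of

SIGN_CONVENTIONS = ("A_minus_B", "B_minus_A")


@dataclass
class TestConfig:
    """Shared settings for the permutation tests.

    ``n_resamples`` counts the rows of the null distribution *including*
    the observed labelling (default 2000); ``alpha`` is the two-tailed
    rejection threshold; ``sign_convention`` fixes the direction of the
    GFP difference (it does not affect two-tailed p-values).
    """

    n_resamples: int = 2000
    alpha: float = 0.05
    seed: Optional[int] = None
    sign_convention: str = "A_minus_B"

    __test__ = False  # not a pytest collectable despite the name

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ValueError(f"sign_convention must be one of {SIGN_CONVENTIONS}")


def two_tailed_p(null_with_observed: np.ndarray, observed: float) -> float:
    """Two-tailed permutation p-value with the observed value in the null.

    p = 2 * min(#entries <= observed, #entries >= observed) / n, capped
    at 1.  The observed statistic must itself be an entry of
    ``null_with_observed`` (the Edgington & Onghena convention), which
    bounds p away from 0 at 2/n.
    """
    null = np.asarray(null_with_observed, dtype=np.float64).ravel()
    if not np.any(null == observed):
        raise GfppermError("observed statistic must be an entry of the null distribution")
    n = null.size
    n_le = int(np.count_nonzero(null <= observed))
    n_ge = int(np.count_nonzero(null >= observed))
    return min(1.0, 2.0 * min(n_le, n_ge) / n)


def _p_values_rows(null: np.ndarray, observed_rows: np.ndarray) -> np.ndarray:
    """Vectorised two-tailed p of each row of ``observed_rows`` against
    ``null`` (rows x timepoints), column-wise."""
    n = null.shape[0]
    n_le = (null[:, None, :] <= observed_rows[None, :, :]).sum(axis=0)
    n_ge = (null[:, None, :] >= observed_rows[None, :, :]).sum(axis=0)
    return np.minimum(1.0, 2.0 * np.minimum(n_le, n_ge) / n)


def _p_values(null: np.ndarray) -> np.ndarray:
    """Two-tailed p per timepoint of the observed row (row 0) of a null
    distribution matrix."""
    obs = null[0]
    n = null.shape[0]
    n_le = (null <= obs).sum(axis=0)
    n_ge = (null >= obs).sum(axis=0)
    return np.minimum(1.0, 2.0 * np.minimum(n_le, n_ge) / n)


@dataclass
class PermutationResult:
    """Observed group-mean GFP difference, its permutation null, and
    per-timepoint two-tailed p-values.

    Row 0 of ``null_distribution`` is the observed statistic (the
    observed-in-null convention), so every p-value is an integer multiple
    of ``2 / n_resamples`` capped at 1.
    """

    observed: np.ndarray
    null_distribution: np.ndarray
    p_values: np.ndarray
    config: TestConfig
    times: Optional[np.ndarray] = None
    method: str = "unbalanced_paired_permutation"

    def reject(self, alpha: Optional[float] = None) -> np.ndarray:
        """Boolean per-timepoint rejection mask at ``alpha`` (uncorrected)."""
        a = self.config.alpha if alpha is None else alpha
        return self.p_values <= a

    # corrections -----------------------------------------------------
    def fdr(self, q: float = 0.05, variant: str = "bh"):
        from .corrections import fdr_correct

        return fdr_correct(self.p_values, q=q, variant=variant)

    def max_stat(self, alpha: Optional[float] = None):
        from .corrections import max_stat_correct

        return max_stat_correct(self, self.config.alpha if alpha is None else alpha)

    def cluster_size(self, inclusion_alpha: float = 0.05, alpha: Optional[float] = None):
        from .corrections import cluster_size_correct

        return cluster_size_correct(
            self, inclusion_alpha, self.config.alpha if alpha is None else alpha
        )

    # reporting -------------------------------------------------------
    def summary(self, corrections: Sequence = ()) -> pd.DataFrame:
        """Tidy per-timepoint table: time, observed dGFP, p, rejection
        masks (uncorrected plus any supplied correction results)."""
        times = self.times if self.times is not None else np.arange(self.observed.size)
        df = pd.DataFrame(
            {
                "time_s": times,
                "observed_dgfp_uV": self.observed,
                "p_value": self.p_values,
                "reject_uncorrected": self.reject(),
            }
        )
        for corr in corrections:
            df[f"reject_{corr.method}"] = corr.reject
        return df

    def to_tsv(self, path, corrections: Sequence = (), header_lines: Sequence[str] = ()) -> None:
        df = self.summary(corrections)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    def plot(self, ax=None, alpha: Optional[float] = None):
        """Observed dGFP trace with the central (1 - alpha) band of the
        permutation distribution."""
        import matplotlib.pyplot as plt

        a = self.config.alpha if alpha is None else alpha
        if ax is None:
            _, ax = plt.subplots()
        times = self.times if self.times is not None else np.arange(self.observed.size)
        lo, hi = np.quantile(self.null_distribution, [a / 2, 1 - a / 2], axis=0)
        ax.fill_between(times, lo, hi, alpha=0.3, label=f"central {1 - a:.0%} of null")
        ax.plot(times, self.observed, lw=1.5, label="observed dGFP")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("dGFP (µV)")
        ax.legend()
        return ax


def _shuffled_masks(rng: np.random.Generator, base_mask: np.ndarray, n_rows: int) -> np.ndarray:
    """``n_rows`` independent row-wise shuffles of a boolean label mask;
    every row has exactly ``base_mask.sum()`` True entries."""
    tiled = np.tile(base_mask, (n_rows, 1))
    return rng.permuted(tiled, axis=1)


def _subject_null_dgfp(
    data: np.ndarray, masks: np.ndarray, sign_convention: str
) -> np.ndarray:
    """Per-resample GFP difference traces for one subject.

    ``data`` is C x S x K; ``masks`` is R x K boolean, each row one
    label assignment (True = condition A).  Returns an R x S matrix of
    GFP(A') - GFP(B') (or the reverse, per the sign convention).
    """
    C, S, K = data.shape
    n_a = int(masks[0].sum())
    n_b = K - n_a
    flat = data.reshape(C * S, K)
    total = flat.sum(axis=1, keepdims=True)
    sum_a = flat @ masks.T.astype(np.float64)  # (C*S, R)
    mean_a = (sum_a / n_a).reshape(C, S, -1)
    mean_b = ((total - sum_a) / n_b).reshape(C, S, -1)
    gfp_a = gfp_of(mean_a)  # (S, R)
    gfp_b = gfp_of(mean_b)
    d = gfp_a - gfp_b
    if sign_convention == "B_minus_A":
        d = -d
    return d.T  # (R, S)


def unbalanced_paired_permutation_test(
    datasets: Sequence[EpochedDataset], config: Optional[TestConfig] = None
) -> PermutationResult:
    """Single-trial-level paired permutation test of group GFP differences.

    For each resample, every subject's trial labels are shuffled while
    holding that subject's A and B counts fixed; per-condition ERPs and
    their GFP traces are recomputed and the GFP difference averaged over
    subjects.  The observed labelling contributes one row of the null
    distribution; two-tailed p-values per timepoint follow
    :func:`two_tailed_p`.

    One shared shuffle per resample is applied across all timepoints, so
    max-statistic and cluster corrections on the resulting null are
    coherent.
    """
    config = config or TestConfig()
    datasets = list(datasets)
    check_compatible(datasets)
    for ds in datasets:
        ds.require_condition("A")
        ds.require_condition("B")
    R = config.n_resamples
    S = datasets[0].n_samples
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(datasets))
    acc = np.zeros((R, S))
    for ds, child in zip(datasets, children):
        rng = np.random.default_rng(child)
        base = ds.trial_mask("A")
        masks = np.empty((R, ds.n_trials), dtype=bool)
        masks[0] = base
        if R > 1:
            masks[1:] = _shuffled_masks(rng, base, R - 1)
        acc += _subject_null_dgfp(ds.data, masks, config.sign_convention)
    null = acc / len(datasets)
    return PermutationResult(
        observed=null[0].copy(),
        null_distribution=null,
        p_values=_p_values(null),
        config=config,
        times=datasets[0].times,
        method="unbalanced_paired_permutation",
    )


def _signed_means(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    return signs.astype(np.float64) @ diffs / diffs.shape[0]


def conventional_paired_permutation_test(
    gfp_a: np.ndarray,
    gfp_b: np.ndarray,
    config: Optional[TestConfig] = None,
    times: Optional[np.ndarray] = None,
) -> PermutationResult:
    """Subject-level paired permutation test on condition GFP traces.

    Inputs are N x S matrices of per-subject GFP for conditions A and B.
    Each resample flips the condition labels independently per subject
    (equivalently, flips the sign of the per-subject GFP difference).
    When 2^N <= n_resamples the full set of 2^N flips is enumerated;
    otherwise random flips are drawn, with the observed (all-unflipped)
    pattern as one row of the null.
    """
    config = config or TestConfig()
    gfp_a = np.asarray(gfp_a, dtype=np.float64)
    gfp_b = np.asarray(gfp_b, dtype=np.float64)
    if gfp_a.shape != gfp_b.shape or gfp_a.ndim != 2:
        raise GfppermError("gfp_a and gfp_b must be matching N x S matrices")
    N = gfp_a.shape[0]
    if N < 2:
        raise GfppermError("need at least 2 subjects")
    diffs = gfp_a - gfp_b
    if config.sign_convention == "B_minus_A":
        diffs = -diffs
    if 2**N <= config.n_resamples:
        bits = (np.arange(2**N)[:, None] >> np.arange(N)[None, :]) & 1
        signs = 1 - 2 * bits  # row 0 is the observed (all +1) pattern
        null = _signed_means(signs, diffs)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        signs = np.empty((config.n_resamples, N), dtype=np.int64)
        signs[0] = 1
        signs[1:] = rng.choice((-1, 1), size=(config.n_resamples - 1, N))
        null = _signed_means(signs, diffs)
    return PermutationResult(
        observed=null[0].copy(),
        null_distribution=null,
        p_values=_p_values(null),
        config=config,
        times=times,
        method="conventional_paired_permutation",
    )


@dataclass
class PairedTTestResult:
    """Per-timepoint paired-samples T test: t, two-tailed p, df = N - 1.

    ``zero_variance`` flags timepoints where the difference variance is
    exactly zero; there p = 1 when the mean difference is also zero and
    p = 0 otherwise (flagged, by convention).
    """

    t: np.ndarray
    p_values: np.ndarray
    df: int
    observed: np.ndarray
    zero_variance: np.ndarray = field(default=None)
    times: Optional[np.ndarray] = None
    method: str = "paired_t"

    def reject(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_values <= alpha

    def summary(self) -> pd.DataFrame:
        times = self.times if self.times is not None else np.arange(self.observed.size)
        return pd.DataFrame(
            {
                "time_s": times,
                "observed_dgfp_uV": self.observed,
                "t": self.t,
                "p_value": self.p_values,
                "df": self.df,
            }
        )


def paired_t_test(
    gfp_a: np.ndarray,
    gfp_b: np.ndarray,
    times: Optional[np.ndarray] = None,
    sign_convention: str = "A_minus_B",
) -> PairedTTestResult:
    """Classical two-tailed paired-samples T test per timepoint.

    The standard error uses the ddof=1 sample variance of the
    per-subject differences; df = N - 1.
    """
    gfp_a = np.asarray(gfp_a, dtype=np.float64)
    gfp_b = np.asarray(gfp_b, dtype=np.float64)
    if gfp_a.shape != gfp_b.shape or gfp_a.ndim != 2:
        raise GfppermError("gfp_a and gfp_b must be matching N x S matrices")
    N = gfp_a.shape[0]
    if N < 2:
        raise GfppermError("need at least 2 subjects")
    diffs = gfp_a - gfp_b
    if sign_convention == "B_minus_A":
        diffs = -diffs
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    se = sd / np.sqrt(N)
    zero_var = se == 0
    t = np.zeros_like(mean)
    np.divide(mean, se, out=t, where=~zero_var)
    df = N - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance conventions: mean 0 -> t=0, p=1; nonzero mean -> p=0 flagged
    p = np.where(zero_var & (mean != 0), 0.0, p)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    return PairedTTestResult(
        t=t, p_values=p, df=df, observed=mean, zero_variance=zero_var, times=times
    )


def subject_condition_gfps(
    datasets: Sequence[EpochedDataset],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject condition GFP traces into N x S matrices
    (inputs to the conventional tests)."""
    from .gfp import compute_erp, compute_gfp

    check_compatible(datasets)
    gfp_a = np.stack(
        [compute_gfp(compute_erp(ds, "A")).values for ds in datasets]
    )
    gfp_b = np.stack(
        [compute_gfp(compute_erp(ds, "B")).values for ds in datasets]
    )
    return gfp_a, gfp_b


def exhaustive_unbalanced_null(
    datasets: Sequence[EpochedDataset], sign_convention: str = "A_minus_B"
) -> np.ndarray:
    """Exact null distribution of the unbalanced test by joint enumeration
    of all within-subject label assignments.

    Only feasible for tiny problems (the number of rows is the product
    over subjects of C(K_s, K_s^A)); used as an oracle and for exact
    p-values on small designs.
    """
    datasets = list(datasets)
    check_compatible(datasets)
    per_subject = []
    for ds in datasets:
        K = ds.n_trials
        n_a = ds.n_trials_in("A")
        rows = []
        for combo in itertools.combinations(range(K), n_a):
            mask = np.zeros(K, dtype=bool)
            mask[list(combo)] = True
            rows.append(mask)
        per_subject.append(
            _subject_null_dgfp(ds.data, np.array(rows), sign_convention)
        )
    total = np.zeros((1, datasets[0].n_samples))
    for rows in per_subject:
        total = (total[:, None, :] + rows[None, :, :]).reshape(-1, rows.shape[1])
    return total / len(datasets)
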