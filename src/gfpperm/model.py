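"""statsmodels-style model front-ends over the testing functions.

Each model class is constructed from data plus settings and exposes
``fit()`` returning a results object (:class:`PermutationResult` or
:class:`PairedTTestResult`) with the estimate, null distribution /
standard errors, p-values and a ``summary()`` table; corrections and
plotting hang off the results.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .datasets import EpochedDataset
from .permutation import (
    PairedTTestResult,
    PermutationResult,
    TestConfig,
    conventional_paired_permutation_test,
    paired_t_test,
    subject_condition_gfps,
    unbalanced_paired_permutation_test,
)


class UnbalancedGFPPermutation:
    """Unbalanced paired permutation model for group GFP differences.

    Parameters
    ----------
    datasets : sequence of EpochedDataset
        One per subject, labels in {"A", "B"}, shared montage/time axis.
    n_resamples, alpha, sign_convention
        See :class:`~gfpperm.permutation.TestConfig`.

    Examples
    --------
    >>> res = UnbalancedGFPPermutation(datasets, n_resamples=2000).fit(seed=7)
    >>> res.summary().head()
    """

    def __init__(
        self,
        datasets: Sequence[EpochedDataset],
        n_resamples: int = 2000,
        alpha: float = 0.05,
        sign_convention: str = "A_minus_B",
    ):
        self.datasets = list(datasets)
        self.config = TestConfig(
            n_resamples=n_resamples, alpha=alpha, sign_convention=sign_convention
        )

    def fit(self, seed: Optional[int] = None) -> PermutationResult:
        return unbalanced_paired_permutation_test(
            self.datasets, replace(self.config, seed=seed)
        )


class PairedGFPPermutation:
    """Conventional subject-level paired permutation model on condition
    GFP traces (valid only for balanced designs)."""

    def __init__(
        self,
        gfp_a: np.ndarray,
        gfp_b: np.ndarray,
        n_resamples: int = 2000,
        alpha: float = 0.05,
        sign_convention: str = "A_minus_B",
        times: Optional[np.ndarray] = None,
    ):
        self.gfp_a = np.asarray(gfp_a)
        self.gfp_b = np.asarray(gfp_b)
        self.times = times
        self.config = TestConfig(
            n_resamples=n_resamples, alpha=alpha, sign_convention=sign_convention
        )

    @classmethod
    def from_datasets(cls, datasets: Sequence[EpochedDataset], **kwargs):
        gfp_a, gfp_b = subject_condition_gfps(datasets)
        return cls(gfp_a, gfp_b, times=datasets[0].times, **kwargs)

    def fit(self, seed: Optional[int] = None) -> PermutationResult:
        return conventional_paired_permutation_test(
            self.gfp_a, self.gfp_b, replace(self.config, seed=seed), times=self.times
        )


class PairedGFPTTest:
    """Classical paired-samples T model on condition GFP traces."""

    def __init__(
        self,
        gfp_a: np.ndarray,
        gfp_b: np.ndarray,
        sign_convention: str = "A_minus_B",
        times: Optional[np.ndarray] = None,
    ):
        self.gfp_a = np.asarray(gfp_a)
        self.gfp_b = np.asarray(gfp_b)
        self.sign_convention = sign_convention
        self.times = times

    @classmethod
    def from_datasets(cls, datasets: Sequence[EpochedDataset], **kwargs):
        gfp_a, gfp_b = subject_condition_gfps(datasets)
        return cls(gfp_a, gfp_b, times=datasets[0].times, **kwargs)

    def fit(self) -> PairedTTestResult:
        return paired_t_test(
            self.gfp_a, self.gfp_b, times=self.times,
            sign_convention=self.sign_convention,
        )
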