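"""Global field power and its trial-count-dependent expectation.

Global field power (GFP) is the spatial standard deviation of an
average-referenced electrode montage at one time point, computed here on
the trial-averaged ERP:

    GFP(s) = sqrt( (1/C) * sum_i ( ybar_i(s) - ybar_.(s) )^2 )

with the population (divide-by-C) normalisation.  GFP is a biased
statistic: residual noise in the ERP inflates it, and the residual noise
level depends on the number of trials K averaged.  Under the moment
assumptions (channel means mu_i, channel variances sigma_i^2, trials
independent, within-trial cross-channel covariances rho_ij), a
delta-method approximation of the expectation is

    E(GFP) = sqrt( (1/C) sum_i (sigma_i^2 / K + mu_i^2)
                   - ( sum_i 2 mu_i^2 sigma_i^2
                       + (1/K) sum_{i>j} mu_i mu_j rho_ij )
                     / ( K (C-1) sqrt( [ (1/(C-1)) sum_i
                                          (sigma_i^2/K + mu_i^2) ]^3 ) ) )

whose leading term sqrt((1/C) sum_i (sigma_i^2/K + mu_i^2)) makes the K
dependence explicit: more trials, less noise, smaller expected GFP.  This
is why naive GFP comparisons on unbalanced trial counts are invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ERP, EpochedDataset, GFPTrace
from .errors import ApproximationRangeError, InvalidMontageError


def average_reference(epochs: EpochedDataset) -> EpochedDataset:
    """Re-reference every sample of every trial to the spatial mean.

    After this operation the mean over channels is zero for each
    (sample, trial) pair.  Idempotent; shape unchanged.
    """
    if epochs.n_channels < 2:
        raise InvalidMontageError("average reference requires >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return epochs.with_data(data)


def compute_erp(epochs: EpochedDataset, condition: str) -> ERP:
    """Average the trials carrying ``condition`` into a C x S ERP."""
    epochs.require_condition(condition)
    mask = epochs.trial_mask(condition)
    values = epochs.data[:, :, mask].mean(axis=2)
    return ERP(values=values, times=epochs.times, channel_names=epochs.channel_names)


def gfp_of(values: np.ndarray) -> np.ndarray:
    """Population spatial standard deviation over the channel (first) axis."""
    return np.std(values, axis=0)


def compute_gfp(erp: ERP) -> GFPTrace:
    """Global field power trace of a condition-average ERP.

    Invariant to adding a constant to all channels and absolutely
    homogeneous under scaling.
    """
    if erp.values.shape[0] < 2:
        raise InvalidMontageError("GFP requires >= 2 channels")
    return GFPTrace(values=gfp_of(erp.values), times=erp.times)


@dataclass
class GfpMoments:
    """First and second moments of single-trial channel voltages.

    ``mu`` (C,) channel means in microvolts, ``sigma2`` (C,) channel
    variances in microvolts^2, ``rho`` (C, C) symmetric within-trial
    cross-channel covariances (diagonal ignored), ``K`` the trial count.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    rho: np.ndarray
    K: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma2 = np.asarray(self.sigma2, dtype=np.float64)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        C = self.mu.shape[0]
        if self.sigma2.shape != (C,) or self.rho.shape != (C, C):
            raise ValueError("inconsistent moment shapes")
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def C(self) -> int:
        return self.mu.shape[0]

    @classmethod
    def from_trials(cls, trials: np.ndarray) -> "GfpMoments":
        """Sample moments from a C x K matrix of single-trial voltages
        at one time point (unbiased variance/covariance, ddof=1)."""
        trials = np.asarray(trials, dtype=np.float64)
        C, K = trials.shape
        cov = np.cov(trials, ddof=1)
        return cls(mu=trials.mean(axis=1), sigma2=np.diag(cov).copy(), rho=cov, K=K)


def expected_gfp(moments: GfpMoments) -> float:
    """Delta-method approximation to E(GFP) of a K-trial average.

    Implements the closed-form approximation verbatim (see module
    docstring); strictly decreasing in K when all channel means are zero.

    Raises
    ------
    ApproximationRangeError
        If the outer radicand is negative (moments outside the
        approximation's range); the radicand is carried on the error.
    """
    mu, sigma2, rho, K = moments.mu, moments.sigma2, moments.rho, moments.K
    C = moments.C
    if C < 2:
        raise InvalidMontageError("expected_gfp requires >= 2 channels")
    per_channel = sigma2 / K + mu**2
    leading = per_channel.mean()
    # sum over channel pairs i > j of mu_i mu_j rho_ij
    pair_sum = float(np.sum(np.tril(np.outer(mu, mu) * rho, k=-1)))
    numerator = float(np.sum(2.0 * mu**2 * sigma2)) + pair_sum / K
    inner = per_channel.sum() / (C - 1)
    correction = numerator / (K * (C - 1) * np.sqrt(inner**3)) if numerator != 0.0 else 0.0
    radicand = leading - correction
    if radicand < 0:
        raise ApproximationRangeError(radicand)
    return float(np.sqrt(radicand))
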