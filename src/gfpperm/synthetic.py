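"""Synthetic multi-subject epoched EEG with controlled condition effects.

The generator realises exactly the moment structure the GFP bias
analysis assumes: every trial is an independent draw of spatially
correlated, zero-mean Gaussian noise (channel covariance ``channel_cov``),
optionally smoothed along time so that temporal corrections are
non-trivial.  Condition effects are injected as an additive offset that
is positive on half the electrodes and negative on the other half at a
controlled spatial RMS amplitude — deliberately unlike a physiological
ERP, but trivially parameterised and with GFP equal to its RMS
amplitude.

Defaults mirror a typical 64-channel, 256 Hz recording with ~178
accepted epochs per subject across 13 subjects and a per-channel
single-trial noise SD of 12 µV (see docs/methods.md for the
calibration rationale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import EpochedDataset
from .errors import GfppermError, ZeroNoiseError

#: effect amplitudes (spatial RMS, µV) swept by the sensitivity experiment
DEFAULT_EFFECT_SWEEP = (1.17, 1.47, 1.76, 2.05, 2.35, 2.64, 2.93, 3.25, 3.59)

#: imbalance ratios (share of trials labelled A) swept by the validity experiment
DEFAULT_VALIDITY_RATIOS = (1 / 2, 1 / 5, 1 / 8, 1 / 10, 1 / 15)

#: imbalance ratios swept by the sensitivity experiment (A fixed at 30 trials)
DEFAULT_SENSITIVITY_RATIOS = (1 / 2, 1 / 3, 1 / 4, 1 / 5)


@dataclass
class NoiseModel:
    """Spatially correlated Gaussian trial noise.

    ``channel_cov`` is the C x C positive-semidefinite within-trial
    cross-channel covariance (µV²).  ``temporal_smoothing`` is an
    optional low-pass cutoff in Hz realised as a variance-preserving
    Gaussian smoother along time (raw white noise in time makes
    time-series corrections trivial).  ``trial_sd_scale`` adds
    multiplicative between-subject variability: subject noise is scaled
    by a factor drawn uniformly from [1 - s, 1 + s].
    """

    C: int = 64
    S: int = 768
    sampling_rate: float = 256.0
    channel_cov: np.ndarray = None
    temporal_smoothing: Optional[float] = None
    trial_sd_scale: float = 0.0
    t_start: float = -1.0

    def __post_init__(self):
        if self.channel_cov is None:
            self.channel_cov = equicorrelated_cov(self.C)
        self.channel_cov = np.asarray(self.channel_cov, dtype=np.float64)
        if self.channel_cov.shape != (self.C, self.C):
            raise ValueError("channel_cov must be C x C")
        if not np.allclose(self.channel_cov, self.channel_cov.T):
            raise GfppermError("channel_cov must be symmetric")
        w = np.linalg.eigvalsh(self.channel_cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise GfppermError("channel_cov must be positive semidefinite")

    @classmethod
    def equicorrelated(
        cls,
        C: int = 64,
        S: int = 768,
        sampling_rate: float = 256.0,
        sd: float = 12.0,
        rho: float = 0.2,
        **kwargs,
    ) -> "NoiseModel":
        """Homogeneous montage: per-channel SD ``sd`` µV, common
        inter-channel correlation ``rho``."""
        return cls(
            C=C,
            S=S,
            sampling_rate=sampling_rate,
            channel_cov=equicorrelated_cov(C, sd=sd, rho=rho),
            **kwargs,
        )

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.S) / self.sampling_rate

    def _factor(self) -> np.ndarray:
        # PSD square root (handles singular covariances, e.g. all-zero)
        w, v = np.linalg.eigh(self.channel_cov)
        return v * np.sqrt(np.clip(w, 0.0, None))

    def sample(self, n_trials: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
        """One subject's C x S x K noise tensor."""
        z = rng.standard_normal((self.C, self.S, n_trials))
        if self.temporal_smoothing is not None:
            from scipy.ndimage import gaussian_filter1d

            # cutoff f_c -> Gaussian sigma in samples; renormalise so the
            # per-sample variance is preserved after smoothing
            sigma = self.sampling_rate / (2.0 * np.pi * self.temporal_smoothing)
            z = gaussian_filter1d(z, sigma=sigma, axis=1, mode="wrap")
            z /= max(z.std(), 1e-12)
        return scale * np.einsum("ij,jsk->isk", self._factor(), z)


def equicorrelated_cov(C: int, sd: float = 12.0, rho: float = 0.2) -> np.ndarray:
    """sd² * [(1 - rho) I + rho J]: equal channel variances, equal
    pairwise correlation."""
    return sd**2 * ((1 - rho) * np.eye(C) + rho * np.ones((C, C)))


@dataclass
class EffectSpec:
    """Additive offset effect: + on the first half of the channels and
    - on the second half, at spatial RMS ``rms_amplitude`` µV, applied
    within [onset_s, offset_s) (default: the whole epoch)."""

    rms_amplitude: float
    onset_s: Optional[float] = None
    offset_s: Optional[float] = None

    def __post_init__(self):
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be >= 0")
        if self.onset_s is not None and self.offset_s is not None:
            if not self.onset_s < self.offset_s:
                raise ValueError("onset_s must precede offset_s")

    def window_mask(self, times: np.ndarray) -> np.ndarray:
        mask = np.ones_like(times, dtype=bool)
        if self.onset_s is not None:
            mask &= times >= self.onset_s
        if self.offset_s is not None:
            mask &= times < self.offset_s
        return mask

    def pattern(self, C: int, times: np.ndarray) -> np.ndarray:
        """The injected C x S effect pattern (zero outside the window).

        For the half/half polarity split the per-channel amplitude
        equals ``rms_amplitude`` and so does the pattern's GFP.
        """
        if C % 2 != 0:
            raise GfppermError("offset effect requires an even channel count")
        spatial = np.concatenate(
            [np.full(C // 2, self.rms_amplitude), np.full(C // 2, -self.rms_amplitude)]
        )
        return spatial[:, None] * self.window_mask(times)[None, :]


def generate_null_epochs(
    noise: NoiseModel,
    n_subjects: int = 13,
    trials_per_subject: int = 178,
    seed=None,
) -> list[EpochedDataset]:
    """Multi-subject null data: i.i.d. zero-mean correlated-noise trials.

    All trials are labelled "B"; condition labels are meant to be
    assigned afterwards (e.g. via :func:`split_labels`), so the null of
    no condition difference is true by construction.  Deterministic
    given ``seed``.
    """
    if n_subjects < 1 or trials_per_subject < 2:
        raise ValueError("need n_subjects >= 1 and trials_per_subject >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    datasets = []
    for j, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        scale = 1.0
        if noise.trial_sd_scale > 0:
            scale = 1.0 + noise.trial_sd_scale * rng.uniform(-1.0, 1.0)
        data = noise.sample(trials_per_subject, rng, scale=scale)
        datasets.append(
            EpochedDataset(
                subject_id=f"sub-{j + 1:02d}",
                data=data,
                labels=np.full(trials_per_subject, "B"),
                times=noise.times,
                sampling_rate=noise.sampling_rate,
            )
        )
    return datasets


def split_labels(K: int, ratio: float, seed=None, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Random condition labels: round(ratio*K) trials "A" (nearest
    integer, ties to even, minimum 1), the rest "B"."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n_a = max(1, int(np.rint(ratio * K)))
    if n_a >= K:
        raise GfppermError(f"degenerate split: {n_a} of {K} trials labelled A")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.full(K, "B", dtype="U1")
    labels[rng.choice(K, size=n_a, replace=False)] = "A"
    return labels


def add_offset_effect(
    epochs: EpochedDataset, which_label: str, effect: EffectSpec
) -> EpochedDataset:
    """Add the polarity-split offset to the trials carrying
    ``which_label``; all other trials and all samples outside the
    effect window are untouched."""
    pattern = effect.pattern(epochs.n_channels, epochs.times)
    data = epochs.data.copy()
    mask = epochs.trial_mask(which_label)
    data[:, :, mask] += pattern[:, :, None]
    return epochs.with_data(data)


def compute_snr(effect_pattern: np.ndarray, epochs: EpochedDataset) -> float:
    """RMS of the effect over its channels x window samples divided by
    the RMS residual of the epochs about their trial mean.

    Pass the effect pattern restricted to (or zero-padded over) the
    samples you count as signal; zeros dilute the numerator.
    """
    effect_pattern = np.asarray(effect_pattern, dtype=np.float64)
    if effect_pattern.shape[0] != epochs.n_channels:
        raise GfppermError("effect pattern and epochs disagree on channel count")
    rms_effect = float(np.sqrt(np.mean(effect_pattern**2)))
    residual = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    rms_noise = float(np.sqrt(np.mean(residual**2)))
    if rms_noise == 0:
        raise ZeroNoiseError("residual noise RMS is zero; SNR undefined")
    return rms_effect / rms_noise


def pooled_noise_rms(datasets: Sequence[EpochedDataset]) -> float:
    """RMS residual about the per-subject trial mean, pooled over subjects."""
    total, count = 0.0, 0
    for ds in datasets:
        residual = ds.data - ds.data.mean(axis=2, keepdims=True)
        total += float(np.sum(residual**2))
        count += residual.size
    if total == 0:
        raise ZeroNoiseError("residual noise RMS is zero; SNR undefined")
    return np.sqrt(total / count)
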