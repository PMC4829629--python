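"""Validity (type-I error) and sensitivity (power) simulation harnesses.

The validity harness generates a fixed multi-subject null dataset once
(mirroring a real recording that is re-split many times), then repeatedly
assigns condition labels at random at a given imbalance ratio and runs
the three tests.  Because labels are assigned by the simulation, every
rejection is a false positive; the false positive rate is pooled over
timepoints and repetitions.

The sensitivity harness fixes the number of Condition-A trials (default
30), sizes Condition B to realise each imbalance ratio, injects the
polarity-split offset into the A trials at each amplitude of the effect
sweep and scores a true positive when the unbalanced test rejects
anywhere inside the effect window.  Per ratio, a two-parameter logistic
(binomial GLM in SNR) summarises the power curve as the SNR at which
sensitivity reaches .5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import EpochedDataset
from .errors import GfppermError
from .permutation import (
    TestConfig,
    conventional_paired_permutation_test,
    paired_t_test,
    subject_condition_gfps,
    unbalanced_paired_permutation_test,
)
from .synthetic import (
    DEFAULT_EFFECT_SWEEP,
    DEFAULT_SENSITIVITY_RATIOS,
    DEFAULT_VALIDITY_RATIOS,
    EffectSpec,
    NoiseModel,
    add_offset_effect,
    generate_null_epochs,
    pooled_noise_rms,
    split_labels,
)

VALIDITY_METHODS = ("unbalanced", "conventional_permutation", "paired_t")


def _child_seed(seq: np.random.SeedSequence) -> int:
    # keep derived seeds below 2**31 so they stay plain ints everywhere
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass
class ValidityReport:
    """False-positive-rate table per (method, ratio) with 95% CIs and a
    one-sample two-tailed t test of per-repetition FPRs against alpha."""

    table: pd.DataFrame
    alpha: float
    n_repetitions: int
    p_values: dict
    per_rep_fpr: dict
    seed: Optional[int] = None

    def fpr(self, method: str, ratio: float) -> float:
        t = self.table
        row = t[(t["method"] == method) & np.isclose(t["ratio"], ratio)]
        if row.empty:
            raise KeyError((method, ratio))
        return float(row["fpr"].iloc[0])

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def plot(self, ax=None):
        """FPR vs imbalance ratio per method (log y), nominal level dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for method, grp in self.table.groupby("method"):
            grp = grp.sort_values("ratio")
            ratio = grp["ratio"].to_numpy()
            fpr = grp["fpr"].to_numpy()
            yerr = np.stack([fpr - grp["ci_lo"].to_numpy(), grp["ci_hi"].to_numpy() - fpr])
            ax.errorbar(ratio, fpr, yerr=yerr, marker="o", label=method)
        ax.axhline(self.alpha, ls="--", color="k", lw=0.8)
        ax.set_xlabel("proportion of trials labelled A")
        ax.set_ylabel("false positive rate")
        ax.set_yscale("log")
        ax.legend()
        return ax


def run_validity_experiment(
    ratios: Sequence[float] = DEFAULT_VALIDITY_RATIOS,
    n_repetitions: int = 100,
    config: Optional[TestConfig] = None,
    noise: Optional[NoiseModel] = None,
    n_subjects: int = 13,
    trials_per_subject: int = 178,
    seed=None,
    methods: Sequence[str] = VALIDITY_METHODS,
    datasets: Optional[Sequence[EpochedDataset]] = None,
) -> ValidityReport:
    """Type-I-error simulation under a true null.

    Null epochs are generated once (or supplied); for each repetition and
    ratio, each subject's labels are drawn afresh, all requested tests
    run, and per-timepoint rejections at ``config.alpha`` recorded.  FPR
    is pooled over timepoints and repetitions; ``ci95`` is the t-based
    95% interval over per-repetition FPRs, and ``one_sample_t_vs_alpha``
    tests the per-repetition FPRs against the nominal level (two-tailed).
    """
    config = config or TestConfig()
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    for r in ratios:
        if not 0 < r < 1:
            raise ValueError(f"ratio {r} outside (0, 1)")
    unknown = set(methods) - set(VALIDITY_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    data_seq, label_seq, test_seq = ss.spawn(3)
    if datasets is None:
        noise = noise or NoiseModel.equicorrelated()
        datasets = generate_null_epochs(
            noise, n_subjects=n_subjects, trials_per_subject=trials_per_subject,
            seed=data_seq,
        )
    datasets = list(datasets)
    label_rng = np.random.default_rng(label_seq)
    rejects = {(m, r): [] for m in methods for r in ratios}
    pvals = {(m, r): [] for m in methods for r in ratios}
    for rep in range(n_repetitions):
        for ratio in ratios:
            relabeled = [
                ds.with_labels(split_labels(ds.n_trials, ratio, rng=label_rng))
                for ds in datasets
            ]
            if "unbalanced" in methods:
                cfg = replace(config, seed=_child_seed(test_seq.spawn(1)[0]))
                res = unbalanced_paired_permutation_test(relabeled, cfg)
                rejects[("unbalanced", ratio)].append(res.reject())
                pvals[("unbalanced", ratio)].append(res.p_values)
            if "conventional_permutation" in methods or "paired_t" in methods:
                gfp_a, gfp_b = subject_condition_gfps(relabeled)
                if "conventional_permutation" in methods:
                    cfg = replace(config, seed=_child_seed(test_seq.spawn(1)[0]))
                    res = conventional_paired_permutation_test(gfp_a, gfp_b, cfg)
                    rejects[("conventional_permutation", ratio)].append(res.reject())
                    pvals[("conventional_permutation", ratio)].append(res.p_values)
                if "paired_t" in methods:
                    res = paired_t_test(gfp_a, gfp_b)
                    rejects[("paired_t", ratio)].append(res.reject(config.alpha))
                    pvals[("paired_t", ratio)].append(res.p_values)
    rows = []
    per_rep_fpr = {}
    pooled_p = {}
    for (m, r), masks in rejects.items():
        masks = np.array(masks)  # (reps, S)
        rep_fpr = masks.mean(axis=1)
        per_rep_fpr[(m, r)] = rep_fpr
        pooled_p[(m, r)] = np.concatenate(pvals[(m, r)])
        fpr = float(masks.mean())
        n = rep_fpr.size
        if n > 1 and rep_fpr.std(ddof=1) > 0:
            sem = rep_fpr.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            ci = (fpr - tcrit * sem, fpr + tcrit * sem)
            tstat, tp = stats.ttest_1samp(rep_fpr, config.alpha)
        else:
            ci = (fpr, fpr)
            tstat, tp = np.nan, np.nan
        rows.append(
            {
                "method": m,
                "ratio": r,
                "n_repetitions": n,
                "fpr": fpr,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "t_vs_alpha": float(tstat),
                "df": n - 1,
                "p_vs_alpha": float(tp),
            }
        )
    table = pd.DataFrame(rows).sort_values(["method", "ratio"]).reset_index(drop=True)
    return ValidityReport(
        table=table,
        alpha=config.alpha,
        n_repetitions=n_repetitions,
        p_values=pooled_p,
        per_rep_fpr=per_rep_fpr,
        seed=seed,
    )


@dataclass
class SigmoidFit:
    """Two-parameter logistic power curve P(reject | snr) =
    1 / (1 + exp(-(intercept + slope * snr)))."""

    intercept: float
    slope: float
    snr_at_half: float
    extrapolated: bool
    identifiable: bool

    @property
    def params(self) -> tuple[float, float]:
        return (self.intercept, self.slope)


def fit_sensitivity_sigmoid(
    snr: np.ndarray, tpr: np.ndarray, n_per_point: int
) -> SigmoidFit:
    """Binomial-MLE logistic fit of the power curve; ``snr_at_half`` is
    -intercept/slope (flagged extrapolated when outside the swept SNR
    range, non-identifiable under complete separation / degeneracy)."""
    import statsmodels.api as sm

    snr = np.asarray(snr, dtype=np.float64)
    tpr = np.asarray(tpr, dtype=np.float64)
    if np.unique(snr).size < 3:
        raise GfppermError("need at least 3 distinct SNR values")
    successes = np.rint(tpr * n_per_point)
    if np.all(successes == 0) or np.all(successes == n_per_point) or np.all(
        np.isin(successes, [0, n_per_point])
    ):
        return SigmoidFit(np.nan, np.nan, np.nan, False, False)
    endog = np.column_stack([successes, n_per_point - successes])
    exog = sm.add_constant(snr)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
        intercept, slope = fit.params
    except Exception:
        return SigmoidFit(np.nan, np.nan, np.nan, False, False)
    if not np.all(np.isfinite([intercept, slope])) or abs(slope) > 1e6:
        return SigmoidFit(np.nan, np.nan, np.nan, False, False)
    snr_half = -intercept / slope if slope != 0 else np.nan
    extrapolated = not (snr.min() <= snr_half <= snr.max())
    return SigmoidFit(float(intercept), float(slope), float(snr_half), extrapolated, True)


@dataclass
class SensitivityReport:
    """True-positive-rate table per (ratio, effect RMS) with the
    realised SNR, plus per-ratio logistic fits and SNR-at-.5."""

    table: pd.DataFrame
    fits: dict
    alpha: float
    n_repetitions: int
    seed: Optional[int] = None

    def tpr(self, ratio: float, effect_rms: float) -> float:
        t = self.table
        row = t[np.isclose(t["ratio"], ratio) & np.isclose(t["effect_rms"], effect_rms)]
        if row.empty:
            raise KeyError((ratio, effect_rms))
        return float(row["tpr"].iloc[0])

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def plot(self, ax=None):
        """Power curves (TPR vs SNR) per imbalance ratio with fitted
        logistics where identifiable."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for ratio, grp in self.table.groupby("ratio"):
            grp = grp.sort_values("snr")
            (line,) = ax.plot(grp["snr"], grp["tpr"], "o", label=f"ratio {ratio:.3g}")
            fit = self.fits.get(float(ratio))
            if fit is not None and fit.identifiable:
                xs = np.linspace(grp["snr"].min(), grp["snr"].max(), 200)
                ys = 1.0 / (1.0 + np.exp(-(fit.intercept + fit.slope * xs)))
                ax.plot(xs, ys, color=line.get_color(), lw=1)
        ax.set_xlabel("SNR")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def run_sensitivity_experiment(
    effect_rms_levels: Sequence[float] = DEFAULT_EFFECT_SWEEP,
    ratios: Sequence[float] = DEFAULT_SENSITIVITY_RATIOS,
    n_condition_a: int = 30,
    n_repetitions: int = 100,
    config: Optional[TestConfig] = None,
    noise: Optional[NoiseModel] = None,
    n_subjects: int = 13,
    trials_per_subject: int = 178,
    effect: Optional[EffectSpec] = None,
    seed=None,
    datasets: Optional[Sequence[EpochedDataset]] = None,
) -> SensitivityReport:
    """Power simulation with a known injected effect.

    Condition A is fixed at ``n_condition_a`` trials; Condition B is
    sized so A makes up each ``ratio`` of the experiment.  The
    polarity-split offset is added to the A trials at each RMS level of
    the sweep and the unbalanced test is run.  TPR is the proportion of
    per-timepoint tests rejecting at ``config.alpha``, pooled over the
    effect-window timepoints and repetitions (the same pooling as the
    validity experiment's FPR, so TPR falls back to alpha at zero
    effect; rejections outside the window are not counted).  SNR is the
    effect RMS over the pooled residual noise RMS of the original
    (effect-free) epochs.
    """
    config = config or TestConfig()
    if n_condition_a < 2:
        raise ValueError("n_condition_a must be >= 2")
    effect = effect or EffectSpec(rms_amplitude=0.0)
    ss = np.random.SeedSequence(seed)
    data_seq, pick_seq, test_seq = ss.spawn(3)
    if datasets is None:
        noise = noise or NoiseModel.equicorrelated()
        datasets = generate_null_epochs(
            noise, n_subjects=n_subjects, trials_per_subject=trials_per_subject,
            seed=data_seq,
        )
    datasets = list(datasets)
    times = datasets[0].times
    window = effect.window_mask(times)
    noise_rms = pooled_noise_rms(datasets)
    pick_rng = np.random.default_rng(pick_seq)
    totals = {}
    for ratio in ratios:
        k_total = int(np.rint(n_condition_a / ratio))
        k_b = k_total - n_condition_a
        if k_b < 1:
            raise GfppermError(f"ratio {ratio} leaves no Condition B trials")
        short = [ds for ds in datasets if ds.n_trials < k_total]
        if short:
            raise GfppermError(
                f"ratio {ratio} needs {k_total} trials/subject; "
                f"{len(short)} subject(s) have fewer"
            )
        totals[ratio] = k_total
    hits = {(r, a): 0 for r in ratios for a in effect_rms_levels}
    for rep in range(n_repetitions):
        for ratio in ratios:
            k_total = totals[ratio]
            subset = []
            for ds in datasets:
                idx = pick_rng.choice(ds.n_trials, size=k_total, replace=False)
                labels = np.full(k_total, "B", dtype="U1")
                labels[:n_condition_a] = "A"  # idx already random; first 30 are A
                subset.append(
                    EpochedDataset(
                        subject_id=ds.subject_id,
                        data=ds.data[:, :, idx],
                        labels=labels,
                        times=ds.times,
                        channel_names=ds.channel_names,
                        sampling_rate=ds.sampling_rate,
                    )
                )
            for amp in effect_rms_levels:
                spec = replace(effect, rms_amplitude=amp)
                with_effect = [add_offset_effect(ds, "A", spec) for ds in subset]
                cfg = replace(config, seed=_child_seed(test_seq.spawn(1)[0]))
                res = unbalanced_paired_permutation_test(with_effect, cfg)
                hits[(ratio, amp)] += float(res.reject()[window].mean())
    rows = []
    for (ratio, amp), h in hits.items():
        pattern = replace(effect, rms_amplitude=amp).pattern(
            datasets[0].n_channels, times
        )[:, window]
        snr = float(np.sqrt(np.mean(pattern**2)) / noise_rms)
        rows.append(
            {
                "ratio": ratio,
                "effect_rms": amp,
                "snr": snr,
                "tpr": h / n_repetitions,
                "n_repetitions": n_repetitions,
            }
        )
    table = pd.DataFrame(rows).sort_values(["ratio", "effect_rms"]).reset_index(drop=True)
    fits = {}
    for ratio in ratios:
        grp = table[np.isclose(table["ratio"], ratio)]
        if np.unique(grp["snr"]).size < 3:
            fits[float(ratio)] = SigmoidFit(np.nan, np.nan, np.nan, False, False)
        else:
            fits[float(ratio)] = fit_sensitivity_sigmoid(
                grp["snr"].to_numpy(), grp["tpr"].to_numpy(), n_repetitions
            )
    return SensitivityReport(
        table=table, fits=fits, alpha=config.alpha, n_repetitions=n_repetitions, seed=seed
    )
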