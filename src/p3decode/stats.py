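"""Amplitude measurement and hypothesis testing.

ROI averaging, per-trial window means, subject-baselined condition contrasts
(Welch one-tailed t-test), trial-downselection power curves run on identical
selected trials for the amplitude- and decoder-based tests, reaction-time
tertiles, lognormal latency mode, and latency splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import constants as C
from .preprocess import EpochSet

__all__ = [
    "RoiTraces", "ContrastResult", "PowerCurve",
    "roi_average", "window_mean", "baselined_values", "amplitude_contrast",
    "decode_contrast", "downselect_power_curve", "rt_tertiles",
    "lognormal_mode", "latency_split",
]


@dataclass
class RoiTraces:
    """Per-trial ROI-averaged time series (n_trials, n_times)."""

    values: np.ndarray
    times_s: np.ndarray
    meta: pd.DataFrame

    def evoked(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class ContrastResult:
    """One-tailed Welch t-test between per-subject-baselined condition values."""

    condition_a: str
    condition_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    t: float
    p: float
    n_a: int
    n_b: int
    alternative: str = "greater"


@dataclass
class PowerCurve:
    records: pd.DataFrame  # columns: fraction, method, rep, p
    summary: pd.DataFrame  # columns: fraction, method, mean_p, median_p, n_reps
    n_reps: int
    skipped_fractions: list = field(default_factory=list)


def roi_average(epochs: EpochSet, roi: Sequence[str] = C.ROI_CHANNELS) -> RoiTraces:
    """Unweighted mean over the parietal ROI channels, per trial."""
    missing = [ch for ch in roi if ch not in epochs.channel_names]
    if missing:
        raise ValueError(f"missing ROI channels: {missing}")
    idx = [epochs.channel_names.index(ch) for ch in roi]
    return RoiTraces(
        values=epochs.data[:, idx, :].mean(axis=1),
        times_s=epochs.times_s,
        meta=epochs.meta,
    )


def window_mean(
    values: np.ndarray,
    times_s: np.ndarray,
    window: tuple[float, float] = C.AMPLITUDE_WINDOW_S,
) -> np.ndarray:
    """Mean over samples with time in [window[0], window[1]], inclusive both ends."""
    times_s = np.asarray(times_s)
    if window[0] < times_s[0] or window[1] > times_s[-1]:
        raise ValueError(f"window {window} outside trace grid [{times_s[0]}, {times_s[-1]}]")
    sel = (times_s >= window[0]) & (times_s <= window[1])
    values = np.asarray(values)
    return values[..., sel].mean(axis=-1)


def baselined_values(
    target_df: pd.DataFrame,
    background_df: pd.DataFrame,
    value_col: str,
) -> pd.DataFrame:
    """Subtract, per subject, the mean background value from each target value."""
    bg_means = background_df.groupby("subject")[value_col].mean()
    missing = set(target_df["subject"]) - set(bg_means.index)
    if missing:
        raise ValueError(f"subjects lacking background trials: {sorted(missing)}")
    out = target_df.copy()
    out[value_col] = out[value_col] - out["subject"].map(bg_means)
    return out


def _contrast(
    target_df: pd.DataFrame,
    background_df: pd.DataFrame,
    value_col: str,
    condition_a: str,
    condition_b: str,
    alternative: str = "greater",
) -> ContrastResult:
    baselined = baselined_values(target_df, background_df, value_col)
    a = baselined.loc[baselined["condition"] == condition_a, value_col].to_numpy()
    b = baselined.loc[baselined["condition"] == condition_b, value_col].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty condition group: {condition_a if not len(a) else condition_b}")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return ContrastResult(
        condition_a=condition_a, condition_b=condition_b,
        values_a=a, values_b=b,
        t=float(res.statistic), p=float(res.pvalue),
        n_a=len(a), n_b=len(b), alternative=alternative,
    )


def amplitude_contrast(
    target_df: pd.DataFrame,
    background_df: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    value_col: str = "amp",
    alternative: str = "greater",
) -> ContrastResult:
    """Contrast of per-trial ROI window means, baselined per subject."""
    return _contrast(target_df, background_df, value_col, condition_a, condition_b, alternative)


def decode_contrast(
    target_df: pd.DataFrame,
    background_df: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    value_col: str = "prob",
    alternative: str = "greater",
) -> ContrastResult:
    """Same contrast with the CNN output at T = 0 as the per-trial value."""
    return _contrast(target_df, background_df, value_col, condition_a, condition_b, alternative)


def downselect_power_curve(
    target_df: pd.DataFrame,
    background_df: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    fractions: Sequence[float],
    n_reps: int = C.N_POWER_REPETITIONS,
    seed: int = 0,
    methods: dict[str, str] | None = None,
    alternative: str = "greater",
) -> PowerCurve:
    """p-value vs trial fraction, both test methods run on identical selections.

    Per repetition, target trials are sampled without replacement per subject
    (and per condition); the amplitude and decoder tests then both use exactly
    those trials. Fractions leaving fewer than 2 trials for some
    subject x condition cell are skipped with a warning.
    """
    methods = methods or {"amplitude": "amp", "decode": "prob"}
    bad = [f for f in fractions if not 0 < f <= 1]
    if bad:
        raise ValueError(f"fractions must be in (0, 1], got {bad}")
    rng = np.random.default_rng(seed)
    groups = list(target_df.groupby(["subject", "condition"]).groups.items())
    records = []
    skipped = []
    for frac in fractions:
        counts = {key: max(int(round(frac * len(idx))), 0) for key, idx in groups}
        if any(c < 2 for c in counts.values()):
            warnings.warn(f"fraction {frac} leaves <2 trials in some subject/condition cell; skipped")
            skipped.append(frac)
            continue
        for rep in range(n_reps):
            take = []
            for key, idx in groups:
                idx = np.asarray(idx)
                k = counts[key]
                if k >= len(idx):
                    take.append(idx)
                else:
                    take.append(rng.choice(idx, size=k, replace=False))
            sel = target_df.loc[np.concatenate(take)]
            for method, col in methods.items():
                res = _contrast(sel, background_df, col, condition_a, condition_b, alternative)
                records.append(dict(fraction=frac, method=method, rep=rep, p=res.p))
    rec_df = pd.DataFrame(records, columns=["fraction", "method", "rep", "p"])
    if len(rec_df):
        summary = (
            rec_df.groupby(["fraction", "method"])["p"]
            .agg(mean_p="mean", median_p="median", n_reps="count")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["fraction", "method", "mean_p", "median_p", "n_reps"])
    return PowerCurve(records=rec_df, summary=summary, n_reps=n_reps, skipped_fractions=skipped)


def rt_tertiles(rts: np.ndarray) -> tuple[list[np.ndarray], tuple[float, float]]:
    """Fast/medium/slow groups cut at the 33rd and 66th percentiles.

    Percentiles use linear interpolation between order statistics. Returns
    (list of index arrays, (q33, q66)).
    """
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 3:
        raise ValueError("need at least 3 reaction times")
    if not np.isfinite(rts).all():
        raise ValueError("non-finite reaction times")
    q33, q66 = np.percentile(rts, C.RT_PERCENTILE_CUTS)
    if q33 == q66:
        warnings.warn("degenerate RT cutoffs (ties); all trials fall in one group")
    idx = np.arange(len(rts))
    groups = [idx[rts < q33], idx[(rts >= q33) & (rts < q66)], idx[rts >= q66]]
    return groups, (float(q33), float(q66))


def lognormal_mode(latencies: np.ndarray) -> float:
    """Mode exp(mu - sigma^2) of the maximum-likelihood lognormal fit."""
    lat = np.asarray(latencies, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(lat <= 0):
        raise ValueError("latencies must be finite and positive")
    logs = np.log(lat)
    mu = logs.mean()
    sigma2 = logs.var()
    return float(np.exp(mu - sigma2))


def latency_split(
    latencies: np.ndarray,
    threshold_s: float = C.FIXATION_SPLIT_THRESHOLD_S,
) -> dict[str, np.ndarray]:
    """Strict-less-than split: short = latency < threshold, long = >= threshold."""
    lat = np.asarray(latencies, dtype=float)
    if np.any(~np.isfinite(lat)):
        raise ValueError("missing or non-finite latencies")
    idx = np.arange(len(lat))
    short = idx[lat < threshold_s]
    long_ = idx[lat >= threshold_s]
    if len(short) == 0 or len(long_) == 0:
        warnings.warn(
            f"latency split at {threshold_s} s left an empty group "
            f"(short={len(short)}, long={len(long_)})"
        )
    return {"short": short, "long": long_}
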