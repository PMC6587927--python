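"""Synthetic multi-experiment EEG databases with a controllable parietal component.

Each database emulates one experiment: per-subject continuous recordings built
from 1/f background noise, a ~10 Hz oscillation, white noise, and a Gaussian
positive deflection with a parietal-maximal topography inserted at target and
distractor events. Per-trial ground truth (true amplitude, true latency) is
kept alongside the event table so downstream estimators can be validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import constants as C
from .montage import MontageSpec, standard_montage
from .preprocess import EventTable, Recording

LOCKINGS = ("stimulus", "fixation")


@dataclass(frozen=True)
class ErpTemplate:
    """Gaussian-bump evoked component with a spatial-Gaussian topography."""

    peak_latency_s: float
    width_s: float  # Gaussian sigma, seconds
    amplitude: float
    topography: np.ndarray  # (64,) channel gains, max 1
    jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width_s must be > 0")
        if self.jitter_sd_s < 0:
            raise ValueError("jitter_sd_s must be >= 0")

    def waveform(self, times_s: np.ndarray, peak_s: float | None = None, amplitude: float | None = None) -> np.ndarray:
        peak = self.peak_latency_s if peak_s is None else peak_s
        amp = self.amplitude if amplitude is None else amplitude
        return amp * np.exp(-0.5 * ((np.asarray(times_s) - peak) / self.width_s) ** 2)


@dataclass(frozen=True)
class TtiModel:
    """Saturating amplitude-vs-target-interval rule ``A(tti) = 1 - exp(-tti/tau)``.

    With the default ``tau_s`` the amplitude is near-asymptotic by 6-8 s.
    """

    tau_s: float = C.TTI_TAU_S

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")

    def amplitude_factor(self, tti_s: float) -> float:
        if not tti_s > 0:
            raise ValueError("tti must be positive")
        return 1.0 - math.exp(-tti_s / self.tau_s)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: amplitude/latency modulation and class mix."""

    name: str
    amplitude_scale: float = 1.0
    latency_shift_s: float = 0.0
    jitter_sd_s: float | None = None  # None -> template default
    class_ratio: tuple[float, float, float] = (1.0, 1.0, 12.0)  # target:distractor:background
    locking: str = "stimulus"
    tti_model: TtiModel | None = None
    tti_s: float | None = None  # nominal TTI fed to tti_model; None -> scheduled interval
    distractor_scale: float = 0.6
    fixation_cue_threshold_s: float = C.FIXATION_SPLIT_THRESHOLD_S
    fixation_latency_lognorm: tuple[float, float] = (-1.3567, 0.4)

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")
        if any(p < 0 for p in self.class_ratio) or sum(self.class_ratio) <= 0:
            raise ValueError("class_ratio proportions must be non-negative with positive sum")
        if self.locking not in LOCKINGS:
            raise ValueError(f"locking must be one of {LOCKINGS}")


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f noise + narrowband oscillation + white noise."""

    pink_exponent: float = C.NOISE_PINK_EXPONENT
    pink_sd: float = 0.3
    osc_freq_hz: float = C.NOISE_OSC_FREQ_HZ
    osc_amp: float = 0.2
    white_sd: float = 0.2


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    n_subjects: int
    n_trials_per_subject: int
    conditions: tuple[ConditionSpec, ...]
    seed: int
    sample_rate_hz: float = 128.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    isi_s: float = 1.25
    edge_pad_s: float = 4.0
    duration_s: float | None = None  # None -> derived from the schedule

    def __post_init__(self) -> None:
        if self.sample_rate_hz < 128:
            raise ValueError("sample_rate_hz must be >= 128")
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition required")


@dataclass
class SimulatedDatabase:
    """One experiment's recordings, events and per-trial ground truth."""

    experiment_id: str
    recordings: dict[str, Recording]  # keyed by subject
    events: EventTable
    ground_truth: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.ground_truth) != len(self.events):
            raise ValueError("ground truth must align one-to-one with events")


def make_template(
    peak_latency_s: float = 0.45,
    width_s: float = 0.08,
    amplitude: float = 1.0,
    montage: MontageSpec | None = None,
    roi_center: str = "Pz",
    jitter_sd_s: float = 0.0,
    spatial_sigma: float = 0.35,
) -> ErpTemplate:
    """Build the simulated component: Gaussian in time, spatial Gaussian topography.

    The topography is centred on ``roi_center`` and normalized to max gain 1.
    """
    montage = montage or standard_montage()
    center = montage.positions[montage.index(roi_center)]
    d2 = np.sum((montage.positions - center) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * spatial_sigma**2))
    topo = topo / topo.max()
    return ErpTemplate(
        peak_latency_s=peak_latency_s,
        width_s=width_s,
        amplitude=amplitude,
        topography=topo,
        jitter_sd_s=jitter_sd_s,
    )


def _label_sequence(n: int, ratio: tuple[float, float, float], rng: np.random.Generator) -> list[str]:
    """Deterministic counts honouring the ratio, then a seeded shuffle."""
    total = sum(ratio)
    exact = [n * p / total for p in ratio]
    counts = [int(math.floor(e)) for e in exact]
    # distribute the remainder by largest fractional part
    order = np.argsort([c - e for c, e in zip(counts, exact)])
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    labels = (["target"] * counts[0] + ["distractor"] * counts[1] + ["background"] * counts[2])
    return [labels[i] for i in rng.permutation(n)]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float, exponent: float, sd: float) -> np.ndarray:
    """Per-channel noise with PSD ~ 1/f**exponent, scaled to the requested sd."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n, axis=1)
    scale = shaped.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def _oscillation(rng: np.random.Generator, shape: tuple[int, int], fs: float, freq: float, amp: float) -> np.ndarray:
    """Narrowband noise around ``freq``: a sinusoid whose phase drifts randomly."""
    sos = signal.butter(4, [max(freq - 2.0, 0.5), freq + 2.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(shape), axis=1)
    scale = x.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return x / scale * amp


def simulate_experiment(
    spec: ExperimentSpec,
    template: ErpTemplate | None = None,
    montage: MontageSpec | None = None,
) -> SimulatedDatabase:
    """Generate one experiment's database; identical seeds give identical output."""
    montage = montage or standard_montage()
    template = template if template is not None else make_template(montage=montage)
    fs = spec.sample_rate_hz

    n_cond = len(spec.conditions)
    per_cond = [spec.n_trials_per_subject // n_cond] * n_cond
    for i in range(spec.n_trials_per_subject % n_cond):
        per_cond[i] += 1

    needed_s = 2 * spec.edge_pad_s + spec.n_trials_per_subject * spec.isi_s
    duration_s = spec.duration_s if spec.duration_s is not None else needed_s
    if duration_s < needed_s:
        raise ValueError(
            f"trial schedule needs {needed_s:.1f} s but duration_s={duration_s:.1f} s"
        )
    n_samp = round(duration_s * fs)

    seed_seq = np.random.SeedSequence(spec.seed)
    subject_seeds = seed_seq.spawn(spec.n_subjects)

    recordings: dict[str, Recording] = {}
    event_rows: list[dict] = []
    truth_rows: list[dict] = []

    for si in range(spec.n_subjects):
        subject = f"{spec.experiment_id}-s{si + 1:02d}"
        rng = np.random.default_rng(subject_seeds[si])

        data = np.zeros((64, n_samp), dtype=np.float64)
        noise = spec.noise
        if noise.pink_sd > 0:
            data += _pink_noise(rng, data.shape, fs, noise.pink_exponent, noise.pink_sd)
        if noise.osc_amp > 0:
            data += _oscillation(rng, data.shape, fs, noise.osc_freq_hz, noise.osc_amp)
        if noise.white_sd > 0:
            data += noise.white_sd * rng.standard_normal(data.shape)

        trial_i = 0
        for cond, n_trials in zip(spec.conditions, per_cond):
            labels = _label_sequence(n_trials, cond.class_ratio, rng)
            jitter_sd = template.jitter_sd_s if cond.jitter_sd_s is None else cond.jitter_sd_s
            last_target_onset: float | None = None
            for lab in labels:
                onset = spec.edge_pad_s + trial_i * spec.isi_s
                trial_i += 1
                rt = np.nan
                fix_lat = np.nan
                true_amp = 0.0
                true_lat = np.nan
                if lab in ("target", "distractor"):
                    amp = template.amplitude * cond.amplitude_scale
                    if lab == "distractor":
                        amp *= cond.distractor_scale
                    if cond.tti_model is not None and lab == "target":
                        tti = cond.tti_s
                        if tti is None:
                            tti = math.inf if last_target_onset is None else onset - last_target_onset
                        amp *= cond.tti_model.amplitude_factor(tti) if math.isfinite(tti) else 1.0
                    latency = template.peak_latency_s + cond.latency_shift_s
                    if jitter_sd > 0:
                        latency += rng.normal(0.0, jitter_sd)
                    if cond.locking == "fixation":
                        mu, sigma = cond.fixation_latency_lognorm
                        fix_lat = float(rng.lognormal(mu, sigma))
                        if fix_lat >= cond.fixation_cue_threshold_s:
                            # peripherally cued: component is stimulus-locked, and the
                            # stimulus happened fix_lat seconds before this fixation
                            peak_rel = latency - fix_lat
                        else:
                            peak_rel = latency  # top-down: fixation-locked
                    else:
                        peak_rel = latency
                    if lab == "target":
                        rt = latency + float(rng.lognormal(C.RT_RESIDUAL_MU, C.RT_RESIDUAL_SIGMA))
                        last_target_onset = onset
                    # insert the bump over +-6 sigma: the truncated tail
                    # (< 1.6e-8 of the amplitude) is below float32 resolution
                    lo = max(0, round((onset + peak_rel - 6 * template.width_s) * fs))
                    hi = min(n_samp, round((onset + peak_rel + 6 * template.width_s) * fs) + 1)
                    if lo < hi and amp != 0.0:
                        t_abs = np.arange(lo, hi) / fs
                        bump = template.waveform(t_abs - onset, peak_s=peak_rel, amplitude=amp)
                        data[:, lo:hi] += template.topography[:, None] * bump[None, :]
                    true_amp = amp
                    true_lat = peak_rel
                event_rows.append(
                    dict(
                        onset_s=onset, label=lab, subject=subject,
                        experiment=spec.experiment_id, condition=cond.name,
                        rt_s=rt, fixation_latency_s=fix_lat, locking=cond.locking,
                    )
                )
                truth_rows.append(
                    dict(
                        subject=subject, experiment=spec.experiment_id,
                        condition=cond.name, onset_s=onset, label=lab,
                        true_amplitude=true_amp, true_latency_s=true_lat,
                    )
                )
        recordings[subject] = Recording(
            data=data.astype(np.float32),
            sample_rate_hz=fs,
            channel_names=montage.channel_names,
            subject=subject,
            experiment=spec.experiment_id,
        )

    events = EventTable(pd.DataFrame(event_rows))
    truth = pd.DataFrame(truth_rows)
    return SimulatedDatabase(spec.experiment_id, recordings, events, truth)


def simulate_database(
    specs: Sequence[ExperimentSpec],
    template: ErpTemplate | None = None,
    montage: MontageSpec | None = None,
) -> list[SimulatedDatabase]:
    """Simulate several experiments with independent per-experiment seed streams."""
    ids = [s.experiment_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate experiment_id: {dupes}")
    return [simulate_experiment(s, template=template, montage=montage) for s in specs]
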