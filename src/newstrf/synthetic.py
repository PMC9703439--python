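"""Synthetic cohorts of word-onset-locked EEG, ratings and labels.

The generator emulates the study design the analysis assumes: two groups
(depressed / non-depressed by BDI-II >= 14), 15 news trials per subject
(5 negative / 5 neutral / 5 positive, 45-83 s each), three channels
(Fpz, Cz, Pz), and EEG that is a superposition of Gaussian component
kernels (N1, P2, N400) placed at content-word onsets plus 1/f background
noise.  Group x news effects are injected as latency shifts and amplitude
gains on the kernels and as mean shifts on the 1-5 subjective ratings;
``effect_scale`` multiplies every injected effect (0 = exact null cohort).

Ground truth (injected per-subject kernel parameters and configured
population means) is serialized alongside the cohort and is never read by
any analysis stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    CHANNELS,
    CONDITIONS,
    CohortDataset,
    TrialRecording,
    write_cohort,
)

COMPONENTS = ("N1", "P2", "N400")

#: relative kernel gain per channel: N1/P2 dominate frontally (Fpz), N400
#: parietally (Pz); Cz carries everything (auditory ERP topography)
CHANNEL_GAINS = {
    "Fpz": {"N1": 1.0, "P2": 1.0, "N400": 0.3},
    "Cz": {"N1": 0.7, "P2": 0.7, "N400": 0.7},
    "Pz": {"N1": 0.5, "P2": 0.4, "N400": 1.0},
}

#: baseline kernel parameters (peak ms, amplitude uV, FWHM ms); amplitudes
#: are ERP-scale microvolts so noise levels and ridge penalties behave like
#: real recordings
BASE_KERNELS = {
    "N1": {"polarity": "negative", "peak_latency_ms": 130.0, "amplitude": -5.0, "width_ms": 40.0},
    "P2": {"polarity": "positive", "peak_latency_ms": 200.0, "amplitude": 5.0, "width_ms": 50.0},
    "N400": {"polarity": "negative", "peak_latency_ms": 420.0, "amplitude": -6.0, "width_ms": 180.0},
}

#: latent rating means per condition (preliminary-survey profile of the
#: news set: valence orders pos > neu > neg; arousal neg ~ pos > neu)
RATING_MEANS = {
    "valence": {"negative": 1.8, "neutral": 3.2, "positive": 3.9},
    "arousal": {"negative": 3.1, "neutral": 2.8, "positive": 3.0},
    "interest": {"negative": 3.1, "neutral": 2.7, "positive": 2.8},
    "comprehensibility": {"negative": 3.7, "neutral": 3.4, "positive": 3.9},
}
RATING_LATENT_SD = 0.7
RATING_SUBJECT_SD = 0.3

#: between-subject variability of the injected kernels
SUBJECT_LATENCY_SD_MS = 8.0
SUBJECT_AMP_LOG_SD = 0.1


class InvalidSpecError(ValueError):
    """A kernel or cohort specification violates its invariants."""


@dataclass
class CohortConfig:
    """Shape and noise of a synthetic cohort (defaults = study conditions)."""

    n_depressed: int = 32
    n_nondepressed: int = 103
    n_trials_per_condition: int = 5
    trial_duration_s: tuple = (45.0, 83.0)
    fs_hz: float = 500.0
    word_rate_hz: float = 2.5
    snr_db: float = -10.0
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_depressed <= 0 or self.n_nondepressed <= 0:
            raise InvalidSpecError("subject counts must be positive")
        if self.n_trials_per_condition <= 0:
            raise InvalidSpecError("n_trials_per_condition must be positive")
        if self.fs_hz < 200:
            raise InvalidSpecError("fs_hz must be >= 200")
        if self.effect_scale < 0:
            raise InvalidSpecError("effect_scale must be >= 0")
        lo, hi = self.trial_duration_s
        if not 0 < lo <= hi:
            raise InvalidSpecError("trial_duration_s range must be positive and ordered")


@dataclass
class ComponentKernelSpec:
    name: str
    polarity: str
    peak_latency_ms: float
    amplitude: float
    width_ms: float

    def __post_init__(self):
        if self.name not in COMPONENTS:
            raise InvalidSpecError(f"unknown component {self.name!r}")
        if self.polarity not in ("negative", "positive"):
            raise InvalidSpecError(f"polarity must be negative/positive, got {self.polarity!r}")
        if not 0.0 <= self.peak_latency_ms <= 800.0:
            raise InvalidSpecError("peak latency must lie in [0, 800] ms")
        if self.width_ms <= 0:
            raise InvalidSpecError("kernel width must be positive")
        if self.amplitude != 0.0:
            sign_ok = (self.amplitude < 0) == (self.polarity == "negative")
            if not sign_ok:
                raise InvalidSpecError(
                    f"amplitude sign {np.sign(self.amplitude):+.0f} does not match "
                    f"polarity {self.polarity!r}"
                )


@dataclass
class EffectPlan:
    """Injected group x news effects (all scaled by CohortConfig.effect_scale).

    Latency shifts are additive in ms; amplitude gains are multiplicative
    (> 1 deepens the component); rating shifts are additive on the latent
    1-5 scale.
    """

    n1_latency_shift_positive_ms: float = 21.0
    p2_latency_shift_positive_ms: float = 27.0
    n400_latency_negative_vs_positive_ms: float = -33.3
    n400_amp_gain_negative_depressed: float = 1.4
    n1_amp_gain_nondepressed: float = 1.3
    arousal_shift_depressed: float = -0.3
    comprehensibility_shift_depressed: float = -0.4


def kernel_population_params(group: str, condition: str, component: str,
                             plan: EffectPlan, effect_scale: float) -> dict:
    """Configured (noise-free) kernel parameters for one group x condition cell."""
    base = BASE_KERNELS[component]
    peak = base["peak_latency_ms"]
    amp = base["amplitude"]
    s = effect_scale
    if component == "N1":
        if group == "depressed" and condition == "positive":
            peak += s * plan.n1_latency_shift_positive_ms
        if group == "non-depressed":
            amp *= 1.0 + s * (plan.n1_amp_gain_nondepressed - 1.0)
    elif component == "P2":
        if group == "depressed" and condition == "positive":
            peak += s * plan.p2_latency_shift_positive_ms
    elif component == "N400":
        if condition == "negative":
            peak += s * plan.n400_latency_negative_vs_positive_ms
            if group == "depressed":
                amp *= 1.0 + s * (plan.n400_amp_gain_negative_depressed - 1.0)
    return {"peak_latency_ms": peak, "amplitude": amp, "width_ms": base["width_ms"],
            "polarity": base["polarity"]}


def generate_word_onsets(duration_s: float, word_rate_hz: float, rng) -> np.ndarray:
    """Draw content-word onset times for one news item.

    A jittered renewal process: inter-onset gaps are 150 ms plus an
    exponential tail whose mean keeps the overall gap mean at
    1/word_rate_hz, so the expected count is ~ duration * rate.  Onsets are
    confined to [0.5 s, duration - 1.0 s] so every word's full 800 ms
    response fits inside the trial.
    """
    if duration_s <= 0 or word_rate_hz <= 0:
        raise ValueError("duration_s and word_rate_hz must be positive")
    floor = 0.150
    lo, hi = 0.5, duration_s - 1.0
    if hi <= lo:
        warnings.warn(f"trial of {duration_s:g} s leaves no room for onsets", stacklevel=2)
        return np.empty(0)
    mean_gap = 1.0 / word_rate_hz
    tail = max(mean_gap - floor, 1e-3)
    onsets = []
    t = lo + floor + rng.exponential(tail)
    while t <= hi:
        onsets.append(t)
        t += floor + rng.exponential(tail)
    return np.asarray(onsets)


def component_kernel(spec: ComponentKernelSpec, fs_hz: float) -> np.ndarray:
    """Sample a Gaussian component kernel on the 0..800 ms lag grid at fs_hz."""
    if fs_hz < 200:
        raise InvalidSpecError("fs_hz must be >= 200")
    t_ms = np.arange(int(round(0.8 * fs_hz)) + 1) * (1000.0 / fs_hz)
    sigma = spec.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return spec.amplitude * np.exp(-0.5 * ((t_ms - spec.peak_latency_ms) / sigma) ** 2)


def pink_noise(n_samples: int, fs_hz: float, rng,
               band=(1.0, 50.0)) -> np.ndarray:
    """1/f-power noise band-limited to ``band`` (EEG-like background)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shaping = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    shaping[inband] = 1.0 / np.sqrt(freqs[inband])
    x = np.fft.irfft(spec * shaping, n=n_samples)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize_trial(onsets, kernels: dict, n_samples: int, fs_hz: float,
                     snr_db: float, rng) -> np.ndarray:
    """Superpose per-channel kernels at word onsets and add 1/f noise.

    ``kernels`` maps channel name -> sampled kernel (the channel-specific
    mixture of components).  Noise is scaled per channel so the ratio of
    kernel-train power to noise power matches ``snr_db`` exactly; channels
    with a silent kernel train get unit-RMS noise.
    """
    onsets = np.asarray(onsets, dtype=float)
    duration = n_samples / fs_hz
    bad = onsets[(onsets < 0) | (onsets >= duration)]
    if bad.size:
        raise ValueError(f"onset {bad[0]:g} s outside trial of {duration:g} s")
    impulse = np.zeros(n_samples)
    if onsets.size:
        impulse[np.round(onsets * fs_hz).astype(int)] = 1.0
    data = np.zeros((len(CHANNELS), n_samples))
    for i, ch in enumerate(CHANNELS):
        clean = np.convolve(impulse, kernels[ch])[:n_samples]
        p_sig = np.mean(clean ** 2)
        noise = pink_noise(n_samples, fs_hz, rng)
        if p_sig > 0:
            p_noise_target = p_sig / (10.0 ** (snr_db / 10.0))
            noise = noise * np.sqrt(p_noise_target)
        data[i] = clean + noise
    return data


def generate_ratings(group: str, condition: str, plan: EffectPlan,
                     effect_scale: float, rng, n: int = 1,
                     subject_offset: float = 0.0) -> pd.DataFrame:
    """Draw n trials' worth of 1-5 ratings for one subject x condition cell.

    Latent Gaussian means per (scale, condition) with depressed-group shifts
    on arousal and comprehensibility; rounded and clamped to {1..5}.
    """
    if group not in ("depressed", "non-depressed"):
        raise ValueError(f"unknown group {group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    out = {}
    for scale, means in RATING_MEANS.items():
        mu = means[condition] + subject_offset
        if group == "depressed":
            if scale == "arousal":
                mu += effect_scale * plan.arousal_shift_depressed
            elif scale == "comprehensibility":
                mu += effect_scale * plan.comprehensibility_shift_depressed
        latent = rng.normal(mu, RATING_LATENT_SD, size=n)
        out[scale] = np.clip(np.round(latent), 1, 5).astype(int)
    return pd.DataFrame(out)


def _subject_ids(config: CohortConfig):
    dep = [f"S{i:03d}" for i in range(1, config.n_depressed + 1)]
    nd = [f"S{i:03d}" for i in range(config.n_depressed + 1,
                                     config.n_depressed + config.n_nondepressed + 1)]
    return dep, nd


def generate_cohort(config: CohortConfig, plan: EffectPlan | None = None,
                    out_dir=None, overwrite: bool = False):
    """Generate a full labeled cohort and its ground-truth sidecar.

    Returns ``(CohortDataset, ground_truth dict)``; if ``out_dir`` is given
    the cohort is also written there via io_core (plus ground_truth.json).
    """
    plan = plan or EffectPlan()
    rng = np.random.default_rng(config.seed)
    dep_ids, nd_ids = _subject_ids(config)

    # shared stimulus side: one duration + onset list per news item
    news_ids, news_rows, onset_rows = [], [], []
    for cond in CONDITIONS:
        for k in range(1, config.n_trials_per_condition + 1):
            news_id = f"{cond[:3]}{k}"
            dur = float(rng.uniform(*config.trial_duration_s))
            news_ids.append((news_id, cond, dur))
            news_rows.append({"news_id": news_id, "condition": cond,
                              "duration_s": round(dur, 3)})
            for j, t in enumerate(generate_word_onsets(dur, config.word_rate_hz, rng)):
                onset_rows.append({"news_id": news_id, "onset_s": round(float(t), 4),
                                   "token": f"w{j:03d}"})
    news = pd.DataFrame(news_rows)
    onsets = pd.DataFrame(onset_rows)
    onset_by_news = {nid: onsets.loc[onsets["news_id"] == nid, "onset_s"].to_numpy()
                     for nid, _, _ in news_ids}

    population_means = {
        g: {c: {comp: kernel_population_params(g, c, comp, plan, config.effect_scale)
                for comp in COMPONENTS}
            for c in CONDITIONS}
        for g in ("depressed", "non-depressed")
    }

    subject_rows, rating_rows, trials = [], [], {}
    gt_subjects = {}
    for sid, group in [(s, "depressed") for s in dep_ids] + [(s, "non-depressed") for s in nd_ids]:
        if group == "depressed":
            bdi = int(np.clip(np.round(rng.normal(21.1, 8.6)), 14, 63))
        else:
            bdi = int(np.clip(np.round(rng.normal(6.6, 3.3)), 0, 13))
        subject_rows.append({"subject_id": sid, "group": group, "bdi_score": bdi})

        lat_jit = {comp: float(rng.normal(0.0, SUBJECT_LATENCY_SD_MS)) for comp in COMPONENTS}
        amp_gain = {comp: float(np.exp(rng.normal(0.0, SUBJECT_AMP_LOG_SD))) for comp in COMPONENTS}
        rating_offset = float(rng.normal(0.0, RATING_SUBJECT_SD))

        gt_cells = {}
        for cond in CONDITIONS:
            cell = {}
            for comp in COMPONENTS:
                pop = population_means[group][cond][comp]
                peak = float(np.clip(pop["peak_latency_ms"] + lat_jit[comp], 0.0, 800.0))
                amp = pop["amplitude"] * amp_gain[comp]
                cell[comp] = {"peak_latency_ms": peak, "amplitude": amp,
                              "width_ms": pop["width_ms"]}
            gt_cells[cond] = cell
        gt_subjects[sid] = {"group": group, "bdi_score": bdi, "components": gt_cells,
                            "rating_offset": rating_offset}

        # channel-specific kernel mixtures per condition
        mixtures = {}
        for cond in CONDITIONS:
            per_ch = {}
            for ch in CHANNELS:
                k = np.zeros(int(round(0.8 * config.fs_hz)) + 1)
                for comp in COMPONENTS:
                    p = gt_cells[cond][comp]
                    spec = ComponentKernelSpec(
                        name=comp, polarity=BASE_KERNELS[comp]["polarity"],
                        peak_latency_ms=p["peak_latency_ms"],
                        amplitude=p["amplitude"], width_ms=p["width_ms"])
                    k = k + CHANNEL_GAINS[ch][comp] * component_kernel(spec, config.fs_hz)
                per_ch[ch] = k
            mixtures[cond] = per_ch

        for news_id, cond, dur in news_ids:
            n_samples = int(round(dur * config.fs_hz))
            data = synthesize_trial(onset_by_news[news_id], mixtures[cond],
                                    n_samples, config.fs_hz, config.snr_db, rng)
            trials[(sid, news_id)] = TrialRecording(
                subject_id=sid, news_id=news_id, condition=cond,
                fs_hz=config.fs_hz, data=data)
            r = generate_ratings(group, cond, plan, config.effect_scale, rng,
                                 n=1, subject_offset=rating_offset)
            rating_rows.append({"subject_id": sid, "news_id": news_id, "condition": cond,
                                **{k: int(v) for k, v in r.iloc[0].items()}})

    ds = CohortDataset(
        fs_hz=config.fs_hz,
        subjects=pd.DataFrame(subject_rows),
        news=news,
        onsets=onsets,
        ratings=pd.DataFrame(rating_rows),
        trials=trials,
    )
    ground_truth = {
        "config": asdict(config),
        "plan": asdict(plan),
        "population_means": population_means,
        "subjects": gt_subjects,
    }
    if out_dir is not None:
        write_cohort(ds, out_dir, overwrite=overwrite)
        Path(out_dir, "ground_truth.json").write_text(
            json.dumps(ground_truth, sort_keys=True, indent=1, default=float) + "\n",
            encoding="utf-8")
    return ds, ground_truth
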