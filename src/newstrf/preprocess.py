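"""Filtering/resampling chain turning raw trials into 1-8 Hz analysis signals.

Chain per trial: 1-50 Hz FIR band-pass (order 3300 at the native rate) ->
resample to 200 Hz -> threshold-based artifact interpolation (stand-in for
subspace/ICA cleaning; transient high-amplitude windows are linearly
interpolated) -> 1-8 Hz FIR band-pass (order 1320).  All FIR filters are
applied zero-phase by centering the symmetric impulse response, so component
latencies are not biased by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_core import CohortDataset, PipelineConfig, TrialRecording


@dataclass
class ArtifactReport:
    """Rejection bookkeeping for one trial."""

    subject_id: str
    news_id: str
    windows: list            # (start_s, end_s) of interpolated windows
    fraction_rejected: float
    usable: bool             # False when > 50% of samples were rejected


def design_fir_bandpass(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass taps (Hamming window design, order+1 taps)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz invalid at fs={fs}")
    return sps.firwin(order + 1, [low_hz, high_hz], pass_zero=False, fs=fs)


def fir_bandpass(x: np.ndarray, low_hz: float, high_hz: float, order: int,
                 fs: float) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis, same output length.

    The symmetric (type-I) impulse response is applied by centered
    convolution, which compensates the order/2-sample group delay exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= order:
        raise ValueError(f"signal length {x.shape[-1]} must exceed filter order {order}")
    taps = design_fir_bandpass(low_hz, high_hz, order, fs)
    if x.ndim == 1:
        return sps.oaconvolve(x, taps, mode="same")
    return np.stack([sps.oaconvolve(row, taps, mode="same") for row in x])


def resample(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Polyphase resampling along the last axis to length round(n*fs_to/fs_from)."""
    if fs_to <= 0:
        raise ValueError("fs_to must be positive")
    if fs_from < fs_to:
        raise ValueError("only downsampling or identity supported (fs_from >= fs_to)")
    x = np.asarray(x, dtype=float)
    if fs_from == fs_to:
        return x.copy()
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(x.shape[-1] * fs_to / fs_from))
    if y.shape[-1] > n_out:
        y = y[..., :n_out]
    elif y.shape[-1] < n_out:
        pad = n_out - y.shape[-1]
        y = np.concatenate([y, np.zeros(y.shape[:-1] + (pad,))], axis=-1)
    return y


def reject_artifacts(trial: TrialRecording, threshold: float,
                     window_s: float = 0.2):
    """Interpolate over fixed windows containing samples beyond |threshold|.

    The trial is split into consecutive ``window_s`` windows; any window with
    a sample exceeding the threshold (on any channel) is replaced by linear
    interpolation between its boundary samples.  Returns
    ``(cleaned TrialRecording, ArtifactReport)``; trials with more than half
    their samples rejected are flagged unusable (reported, not dropped --
    exclusion is a dataset-level decision).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    data = trial.data.copy()
    n = data.shape[1]
    win = max(1, int(round(window_s * trial.fs_hz)))
    bad_windows = []
    rejected = np.zeros(n, dtype=bool)
    for start in range(0, n, win):
        stop = min(start + win, n)
        if np.any(np.abs(data[:, start:stop]) > threshold):
            bad_windows.append((start / trial.fs_hz, stop / trial.fs_hz))
            rejected[start:stop] = True
    if bad_windows:
        good = ~rejected
        idx = np.arange(n)
        for ch in range(data.shape[0]):
            if good.any():
                data[ch] = np.interp(idx, idx[good], data[ch, good])
            else:
                data[ch] = 0.0
    frac = float(rejected.mean())
    report = ArtifactReport(
        subject_id=trial.subject_id, news_id=trial.news_id,
        windows=[(round(a, 4), round(b, 4)) for a, b in bad_windows],
        fraction_rejected=frac, usable=frac <= 0.5)
    return replace(trial, data=data), report


def preprocess_trial(trial: TrialRecording, cfg: PipelineConfig):
    """Apply the full chain to one trial; returns (trial at 200 Hz, report)."""
    x = fir_bandpass(trial.data, cfg.bp1_low_hz, cfg.bp1_high_hz, cfg.bp1_order,
                     trial.fs_hz)
    x = resample(x, trial.fs_hz, cfg.resample_to_hz)
    resampled = replace(trial, data=x, fs_hz=cfg.resample_to_hz)
    cleaned, report = reject_artifacts(resampled, cfg.artifact_threshold,
                                       cfg.artifact_window_s)
    x = fir_bandpass(cleaned.data, cfg.bp2_low_hz, cfg.bp2_high_hz, cfg.bp2_order,
                     cfg.resample_to_hz)
    return replace(cleaned, data=x), report


def preprocess_cohort(ds: CohortDataset, cfg: PipelineConfig):
    """Preprocess every trial; returns (new CohortDataset, list of reports)."""
    trials, reports = {}, []
    for key in sorted(ds.trials):
        out, rep = preprocess_trial(ds.trials[key], cfg)
        trials[key] = out
        reports.append(rep)
    out_ds = CohortDataset(
        fs_hz=cfg.resample_to_hz, subjects=ds.subjects.copy(), news=ds.news.copy(),
        onsets=ds.onsets.copy(), ratings=ds.ratings.copy(), trials=trials)
    return out_ds, reports
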