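"""Component measures on TRF weight curves and the classifier feature table.

Amplitudes are fixed-window means of the weight curve: N1 [100,160] ms,
P2 [170,230] ms, N400 [300,600] ms (window endpoints inclusive on the lag
grid).  Latencies are per-subject: the grand-average (GA) curve's
polarity-appropriate extremum is located inside the component window, the
subject curve is non-linearly aligned to the GA by dynamic time warping
(local cost |a - b| on per-curve z-scored series, symmetric unit steps
(1,0)/(0,1)/(1,1)), and the subject's latency is the mean lag of the
subject samples that the warp maps onto the GA peak sample.

The feature table carries 12 EEG features (N1/P2 peak latency at Fpz and
N1/N400 mean amplitude at Pz, per news condition) and 6 rating features
(arousal and comprehensibility condition means).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import CONDITIONS, PipelineConfig

COMPONENTS = ("N1", "P2", "N400")

#: (component, measure, channel) entering the classifier, per the feature sets
EEG_FEATURE_SPEC = [
    ("N1", "latency", "Fpz"),
    ("P2", "latency", "Fpz"),
    ("N1", "amplitude", "Pz"),
    ("N400", "amplitude", "Pz"),
]
RATING_FEATURES = ("arousal", "comprehensibility")


def window_indices(lag_ms: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    idx = np.flatnonzero((lag_ms >= lo - 1e-9) & (lag_ms <= hi + 1e-9))
    if idx.size == 0:
        raise ValueError(f"window {window} ms contains no lag samples")
    return idx


def window_mean_amplitude(weights: np.ndarray, lag_ms: np.ndarray, window) -> float:
    """Arithmetic mean of the weight curve over the (inclusive) window."""
    return float(np.mean(np.asarray(weights)[window_indices(lag_ms, window)]))


def grand_average_trf(curves) -> np.ndarray:
    """Pointwise mean across subjects (equal weights)."""
    curves = np.asarray(list(curves), dtype=float)
    if curves.ndim != 2 or curves.shape[0] == 0:
        raise ValueError("need a non-empty stack of equal-length curves")
    return curves.mean(axis=0)


def detect_ga_peak(ga: np.ndarray, lag_ms: np.ndarray, window, polarity: int) -> float:
    """Lag (ms) of the polarity-appropriate extremum inside the window.

    polarity -1 -> minimum (N1/N400), +1 -> maximum (P2); ties and flat
    windows resolve to the earliest lag.
    """
    idx = window_indices(lag_ms, window)
    seg = np.asarray(ga, dtype=float)[idx]
    if np.allclose(seg, seg[0]):
        warnings.warn("flat curve in component window; returning earliest lag",
                      stacklevel=2)
        return float(lag_ms[idx[0]])
    pos = np.argmin(seg) if polarity < 0 else np.argmax(seg)  # first on ties
    return float(lag_ms[idx[pos]])


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def dtw_warp(a, b, normalize: bool = True):
    """Dynamic time warping of a onto b.

    Local cost |a_i - b_j| (on z-scored curves unless ``normalize=False``),
    monotone unit steps (1,0), (0,1), (1,1), no warping window.  Returns
    (path, cost): path is the list of index pairs from (0,0) to
    (n-1, m-1), cost the summed local cost along it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both series must have length >= 2")
    if normalize:
        a, b = _zscore(a), _zscore(b)
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    # classic O(nm) recurrence; python loops are fine at ERP curve lengths
    Dl = D.tolist()
    cl = cost.tolist()
    for i in range(1, n + 1):
        Di, Dp, ci = Dl[i], Dl[i - 1], cl[i - 1]
        for j in range(1, m + 1):
            best = Dp[j - 1]
            if Dp[j] < best:
                best = Dp[j]
            if Di[j - 1] < best:
                best = Di[j - 1]
            Di[j] = ci[j - 1] + best
    D = np.asarray(Dl)
    # backtrack, preferring the diagonal on ties
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        candidates = []
        if i > 1 and j > 1:
            candidates.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            candidates.append((D[i - 1, j], (i - 1, j)))
        if j > 1:
            candidates.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return path, float(D[n, m])


def subject_peak_latency(subject_curve: np.ndarray, ga_curve: np.ndarray,
                         ga_peak_latency_ms: float, lag_ms: np.ndarray) -> float:
    """Subject latency: mean lag of subject samples aligned to the GA peak."""
    path, _ = dtw_warp(subject_curve, ga_curve)
    peak_j = int(np.argmin(np.abs(lag_ms - ga_peak_latency_ms)))
    aligned_i = [i for i, j in path if j == peak_j]
    return float(np.mean(lag_ms[np.asarray(aligned_i)]))


def compute_component_measures(trf_df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Window amplitudes and DTW latencies for every subject/channel/condition.

    ``trf_df`` is the TRF stage output (subject_id, channel, condition,
    lag_ms, weight).  The GA peak is located per channel x condition within
    the component's amplitude window.
    """
    rows = []
    for (ch, cond), sub in trf_df.groupby(["channel", "condition"]):
        wide = sub.pivot(index="subject_id", columns="lag_ms", values="weight")
        lag_axis = wide.columns.to_numpy(dtype=float)
        curves = wide.to_numpy()
        ga = grand_average_trf(curves)
        for comp in COMPONENTS:
            window = cfg.component_windows[comp]
            polarity = cfg.component_polarities[comp]
            ga_peak = detect_ga_peak(ga, lag_axis, window, polarity)
            for sid, curve in zip(wide.index, curves):
                rows.append({
                    "subject_id": sid, "channel": ch, "condition": cond,
                    "component": comp,
                    "mean_amplitude": window_mean_amplitude(curve, lag_axis, window),
                    "peak_latency_ms": subject_peak_latency(curve, ga, ga_peak, lag_axis),
                    "ga_peak_latency_ms": ga_peak,
                })
    return pd.DataFrame(rows)


def eeg_feature_columns():
    return [f"{comp}_{meas}_{ch}_{cond}"
            for comp, meas, ch in EEG_FEATURE_SPEC for cond in CONDITIONS]


def rating_feature_columns():
    return [f"{scale}_{cond}" for scale in RATING_FEATURES for cond in CONDITIONS]


def build_feature_table(measures: pd.DataFrame, ratings: pd.DataFrame,
                        labels: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 18-column feature table (plus subject_id and label).

    Rating features are condition means over each subject's trials; a
    subject missing every measure/rating cell raises with the offending
    subject and feature named.
    """
    measure_col = {"latency": "peak_latency_ms", "amplitude": "mean_amplitude"}
    out = labels[["subject_id", "group"]].copy().set_index("subject_id")
    for comp, meas, ch in EEG_FEATURE_SPEC:
        sel = measures[(measures["component"] == comp) & (measures["channel"] == ch)]
        piv = sel.pivot(index="subject_id", columns="condition",
                        values=measure_col[meas])
        for cond in CONDITIONS:
            col = f"{comp}_{meas}_{ch}_{cond}"
            if cond not in piv.columns:
                raise ValueError(f"missing measures for feature {col}")
            out[col] = piv[cond]
    rating_means = ratings.groupby(["subject_id", "condition"])[list(RATING_FEATURES)].mean()
    for scale in RATING_FEATURES:
        piv = rating_means[scale].unstack("condition")
        for cond in CONDITIONS:
            out[f"{scale}_{cond}"] = piv[cond]
    missing = out.columns[out.isna().any()]
    if len(missing):
        bad = {col: list(out.index[out[col].isna()]) for col in missing}
        raise ValueError(f"missing feature cells: {bad}")
    return out.reset_index()


def feature_matrix(features: pd.DataFrame, feature_set: str):
    """(X, y, feature names) for one of the three classifier feature sets."""
    if feature_set == "eeg_only":
        cols = eeg_feature_columns()
    elif feature_set == "subjective_only":
        cols = rating_feature_columns()
    elif feature_set == "combination":
        cols = eeg_feature_columns() + rating_feature_columns()
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    X = features[cols].to_numpy(dtype=float)
    y = (features["group"] == "depressed").to_numpy().astype(int)
    return X, y, cols
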