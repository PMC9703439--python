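"""Temporal response function estimation by lagged ridge regression.

The preprocessed EEG response r_ch(t) is modeled as a convolution of the
binary content-word impulse train s(t) with an unknown weight curve w_ch(tau)
over lags tau = -100..800 ms:

    r_ch(t) = sum_tau w_ch(tau) s(t - tau) + eps_ch(t)

Weights are estimated per trial by ridge regression on the lagged design
matrix (no intercept, no column scaling; zero-padded edges).  The penalty
lambda is chosen per subject by leave-one-trial-out CV -- fit per-trial
weights on the training trials, average them, score the held-out trial by
MSE, average over held-out trials and channels -- and a single population
lambda (the mode of the per-subject choices, ties toward smaller) is then
used to estimate every subject's final TRFs as condition-wise means of the
single-trial fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CHANNELS, CONDITIONS, CohortDataset, PipelineConfig


@dataclass
class StimulusVector:
    values: np.ndarray
    fs_hz: float
    news_id: str = ""


@dataclass
class SubjectTRFs:
    """Final per-subject weights: dict (channel, condition) -> weight curve."""

    subject_id: str
    lag_ms: np.ndarray
    weights: dict
    selected_lambda: float


def lag_axis_samples(fs_hz: float, lag_min_ms: float = -100.0,
                     lag_max_ms: float = 800.0) -> np.ndarray:
    lo = int(round(lag_min_ms * fs_hz / 1000.0))
    hi = int(round(lag_max_ms * fs_hz / 1000.0))
    return np.arange(lo, hi + 1)


def lag_axis_ms(fs_hz: float, lag_min_ms: float = -100.0,
                lag_max_ms: float = 800.0) -> np.ndarray:
    return lag_axis_samples(fs_hz, lag_min_ms, lag_max_ms) * (1000.0 / fs_hz)


def build_stimulus_vector(onsets, fs_hz: float, n_samples: int,
                          news_id: str = "") -> StimulusVector:
    """Binary impulse train: 1 at round(onset * fs), 0 elsewhere.

    Onsets must lie in [0, n_samples/fs); onsets rounding to the same sample
    clip to a single 1.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size:
        bad = onsets[(onsets < 0) | (onsets >= n_samples / fs_hz)]
        if bad.size:
            raise ValueError(f"onset {bad[0]:g} s outside [0, {n_samples / fs_hz:g}) s")
    values = np.zeros(n_samples)
    if onsets.size:
        values[np.round(onsets * fs_hz).astype(int)] = 1.0
    return StimulusVector(values=values, fs_hz=fs_hz, news_id=news_id)


def build_lagged_design(stim: StimulusVector, lag_min_ms: float = -100.0,
                        lag_max_ms: float = 800.0) -> np.ndarray:
    """Design matrix X[t, j] = s(t - tau_j), zero-padded at the edges.

    At 200 Hz with lags -100..800 ms this yields 181 columns.
    """
    s = stim.values
    n = s.shape[0]
    lags = lag_axis_samples(stim.fs_hz, lag_min_ms, lag_max_ms)
    X = np.zeros((n, lags.size))
    for j, tau in enumerate(lags):
        if tau >= 0:
            X[tau:, j] = s[: n - tau] if tau < n else 0.0
        else:
            X[: n + tau, j] = s[-tau:]
    return X


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve min ||y - Xw||^2 + lam ||w||^2 (no intercept, no scaling)."""
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows must match response length")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    XtX = X.T @ X
    Xty = X.T @ y
    A = XtX + lam * np.eye(X.shape[1])
    if lam == 0:
        rank = np.linalg.matrix_rank(XtX)
        if rank < X.shape[1]:
            warnings.warn("singular normal matrix at lambda=0; using pseudo-inverse",
                          stacklevel=2)
            return np.linalg.pinv(X) @ y
    return np.linalg.solve(A, Xty)


def predict_response(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return X @ w


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((actual - predicted) ** 2))


class _TrialCache:
    """Eigendecomposed normal equations for fast multi-lambda solves.

    Held-out MSE uses the quadratic form
    ``(y.y - 2 w.X'y + w'X'Xw) / n`` so no pass over the samples is needed
    once X'X and X'y are cached.
    """

    def __init__(self, X: np.ndarray, responses: np.ndarray):
        # responses: (n_channels, n_samples)
        self.n_samples = X.shape[0]
        self.Xty = X.T @ responses.T            # (n_lags, n_channels)
        evals, evecs = np.linalg.eigh(X.T @ X)
        self.evals = np.clip(evals, 0.0, None)
        self.evecs = evecs
        self.y_ss = np.sum(responses ** 2, axis=1)  # per channel

    def weights(self, lam: float) -> np.ndarray:
        """(n_lags, n_channels) ridge weights at penalty lam."""
        qb = self.evecs.T @ self.Xty
        return self.evecs @ (qb / (self.evals + lam)[:, None])

    def mse(self, w: np.ndarray) -> np.ndarray:
        """Per-channel mean squared error of weights ``w`` on this trial."""
        z = self.evecs.T @ w                    # eigen-coordinates
        quad = np.einsum("l,lc,lc->c", self.evals, z, z)
        cross = np.einsum("lc,lc->c", self.Xty, w)
        return (self.y_ss - 2.0 * cross + quad) / self.n_samples


def _subject_cv(designs: list, responses: list, grid: list):
    """CV over the lambda grid; also returns per-trial weights per lambda."""
    if len(designs) != len(responses):
        raise ValueError("designs and responses must align")
    if len(designs) < 2:
        raise ValueError("leave-one-trial-out CV needs at least 2 trials")
    caches = [_TrialCache(X, r) for X, r in zip(designs, responses)]
    n_trials = len(caches)
    mean_mse = []
    w_by_lambda = {}
    for lam in grid:
        w_all = np.stack([c.weights(lam) for c in caches])  # (n_trials, n_lags, n_ch)
        w_by_lambda[lam] = w_all
        w_sum = w_all.sum(axis=0)
        fold_mses = []
        for i in range(n_trials):
            w_bar = (w_sum - w_all[i]) / (n_trials - 1)
            fold_mses.append(caches[i].mse(w_bar))      # per channel
        mean_mse.append(float(np.mean(fold_mses)))
    best = int(np.argmin(mean_mse))  # argmin takes the first (smallest) on ties
    diagnostics = pd.DataFrame({"lambda": grid, "mean_mse": mean_mse})
    return grid[best], diagnostics, w_by_lambda


def loocv_lambda_select(designs: list, responses: list, lambda_grid):
    """Per-subject lambda by leave-one-trial-out CV.

    For each lambda and each held-out trial: average the remaining trials'
    single-trial weights, predict the held-out responses, record the MSE;
    the winner minimizes MSE averaged over held-out trials and channels
    (ties toward smaller lambda).  Returns (lambda, DataFrame of mean MSE
    per lambda).
    """
    lam, diagnostics, _ = _subject_cv(designs, responses, list(lambda_grid))
    return lam, diagnostics


def population_lambda(selected: list) -> float:
    """Mode of the per-subject lambdas; ties broken toward the smaller value."""
    if len(selected) == 0:
        raise ValueError("need at least one selected lambda")
    values, counts = np.unique(np.asarray(selected, dtype=float), return_counts=True)
    return float(values[np.argmax(counts)])  # np.unique sorts ascending


def estimate_subject_trfs(subject_id: str, designs: list, responses: list,
                          conditions: list, lam: float, fs_hz: float,
                          lag_min_ms: float = -100.0,
                          lag_max_ms: float = 800.0) -> SubjectTRFs:
    """Condition-wise mean of single-trial ridge weights at the population lambda."""
    present = set(conditions)
    missing = [c for c in CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"subject {subject_id}: no trials for condition(s) {missing}")
    caches = [_TrialCache(X, r) for X, r in zip(designs, responses)]
    per_trial = [c.weights(lam) for c in caches]        # (n_lags, n_ch)
    weights = {}
    for cond in CONDITIONS:
        idx = [i for i, c in enumerate(conditions) if c == cond]
        w_cond = np.mean([per_trial[i] for i in idx], axis=0)
        for ci, ch in enumerate(CHANNELS):
            weights[(ch, cond)] = w_cond[:, ci]
    return SubjectTRFs(subject_id=subject_id, lag_ms=lag_axis_ms(fs_hz, lag_min_ms, lag_max_ms),
                       weights=weights, selected_lambda=lam)


def _subject_designs(ds: CohortDataset, sid: str, cfg: PipelineConfig):
    designs, responses, conditions = [], [], []
    onset_by_news = {nid: g["onset_s"].to_numpy() for nid, g in ds.onsets.groupby("news_id")}
    for trial in ds.subject_trials(sid):
        stim = build_stimulus_vector(onset_by_news.get(trial.news_id, []),
                                     trial.fs_hz, trial.n_samples, trial.news_id)
        designs.append(build_lagged_design(stim, cfg.lag_min_ms, cfg.lag_max_ms))
        responses.append(trial.data)
        conditions.append(trial.condition)
    return designs, responses, conditions


def estimate_cohort_trfs(ds: CohortDataset, cfg: PipelineConfig):
    """Full TRF stage: per-subject lambda CV, population mode, final TRFs.

    Returns (trfs DataFrame with columns subject/channel/condition/lag_ms/
    weight, diagnostics DataFrame with per-subject lambda CV curves,
    population lambda).
    """
    subject_ids = sorted(ds.subjects["subject_id"])
    grid = [float(l) for l in cfg.lambda_grid]
    selected, diag_rows = [], []
    cached = {}  # per-trial weights for every grid lambda (small); designs are not kept
    for sid in subject_ids:
        designs, responses, conditions = _subject_designs(ds, sid, cfg)
        lam, diag, w_by_lambda = _subject_cv(designs, responses, grid)
        selected.append(lam)
        diag["subject_id"] = sid
        diag_rows.append(diag)
        cached[sid] = (conditions, w_by_lambda)
    lam_star = population_lambda(selected)
    lags = lag_axis_ms(ds.fs_hz, cfg.lag_min_ms, cfg.lag_max_ms)
    trf_rows = []
    for sid in subject_ids:
        conditions, w_by_lambda = cached[sid]
        present = set(conditions)
        missing = [c for c in CONDITIONS if c not in present]
        if missing:
            raise ValueError(f"subject {sid}: no trials for condition(s) {missing}")
        w_all = w_by_lambda[lam_star]           # (n_trials, n_lags, n_ch)
        for cond in CONDITIONS:
            idx = [i for i, c in enumerate(conditions) if c == cond]
            w_cond = w_all[idx].mean(axis=0)
            for ci, ch in enumerate(CHANNELS):
                trf_rows.append(pd.DataFrame({
                    "subject_id": sid, "channel": ch, "condition": cond,
                    "lag_ms": lags, "weight": w_cond[:, ci]}))
    trf_df = pd.concat(trf_rows, ignore_index=True)
    diagnostics = pd.concat(diag_rows, ignore_index=True)
    diagnostics["selected"] = diagnostics.groupby("subject_id")["mean_mse"].transform(
        lambda s: s == s.min())
    return trf_df, diagnostics, lam_star
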