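"""Readers/writers for on-disk artifacts plus pipeline configuration.

A cohort lives in one directory::

    cohort/
      metadata.json        fs, channel names, news item index (id, condition,
                           duration), subject ids
      labels.csv           subject_id, group, bdi_score
      onsets.tsv           news_id, onset_s, token   (shared across subjects --
                           each news item is one fixed audio clip)
      ratings.csv          subject_id, news_id, condition, valence, arousal,
                           interest, comprehensibility
      eeg/<subject>.npz    one file per subject; one named array per news item,
                           shape (n_channels, n_samples)

All times are stored in seconds, trial-relative, with 0-based sample
indexing; lag axes elsewhere in the package are in milliseconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("Fpz", "Cz", "Pz")
CONDITIONS = ("negative", "neutral", "positive")
GROUPS = ("depressed", "non-depressed")


class SchemaError(ValueError):
    """An artifact violates the documented on-disk schema."""


class DataValidationError(ValueError):
    """Artifact contents are internally inconsistent."""


class ConfigError(ValueError):
    """Configuration file or override is invalid."""


@dataclass
class TrialRecording:
    """One subject x news-item EEG segment: the response r_ch(t).

    ``data`` is (n_channels, n_samples) in microvolt-scale units at ``fs_hz``.
    """

    subject_id: str
    news_id: str
    condition: str
    fs_hz: float
    data: np.ndarray
    channels: tuple = CHANNELS

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_hz


@dataclass
class CohortDataset:
    """In-memory view of a cohort directory.

    subjects : DataFrame (subject_id, group, bdi_score)
    news     : DataFrame (news_id, condition, duration_s)
    onsets   : DataFrame (news_id, onset_s, token)
    ratings  : DataFrame (subject_id, news_id, condition, valence, arousal,
               interest, comprehensibility)
    trials   : dict (subject_id, news_id) -> TrialRecording
    """

    fs_hz: float
    subjects: pd.DataFrame
    news: pd.DataFrame
    onsets: pd.DataFrame
    ratings: pd.DataFrame
    trials: dict

    def subject_trials(self, subject_id: str) -> list:
        return [t for (sid, _), t in sorted(self.trials.items()) if sid == subject_id]


def validate_dataset(ds: CohortDataset) -> None:
    """Raise SchemaError / DataValidationError on malformed cohorts."""
    if ds.subjects["subject_id"].duplicated().any():
        raise DataValidationError("duplicate subject labels")
    bad_groups = set(ds.subjects["group"]) - set(GROUPS)
    if bad_groups:
        raise DataValidationError(f"unknown group labels: {sorted(bad_groups)}")
    durations = dict(zip(ds.news["news_id"], ds.news["duration_s"]))
    for (sid, news_id), trial in ds.trials.items():
        missing = [c for c in CHANNELS if c not in trial.channels]
        if missing:
            raise SchemaError(
                f"trial {sid}/{news_id}: missing channel(s) {missing}; "
                f"required channels are {list(CHANNELS)}"
            )
        if sid not in set(ds.subjects["subject_id"]):
            raise DataValidationError(f"trial references unknown subject {sid}")
        if news_id not in durations:
            raise DataValidationError(f"trial references unknown news item {news_id}")
    for news_id, sub in ds.onsets.groupby("news_id"):
        if news_id not in durations:
            raise DataValidationError(f"onsets reference unknown news item {news_id}")
        dur = durations[news_id]
        over = sub[sub["onset_s"] >= dur]
        if not over.empty:
            raise DataValidationError(
                f"news {news_id}: onset {float(over['onset_s'].iloc[0]):g} s "
                f"lies outside trial duration {dur:g} s"
            )


def _write_named_arrays(path: Path, arrays: dict) -> None:
    # deterministic .npz: fixed entry order and zip timestamps so identical
    # cohorts are byte-identical on disk
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def write_cohort(ds: CohortDataset, path, overwrite: bool = False) -> None:
    """Serialize a cohort to ``path`` (refuses existing dirs unless overwrite)."""
    validate_dataset(ds)
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists and is not empty (pass overwrite=True)")
    (path / "eeg").mkdir(parents=True, exist_ok=True)
    meta = {
        "fs_hz": ds.fs_hz,
        "channels": list(CHANNELS),
        "news": ds.news.to_dict(orient="records"),
        "subjects": sorted(ds.subjects["subject_id"]),
    }
    (path / "metadata.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    ds.subjects.to_csv(path / "labels.csv", index=False)
    ds.onsets.to_csv(path / "onsets.tsv", sep="\t", index=False)
    ds.ratings.to_csv(path / "ratings.csv", index=False)
    for sid in sorted(ds.subjects["subject_id"]):
        arrays = {
            news_id: trial.data
            for (s, news_id), trial in ds.trials.items()
            if s == sid
        }
        _write_named_arrays(path / "eeg" / f"{sid}.npz", arrays)


def read_cohort(path) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    if not (path / "metadata.json").exists():
        raise FileNotFoundError(f"no cohort at {path}: missing metadata.json")
    meta = json.loads((path / "metadata.json").read_text(encoding="utf-8"))
    if list(meta["channels"]) != list(CHANNELS):
        missing = [c for c in CHANNELS if c not in meta["channels"]]
        raise SchemaError(f"cohort channels {meta['channels']} != {list(CHANNELS)}; missing {missing}")
    news = pd.DataFrame(meta["news"])[["news_id", "condition", "duration_s"]]
    subjects = pd.read_csv(path / "labels.csv")
    onsets = pd.read_csv(path / "onsets.tsv", sep="\t")
    ratings = pd.read_csv(path / "ratings.csv")
    cond = dict(zip(news["news_id"], news["condition"]))
    trials = {}
    for sid in meta["subjects"]:
        with np.load(path / "eeg" / f"{sid}.npz") as npz:
            for news_id in npz.files:
                trials[(sid, news_id)] = TrialRecording(
                    subject_id=sid,
                    news_id=news_id,
                    condition=cond[news_id],
                    fs_hz=float(meta["fs_hz"]),
                    data=npz[news_id],
                )
    ds = CohortDataset(
        fs_hz=float(meta["fs_hz"]),
        subjects=subjects,
        news=news,
        onsets=onsets,
        ratings=ratings,
        trials=trials,
    )
    validate_dataset(ds)
    return ds


def dataset_hash(ds: CohortDataset) -> str:
    """Content hash (sha256) over signal values and metadata tables."""
    h = hashlib.sha256()
    h.update(repr(float(ds.fs_hz)).encode())
    for df in (ds.subjects, ds.news, ds.onsets, ds.ratings):
        h.update(df.to_csv(index=False).encode())
    for key in sorted(ds.trials):
        h.update(repr(key).encode())
        h.update(np.ascontiguousarray(ds.trials[key].data).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline configuration


def _default_lambda_grid():
    return [2.0 ** k for k in range(1, 22)]


def _default_windows():
    return {"N1": [100.0, 160.0], "P2": [170.0, 230.0], "N400": [300.0, 600.0]}


def _default_polarities():
    return {"N1": -1, "P2": 1, "N400": -1}


def _default_c_grid():
    return [10.0 ** k for k in range(-3, 4)]


@dataclass
class PipelineConfig:
    """All analysis parameters with the study's settings as defaults.

    Filters: 1-50 Hz order-3300 FIR at the native rate, resampling to 200 Hz,
    then 1-8 Hz order-1320 FIR.  TRF lags span -100..800 ms with the ridge
    penalty chosen from {2^1 .. 2^21} by leave-one-trial-out CV.  Component
    windows are [100,160] / [170,230] / [300,600] ms for N1 / P2 / N400.  The
    classifier grid is C in {1e-3 .. 1e3} with stratified 3-fold inner CV,
    RFE to 6 features and 1000 label permutations.
    """

    bp1_low_hz: float = 1.0
    bp1_high_hz: float = 50.0
    bp1_order: int = 3300
    resample_to_hz: float = 200.0
    bp2_low_hz: float = 1.0
    bp2_high_hz: float = 8.0
    bp2_order: int = 1320
    artifact_threshold: float = 100.0
    artifact_window_s: float = 0.2
    lag_min_ms: float = -100.0
    lag_max_ms: float = 800.0
    lambda_grid: list = field(default_factory=_default_lambda_grid)
    component_windows: dict = field(default_factory=_default_windows)
    component_polarities: dict = field(default_factory=_default_polarities)
    feature_set: str = "combination"
    n_selected: int = 6
    c_grid: list = field(default_factory=_default_c_grid)
    inner_folds: int = 3
    rfe_c: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if len(self.lambda_grid) == 0:
            raise ConfigError("lambda_grid must be non-empty")
        if list(self.lambda_grid) != sorted(set(map(float, self.lambda_grid))):
            raise ConfigError("lambda_grid must be strictly increasing")
        if len(self.c_grid) == 0:
            raise ConfigError("c_grid must be non-empty")
        if self.feature_set not in ("eeg_only", "subjective_only", "combination"):
            raise ConfigError(f"unknown feature_set {self.feature_set!r}")


def load_config(path=None, overrides=None) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML/JSON file plus overrides.

    Unknown keys are rejected; an empty file yields all defaults.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigError(f"cannot parse config {path}{line}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
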