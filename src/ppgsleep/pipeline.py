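"""End-to-end glue: recording + hypnogram -> per-epoch feature matrix.

The feature matrix is a pandas DataFrame with the 79 canonical feature
columns plus ``epoch_index``, ``subject_id``, ``label`` and ``valid``.
Epochs whose pulse detection degenerates (fewer than 4 beats, or too few
plausible intervals) are flagged invalid and carry NaN features; they are
excluded from selection and classification downstream.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .io import Epoch, PPGRecording, segment_epochs
from .preprocess import PreprocessConfig, preprocess_epoch
from .pulse import (InvalidEpochError, build_pulse_series, detect_peaks,
                    locate_fiducials)

logger = logging.getLogger(__name__)

META_COLUMNS = ("epoch_index", "subject_id", "label", "valid")


def extract_epoch_features(epoch: Epoch,
                           config: PreprocessConfig | None = None) -> np.ndarray:
    """Preprocess one epoch and compute its 79-feature vector.

    Raises :class:`InvalidEpochError` on degenerate pulse detection.
    """
    y = preprocess_epoch(epoch.samples, epoch.fs, config)
    peaks = detect_peaks(y, epoch.fs)
    ps = build_pulse_series(peaks, y, epoch.fs)
    beats = locate_fiducials(y, peaks, epoch.fs)
    if len(beats) < 2:
        raise InvalidEpochError(f"only {len(beats)} complete beats delineated")
    return extract_features(y, beats, ps)


def extract_night_features(rec: PPGRecording, labels: Sequence[str],
                           config: PreprocessConfig | None = None,
                           subject_id: str | None = None) -> pd.DataFrame:
    """Feature matrix of a whole labelled recording (one row per epoch)."""
    subject = subject_id if subject_id is not None else rec.subject_id
    rows = []
    for ep in segment_epochs(rec, labels):
        valid = True
        try:
            vec = extract_epoch_features(ep, config)
            valid = bool(np.all(np.isfinite(vec)))
        except InvalidEpochError as exc:
            logger.warning("epoch %d invalid: %s", ep.index, exc)
            vec = np.full(len(FEATURE_NAMES), np.nan)
            valid = False
        rows.append({**dict(zip(FEATURE_NAMES, vec)),
                     "epoch_index": ep.index, "subject_id": subject,
                     "label": ep.label, "valid": valid})
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + list(META_COLUMNS))


def extract_corpus_features(corpus, config: PreprocessConfig | None = None
                            ) -> pd.DataFrame:
    """Concatenate feature matrices over ``(subject_id, rec, labels)`` tuples."""
    frames = [extract_night_features(rec, labels, config, subject_id=sid)
              for sid, rec, labels in corpus]
    return pd.concat(frames, ignore_index=True)


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in list(FEATURE_NAMES) + list(META_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing[:5]} ...")
    return df
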