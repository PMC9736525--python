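"""Window labeling, pooling, class balancing and train/validation splitting.

Windows are first assigned ictal (I) if their midpoint falls inside an
annotated ictal interval; then, for each maximal run of ictal windows, up to
5 immediately preceding non-ictal windows are relabeled preictal (P),
stopping early at any earlier ictal window. Everything else is normal (N).

Per-recording tables are pooled and shuffled, the majority class is
randomly undersampled (RUS) down to the second-largest class, and the
train/validation split is stratified 70/30. The training pool is balanced;
the validation set keeps the original class imbalance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .synthetic import StateTimeline

logger = logging.getLogger(__name__)

PREICTAL_LOOKBACK = 5
LABELS = ("N", "P", "I")
META_COLUMNS = ("t_start_s", "t_end_s", "recording")


class DatasetError(ValueError):
    pass


def label_windows(
    midpoints: np.ndarray | list[float], annotations: StateTimeline
) -> np.ndarray:
    """Two-step N/P/I labeling of time-ordered windows (given midpoints)."""
    mids = np.asarray(midpoints, float)
    if np.any(np.diff(mids) < 0):
        raise DatasetError("windows must be time-ordered")
    if np.any(mids < 0) or np.any(mids > annotations.total_duration):
        raise DatasetError("window midpoint outside the annotation span")
    labels = np.array(["N"] * len(mids), dtype=object)
    is_ictal = annotations.states_at(mids) == "I"
    labels[is_ictal] = "I"
    # relabel up to 5 windows before each ictal run as preictal
    i = 0
    n = len(mids)
    while i < n:
        if is_ictal[i] and (i == 0 or not is_ictal[i - 1]):
            j = i - 1
            count = 0
            while j >= 0 and count < PREICTAL_LOOKBACK and not is_ictal[j]:
                labels[j] = "P"
                j -= 1
                count += 1
        i += 1
    return labels.astype(str)


def label_feature_table(frame: pd.DataFrame, annotations: StateTimeline) -> pd.DataFrame:
    """Attach a label column from window midpoints."""
    mids = 0.5 * (frame["t_start_s"].to_numpy() + frame["t_end_s"].to_numpy())
    out = frame.copy()
    out["label"] = label_windows(mids, annotations)
    return out


def pool_and_shuffle(tables: list[pd.DataFrame], seed: int) -> pd.DataFrame:
    """Pool labeled per-recording tables and shuffle rows; window-time and
    provenance columns are dropped after shuffling."""
    if not tables:
        raise DatasetError("no tables to pool")
    cols = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=1):
        if list(t.columns) != cols:
            diff = set(t.columns).symmetric_difference(cols)
            raise DatasetError(f"feature manifest mismatch in table {i}: {sorted(diff)}")
    pooled = pd.concat(tables, ignore_index=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pooled))
    pooled = pooled.iloc[order].reset_index(drop=True)
    return pooled.drop(columns=[c for c in META_COLUMNS if c in pooled.columns])


def rus_balance(frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Random undersampling of the single majority class down to the
    second-largest class count; minority classes are untouched."""
    counts = frame["label"].value_counts()
    if len(counts) < 2:
        raise DatasetError("need at least 2 classes to balance")
    if counts.iloc[0] == counts.iloc[1]:
        logger.info("majority tie (%s); no undersampling applied", dict(counts))
        return frame.copy()
    majority = counts.index[0]
    target = int(counts.iloc[1])
    rng = np.random.default_rng(seed)
    maj_idx = frame.index[frame["label"] == majority].to_numpy()
    keep = rng.choice(maj_idx, size=target, replace=False)
    keep_mask = frame["label"] != majority
    keep_mask.loc[np.sort(keep)] = True
    return frame[keep_mask].reset_index(drop=True)


def stratified_split(
    frame: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class 70/30 partition (half rows rounding to train)."""
    counts = frame["label"].value_counts()
    if (counts < 2).any():
        raise DatasetError("every class needs at least 2 rows to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for label in counts.index:
        idx = frame.index[frame["label"] == label].to_numpy()
        idx = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * train_frac + 0.5))
        train_idx.extend(idx[:n_train].tolist())
    mask = frame.index.isin(train_idx)
    train = frame[mask].reset_index(drop=True)
    valid = frame[~mask].reset_index(drop=True)
    return train, valid


def split_xy(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (93 columns in manifest order) and label vector."""
    return frame[list(FEATURE_NAMES)].to_numpy(float), frame["label"].to_numpy(str)
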