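"""Signal preprocessing: trimming, segmentation, and robust normalization.

A qualified read (>= ``min_read_samples`` samples) is trimmed of its first
``trim_samples`` samples (adaptor region), converted to picoamperes, cut
into fixed-length segments (four random windows for training, the first
window only for inference), and each segment is normalized with the
MAD-based modified z-score

    z_i = 0.6745 * (x_i - median(x)) / MAD(x),   MAD = median(|x_i - median(x)|)

then winsorized: |z| > threshold is clamped to +/- threshold. Clamping
(rather than sample deletion) preserves the fixed segment length the
classifier requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .signal_io import RawRead, to_picoamps

__all__ = [
    "PreprocessConfig",
    "SignalSegment",
    "DegenerateSignalError",
    "EmptyDatasetError",
    "qualifies",
    "trim",
    "extract_training_segments",
    "mad_stats",
    "modified_zscore",
    "apply_mad_threshold",
    "preprocess_dataset",
]

#: 0.75-quantile of the standard normal; scales MAD to estimate sigma
MAD_SCALE = 0.6745


class DegenerateSignalError(ValueError):
    """Raised when a segment has MAD == 0 and cannot be normalized."""


class EmptyDatasetError(ValueError):
    """Raised when preprocessing yields zero usable segments."""


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults are the standard operating point: trim the first 1500 samples,
    3000-sample segments, reads qualify at >= 4500 samples, four random
    segments per read for training, first segment only for inference.
    """

    trim_samples: int = 1500
    segment_length: int = 3000
    min_read_samples: int = 4500
    segments_per_read_train: int = 4
    segments_per_read_infer: int = 1  # fixed: the first segment
    mad_threshold: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.trim_samples < 0:
            raise ValueError("trim_samples must be nonnegative")
        if self.min_read_samples < self.trim_samples + self.segment_length:
            raise ValueError(
                "min_read_samples must be >= trim_samples + segment_length"
            )
        if self.mad_threshold <= 0:
            raise ValueError("mad_threshold must be positive")
        if self.segments_per_read_infer != 1:
            raise ValueError("inference always uses exactly the first segment")


@dataclass
class SignalSegment:
    """A fixed-length normalized window of a read's trimmed pA signal."""

    read_id: str
    start: int  # 0-based offset into the trimmed pA signal
    values: np.ndarray
    label: int | None = None


def qualifies(read: RawRead, cfg: PreprocessConfig) -> bool:
    """A read qualifies iff it has at least ``cfg.min_read_samples`` samples."""
    return len(read) >= cfg.min_read_samples


def trim(signal: np.ndarray, n: int) -> np.ndarray:
    """Drop the first ``n`` samples (adaptor region)."""
    signal = np.asarray(signal)
    if n < 0:
        raise ValueError("n must be nonnegative")
    if signal.size < n:
        raise ValueError(f"signal has {signal.size} samples, cannot trim {n}")
    return signal[n:]


def extract_training_segments(
    trimmed: np.ndarray, cfg: PreprocessConfig, rng: np.random.Generator
) -> list[tuple[int, np.ndarray]]:
    """Draw ``segments_per_read_train`` random fixed-length windows.

    Starts are uniform on [0, len - segment_length], independent, with
    replacement (overlaps allowed). Returns (start, window) pairs.
    """
    trimmed = np.asarray(trimmed)
    L, seg = trimmed.size, cfg.segment_length
    if L < seg:
        raise ValueError(f"trimmed signal ({L}) shorter than segment length ({seg})")
    starts = rng.integers(0, L - seg + 1, size=cfg.segments_per_read_train)
    return [(int(s), trimmed[s : s + seg]) for s in starts]


def mad_stats(values: np.ndarray) -> tuple[float, float]:
    """Median and median absolute deviation of a non-empty vector.

    Even-length median is the midpoint of the two central order statistics.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("mad_stats requires a non-empty vector")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def modified_zscore(values: np.ndarray) -> np.ndarray:
    """MAD-based modified z-score; invariant under x -> a*x + b (a > 0).

    Raises :class:`DegenerateSignalError` when MAD == 0 (e.g. a constant
    signal); such segments are discarded upstream.
    """
    values = np.asarray(values, dtype=np.float64)
    med, mad = mad_stats(values)
    if mad == 0.0:
        raise DegenerateSignalError("MAD is zero; segment cannot be normalized")
    return MAD_SCALE * (values - med) / mad


def apply_mad_threshold(z: np.ndarray, threshold: float) -> np.ndarray:
    """Clamp outliers: entries with |z| > threshold become +/- threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.clip(z, -threshold, threshold)


def preprocess_dataset(
    reads: Sequence[RawRead],
    cfg: PreprocessConfig,
    mode: Literal["train", "infer"],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[SignalSegment], list[tuple[str, str]]]:
    """Preprocess reads into a segment matrix ready for the classifier.

    Pipeline per read: qualification filter -> trim -> pA conversion ->
    segmentation (train: random windows; infer: first window) -> modified
    z-score -> MAD-threshold clamping.

    Returns
    -------
    X : (n_segments, segment_length) float32 matrix
    y : (n_segments,) int8 label vector (-1 where the read has no label)
    provenance : list of SignalSegment (read_id, start, values row, label)
    skipped : list of (read_id, reason) for unqualified/degenerate reads

    Raises
    ------
    EmptyDatasetError
        If no segment survives filtering.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    rows: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[SignalSegment] = []
    skipped: list[tuple[str, str]] = []

    for read in reads:
        if not qualifies(read, cfg):
            skipped.append((read.read_id, f"short read ({len(read)} samples)"))
            continue
        pa = trim(to_picoamps(read), cfg.trim_samples)
        if mode == "train":
            windows = extract_training_segments(pa, cfg, rng)
        else:
            windows = [(0, pa[: cfg.segment_length])]
        emitted = 0
        for start, window in windows:
            try:
                z = modified_zscore(window)
            except DegenerateSignalError:
                continue
            z = apply_mad_threshold(z, cfg.mad_threshold)
            rows.append(z.astype(np.float32))
            labels.append(read.label if read.label is not None else -1)
            provenance.append(
                SignalSegment(read.read_id, start, rows[-1], read.label)
            )
            emitted += 1
        if emitted == 0:
            skipped.append((read.read_id, "degenerate signal (MAD == 0)"))

    if not rows:
        raise EmptyDatasetError("no usable segments after preprocessing")
    X = np.stack(rows)
    y = np.asarray(labels, dtype=np.int8)
    return X, y, provenance, skipped
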