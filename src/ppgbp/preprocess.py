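"""PPG smoothing, baseline-wander removal, quality control and BP labeling.

The PPG channel is smoothed with a short centered moving average and
detrended by subtracting a long moving-average trend (respiratory-band
baseline wander).  The ABP channel supplies the labels: within a segment,
SBP = mean of detected systolic peak values and DBP = mean of diastolic
trough values, then the 2017 ACC/AHA thresholds assign one of four
categories (normal / elevated / stage-1 / stage-2 hypertension), binarized
as normal vs abnormal.  Records failing automated quality checks
(no signal, missing peaks, gross artifacts) are excluded.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


class BPCategory(enum.IntEnum):
    """2017 ACC/AHA blood-pressure category, totally ordered."""

    NORMAL = 0
    ELEVATED = 1
    STAGE1 = 2
    STAGE2 = 3


@dataclass(frozen=True)
class SegmentLabel:
    sbp: float
    dbp: float
    category: BPCategory
    binary: int

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise ValueError(f"sbp {self.sbp} must exceed dbp {self.dbp}")
        if (self.binary == 0) != (self.category == BPCategory.NORMAL):
            raise ValueError("binary must be 0 iff category is NORMAL")


@dataclass(frozen=True)
class QCReport:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold iff reasons is empty")


@dataclass(frozen=True)
class PreprocessConfig:
    """All preprocessing/QC thresholds in one place.

    smoothing_window: samples, odd (40 ms at 125 Hz by default).
    trend_window_s: seconds of moving-average trend for detrending.
    min_peak_distance_s: refractory period between systolic peaks (<=180 bpm).
    peak_prominence_frac: required prominence as fraction of signal range.
    max_peak_gap_s: inter-peak gap beyond which peaks count as missing.
    flat_std_frac: std below this fraction of range flags "no signal".
    artifact_mad_k: |x - median| > k * MAD flags an artifact sample.
    """

    smoothing_window: int = 5
    trend_window_s: float = 2.0
    min_peak_distance_s: float = 0.33
    peak_prominence_frac: float = 0.25
    max_peak_gap_s: float = 2.0
    flat_std_frac: float = 1e-6
    artifact_mad_k: float = 8.0


DEFAULT_CONFIG = PreprocessConfig()


class LabelingError(RuntimeError):
    """Raised when a segment's ABP yields no usable peaks/troughs.

    Distinct from QC failure: the record passed QC but this particular
    window cannot be labeled.
    """


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the shortened available window."""
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if x.size < window:
        raise ValueError(f"series of length {x.size} shorter than window {window}")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def remove_baseline(x: np.ndarray, fs: float, trend_window_s: float = 2.0) -> np.ndarray:
    """Subtract a moving-average trend estimate (respiratory baseline wander).

    The trend is a centered boxcar mean over ``trend_window_s`` seconds; the
    residual passes the pulse band (~1-2 Hz) with modest loss while
    suppressing slow drift.
    """
    if trend_window_s <= 0:
        raise ValueError("trend_window_s must be positive")
    x = np.asarray(x, dtype=float)
    w = int(round(trend_window_s * fs))
    w = w + 1 if w % 2 == 0 else w
    if x.size <= w:
        raise ValueError(
            f"series of {x.size} samples shorter than {trend_window_s} s trend window"
        )
    return x - moving_average(x, w)


def smooth_ppg(x: np.ndarray, config: PreprocessConfig = DEFAULT_CONFIG) -> np.ndarray:
    return moving_average(x, config.smoothing_window)


def preprocess_ppg(
    x: np.ndarray, fs: float, config: PreprocessConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Moving-average smoothing followed by baseline-wander removal."""
    return remove_baseline(smooth_ppg(x, config), fs, config.trend_window_s)


def detect_peaks_troughs(
    abp: np.ndarray, fs: float, config: PreprocessConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray]:
    """Systolic peak and diastolic trough indices of an ABP series.

    Peaks: local maxima separated by at least ``min_peak_distance_s`` with
    prominence at least ``peak_prominence_frac`` of the signal range.
    Exactly one trough (the minimum) between consecutive peaks.
    """
    abp = np.asarray(abp, dtype=float)
    if abp.size < fs:
        raise ValueError("need at least 1 s of samples for peak detection")
    rng_ = float(np.ptp(abp))
    if rng_ == 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)
    peaks, _ = find_peaks(
        abp,
        distance=max(1, int(round(config.min_peak_distance_s * fs))),
        prominence=config.peak_prominence_frac * rng_,
    )
    troughs = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        troughs.append(p0 + int(np.argmin(abp[p0:p1])))
    return peaks, np.asarray(troughs, dtype=int)


def quality_check(
    record, fs: float | None = None, config: PreprocessConfig = DEFAULT_CONFIG
) -> QCReport:
    """Automated screen replacing a manual record check.

    Flags ``no_signal`` (flat channel), ``missing_peaks`` (no detectable
    beats or an inter-peak gap over ``max_peak_gap_s``), and ``artifact``
    (any sample more than ``artifact_mad_k`` robust scales from the median).
    """
    fs = record.fs if fs is None else fs
    reasons: list[str] = []
    for name, x in (("ppg", record.ppg), ("abp", record.abp)):
        rng_ = float(np.ptp(x))
        if rng_ == 0.0 or float(np.std(x)) < config.flat_std_frac * rng_:
            reasons.append("no_signal")
            continue
        med = float(np.median(x))
        # robust scale: MAD-consistent sigma estimate; a raw MAD is too
        # tight for pulsatile waveforms (clean beats reach ~8 MADs)
        scale = 1.4826 * float(np.median(np.abs(x - med)))
        if scale > 0 and np.any(np.abs(x - med) > config.artifact_mad_k * scale):
            reasons.append("artifact")
        peaks, _ = detect_peaks_troughs(x, fs, config)
        if peaks.size == 0:
            reasons.append("missing_peaks")
        else:
            gaps = np.diff(np.concatenate([[0], peaks, [x.size - 1]]))
            if np.any(gaps > config.max_peak_gap_s * fs):
                reasons.append("missing_peaks")
    reasons_t = tuple(dict.fromkeys(reasons))  # dedupe, keep order
    if reasons_t:
        logger.info("record %s excluded: %s", getattr(record, "record_id", "?"),
                    ",".join(reasons_t))
    return QCReport(passed=not reasons_t, reasons=reasons_t)


def segment_bp(
    abp_segment: np.ndarray, fs: float, config: PreprocessConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """(SBP, DBP) of a segment: mean of peak values, mean of trough values."""
    abp_segment = np.asarray(abp_segment, dtype=float)
    peaks, troughs = detect_peaks_troughs(abp_segment, fs, config)
    if peaks.size == 0:
        raise LabelingError("no systolic peaks detected in segment")
    if troughs.size == 0:
        # single-beat window: use the global minimum as the lone trough
        troughs = np.array([int(np.argmin(abp_segment))])
    sbp = float(np.mean(abp_segment[peaks]))
    dbp = float(np.mean(abp_segment[troughs]))
    if not sbp > dbp:
        raise LabelingError(f"degenerate segment: sbp {sbp} <= dbp {dbp}")
    return sbp, dbp


def classify_acc_aha(sbp: float, dbp: float) -> BPCategory:
    """2017 ACC/AHA category from (SBP, DBP) in mmHg.

    Stage 2 if SBP >= 140 or DBP >= 90; stage 1 if SBP >= 130 or DBP >= 80;
    elevated if SBP >= 120; normal otherwise.  The higher category wins.
    """
    if not (sbp > dbp > 0):
        raise ValueError(f"require sbp > dbp > 0, got {sbp}/{dbp}")
    if sbp >= 140 or dbp >= 90:
        return BPCategory.STAGE2
    if sbp >= 130 or dbp >= 80:
        return BPCategory.STAGE1
    if sbp >= 120:
        return BPCategory.ELEVATED
    return BPCategory.NORMAL


def binarize(category: BPCategory) -> int:
    """0 for normal BP, 1 for any abnormal category (elevated or worse)."""
    return 0 if BPCategory(category) == BPCategory.NORMAL else 1


def label_segment(
    abp_segment: np.ndarray, fs: float, config: PreprocessConfig = DEFAULT_CONFIG
) -> SegmentLabel:
    """Full labeling of one ABP window: (SBP, DBP) -> category -> binary."""
    sbp, dbp = segment_bp(abp_segment, fs, config)
    category = classify_acc_aha(sbp, dbp)
    return SegmentLabel(sbp=sbp, dbp=dbp, category=category, binary=binarize(category))
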