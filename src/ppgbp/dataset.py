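"""Segmentation, labeling, randomized splitting and image-dataset emission.

Records are sliced into non-overlapping fixed-length windows; each window's
PPG is preprocessed and rendered as a scalogram (or raw-segment baseline
image) while its ABP yields the blood-pressure label.  Segments are then
shuffled deterministically and split 90/10 into train/validation, and a CSV
manifest ties image paths to labels and provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .preprocess import LabelingError, PreprocessConfig, quality_check
from .scalogram import render_cwt, render_raw_segment, save_image
from .synthetic import WaveformRecord
from .wavelets import WaveletSpec, cwt, default_scales

logger = logging.getLogger(__name__)

SEGMENT_LENGTHS = (100, 150, 200, 250, 300, 350, 400, 450, 500)

MANIFEST_COLUMNS = (
    "image_path", "split", "record_id", "start", "length",
    "sbp", "dbp", "category", "binary", "wavelet", "seed",
)


def segment_indices(n_total: int, length: int) -> list[tuple[int, int]]:
    """Half-open non-overlapping windows [k*L, (k+1)*L); remainder discarded."""
    if length < 1:
        raise ValueError("segment length must be >= 1")
    return [(k * length, (k + 1) * length) for k in range(n_total // length)]


def split(n_items: int, train_frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic shuffled split: first floor(train_frac*n) go to train."""
    if n_items <= 0:
        raise ValueError("cannot split an empty collection")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n_items)
    n_train = int(np.floor(train_frac * n_items))
    return order[:n_train], order[n_train:]


def segment_duration_s(length: int, fs: float = 125.0) -> float:
    """Duration of a segment in seconds (e.g. 300 samples at 125 Hz = 2.4 s)."""
    return length / fs


@dataclass
class DatasetManifest:
    """Manifest of a built image dataset plus its run configuration."""

    frame: pd.DataFrame
    config: dict

    @property
    def train(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == "train"]

    @property
    def val(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == "val"]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.frame.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "run_config.json").write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "DatasetManifest":
        out_dir = Path(out_dir)
        frame = pd.read_csv(out_dir / "manifest.csv")
        config = json.loads((out_dir / "run_config.json").read_text())
        return cls(frame=frame, config=config)


def build_dataset(
    records: list[WaveformRecord],
    wavelet: WaveletSpec | None,
    length: int,
    out_dir: str | Path,
    train_frac: float = 0.9,
    seed: int = 0,
    fs: float | None = None,
    config: PreprocessConfig = pp.DEFAULT_CONFIG,
    record_level_split: bool = False,
) -> DatasetManifest:
    """Build an image+manifest dataset from paired PPG/ABP records.

    ``wavelet=None`` selects the no-CWT baseline (raw segment tiled into an
    image).  Records failing QC are excluded with a logged reason; segments
    whose ABP window yields no peaks are dropped and logged.  By default the
    90/10 split randomizes at segment level; ``record_level_split`` keeps
    whole records in one split for leakage-aware experiments.
    """
    if not records:
        raise ValueError("no input records")
    fs = records[0].fs if fs is None else fs
    wavelet_name = wavelet.name if wavelet is not None else "none"
    out_dir = Path(out_dir)
    img_dir = out_dir / wavelet_name / str(length)
    img_dir.mkdir(parents=True, exist_ok=True)

    scales = None
    if wavelet is not None:
        scales = default_scales(length, fs, wavelet)

    rows: list[dict] = []
    n_dropped = 0
    n_qc_failed = 0
    for record in records:
        qc = quality_check(record, fs, config)
        if not qc.passed:
            n_qc_failed += 1
            logger.info("record %s excluded by QC: %s", record.record_id, qc.reasons)
            continue
        ppg_clean = pp.preprocess_ppg(record.ppg, fs, config)
        for start, stop in segment_indices(record.n_samples, length):
            try:
                label = pp.label_segment(record.abp[start:stop], fs, config)
            except (LabelingError, ValueError) as exc:
                n_dropped += 1
                logger.info("segment %s[%d:%d] dropped: %s",
                            record.record_id, start, stop, exc)
                continue
            segment = ppg_clean[start:stop]
            if wavelet is None:
                img = render_raw_segment(segment)
            else:
                img = render_cwt(cwt(segment, scales, wavelet, fs))
            img_path = img_dir / f"{record.record_id}_{start:06d}.png"
            img.meta.update(record_id=record.record_id, start=start, length=length)
            save_image(img, img_path)
            rows.append({
                "image_path": str(img_path),
                "split": "",
                "record_id": record.record_id,
                "start": start,
                "length": length,
                "sbp": label.sbp,
                "dbp": label.dbp,
                "category": label.category.name,
                "binary": label.binary,
                "wavelet": wavelet_name,
                "seed": seed,
            })
    if not rows:
        raise RuntimeError(
            f"no segments survived: {n_qc_failed} records failed QC, "
            f"{n_dropped} segments dropped"
        )
    frame = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    if record_level_split:
        rec_ids = sorted(frame["record_id"].unique())
        tr_idx, _ = split(len(rec_ids), train_frac, seed)
        train_ids = {rec_ids[i] for i in tr_idx}
        frame["split"] = np.where(frame["record_id"].isin(train_ids), "train", "val")
    else:
        tr_idx, va_idx = split(len(frame), train_frac, seed)
        splits = np.empty(len(frame), dtype=object)
        splits[tr_idx] = "train"
        splits[va_idx] = "val"
        frame["split"] = splits
    run_config = {
        "wavelet": wavelet_name,
        "length": length,
        "train_frac": train_frac,
        "seed": seed,
        "fs": fs,
        "n_records": len(records),
        "n_qc_failed": n_qc_failed,
        "n_dropped_segments": n_dropped,
        "record_level_split": record_level_split,
        "scales": scales.tolist() if scales is not None else None,
    }
    manifest = DatasetManifest(frame=frame, config=run_config)
    manifest.save(out_dir)
    return manifest
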