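"""Synthetic paired PPG/ABP waveform generator.

Produces quasi-periodic arterial blood pressure (ABP) beat trains with
exact systolic/diastolic targets and a photoplethysmogram (PPG) whose
pulse morphology is coupled to the blood-pressure targets, so that every
downstream stage (labeling, scalogram rendering, classification) can be
exercised without access to clinical waveform databases.

The ABP beat is a piecewise template: a raised-cosine systolic upstroke
occupying ~30% of the beat followed by an exponential diastolic decay
back to the trough.  The PPG beat is a sum of two Gaussian bumps (the
systolic wave and a dicrotic secondary wave); the systolic width grows
affinely with SBP and the dicrotic depth with DBP.  This coupling is a
declared fixture that makes the normal/abnormal regimes separable by a
classifier; it makes no claim of hemodynamic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

DEFAULT_FS = 125.0

# Abnormal-heavy default mix mirrors the published cohort proportions
# (normal 1641 : elevated 1739 : stage1 2692 : stage2 334).
DEFAULT_CATEGORY_MIX = (0.2562, 0.2715, 0.4202, 0.0521)

_UPSTROKE_FRACTION = 0.3     # fraction of the beat spent on the systolic rise
_DECAY_RATE = 3.0            # exponential diastolic decay constant (per beat)
_HR_JITTER = 0.02            # per-beat period perturbation, fraction


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generator settings for one synthetic subject."""

    sbp_target: float
    dbp_target: float
    heart_rate: float = 70.0
    wander_amplitude: float = 0.0   # fraction of unit pulse amplitude
    wander_frequency: float = 0.25  # Hz, respiratory band
    noise_sd: float = 0.0           # fraction of pulse amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sbp_target > self.dbp_target > 0):
            raise ValueError(
                f"require sbp_target > dbp_target > 0, got "
                f"{self.sbp_target}/{self.dbp_target}"
            )
        if not (30.0 <= self.heart_rate <= 220.0):
            raise ValueError(f"heart_rate {self.heart_rate} outside [30, 220]")
        if not (0.1 <= self.wander_frequency <= 0.5):
            raise ValueError(
                f"wander_frequency {self.wander_frequency} outside respiratory "
                "band [0.1, 0.5] Hz"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class WaveformRecord:
    """Paired PPG (arbitrary units) and ABP (mmHg) series at fixed fs."""

    ppg: np.ndarray
    abp: np.ndarray
    fs: float
    profile: SubjectProfile
    record_id: str = "rec"

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.shape != self.abp.shape:
            raise ValueError("ppg and abp must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.ppg.size)


def _beat_boundaries(
    profile: SubjectProfile, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative beat start indices covering [0, n_samples).

    Each beat period is the nominal heart-rate period perturbed by up to
    +/-2% so segments are not perfectly periodic.
    """
    period = fs * 60.0 / profile.heart_rate  # samples
    starts = [0]
    while starts[-1] < n_samples:
        jitter = 1.0 + _HR_JITTER * rng.uniform(-1.0, 1.0)
        starts.append(starts[-1] + max(4, int(round(period * jitter))))
    return np.asarray(starts, dtype=int)


def _abp_beat(n: int, sbp: float, dbp: float) -> np.ndarray:
    """One ABP beat: raised-cosine upstroke then exponential decay to dbp."""
    n_up = max(2, int(round(_UPSTROKE_FRACTION * n)))
    n_down = n - n_up
    u = np.arange(n_up) / (n_up - 1)  # endpoint included: peak hits sbp exactly
    upstroke = dbp + (sbp - dbp) * 0.5 * (1.0 - np.cos(np.pi * u))
    if n_down <= 0:
        return upstroke[:n]
    v = np.arange(1, n_down + 1) / n_down
    # normalized so the decay starts at sbp (v=0 limit) and ends exactly at dbp
    decay = dbp + (sbp - dbp) * (np.exp(-_DECAY_RATE * v) - np.exp(-_DECAY_RATE)) / (
        1.0 - np.exp(-_DECAY_RATE)
    )
    return np.concatenate([upstroke, decay])


def generate_abp(
    profile: SubjectProfile, n_samples: int, fs: float = DEFAULT_FS
) -> np.ndarray:
    """Generate a quasi-periodic ABP beat train in mmHg.

    With ``noise_sd == 0`` every complete beat attains its maximum at
    exactly ``sbp_target`` and its minimum at ``dbp_target``.
    Deterministic given ``profile.seed``.
    """
    period = int(round(fs * 60.0 / profile.heart_rate))
    if n_samples < period:
        raise ValueError(
            f"n_samples={n_samples} shorter than one beat period "
            f"({period} samples at {profile.heart_rate} bpm)"
        )
    rng = np.random.default_rng(profile.seed)
    starts = _beat_boundaries(profile, n_samples, fs, rng)
    abp = np.empty(starts[-1] + 1, dtype=float)
    for s0, s1 in zip(starts[:-1], starts[1:]):
        abp[s0:s1] = _abp_beat(s1 - s0, profile.sbp_target, profile.dbp_target)
    abp = abp[:n_samples]
    if profile.noise_sd > 0:
        pulse = profile.sbp_target - profile.dbp_target
        abp = abp + rng.normal(0.0, profile.noise_sd * pulse, size=n_samples)
    return abp


def _ppg_beat(n: int, sbp: float, dbp: float) -> np.ndarray:
    """One PPG pulse: systolic Gaussian + dicrotic secondary wave.

    Systolic width is affine in SBP, dicrotic amplitude affine in DBP, so
    morphology varies monotonically with the blood-pressure targets.
    """
    u = (np.arange(n) + 0.5) / n
    sigma_s = np.clip(0.08 + 8e-4 * (sbp - 110.0), 0.05, 0.20)
    dicrotic = np.clip(0.25 + 5e-3 * (dbp - 72.0), 0.05, 0.60)
    beat = np.exp(-0.5 * ((u - 0.30) / sigma_s) ** 2)
    beat += dicrotic * np.exp(-0.5 * ((u - 0.70) / 0.10) ** 2)
    return beat


def generate_ppg(
    abp: np.ndarray, profile: SubjectProfile, fs: float = DEFAULT_FS
) -> np.ndarray:
    """Generate a PPG series beat-synchronized with ``abp``.

    Beat boundaries are recovered from the ABP troughs, then each beat is
    filled with the BP-coupled pulse template; sinusoidal baseline wander
    at ``wander_frequency`` and white Gaussian noise are added on top.
    Deterministic given ``profile.seed``.
    """
    abp = np.asarray(abp, dtype=float)
    if abp.size == 0:
        raise ValueError("abp must be nonempty")
    from .preprocess import detect_peaks_troughs  # local import: no cycle at load

    _, troughs = detect_peaks_troughs(abp, fs)
    bounds = np.concatenate([[0], troughs, [abp.size]])
    bounds = np.unique(bounds)
    rng = np.random.default_rng(profile.seed + 1)  # decoupled from ABP noise draws
    ppg = np.empty(abp.size, dtype=float)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        if s1 > s0:
            ppg[s0:s1] = _ppg_beat(s1 - s0, profile.sbp_target, profile.dbp_target)
    t = np.arange(abp.size) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if profile.wander_amplitude > 0:
        ppg = ppg + profile.wander_amplitude * np.sin(
            2.0 * np.pi * profile.wander_frequency * t + phase
        )
    if profile.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, profile.noise_sd, size=abp.size)
    return ppg


def generate_record(
    profile: SubjectProfile,
    n_samples: int,
    fs: float = DEFAULT_FS,
    record_id: str = "rec",
) -> WaveformRecord:
    """Generate one paired PPG/ABP record."""
    abp = generate_abp(profile, n_samples, fs)
    ppg = generate_ppg(abp, profile, fs)
    return WaveformRecord(ppg=ppg, abp=abp, fs=fs, profile=profile, record_id=record_id)


ARTIFACT_KINDS = ("flatline", "dropout", "spike")


def inject_artifact(
    record: WaveformRecord,
    kind: str,
    start: int,
    span: int,
    channel: str = "ppg",
) -> WaveformRecord:
    """Return a copy of ``record`` with an artifact injected into one channel.

    flatline: constant (last pre-artifact value) over the span;
    dropout: zeros; spike: large-amplitude transient (10x signal range).
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected {ARTIFACT_KINDS}")
    if span < 0 or start < 0 or start + span > record.n_samples:
        raise ValueError(
            f"artifact window [{start}, {start + span}) outside record "
            f"of {record.n_samples} samples"
        )
    ppg = record.ppg.copy()
    abp = record.abp.copy()
    x = ppg if channel == "ppg" else abp
    if span > 0:
        if kind == "flatline":
            x[start : start + span] = x[start]
        elif kind == "dropout":
            x[start : start + span] = 0.0
        else:  # spike
            rng_range = np.ptp(x) if np.ptp(x) > 0 else 1.0
            mid = start + span // 2
            x[mid] = x[mid] + 10.0 * rng_range
    return WaveformRecord(
        ppg=ppg, abp=abp, fs=record.fs, profile=record.profile,
        record_id=record.record_id,
    )


# Representative (SBP, DBP) sampling boxes per ACC/AHA category, chosen so
# that any draw labels back to the intended category.
_CATEGORY_BOXES = {
    0: ((104.0, 118.0), (62.0, 78.0)),   # normal
    1: ((120.0, 129.0), (62.0, 78.0)),   # elevated
    2: ((130.0, 139.0), (80.0, 88.0)),   # stage 1
    3: ((142.0, 170.0), (92.0, 105.0)),  # stage 2
}


def _category_counts(n_records: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n_records across categories."""
    mix_arr = np.asarray(mix, dtype=float)
    if mix_arr.size != 4 or np.any(mix_arr < 0) or mix_arr.sum() == 0:
        raise ValueError("category_mix must be 4 nonnegative proportions, sum > 0")
    mix_arr = mix_arr / mix_arr.sum()
    raw = mix_arr * n_records
    counts = np.floor(raw).astype(int)
    remainder = n_records - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def generate_dataset(
    n_records: int,
    category_mix: tuple[float, ...] = DEFAULT_CATEGORY_MIX,
    base_seed: int = 0,
    n_samples: int = 3750,
    fs: float = DEFAULT_FS,
    heart_rate: float = 70.0,
    wander_amplitude: float = 0.0,
    noise_sd: float = 0.0,
) -> list[WaveformRecord]:
    """Generate a cohort of records spanning the four BP categories.

    Per-record seeds are ``base_seed + index``; with noiseless settings the
    downstream labeler recovers exactly the intended categories.
    """
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    if n_records == 0:
        return []
    counts = _category_counts(n_records, category_mix)
    records: list[WaveformRecord] = []
    idx = 0
    for cat, count in enumerate(counts):
        (s_lo, s_hi), (d_lo, d_hi) = _CATEGORY_BOXES[cat]
        for _ in range(count):
            seed = base_seed + idx
            rng = np.random.default_rng((base_seed, idx))  # BP draws only
            profile = SubjectProfile(
                sbp_target=round(rng.uniform(s_lo, s_hi), 1),
                dbp_target=round(rng.uniform(d_lo, d_hi), 1),
                heart_rate=heart_rate,
                wander_amplitude=wander_amplitude,
                noise_sd=noise_sd,
                seed=seed,
            )
            records.append(
                generate_record(profile, n_samples, fs, record_id=f"rec{idx:04d}")
            )
            idx += 1
    return records


def write_record(record: WaveformRecord, path: str | Path) -> None:
    """Write a record as two-column CSV (ppg, abp) + JSON profile sidecar."""
    path = Path(path)
    data = np.column_stack([record.ppg, record.abp])
    np.savetxt(path, data, delimiter=",", header="ppg,abp", comments="")
    meta = {
        "fs": record.fs,
        "record_id": record.record_id,
        "profile": asdict(record.profile),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_record(path: str | Path) -> WaveformRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    profile = SubjectProfile(**meta["profile"])
    return WaveformRecord(
        ppg=data[:, 0], abp=data[:, 1], fs=meta["fs"], profile=profile,
        record_id=meta["record_id"],
    )


def read_wfdb_record(record_name: str, pn_dir: str | None = None) -> WaveformRecord:
    """Optional reader for PhysioNet WFDB paired waveform records.

    Requires the third-party ``wfdb`` package; raises ImportError with an
    installation hint when it is absent.  Never needed for synthetic work.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb)"
        ) from exc
    rec = wfdb.rdrecord(record_name, pn_dir=pn_dir)  # pragma: no cover
    names = [s.upper() for s in rec.sig_name]  # pragma: no cover
    ppg = rec.p_signal[:, names.index("PLETH")]  # pragma: no cover
    abp = rec.p_signal[:, names.index("ABP")]  # pragma: no cover
    profile = SubjectProfile(sbp_target=120.0, dbp_target=80.0)  # pragma: no cover
    return WaveformRecord(  # pragma: no cover
        ppg=ppg, abp=abp, fs=rec.fs, profile=profile, record_id=record_name
    )
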