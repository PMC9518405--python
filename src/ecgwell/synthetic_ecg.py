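"""Seeded synthetic single-lead ECG cohorts.

The real study population (a small nursing-home cohort measured daily with a
station-based device) is not publicly distributable, so this module produces
ECG-like records with the same external characteristics: 500 Hz sampling,
20-25 s duration, one record per subject-day, and a self-rated health index
(HI) on an ordinal 1-5 scale per day.

The two wellness regimes differ in beat-to-beat *regularity*, not amplitude:
"better" records have tightly controlled inter-beat intervals and stable
beat morphology, "worse" records have larger interval jitter and per-beat
morphology perturbation, with the contrast scaled by ``class_effect``.
Amplitude ranges of the two classes deliberately overlap.

Each beat is a sum of five Gaussian bumps standing in for the P, Q, R, S and
T deflections.  This is not a clinically faithful simulator; it is a test
harness for the downstream feature extractors, which never use clinical beat
semantics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ECGRecord",
    "CohortSpec",
    "generate_record",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

BETTER = "better"
WORSE = "worse"

# (amplitude [mV-like], center offset from R peak [s], width [s]) per deflection
_BEAT_TEMPLATE = (
    (0.15, -0.200, 0.025),  # P
    (-0.12, -0.030, 0.010),  # Q
    (1.00, 0.000, 0.012),  # R
    (-0.22, 0.030, 0.012),  # S
    (0.30, 0.250, 0.045),  # T
)

_BASE_RR_JITTER_SD_S = 0.015
_BASE_MORPH_JITTER = 0.03


@dataclass(frozen=True)
class ECGRecord:
    """One subject-day raw ECG trace plus its self-rated health index."""

    samples: np.ndarray
    fs: float
    subject_id: str
    day_index: int
    hi: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("ECGRecord samples must be finite")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort (subjects x days grid of records)."""

    n_subjects: int = 11
    days_per_subject: int = 90
    fs: float = 500.0
    duration_range_s: tuple[float, float] = (20.0, 25.0)
    class_effect: float = 1.0
    seed: int = 0
    # Ordinal distribution the first HI of each subject is drawn from, and
    # that fresh draws revert to; day-to-day persistence makes the series
    # autocorrelated so that a one-day-forward label still carries signal.
    hi_probs: tuple[float, ...] = (0.05, 0.20, 0.35, 0.25, 0.15)
    hi_persistence: float = 0.6
    snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.days_per_subject < 1:
            raise InvalidArgumentError("n_subjects and days_per_subject must be >= 1")
        if self.class_effect < 0:
            raise InvalidArgumentError("class_effect must be >= 0")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise InvalidArgumentError("duration_range_s must satisfy 0 < min <= max")
        if len(self.hi_probs) != 5 or abs(sum(self.hi_probs) - 1.0) > 1e-9:
            raise InvalidArgumentError("hi_probs must be 5 probabilities summing to 1")
        if not 0.0 <= self.hi_persistence < 1.0:
            raise InvalidArgumentError("hi_persistence must be in [0, 1)")


def generate_record(
    fs: float,
    duration_s: float,
    wellness_class: str,
    class_effect: float = 1.0,
    seed: int = 0,
    *,
    heart_rate_bpm: float = 72.0,
    snr_db: float = 20.0,
    subject_id: str = "S0",
    day_index: int = 1,
    hi: int = 3,
) -> ECGRecord:
    """Generate one quasi-periodic ECG-like record.

    The "worse" class receives inter-beat-interval jitter and per-beat
    morphology perturbation inflated by ``class_effect``; the "better" class
    keeps the baseline jitter.  Identical arguments (including ``seed``)
    reproduce identical samples.
    """
    if fs <= 0 or duration_s <= 0:
        raise InvalidArgumentError("fs and duration_s must be positive")
    if wellness_class not in (BETTER, WORSE):
        raise InvalidArgumentError(f"wellness_class must be '{BETTER}' or '{WORSE}'")
    if class_effect < 0:
        raise InvalidArgumentError("class_effect must be >= 0")

    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs

    base_rr = 60.0 / heart_rate_bpm
    if wellness_class == WORSE:
        rr_sd = _BASE_RR_JITTER_SD_S * (1.0 + 2.0 * class_effect)
        morph_sd = _BASE_MORPH_JITTER * (1.0 + class_effect)
    else:
        rr_sd = _BASE_RR_JITTER_SD_S
        morph_sd = _BASE_MORPH_JITTER

    # Beat onset times: cumulative jittered RR intervals, clipped to stay
    # physiologic (no negative or implausibly long intervals).
    r_times = []
    rr_intervals = []
    t_beat = float(rng.uniform(0.0, base_rr))
    while t_beat < duration_s + 0.5:
        r_times.append(t_beat)
        rr = float(np.clip(base_rr + rng.normal(0.0, rr_sd), 0.30, 2.0))
        rr_intervals.append(rr)
        t_beat += rr

    x = np.zeros(n)
    for t_r in r_times:
        for amp, offset, width in _BEAT_TEMPLATE:
            a = amp * (1.0 + rng.normal(0.0, morph_sd))
            c = t_r + offset * (1.0 + rng.normal(0.0, morph_sd))
            w = width * (1.0 + abs(rng.normal(0.0, morph_sd)))
            lo = np.searchsorted(t, c - 5 * w)
            hi_idx = np.searchsorted(t, c + 5 * w)
            if lo < hi_idx:
                x[lo:hi_idx] += a * np.exp(-0.5 * ((t[lo:hi_idx] - c) / w) ** 2)

    rms = np.sqrt(np.mean(x**2))
    noise_sd = rms / (10.0 ** (snr_db / 20.0)) if rms > 0 else 0.0
    x = x + rng.normal(0.0, noise_sd, size=n)

    return ECGRecord(
        samples=x,
        fs=fs,
        subject_id=subject_id,
        day_index=day_index,
        hi=hi,
        meta={
            "wellness_class": wellness_class,
            "rr_intervals_s": np.array(rr_intervals[:-1]),
            "seed": seed,
        },
    )


def _hi_series(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Persistent ordinal HI series: keep yesterday's score with probability
    ``hi_persistence``, otherwise redraw from the subject's distribution."""
    probs = np.asarray(spec.hi_probs)
    hi = np.empty(spec.days_per_subject, dtype=int)
    hi[0] = rng.choice(5, p=probs) + 1
    for d in range(1, spec.days_per_subject):
        if rng.uniform() < spec.hi_persistence:
            hi[d] = hi[d - 1]
        else:
            hi[d] = rng.choice(5, p=probs) + 1
    return hi


def generate_cohort(spec: CohortSpec) -> list[ECGRecord]:
    """Generate one record per subject-day, fully reproducible under the seed.

    The waveform regime is tied monotonically to the health index: days at or
    above the subject's median HI are generated in the "better" (regular)
    regime, days below in the "worse" regime — mirroring the binarization the
    labeling stage applies downstream.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seqs = root.spawn(spec.n_subjects)
    records: list[ECGRecord] = []
    for j, seq in enumerate(subject_seqs):
        subject_id = f"S{j:03d}"
        rng = np.random.default_rng(seq)
        hi = _hi_series(rng, spec)
        median_hi = float(np.median(hi))
        record_seeds = rng.integers(0, 2**31 - 1, size=spec.days_per_subject)
        for d in range(spec.days_per_subject):
            duration = float(rng.uniform(*spec.duration_range_s))
            wellness_class = BETTER if hi[d] >= median_hi else WORSE
            records.append(
                generate_record(
                    fs=spec.fs,
                    duration_s=duration,
                    wellness_class=wellness_class,
                    class_effect=spec.class_effect,
                    seed=int(record_seeds[d]),
                    snr_db=spec.snr_db,
                    subject_id=subject_id,
                    day_index=d + 1,
                    hi=int(hi[d]),
                )
            )
    return records


def write_cohort(records: Sequence[ECGRecord], out_dir: str | Path) -> Path:
    """Write one CSV per record (time_s, amplitude) plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "day_index", "hi", "fs", "file"])
        for rec in records:
            fname = f"{rec.subject_id}_day{rec.day_index:03d}.csv"
            writer.writerow([rec.subject_id, rec.day_index, rec.hi, rec.fs, fname])
            t = np.arange(len(rec.samples)) / rec.fs
            np.savetxt(
                out_dir / fname,
                np.column_stack([t, rec.samples]),
                delimiter=",",
                header="time_s,amplitude",
                comments="",
            )
    return manifest


def read_cohort(in_dir: str | Path) -> list[ECGRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    records = []
    with open(in_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.loadtxt(in_dir / row["file"], delimiter=",", skiprows=1)
            records.append(
                ECGRecord(
                    samples=data[:, 1],
                    fs=float(row["fs"]),
                    subject_id=row["subject_id"],
                    day_index=int(row["day_index"]),
                    hi=int(row["hi"]),
                )
            )
    return records
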