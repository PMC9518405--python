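"""Assembly of the full 184-dimensional feature vector.

Canonical ordering: F1-F26 time/frequency statistics, F27-F34 wavelet-packet
band energies, F35-F164 per-IMF time-domain statistics (IMF-major: all 13
statistics of IMF1 first), F165-F184 the RCMSE curve at scales 1..20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ExtractionError
from .features_eemd import EEMDConfig, eemd_features
from .features_rcmse import RCMSEParams, rcmse_features
from .features_timefreq import timefreq_features
from .features_wavelet import wavelet_packet_energy
from .preprocess import SegmentDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "FeatureConfig",
    "extract_all",
    "extract_matrix",
    "matrix_to_frame",
]

N_FEATURES = 184
FEATURE_NAMES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, N_FEATURES + 1))

# 1-based inclusive index ranges; they partition 1..184
FEATURE_GROUPS: dict[str, tuple[int, int]] = {
    "timefreq": (1, 26),
    "wavelet": (27, 34),
    "eemd": (35, 164),
    "rcmse": (165, 184),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Per-family extractor settings used by :func:`extract_all`."""

    wavelet_name: str = "db4"
    wavelet_level: int = 3
    eemd: EEMDConfig = field(default_factory=EEMDConfig)
    rcmse: RCMSEParams = field(default_factory=RCMSEParams)


def extract_all(
    x: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> np.ndarray:
    """The full 184-vector for one segment, deterministic under fixed seeds."""
    config = config or FeatureConfig()
    parts = []
    for family, fn in (
        ("timefreq", lambda: timefreq_features(x, fs)),
        (
            "wavelet",
            lambda: wavelet_packet_energy(
                x, config.wavelet_name, config.wavelet_level
            ),
        ),
        ("eemd", lambda: eemd_features(x, config.eemd)),
        ("rcmse", lambda: rcmse_features(x, config.rcmse)),
    ):
        try:
            parts.append(np.asarray(fn(), dtype=float))
        except Exception as exc:  # noqa: BLE001 - aggregated with family name
            raise ExtractionError(f"feature family '{family}' failed: {exc}") from exc
    out = np.concatenate(parts)
    assert out.shape == (N_FEATURES,)
    return out


def extract_matrix(
    dataset: SegmentDataset,
    fs: float,
    config: FeatureConfig | None = None,
    log_every: int = 200,
) -> np.ndarray:
    """Row-per-segment feature matrix (n x 184), preserving dataset order."""
    config = config or FeatureConfig()
    n = dataset.n
    rows = np.empty((n, N_FEATURES))
    for i in range(n):
        try:
            rows[i] = extract_all(dataset.X[i], fs, config)
        except ExtractionError as exc:
            raise ExtractionError(f"row {i}: {exc}") from exc
        if log_every and (i + 1) % log_every == 0:
            logger.info("extracted features for %d / %d segments", i + 1, n)
    return rows


def matrix_to_frame(
    matrix: np.ndarray, dataset: SegmentDataset | None = None
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with F1..F184 headers and, when a
    dataset is given, label and provenance columns appended."""
    df = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
    if dataset is not None:
        df = pd.concat([dataset.provenance.reset_index(drop=True), df], axis=1)
        df["label"] = dataset.labels
    return df
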