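"""Wavelet-packet sub-band energies (F27-F34).

Each segment is decomposed with a full wavelet-packet tree to depth 3,
giving 2^3 = 8 terminal sub-bands of equal depth.  The feature for band w is
its energy, the sum of squared packet coefficients, with bands ordered from
lowest to highest frequency (natural frequency ordering of the terminal
nodes).

Defaults: Daubechies-4 wavelet (a common ECG choice), periodized boundary
handling so that, for orthogonal wavelets and signal lengths divisible by
2^level, the transform is orthonormal and the band energies sum exactly to
the signal energy.
"""

from __future__ import annotations

import numpy as np
import pywt

from .errors import ConfigurationError, InvalidArgumentError

__all__ = ["wavelet_packet_energy"]


def wavelet_packet_energy(
    x: np.ndarray,
    wavelet_name: str = "db4",
    level: int = 3,
    mode: str = "periodization",
) -> np.ndarray:
    """Energies of the 2^level terminal wavelet-packet bands, low to high."""
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ConfigurationError("level must be >= 1")
    if len(x) < 2**level:
        raise InvalidArgumentError(f"need at least {2 ** level} samples")
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}") from exc
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode=mode, maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    return np.array([float(np.sum(node.data**2)) for node in nodes])
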