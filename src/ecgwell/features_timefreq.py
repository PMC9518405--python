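"""Time-domain and frequency-domain statistical features (F1-F26).

Thirteen waveform-shape statistics are computed on the raw segment and the
same thirteen on its one-sided FFT amplitude spectrum, giving 26 features.

The thirteen statistics, in fixed order::

    F1  x_av   mean absolute value
    F2  x_p    peak (max |x|)
    F3  x_pp   peak-to-peak (max - min)
    F4  D_x    mean squared deviation from x_av (deviation taken about the
               absolute mean, not the ordinary mean)
    F5  x_r    root amplitude, (mean sqrt|x|)^2
    F6  C_f    crest factor, x_p / x_rms
    F7  SK_f   skewness, m3 / sigma^3
    F8  K_f    kurtosis, m4 / sigma^4
    F9  S_f    shape factor, x_rms / x_av
    F10 CL_f   clearance factor, x_p / x_r
    F11 I_f    impulse factor, x_p / x_av
    F12 x_rms  root mean square
    F13 K_x    D_x / x_av

D_x and K_x are deliberately non-standard (centered on the absolute mean;
a variance-over-mean ratio labeled a variation coefficient): they are kept
in this form for fidelity to the feature set this pipeline reproduces.
Ratio statistics with a zero denominator (an all-zero segment, say) are set
to 0 and a degenerate-input warning is logged, so feature matrices stay
rectangular on pathological inputs.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "STAT_NAMES",
    "time_domain_stats",
    "amplitude_spectrum",
    "frequency_domain_stats",
    "timefreq_features",
]

STAT_NAMES = (
    "x_av",
    "x_p",
    "x_pp",
    "D_x",
    "x_r",
    "C_f",
    "SK_f",
    "K_f",
    "S_f",
    "CL_f",
    "I_f",
    "x_rms",
    "K_x",
)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        logger.warning("degenerate input: zero denominator for %s; returning 0", name)
        return 0.0
    return num / den


def time_domain_stats(x: np.ndarray) -> np.ndarray:
    """The 13 shape statistics of one segment, in :data:`STAT_NAMES` order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InvalidArgumentError("input must be 1-D with length >= 2")
    if not np.any(x):
        # all-zero input: every ratio denominator is zero -> all statistics 0
        logger.warning("degenerate input: all-zero signal; statistics set to 0")
        return np.zeros(13)

    abs_x = np.abs(x)
    x_av = float(np.mean(abs_x))
    x_p = float(np.max(abs_x))
    x_pp = float(np.max(x) - np.min(x))
    d_x = float(np.mean((x - x_av) ** 2))
    x_r = float(np.mean(np.sqrt(abs_x)) ** 2)
    x_rms = float(np.sqrt(np.mean(x**2)))

    mu = float(np.mean(x))
    m2 = float(np.mean((x - mu) ** 2))
    m3 = float(np.mean((x - mu) ** 3))
    m4 = float(np.mean((x - mu) ** 4))
    sigma = np.sqrt(m2)

    c_f = _safe_ratio(x_p, x_rms, "C_f")
    sk_f = _safe_ratio(m3, sigma**3, "SK_f")
    k_f = _safe_ratio(m4, sigma**4, "K_f")
    s_f = _safe_ratio(x_rms, x_av, "S_f")
    cl_f = _safe_ratio(x_p, x_r, "CL_f")
    i_f = _safe_ratio(x_p, x_av, "I_f")
    k_x = _safe_ratio(d_x, x_av, "K_x")

    return np.array(
        [x_av, x_p, x_pp, d_x, x_r, c_f, sk_f, k_f, s_f, cl_f, i_f, x_rms, k_x]
    )


def amplitude_spectrum(x: np.ndarray, fs: float, include_dc: bool = True) -> np.ndarray:
    """One-sided FFT amplitude spectrum, scaled so a pure sinusoid of
    amplitude A contributes a bin of height ~A."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) / n
    # double the interior bins to fold negative frequencies in
    if n % 2 == 0:
        spec[1:-1] *= 2.0
    else:
        spec[1:] *= 2.0
    return spec if include_dc else spec[1:]


def frequency_domain_stats(
    x: np.ndarray, fs: float, include_dc: bool = True
) -> np.ndarray:
    """The same 13 statistics applied to the amplitude spectrum of ``x``."""
    return time_domain_stats(amplitude_spectrum(x, fs, include_dc=include_dc))


def timefreq_features(x: np.ndarray, fs: float) -> np.ndarray:
    """F1-F26: time-domain statistics followed by frequency-domain statistics."""
    return np.concatenate([time_domain_stats(x), frequency_domain_stats(x, fs)])
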