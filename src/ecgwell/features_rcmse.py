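"""Refined composite multiscale sample entropy (F165-F184).

Sample entropy of a series y with embedding dimension m and tolerance r is
-ln(A/B), where B counts pairs of m-length templates within Chebyshev
distance r of each other and A counts the same for (m+1)-length templates
(self-matches excluded; both counts range over the first N-m templates, the
standard convention that keeps the two scales comparable).

Multiscale entropy evaluates this on coarse-grained versions of the series
(non-overlapping block means at scale tau).  The *refined composite* variant
computes match counts for every one of the tau possible coarse-graining
offsets and sums the counts across offsets before taking the logarithm:

    RCMSE(x, tau, m, r) = -ln( sum_k A_k / sum_k B_k )

which markedly reduces the incidence of undefined entropy (zero counts) on
short series compared with single-offset multiscale entropy.  At tau = 1
there is a single offset and RCMSE reduces exactly to sample entropy.

The tolerance is anchored once to the *original* series, r_abs = r * std(x),
and reused at every scale — the standard multiscale-entropy convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "RCMSEParams",
    "EntropyCurve",
    "coarse_grain",
    "sample_entropy_counts",
    "sample_entropy",
    "rcmse",
    "rcmse_features",
]


@dataclass(frozen=True)
class RCMSEParams:
    """Embedding dimension m, tolerance r (fraction of std), max scale."""

    m: int = 2
    r: float = 0.15
    tau_max: int = 20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidArgumentError("m must be >= 1")
        if self.r <= 0:
            raise InvalidArgumentError("r must be > 0")
        if self.tau_max < 1:
            raise InvalidArgumentError("tau_max must be >= 1")


@dataclass
class EntropyCurve:
    """RCMSE values indexed by scale tau = 1..tau_max.

    ``undefined[t]`` flags scales where a zero match count made the entropy
    undefined; such values are imputed as 0 and logged.
    """

    values: np.ndarray
    undefined: np.ndarray


def coarse_grain(x: np.ndarray, tau: int, k: int = 1) -> np.ndarray:
    """Non-overlapping block means at scale ``tau`` starting at offset ``k``
    (1-based, 1 <= k <= tau).  Output length floor((len(x) - k + 1) / tau)."""
    x = np.asarray(x, dtype=float)
    if tau < 1 or len(x) < tau:
        raise InvalidArgumentError("need tau >= 1 and len(x) >= tau")
    if not 1 <= k <= tau:
        raise InvalidArgumentError(f"offset k={k} outside 1..{tau}")
    seg = x[k - 1 :]
    n_blocks = len(seg) // tau
    return seg[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sample_entropy_counts(
    y: np.ndarray, m: int, r_abs: float
) -> tuple[int, int]:
    """Template match counts (B_m, B_{m+1}) for sample entropy.

    Both counts range over the N-m templates starting at positions
    1..N-m; a pair matches when the Chebyshev distance between the two
    templates is <= ``r_abs``.  Self-matches are excluded (pairs i < j).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < m + 2:
        raise InvalidArgumentError(f"series length {n} < m + 2 = {m + 2}")
    emb = sliding_window_view(y, m + 1)  # (n - m, m + 1)
    d_m = cdist(emb[:, :m], emb[:, :m], metric="chebyshev")
    d_m1 = cdist(emb, emb, metric="chebyshev")
    iu = np.triu_indices(len(emb), k=1)
    b_m = int(np.count_nonzero(d_m[iu] <= r_abs))
    b_m1 = int(np.count_nonzero(d_m1[iu] <= r_abs))
    return b_m, b_m1


def sample_entropy(y: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy -ln(B_{m+1}/B_m); 0 when either count is zero."""
    if r_abs is None:
        r_abs = 0.15 * float(np.std(y))
    b_m, b_m1 = sample_entropy_counts(y, m, r_abs)
    if b_m == 0 or b_m1 == 0:
        return 0.0
    return float(-np.log(b_m1 / b_m))


def rcmse(x: np.ndarray, params: RCMSEParams | None = None) -> EntropyCurve:
    """Refined composite multiscale sample entropy over tau = 1..tau_max."""
    params = params or RCMSEParams()
    x = np.asarray(x, dtype=float)
    if len(x) < (params.m + 2) * params.tau_max:
        raise InvalidArgumentError(
            f"series length {len(x)} < (m + 2) * tau_max = "
            f"{(params.m + 2) * params.tau_max}"
        )
    r_abs = params.r * float(np.std(x))
    values = np.zeros(params.tau_max)
    undefined = np.zeros(params.tau_max, dtype=bool)
    for tau in range(1, params.tau_max + 1):
        total_b = total_a = 0
        for k in range(1, tau + 1):
            b_m, b_m1 = sample_entropy_counts(coarse_grain(x, tau, k), params.m, r_abs)
            total_b += b_m
            total_a += b_m1
        if total_b == 0 or total_a == 0:
            logger.warning("undefined entropy at tau=%d (zero match count); imputing 0", tau)
            undefined[tau - 1] = True
            values[tau - 1] = 0.0
        else:
            values[tau - 1] = -np.log(total_a / total_b)
    return EntropyCurve(values=values, undefined=undefined)


def rcmse_features(x: np.ndarray, params: RCMSEParams | None = None) -> np.ndarray:
    """F165-F184: the entropy curve serialized in tau order (length tau_max)."""
    return rcmse(x, params or RCMSEParams()).values
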