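"""Approximate entropy (ApEn), the regularity statistic of Pincus.

For a series ``u(1..N)`` and embedding dimension ``m``, template
vectors ``x(i) = [u(i), ..., u(i+m-1)]`` are compared under the
Chebyshev (max-component) distance.  With

    C_i^m(r) = #{ j : d[x(i), x(j)] <= r } / (N - m + 1)

(self-matches included, so every count is at least one) and

    Phi_m(r) = mean_i log C_i^m(r)            (natural logarithm),

the estimator is

    ApEn(m, r, N) = Phi_m(r) - Phi_{m+1}(r).

Low values mean a regular, self-similar signal; white noise scores
high.  The tolerance ``r`` is conventionally a fixed multiple of the
series' standard deviation, which makes the statistic invariant to
translation and positive rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DataError

__all__ = ["ApEnParams", "apen", "apen_auto", "DEFAULT_K_GRID"]

#: k grid used for the knn stage; kept here only to centralise defaults.
DEFAULT_K_GRID = (3, 7, 15, 31, 63, 127, 255)

_R_POLICIES = ("per_segment", "global")


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the SD-relative ApEn computation.

    ``m`` is the embedding dimension (2 is the usual choice for
    biological signals).  ``r_multiplier`` scales the series' standard
    deviation into the match tolerance ``r``; values in 0.1-0.25 give
    statistically valid estimates, with 0.2 the default.  ``r_policy``
    selects whose SD is used: each segment's own (``per_segment``) or a
    caller-supplied SD of the full series (``global``).
    """

    m: int = 2
    r_multiplier: float = 0.2
    r_policy: str = "per_segment"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise DataError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r_multiplier <= 0:
            raise DataError(
                f"r_multiplier must be positive, got {self.r_multiplier}"
            )
        if self.r_policy not in _R_POLICIES:
            raise DataError(
                f"r_policy must be one of {_R_POLICIES}, got {self.r_policy!r}"
            )


def _phi(absdiff: np.ndarray, n: int, m: int, r: float) -> float:
    """Phi_m(r) from the precomputed |u_i - u_j| matrix."""
    nv = n - m + 1
    cheb = absdiff[:nv, :nv].copy()
    for k in range(1, m):
        np.maximum(cheb, absdiff[k : k + nv, k : k + nv], out=cheb)
    counts = np.count_nonzero(cheb <= r, axis=1)
    # self-match guarantees counts >= 1, so the log is always defined
    return float(np.mean(np.log(counts / nv)))


def apen(u: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """ApEn(m, r, N) of a real series.

    Requires ``N >= m + 2`` so that at least one template vector exists
    at dimension ``m + 1``, and ``r > 0``.  Uses the natural logarithm.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise DataError("input series must be 1-D")
    n = u.size
    if n < m + 2:
        raise DataError(f"series too short for ApEn: N={n}, need >= {m + 2}")
    if r <= 0:
        raise DataError(f"tolerance r must be positive, got {r}")
    absdiff = np.abs(np.subtract.outer(u, u))
    return _phi(absdiff, n, m, r) - _phi(absdiff, n, m + 1, r)


def apen_auto(
    u: np.ndarray,
    params: ApEnParams = ApEnParams(),
    global_sd: Optional[float] = None,
) -> tuple[float, bool]:
    """ApEn with tolerance derived from the standard deviation.

    Under the ``per_segment`` policy ``r = r_multiplier * sd(u)``; under
    ``global`` the caller supplies the SD of the full series the segment
    was cut from.  The sample SD (ddof=1) is used, matching the
    convention of the common R implementations.

    Returns ``(value, degenerate)``.  A segment with zero SD (constant
    signal) is maximally regular; it is assigned ApEn 0 and flagged
    degenerate instead of raising.
    """
    u = np.asarray(u, dtype=float)
    if params.r_policy == "global":
        if global_sd is None:
            raise DataError("global r policy requires global_sd")
        sd = float(global_sd)
    else:
        sd = float(np.std(u, ddof=1)) if u.size > 1 else 0.0
    if sd == 0.0:
        return 0.0, True
    return apen(u, params.m, params.r_multiplier * sd), False
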