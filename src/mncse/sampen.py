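"""Sample entropy and the original multiscale entropy (MSE) comparator.

SampEn(m, r) = -ln(A / B), where B counts pairs of distinct m-length
templates within Chebyshev distance r and A counts the same for
(m+1)-length templates.  Self-matches are excluded (i != j), which is
what distinguishes sample entropy from approximate entropy.  When no
template pairs match (A = 0 or B = 0) the estimate is undefined; that
failure mode on short coarse-grained series is the behavior MNCSE is
designed to avoid, so undefined values are first-class here: they are
returned as NaN markers, propagated into profiles, and counted.

In the original MSE convention the tolerance r is a fraction (default
0.15) of the standard deviation of the *scale-1* series and is held
fixed across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coarse import coarse_grain
from .signals import SignalSeries, as_values
from .symbolic import EntropyProfile

__all__ = ["SampEnParams", "sample_entropy", "mse_profile"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pair_counts_py(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Chunked numpy count of matching template pairs (fallback path)."""
    n_templates = x.size - m  # both m- and (m+1)-templates, same index range
    win = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    a = b = 0
    for i in range(n_templates - 1):
        rest = win[i + 1 :]
        match_m = np.abs(rest[:, :m] - win[i, :m]).max(axis=1) <= r
        b += int(match_m.sum())
        a += int((match_m & (np.abs(rest[:, m] - win[i, m]) <= r)).sum())
    return a, b


if _HAVE_NUMBA:

    @njit(cache=True)
    def _pair_counts_nb(x, m, r):  # pragma: no cover - jitted
        n_templates = x.shape[0] - m
        a = 0
        b = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

    def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        a, b = _pair_counts_nb(np.ascontiguousarray(x), m, float(r))
        return int(a), int(b)

else:  # pragma: no cover
    _pair_counts = _pair_counts_py


@dataclass
class SampEnParams:
    """Sample-entropy settings for MSE.

    ``m`` is the embedding (template) length; ``r_fraction`` the
    similarity criterion as a fraction of the standard deviation
    (population formula); ``r_reference`` chooses whether that SD comes
    from the scale-1 series (the original-MSE convention) or is
    recomputed per scale.
    """

    m: int = 2
    r_fraction: float = 0.15
    r_reference: str = "scale1"  # or "per_scale"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.r_fraction < 1.0:
            raise ValueError("r_fraction must be in (0, 1)")
        if self.r_reference not in ("scale1", "per_scale"):
            raise ValueError("r_reference must be 'scale1' or 'per_scale'")


def sample_entropy(
    x: SignalSeries | Sequence[float] | np.ndarray, m: int = 2, r: float = 0.15
) -> float:
    """Sample entropy of a series; NaN when no template pairs match.

    ``r`` is an absolute tolerance here — callers wanting the usual
    "fraction of SD" convention should pass ``r_fraction * x.std()``
    (or use :func:`mse_profile`).
    """
    values = as_values(x)
    if values.size <= m + 1:
        raise ValueError(
            f"series length {values.size} too short for m={m} (need > m+1)"
        )
    if r <= 0:
        raise ValueError("r must be positive")
    a, b = _pair_counts(values, int(m), float(r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(
    x: SignalSeries | Sequence[float] | np.ndarray,
    tau_max: int,
    params: SampEnParams | None = None,
) -> EntropyProfile:
    """Original MSE: sample entropy of each coarse-grained series.

    Scales whose coarse-grained series is too short (length <= m+1) or
    where no template pairs match carry NaN markers; a warning reports
    their count.
    """
    params = params or SampEnParams()
    values = as_values(x)
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    r_scale1 = params.r_fraction * float(values.std())  # population SD
    scales = np.arange(1, tau_max + 1)
    out = np.full(scales.size, np.nan)
    for i, tau in enumerate(scales):
        if values.size // tau <= params.m + 1:
            continue
        y = coarse_grain(values, tau).values
        r = (
            params.r_fraction * float(y.std())
            if params.r_reference == "per_scale"
            else r_scale1
        )
        if r <= 0:
            continue
        out[i] = sample_entropy(y, m=params.m, r=r)
    n_undef = int(np.isnan(out).sum())
    if n_undef:
        warnings.warn(
            f"MSE profile has {n_undef} undefined scale(s) "
            f"(N={values.size}, tau_max={tau_max})",
            stacklevel=2,
        )
    source_id = x.source_id if isinstance(x, SignalSeries) else None
    label = x.label if isinstance(x, SignalSeries) else None
    return EntropyProfile(
        method="MSE",
        scales=scales,
        values=out,
        params={
            "m": params.m,
            "r_fraction": params.r_fraction,
            "r_reference": params.r_reference,
        },
        source_id=source_id,
        label=label,
    )
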