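"""Coarse-graining: non-overlapping window averaging at scale tau.

This is step 1 of every multiscale entropy variant.  At scale tau the
series is partitioned into consecutive non-overlapping windows of tau
samples; each window is replaced by its mean.  The coarse-grained
length is floor(N / tau); trailing remainder samples are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signals import SignalSeries, as_values

__all__ = ["CoarseGrainedSeries", "coarse_grain", "DEFAULT_TAU_MAX_RR", "DEFAULT_TAU_MAX_NOISE"]

#: Default maximum scale for RR analyses (clinical comparisons span scales 1-15).
DEFAULT_TAU_MAX_RR = 15
#: Default maximum scale for the noise-signal validation experiments.
DEFAULT_TAU_MAX_NOISE = 20


@dataclass
class CoarseGrainedSeries:
    """A series averaged over non-overlapping windows of length ``scale``."""

    values: np.ndarray
    scale: int
    source_length: int

    def __len__(self) -> int:
        return int(self.values.size)


def coarse_grain(
    x: SignalSeries | Sequence[float] | np.ndarray, tau: int
) -> CoarseGrainedSeries:
    """Average ``x`` over non-overlapping windows of length ``tau``.

    Element j (1-based) of the result is the mean of samples
    (j-1)*tau+1 .. j*tau of the source.  ``tau = 1`` returns the source
    unchanged.
    """
    values = as_values(x)
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = values.size
    if n < tau:
        raise ValueError(
            f"series shorter than scale: length {n} < tau {tau}"
        )
    m = n // tau
    coarse = values[: m * tau].reshape(m, tau).mean(axis=1)
    return CoarseGrainedSeries(coarse, scale=int(tau), source_length=n)
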