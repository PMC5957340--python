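"""Symbolic entropy core: NCSE and its multiscale profile (MNCSE).

The measure works on the distribution of short symbol words rather
than on metric distances between templates, which is what makes it
total (defined for any series long enough to hold one word) where
sample entropy can become undefined.

Pipeline at each scale tau:

1. coarse-grain the series (see :mod:`mncse.coarse`);
2. symbolize: binary quantization, symbol 1 where the sample is >= the
   mean of the coarse-grained series at *this* scale, else 0;
3. slide a window of ``L`` symbols with step 1 and encode each window
   as a base-``xi`` integer word (least-significant symbol first);
4. Shannon entropy of the word histogram in bits, plus the
   (C_R - 1) / (2 M ln 2) small-sample bias correction, where M = xi**L
   is the number of possible words and C_R the number of words that
   actually occur ("corrected Shannon entropy", CSE);
5. normalize by the maximum CSE, attained when all M words occur
   equiprobably, giving NCSE in [0, 1].

NCSE computed across scales tau = 1..tau_max is the MNCSE profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coarse import CoarseGrainedSeries, coarse_grain
from .signals import SignalSeries, as_values

__all__ = [
    "SymbolSequence",
    "WordHistogram",
    "EntropyProfile",
    "symbolize",
    "words",
    "shannon_entropy",
    "corrected_shannon",
    "cse_max",
    "ncse",
    "ncse_series",
    "mncse_profile",
    "profiles_to_frame",
    "frame_to_profiles",
]

_LN2 = float(np.log(2.0))


@dataclass
class SymbolSequence:
    """Integer symbols in [0, xi-1] from quantizing a coarse-grained series."""

    symbols: np.ndarray
    xi: int
    scale: int = 1

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass
class WordHistogram:
    """Counts of overlapping length-``L`` words over an alphabet of size ``xi``.

    This histogram is the sufficient statistic for every entropy formula
    in the package: word index w = sum_k s[j+k] * xi**k for k = 0..L-1.
    """

    counts: np.ndarray
    L: int
    xi: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.M:
            raise ValueError("histogram must have xi**L bins")

    @property
    def M(self) -> int:
        """Number of possible words, xi**L."""
        return int(self.xi) ** int(self.L)

    @property
    def C_R(self) -> int:
        """Number of distinct words actually occurring."""
        return int((self.counts > 0).sum())

    @property
    def n_words(self) -> int:
        """Total number of words counted (= len(symbols) - L + 1)."""
        return int(self.counts.sum())


def symbolize(
    y: CoarseGrainedSeries | SignalSeries | Sequence[float],
    xi: int = 2,
    partition: Sequence[float] | None = None,
) -> SymbolSequence:
    """Quantize a (coarse-grained) series into integer symbols.

    The binary scheme (``xi = 2``) assigns symbol 1 where a sample is
    greater than or equal to the mean of this series — the threshold is
    recomputed at every scale, which makes the symbolization
    amplitude-invariant.  Alphabets with ``xi != 2`` require an explicit
    ``partition`` (xi - 1 increasing bin edges); no data-driven
    partition rule is defined for them.
    """
    values = y.values if isinstance(y, CoarseGrainedSeries) else as_values(y)
    if values.size < 1:
        raise ValueError("cannot symbolize an empty series")
    scale = y.scale if isinstance(y, CoarseGrainedSeries) else 1
    if partition is not None:
        edges = np.asarray(partition, dtype=float)
        if edges.size != xi - 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("partition must be xi-1 strictly increasing edges")
        symbols = np.digitize(values, edges, right=False)
    elif xi == 2:
        symbols = (values >= values.mean()).astype(np.int64)
    else:
        raise ValueError(
            f"unsupported quantization level xi={xi}: only the binary "
            "mean-threshold scheme is defined; pass an explicit partition"
        )
    return SymbolSequence(symbols.astype(np.int64), xi=int(xi), scale=scale)


def words(s: SymbolSequence, L: int = 3) -> WordHistogram:
    """Histogram of overlapping words of length ``L`` (step 1).

    Word j encodes symbols s[j..j+L-1] positionally, least-significant
    first: w_j = sum_k s[j+k] * xi**k.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    sym = s.symbols
    n = sym.size - L + 1
    if n < 1:
        raise ValueError(
            f"too few symbols for word length: {sym.size} symbols, L={L}"
        )
    w = np.zeros(n, dtype=np.int64)
    for k in range(L):
        w += sym[k : k + n] * (s.xi**k)
    counts = np.bincount(w, minlength=s.xi**L)
    return WordHistogram(counts, L=int(L), xi=int(s.xi))


def shannon_entropy(h: WordHistogram) -> float:
    """Shannon entropy of the word distribution, in bits."""
    if h.n_words < 1:
        raise ValueError("empty word histogram")
    p = h.counts[h.counts > 0] / h.n_words
    return float(-(p * np.log2(p)).sum())


def corrected_shannon(h: WordHistogram) -> float:
    """Bias-corrected Shannon entropy: SE + (C_R - 1) / (2 M ln 2) bits.

    The additive term is the leading-order correction for the downward
    bias of the plug-in entropy estimate; M is the number of *possible*
    words, so the correction vanishes exactly when a single word occurs
    and makes the uniform full occupation reach :func:`cse_max`.
    """
    return shannon_entropy(h) + (h.C_R - 1) / (2.0 * h.M * _LN2)


def cse_max(L: int, xi: int) -> float:
    """Maximum corrected Shannon entropy, at uniform occupation of all M words."""
    if L < 1 or xi < 2:
        raise ValueError("require L >= 1 and xi >= 2")
    M = xi**L
    return float(np.log2(M) + (M - 1) / (2.0 * M * _LN2))


def ncse(h: WordHistogram) -> float:
    """Normalized corrected Shannon entropy, in [0, 1].

    0 iff a single word occurs (constant symbol pattern); 1 iff all M
    possible words occur equiprobably.
    """
    return corrected_shannon(h) / cse_max(h.L, h.xi)


def ncse_series(
    x: SignalSeries | Sequence[float] | np.ndarray,
    L: int = 3,
    xi: int = 2,
) -> float:
    """One-shot NCSE of a raw series (the single-scale measure, tau = 1)."""
    return ncse(words(symbolize(as_values(x), xi=xi), L=L))


# ---------------------------------------------------------------------------
# Multiscale profiles

@dataclass
class EntropyProfile:
    """Per-scale entropy values for one signal and one method.

    Undefined scales (possible for MSE, and for MNCSE only when the
    coarse-grained series is shorter than one word) are stored as NaN —
    every scale carries either a finite value or this explicit marker.
    """

    method: str  # "MNCSE" or "MSE"
    scales: np.ndarray
    values: np.ndarray
    params: Mapping[str, float] = field(default_factory=dict)
    source_id: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.scales.shape != self.values.shape:
            raise ValueError("scales and values must align")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of scales carrying a finite value."""
        return np.isfinite(self.values)

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())

    def value_at(self, scale: int) -> float:
        idx = np.flatnonzero(self.scales == scale)
        if idx.size != 1:
            raise KeyError(f"scale {scale} not in profile")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "source_id": self.source_id,
                "label": self.label,
                "method": self.method,
                "scale": self.scales,
                "value": self.values,
                "defined": self.defined.astype(int),
            }
        )
        for key, val in self.params.items():
            df[key] = val
        return df


def mncse_profile(
    x: SignalSeries | Sequence[float] | np.ndarray,
    tau_max: int,
    L: int = 3,
    xi: int = 2,
) -> EntropyProfile:
    """MNCSE profile: NCSE of the coarse-grained series at tau = 1..tau_max.

    The symbolization threshold (series mean) is recomputed on each
    coarse-grained series.  A scale whose coarse-grained length is below
    ``L`` yields a NaN marker plus a warning, never an exception.
    """
    values = as_values(x)
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    scales = np.arange(1, tau_max + 1)
    out = np.full(scales.size, np.nan)
    for i, tau in enumerate(scales):
        if values.size // tau < L:
            warnings.warn(
                f"scale {tau}: coarse-grained length {values.size // tau} "
                f"< word length {L}; marking undefined",
                stacklevel=2,
            )
            continue
        out[i] = ncse(words(symbolize(coarse_grain(values, tau), xi=xi), L=L))
    source_id = x.source_id if isinstance(x, SignalSeries) else None
    label = x.label if isinstance(x, SignalSeries) else None
    return EntropyProfile(
        method="MNCSE",
        scales=scales,
        values=out,
        params={"L": L, "xi": xi},
        source_id=source_id,
        label=label,
    )


# ---------------------------------------------------------------------------
# CSV interchange (shared schema with the sample-entropy module)

def profiles_to_frame(profiles: Iterable[EntropyProfile]) -> pd.DataFrame:
    """Long-format frame: one row per (source, method, scale)."""
    frames = [p.to_frame() for p in profiles]
    if not frames:
        raise ValueError("no profiles to export")
    return pd.concat(frames, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[EntropyProfile]:
    """Rebuild profiles from the long CSV schema written by this package."""
    required = {"source_id", "method", "scale", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile frame missing columns: {sorted(missing)}")
    param_cols = [
        c for c in df.columns
        if c not in ("source_id", "label", "method", "scale", "value", "defined")
    ]
    profiles = []
    for (source_id, method), grp in df.groupby(
        ["source_id", "method"], sort=False
    ):
        grp = grp.sort_values("scale")
        label = None
        if "label" in grp.columns and grp["label"].notna().any():
            label = str(grp["label"].iloc[0])
        params = {
            c: grp[c].iloc[0]
            for c in param_cols
            if pd.notna(grp[c].iloc[0])
        }
        profiles.append(
            EntropyProfile(
                method=str(method),
                scales=grp["scale"].to_numpy(dtype=int),
                values=grp["value"].to_numpy(dtype=float),
                params=params,
                source_id=str(source_id),
                label=label,
            )
        )
    return profiles
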