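"""Reference noise generators and interbeat-interval (RR) series I/O.

White Gaussian noise (WGN) and 1/f ("pink") noise are the two canonical
test signals for multiscale entropy methods: WGN is uncorrelated, while
1/f noise carries long-range correlations and is the classic model of
healthy heart-rate dynamics.  Real analyses start from RR-interval files
(one interval per line, as distributed by Physionet-style archives).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SignalSeries",
    "generate_wgn",
    "generate_pink",
    "read_rr",
    "read_signal",
    "write_signal",
    "filter_artifacts",
]

#: RR intervals longer than this (seconds) are treated as artifacts.
DEFAULT_RR_CUTOFF = 2.0

#: Raw RR values with median above this are interpreted as milliseconds.
#: No human interbeat interval is 10 s, and none is 10 ms.
_MS_DETECTION_THRESHOLD = 10.0


@dataclass
class SignalSeries:
    """A finite, ordered sequence of real-valued samples.

    Values are dimensionless for synthetic noise and in seconds for RR
    intervals.  ``label`` is a free-text group tag (e.g. ``"NSR"``) and
    ``source_id`` identifies the subject or realization.
    """

    values: np.ndarray
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("SignalSeries requires a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SignalSeries values must all be finite")

    def __len__(self) -> int:
        return int(self.values.size)


def as_values(x: "SignalSeries | Sequence[float] | np.ndarray") -> np.ndarray:
    """Return the underlying 1-D float array of a series-like object."""
    if isinstance(x, SignalSeries):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of samples")
    return arr


def generate_wgn(n: int, seed: int, label: str | None = None) -> SignalSeries:
    """Draw ``n`` i.i.d. samples of standard white Gaussian noise.

    The same ``seed`` always yields a bitwise-identical series; an
    ensemble is built from consecutive seeds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return SignalSeries(
        rng.standard_normal(n), label=label, source_id=f"wgn-{seed}"
    )


def generate_pink(n: int, seed: int, label: str | None = None) -> SignalSeries:
    """Generate ``n`` samples of 1/f noise by FFT spectral shaping.

    Uniformly distributed white noise is transformed to the frequency
    domain, each positive-frequency amplitude is rescaled by 1/sqrt(f)
    so that power is proportional to 1/f (the DC bin is zeroed, which
    avoids a division by zero and an arbitrary offset), and the result
    is transformed back and standardized to zero mean, unit variance.
    Phases are inherited from the white-noise spectrum.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    white = rng.uniform(-0.5, 0.5, n)
    spectrum = np.fft.rfft(white)
    k = np.arange(spectrum.size, dtype=float)
    scale = np.zeros_like(k)
    scale[1:] = 1.0 / np.sqrt(k[1:])  # power ~ |amplitude|^2 ~ 1/f
    y = np.fft.irfft(spectrum * scale, n=n)
    y = (y - y.mean()) / y.std()
    return SignalSeries(y, label=label, source_id=f"pink-{seed}")


def _parse_lines(path: Path) -> tuple[np.ndarray, list[int]]:
    """Parse one float per line; '#' comments and blank lines ignored."""
    values: list[float] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable value on line {lineno}: {line!r}"
                ) from None
            linenos.append(lineno)
    if not values:
        raise ValueError(f"{path}: no numeric samples found (empty file?)")
    return np.asarray(values, dtype=float), linenos


def read_signal(path: str | Path, source_id: str | None = None) -> SignalSeries:
    """Read a plain-text signal file, one sample per line."""
    path = Path(path)
    values, _ = _parse_lines(path)
    return SignalSeries(values, source_id=source_id or path.stem)


def read_rr(
    path: str | Path,
    units_hint: str = "auto",
    source_id: str | None = None,
) -> SignalSeries:
    """Read an RR-interval file and return intervals in seconds.

    ``units_hint`` is one of ``"seconds"``, ``"milliseconds"`` or
    ``"auto"``; auto mode divides by 1000 when the median raw value
    exceeds 10 (RR files circulate in both unit conventions).
    """
    if units_hint not in ("seconds", "milliseconds", "auto"):
        raise ValueError(f"unknown units_hint: {units_hint!r}")
    path = Path(path)
    values, _ = _parse_lines(path)
    if units_hint == "milliseconds" or (
        units_hint == "auto" and np.median(values) > _MS_DETECTION_THRESHOLD
    ):
        values = values / 1000.0
    return SignalSeries(values, source_id=source_id or path.stem)


def write_signal(series: SignalSeries | np.ndarray, path: str | Path) -> None:
    """Write a series to plain text, one sample per line (repr precision)."""
    values = as_values(series)
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{float(v)!r}\n")


@dataclass
class FilterResult:
    """Artifact-filtered RR series plus the number of intervals removed."""

    series: SignalSeries
    removed: int

    def __iter__(self):  # allow ``series, removed = filter_artifacts(...)``
        return iter((self.series, self.removed))


def filter_artifacts(
    rr: SignalSeries | Sequence[float],
    max_interval: float = DEFAULT_RR_CUTOFF,
) -> FilterResult:
    """Drop non-physiological RR intervals (<= 0 s or > ``max_interval`` s).

    Order is preserved; the operation is idempotent.  Raises if every
    interval is removed, since an empty series is unusable downstream.
    """
    values = as_values(rr)
    keep = (values > 0.0) & (values <= max_interval)
    removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("artifact filter removed every interval")
    label = rr.label if isinstance(rr, SignalSeries) else None
    source_id = rr.source_id if isinstance(rr, SignalSeries) else None
    return FilterResult(
        SignalSeries(values[keep], label=label, source_id=source_id), removed
    )
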