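"""Multiscale sample entropy.

Sample entropy SampEn(m, r) is −ln(A/B), where B counts pairs of length-m
templates whose Chebyshev distance is ≤ r (self-matches excluded) and A counts
the same pairs extended to length m+1 (Richman–Moorman convention).  Multiscale
entropy evaluates SampEn on progressively coarse-grained copies of the series
(non-overlapping window means, scale factors τ = 1…20 by default) with the
tolerance fixed at ``r_frac`` × SD of the *original* series — the convention of
the physionet ``mse`` tool — so coarse scales are not silently re-normalized.

Defaults: m = 2, r_frac = 0.15, scales 1–20, computed on a 60-s window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DataInsufficiencyError,
    InvalidArgumentError,
    Recording,
)

try:  # pragma: no cover - exercised through the public API
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "SampEnParams",
    "MSECurve",
    "MSEMap",
    "coarse_grain",
    "template_counts",
    "sample_entropy",
    "mse_curve",
    "mse_map",
]


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidArgumentError("m must be ≥ 1")
        if not self.r_frac > 0:
            raise InvalidArgumentError("r_frac must be positive")


@dataclass
class MSECurve:
    scales: np.ndarray  # (n_scales,)
    values: np.ndarray  # (n_scales,), nats; NaN marks undefined entropy

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.scales.shape != self.values.shape:
            raise InvalidArgumentError("scales and values must have equal length")


@dataclass
class MSEMap:
    """Per-subject channels × scales sample entropy matrix (nats)."""

    data: np.ndarray  # (n_channels, n_scales)
    scales: np.ndarray
    channel_names: tuple[str, ...]
    params: SampEnParams = field(default_factory=SampEnParams)
    subject_id: str = ""


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Means over consecutive non-overlapping windows of length ``tau``.

    Scale 1 returns the original series; a trailing remainder shorter than
    ``tau`` is dropped.
    """
    series = np.asarray(series, dtype=float)
    if tau < 1:
        raise InvalidArgumentError("tau must be ≥ 1")
    n = series.shape[0]
    if tau > n:
        raise InvalidArgumentError(f"tau={tau} exceeds series length {n}")
    if tau == 1:
        return series.copy()
    n_out = n // tau
    return series[: n_out * tau].reshape(n_out, tau).mean(axis=1)


@njit(cache=True)
def _counts_kernel(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def template_counts(series: np.ndarray, m: int, r_abs: float) -> tuple[int, int]:
    """(A, B) template-match pair counts for m+1 and m (self-matches excluded)."""
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.shape[0] < m + 2:
        raise InvalidArgumentError("series must be at least m + 2 samples long")
    if not r_abs > 0:
        raise InvalidArgumentError("r_abs must be positive")
    a, b = _counts_kernel(x, m, r_abs)
    return int(a), int(b)


def sample_entropy(series: np.ndarray, params: SampEnParams = SampEnParams(),
                   r_abs: float | None = None) -> float:
    """SampEn in nats; NaN (flagged undefined) when no templates match.

    ``r_abs`` is the absolute amplitude tolerance; when omitted it defaults to
    ``params.r_frac`` × sample SD of ``series``.
    """
    series = np.asarray(series, dtype=float)
    if r_abs is None:
        sd = float(np.std(series, ddof=1)) if series.size > 1 else 0.0
        if sd == 0.0:
            return 0.0  # constant series: all templates match at any tolerance
        r_abs = params.r_frac * sd
    a, b = template_counts(series, params.m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(series: np.ndarray, params: SampEnParams = SampEnParams(),
              scales=range(1, 21)) -> MSECurve:
    """Sample entropy across coarse-graining scales.

    The tolerance is fixed at ``r_frac`` × SD of the original (scale-1) series
    and is *not* recomputed per scale.
    """
    series = np.asarray(series, dtype=float)
    scales = np.asarray(list(scales), dtype=int)
    max_tau = int(scales.max())
    if series.shape[0] < max_tau * (params.m + 2):
        raise InvalidArgumentError(
            f"series of length {series.shape[0]} too short for scale {max_tau}"
        )
    sd = float(np.std(series, ddof=1))
    if sd == 0.0:
        return MSECurve(scales, np.zeros(len(scales)))
    r_abs = params.r_frac * sd
    values = np.empty(len(scales))
    for i, tau in enumerate(scales):
        cg = coarse_grain(series, int(tau))
        values[i] = sample_entropy(cg, params, r_abs=r_abs)
    return MSECurve(scales, values)


def mse_map(
    rec: Recording,
    window: float = 60.0,
    params: SampEnParams = SampEnParams(),
    scales=range(1, 21),
    mode: str = "first",
    reject_threshold: float | None = None,
) -> MSEMap:
    """Channels × scales entropy map from ``window``-second stretches.

    ``mode='first'`` uses the first qualifying window; ``mode='mean'`` averages
    the curves of all complete windows.  A window qualifies when no channel
    exceeds ``reject_threshold`` μV inside it (no constraint when None).
    """
    n_win = int(round(window * rec.sfreq))
    if n_win > rec.n_samples:
        raise DataInsufficiencyError(
            f"recording ({rec.duration:.1f} s) shorter than window ({window} s)"
        )
    starts = range(0, rec.n_samples - n_win + 1, n_win)
    ok = []
    for s in starts:
        seg = rec.data[:, s : s + n_win]
        if reject_threshold is None or np.abs(seg).max() <= reject_threshold:
            ok.append(s)
        if mode == "first" and ok:
            break
    if not ok:
        raise DataInsufficiencyError("no artifact-free window of requested length")
    if mode == "first":
        ok = ok[:1]
    elif mode != "mean":
        raise InvalidArgumentError(f"unknown mode {mode!r}")

    scales = np.asarray(list(scales), dtype=int)
    acc = np.zeros((rec.n_channels, len(scales)))
    for s in ok:
        for ci in range(rec.n_channels):
            acc[ci] += mse_curve(rec.data[ci, s : s + n_win], params, scales).values
    acc /= len(ok)
    if np.isnan(acc).any():
        warnings.warn("undefined sample entropy at some (channel, scale) pixels",
                      stacklevel=2)
    return MSEMap(acc, scales, rec.montage.channel_names, params)
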