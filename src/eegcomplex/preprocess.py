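"""Reading, writing and preprocessing of continuous EEG.

Reproduces a standard resting-state preprocessing chain: resample to 500 Hz,
0.5–45 Hz zero-phase FIR bandpass, optional channel subsetting, segmentation
into fixed epochs, absolute-amplitude artifact rejection (100 μV), and common
average referencing.  Sensor neighborhoods for cluster statistics are built
from layout-plane distances or a Delaunay triangulation.
"""

from __future__ import annotations

import csv
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal, spatial

from .core import (
    DataInsufficiencyError,
    EpochSet,
    FormatError,
    InvalidArgumentError,
    Montage,
    NeighborhoodGraph,
    Recording,
)
from .edf import read_edf, write_edf

__all__ = [
    "read_layout",
    "write_layout",
    "read_recording",
    "write_recording",
    "resample",
    "bandpass",
    "segment",
    "reject_epochs",
    "average_reference",
    "build_neighborhood",
    "preprocess_chain",
]


# ---------------------------------------------------------------------------
# I/O

def read_layout(path) -> Montage:
    """Read a layout CSV with columns ``name,x,y``."""
    names, xs, ys = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "x", "y"} <= set(reader.fieldnames):
            raise FormatError("layout file must have columns name,x,y")
        for row in reader:
            try:
                names.append(row["name"])
                xs.append(float(row["x"]))
                ys.append(float(row["y"]))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"bad layout row {row!r}") from exc
    return Montage(tuple(names), np.column_stack([xs, ys]))


def write_layout(path, montage: Montage) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y"])
        for name, (x, y) in zip(montage.channel_names, montage.positions):
            writer.writerow([name, repr(float(x)), repr(float(y))])


def write_recording(path, rec: Recording, format: str = "delimited") -> None:
    """Write a recording as delimited text (samples × channels) or EDF."""
    if format == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# sfreq={rec.sfreq!r}\n")
            fh.write("\t".join(rec.montage.channel_names) + "\n")
            np.savetxt(fh, rec.data.T, fmt="%.8g", delimiter="\t")
    elif format == "edf":
        write_edf(path, rec.data, rec.sfreq, rec.montage.channel_names)
    else:
        raise InvalidArgumentError(f"unknown format {format!r}")


def read_recording(path, format: str, layout) -> Recording:
    """Read EEG in μV from EDF or delimited text, attaching the given layout.

    ``layout`` may be a Montage or a path to a ``name,x,y`` CSV.  The layout's
    channel names select (and order) the channels kept from the file; names
    absent from the file are a format error.
    """
    montage = layout if isinstance(layout, Montage) else read_layout(layout)
    if format == "edf":
        data, sfreq, names = read_edf(path)
    elif format == "delimited":
        sfreq = None
        with open(path) as fh:
            first = fh.readline().strip()
            if first.startswith("#"):
                for part in first[1:].replace(",", " ").split():
                    if part.startswith("sfreq="):
                        sfreq = float(part.split("=", 1)[1])
                header = fh.readline()
            else:
                header = first
            names = header.split()
            try:
                body = np.loadtxt(fh, ndmin=2)
            except ValueError as exc:
                raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
        if sfreq is None:
            raise FormatError("delimited recording is missing the '# sfreq=' line")
        if body.shape[1] != len(names):
            raise FormatError(
                f"{body.shape[1]} data columns but {len(names)} header names"
            )
        data = body.T
    else:
        raise InvalidArgumentError(f"unknown format {format!r}")

    lookup = {n: i for i, n in enumerate(names)}
    missing = [n for n in montage.channel_names if n not in lookup]
    if missing:
        raise FormatError(f"layout channels not present in data: {missing}")
    extra = set(names) - set(montage.channel_names)
    if extra:
        raise FormatError(f"data channels missing from layout: {sorted(extra)}")
    idx = [lookup[n] for n in montage.channel_names]
    return Recording(np.asarray(data)[idx], float(sfreq), montage)


# ---------------------------------------------------------------------------
# Preprocessing operations

def resample(rec: Recording, target_sfreq: float) -> Recording:
    """Polyphase resampling with anti-aliasing; identity when rates match."""
    if not target_sfreq > 0:
        raise InvalidArgumentError("target_sfreq must be positive")
    if abs(target_sfreq - rec.sfreq) < 1e-12:
        return rec.copy()
    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data, rec.sfreq * frac.numerator / frac.denominator, rec.montage)


def _fir_bandpass(lo: float, hi: float, sfreq: float, transition: float,
                  max_taps: int | None = None) -> np.ndarray:
    """Hamming-window FIR bandpass with the given transition bandwidth (Hz).

    Cutoffs (half-amplitude points) sit at ``lo`` and ``hi``, so the stopband
    begins roughly at ``lo − transition/2``.
    """
    numtaps = int(np.ceil(3.3 * sfreq / transition))
    if max_taps is not None:
        numtaps = min(numtaps, max_taps)
    numtaps |= 1  # odd length, linear phase type I (symmetric)
    hi_edge = min(hi, sfreq / 2 * 0.999)
    return signal.firwin(
        numtaps, [lo, hi_edge], pass_zero=False, window="hamming", fs=sfreq
    )


def _filtfilt_fft(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-pass (zero-phase) FIR filtering via FFT convolution.

    Odd-reflection padding at both ends, as ``scipy.signal.filtfilt`` does;
    FFT convolution keeps long filters affordable on long recordings.
    """
    x = np.atleast_2d(x)
    n = x.shape[-1]
    p = min(len(taps), n - 1)
    left = 2 * x[..., :1] - x[..., p:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -2 - p : -1]
    xp = np.concatenate([left, x, right], axis=-1)
    kern = taps.reshape((1,) * (x.ndim - 1) + (-1,))
    y = signal.fftconvolve(xp, kern, mode="same", axes=-1)
    y = signal.fftconvolve(y, kern[..., ::-1], mode="same", axes=-1)
    return y[..., p : p + n]


def bandpass(rec: Recording, lo: float, hi: float,
             transition: float | None = None) -> Recording:
    """Zero-phase (two-pass) FIR bandpass between ``lo`` and ``hi`` Hz.

    The default lower transition bandwidth ``min(max(lo/2, 2), lo)`` keeps the
    stopband edge at or above ``lo/2`` so that two-pass attenuation there
    exceeds 20 dB even for the 0.5 Hz high-pass edge.
    """
    nyq = rec.sfreq / 2
    if not (0 < lo < hi):
        raise InvalidArgumentError("require 0 < lo < hi")
    if hi >= nyq:
        raise InvalidArgumentError(f"hi={hi} must be below Nyquist ({nyq})")
    if transition is None:
        transition = min(max(lo / 2, 2.0), lo)
    max_taps = max((rec.n_samples - 1) // 3, 3)
    taps = _fir_bandpass(lo, hi, rec.sfreq, transition, max_taps=max_taps)
    return Recording(_filtfilt_fft(taps, rec.data), rec.sfreq, rec.montage)


def segment(rec: Recording, epoch_length: float) -> EpochSet:
    """Cut into non-overlapping consecutive epochs; trailing remainder dropped."""
    n_per = int(round(epoch_length * rec.sfreq))
    if n_per < 2:
        raise InvalidArgumentError("epoch_length × sfreq must be ≥ 2 samples")
    n_ep = rec.n_samples // n_per
    data = rec.data[:, : n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    return EpochSet(data.transpose(1, 0, 2).copy(), rec.sfreq, epoch_length, rec.montage)


def reject_epochs(ep: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Drop every epoch whose peak absolute amplitude exceeds ``threshold`` μV."""
    if not threshold > 0:
        raise InvalidArgumentError("threshold must be positive")
    if ep.n_epochs == 0:
        return ep
    keep = np.abs(ep.data).max(axis=(1, 2)) <= threshold
    if not keep.any():
        warnings.warn(
            f"all {ep.n_epochs} epochs exceeded {threshold} μV; returning empty set",
            stacklevel=2,
        )
    return EpochSet(ep.data[keep], ep.sfreq, ep.epoch_length, ep.montage)


def average_reference(obj):
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if isinstance(obj, Recording):
        if obj.n_channels < 2:
            raise InvalidArgumentError("average reference requires ≥ 2 channels")
        return Recording(obj.data - obj.data.mean(axis=0, keepdims=True),
                         obj.sfreq, obj.montage)
    if isinstance(obj, EpochSet):
        if obj.n_channels < 2:
            raise InvalidArgumentError("average reference requires ≥ 2 channels")
        return EpochSet(obj.data - obj.data.mean(axis=1, keepdims=True),
                        obj.sfreq, obj.epoch_length, obj.montage)
    raise InvalidArgumentError("expected Recording or EpochSet")


def build_neighborhood(montage: Montage, method: str = "distance",
                       radius: float | None = None) -> NeighborhoodGraph:
    """Sensor adjacency from layout distance or Delaunay triangulation.

    With ``method='distance'`` channels are neighbors iff their layout distance
    is ≤ radius (default 1.3 × median nearest-neighbor distance).
    """
    n = montage.n_channels
    if n < 2:
        raise InvalidArgumentError("neighborhood requires ≥ 2 channels")
    pos = montage.positions
    adj = np.zeros((n, n), dtype=bool)
    if method == "distance":
        dist = spatial.distance.squareform(spatial.distance.pdist(pos))
        if radius is None:
            nn = np.where(np.eye(n, dtype=bool), np.inf, dist).min(axis=1)
            radius = 1.3 * float(np.median(nn))
        if not radius > 0:
            raise InvalidArgumentError("radius must be positive")
        adj = dist <= radius
        np.fill_diagonal(adj, False)
    elif method == "delaunay":
        tri = spatial.Delaunay(pos)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                adj[a, b] = adj[b, a] = True
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return NeighborhoodGraph(adj, montage.channel_names)


def preprocess_chain(
    rec: Recording,
    *,
    target_sfreq: float = 500.0,
    band: tuple[float, float] = (0.5, 45.0),
    channel_subset: list[str] | None = None,
    epoch_length: float = 2.0,
    reject_threshold: float = 100.0,
) -> EpochSet:
    """The default preprocessing chain.

    Order: resample → bandpass → channel subset → segment → reject → average
    reference.  Returns the surviving, re-referenced epochs.
    """
    rec = resample(rec, target_sfreq)
    rec = bandpass(rec, *band)
    if channel_subset is not None:
        idx = rec.montage.index(channel_subset)
        sub = Montage(tuple(channel_subset), rec.montage.positions[idx])
        rec = Recording(rec.data[idx], rec.sfreq, sub)
    ep = segment(rec, epoch_length)
    ep = reject_epochs(ep, reject_threshold)
    if ep.n_epochs == 0:
        raise DataInsufficiencyError("no artifact-free epochs survive rejection")
    return average_reference(ep)
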