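"""Phase-amplitude coupling via the Hilbert transform and the mean-vector
modulation index.

For each (low-frequency phase band Φ, gamma amplitude band) pair the signal is
zero-phase bandpass filtered in both bands, the analytic signal supplies the
instantaneous phase φ(t) (low band) and amplitude envelope A(t) (high band),
and the modulation index is

    MI = | ⟨ A(t) · e^{iφ(t)} ⟩_t |,

the magnitude of the time-averaged composite signal, computed per 2-s epoch
and averaged across epochs.  MI is zero when amplitude is independent of
phase and grows with the coupling depth.  Raw MI scales linearly with the
amplitude of the high-frequency signal; an optional surrogate z-score mode
(circular time shifts of the envelope) removes that scale dependence.

Defaults follow the six canonical phase bands (delta 1–4, theta 4–8, low
alpha 8–10, high alpha 10–13, low beta 13–20, high beta 20–30 Hz) paired with
gamma (30–45 Hz) amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import (
    GAMMA,
    PHASE_BANDS,
    BandDefinition,
    DataInsufficiencyError,
    EpochSet,
    InvalidArgumentError,
    Recording,
)
from .preprocess import _filtfilt_fft, _fir_bandpass

__all__ = [
    "MIOptions",
    "PACMap",
    "extract_phase",
    "extract_amplitude",
    "modulation_index",
    "pac_map",
]


@dataclass
class MIOptions:
    normalization: str = "raw"  # raw | mean_amp | surrogate_z
    n_surrogates: int = 200
    epoch_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in ("raw", "mean_amp", "surrogate_z"):
            raise InvalidArgumentError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "surrogate_z" and self.n_surrogates < 100:
            raise InvalidArgumentError("surrogate_z requires n_surrogates ≥ 100")


@dataclass
class PACMap:
    """Per-subject channels × band-pairs modulation-index matrix."""

    data: np.ndarray  # (n_channels, n_pairs)
    pair_labels: tuple[str, ...]
    channel_names: tuple[str, ...]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.channel_names), len(self.pair_labels)):
            raise InvalidArgumentError("PACMap shape mismatch")
        if self.normalization in ("raw", "mean_amp") and np.any(self.data < 0):
            raise InvalidArgumentError("raw MI must be nonnegative")


def _band_filter(series: np.ndarray, band: BandDefinition, sfreq: float) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if band.hi >= sfreq / 2:
        raise InvalidArgumentError(
            f"band {band.name} upper edge {band.hi} reaches Nyquist ({sfreq / 2})"
        )
    transition = max(0.25 * band.width, 1.0)
    max_taps = max((series.shape[-1] - 1) // 3, 3)
    taps = _fir_bandpass(band.lo, band.hi, sfreq, transition, max_taps=max_taps)
    out = _filtfilt_fft(taps, series)
    return out[0] if series.ndim == 1 else out


def extract_phase(series: np.ndarray, band: BandDefinition, sfreq: float) -> np.ndarray:
    """Instantaneous phase (radians, in (−π, π]) of the band-limited signal."""
    filt = _band_filter(series, band, sfreq)
    if np.sqrt(np.mean(filt**2)) < 1e-15:
        raise DataInsufficiencyError("zero amplitude in band; phase undefined")
    return np.angle(hilbert(filt, axis=-1))


def extract_amplitude(series: np.ndarray, band: BandDefinition,
                      sfreq: float) -> np.ndarray:
    """Analytic amplitude envelope (μV, nonnegative) of the band-limited signal."""
    filt = _band_filter(series, band, sfreq)
    return np.abs(hilbert(filt, axis=-1))


def _epoch_mi(phase: np.ndarray, amp: np.ndarray, n_per: int) -> float:
    """Mean over consecutive ``n_per``-sample epochs of |⟨A·e^{iφ}⟩|."""
    n = phase.shape[-1]
    n_ep = max(n // n_per, 1)
    n_per = min(n_per, n)
    comp = amp[: n_ep * n_per] * np.exp(1j * phase[: n_ep * n_per])
    return float(np.mean(np.abs(comp.reshape(n_ep, n_per).mean(axis=1))))


def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     opts: MIOptions = MIOptions(),
                     sfreq: float | None = None) -> float:
    """Canolty-style mean-vector modulation index.

    When ``sfreq`` is given, MI is computed per ``opts.epoch_length`` epoch and
    averaged; otherwise the whole series is one epoch.  ``surrogate_z`` mode
    z-scores the observed MI against circularly time-shifted envelopes (shifts
    of at least 1 s or 10% of the series); ``mean_amp`` divides MI by the
    time-mean envelope, a cheap normalization that also removes the amplitude
    scale (and with it per-subject gain differences) from group contrasts.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape:
        raise InvalidArgumentError("phase and amplitude must have equal length")
    if phase.shape[-1] < 2:
        raise InvalidArgumentError("need at least 2 samples")
    n = phase.shape[-1]
    n_per = n if sfreq is None else max(int(round(opts.epoch_length * sfreq)), 2)
    mi = _epoch_mi(phase, amp, n_per)
    if opts.normalization == "raw":
        return mi
    if opts.normalization == "mean_amp":
        mean_amp = float(amp.mean())
        return mi / mean_amp if mean_amp > 0 else 0.0
    rng = np.random.default_rng(opts.seed)
    min_shift = max(int(sfreq) if sfreq else n // 10, n // 10, 1)
    null = np.empty(opts.n_surrogates)
    for s in range(opts.n_surrogates):
        shift = int(rng.integers(min_shift, n - min_shift)) if n > 2 * min_shift else (
            int(rng.integers(1, n))
        )
        null[s] = _epoch_mi(phase, np.roll(amp, shift), n_per)
    sd = null.std()
    return float((mi - null.mean()) / sd) if sd > 0 else 0.0


def pac_map(
    data: Recording | EpochSet,
    phase_bands=PHASE_BANDS,
    amp_band: BandDefinition = GAMMA,
    opts: MIOptions = MIOptions(),
) -> PACMap:
    """Channels × band-pairs MI map.

    A continuous ``Recording`` is the preferred input: filters and Hilbert
    transforms run on the continuous signal (a 1–4 Hz FIR needs seconds of
    data), then MI is taken per 2-s epoch and averaged.  An ``EpochSet`` is
    also accepted; each epoch is then filtered independently with transition
    bands widened to fit the epoch.
    """
    for band in phase_bands:
        if band.hi > amp_band.lo:
            raise InvalidArgumentError(
                f"phase band {band.name} overlaps amplitude band {amp_band.name}"
            )
    if isinstance(data, Recording):
        sig = data.data
        sfreq = data.sfreq
        names = data.montage.channel_names
    elif isinstance(data, EpochSet):
        if data.n_epochs == 0:
            raise DataInsufficiencyError("empty EpochSet")
        sig = data.data  # (n_ep, n_ch, n)
        sfreq = data.sfreq
        names = data.montage.channel_names
    else:
        raise InvalidArgumentError("expected Recording or EpochSet")

    n_per = max(int(round(opts.epoch_length * sfreq)), 2)
    out = np.empty((len(names), len(phase_bands)))
    amp_opts = MIOptions(opts.normalization, opts.n_surrogates, opts.epoch_length,
                         opts.seed)
    if isinstance(data, Recording):
        amp_env = extract_amplitude(sig, amp_band, sfreq)
        for bi, band in enumerate(phase_bands):
            ph = extract_phase(sig, band, sfreq)
            for ci in range(len(names)):
                out[ci, bi] = modulation_index(ph[ci], amp_env[ci], amp_opts, sfreq)
    else:
        n_ep, n_ch, _ = sig.shape
        flat = sig.reshape(n_ep * n_ch, -1)
        amp_env = extract_amplitude(flat, amp_band, sfreq)
        for bi, band in enumerate(phase_bands):
            ph = extract_phase(flat, band, sfreq)
            mis = np.empty(n_ep * n_ch)
            for r in range(n_ep * n_ch):
                mis[r] = modulation_index(ph[r], amp_env[r], amp_opts, sfreq)
            out[:, bi] = mis.reshape(n_ep, n_ch).mean(axis=0)
    labels = tuple(f"{b.name}-{amp_band.name}" for b in phase_bands)
    return PACMap(out, labels, names, opts.normalization)
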