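"""Core data containers and exceptions shared by every analysis stage.

The containers are deliberately thin: plain ``numpy`` arrays with just enough
metadata (sampling rate, montage) to keep the downstream signal-processing
honest.  Units are microvolts throughout; sensor layout coordinates live in an
arbitrary 2-D layout plane (unit disc for simulated montages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """An input file does not parse or is inconsistent with its layout."""


class DataInsufficiencyError(ValueError):
    """Not enough clean data to compute the requested quantity."""


@dataclass(frozen=True)
class Montage:
    """Sensor layout: unique channel names plus 2-D layout-plane positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise InvalidArgumentError("channel names must be unique")
        if pos.shape != (len(names), 2):
            raise InvalidArgumentError(
                f"positions must have shape ({len(names)}, 2), got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, names) -> np.ndarray:
        """Integer indices of the given channel names (order preserved)."""
        lookup = {n: i for i, n in enumerate(self.channel_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise InvalidArgumentError(f"unknown channel {exc.args[0]!r}") from exc


@dataclass
class Recording:
    """Continuous multichannel EEG: ``data`` is (n_channels, n_samples) in μV."""

    data: np.ndarray
    sfreq: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("Recording data must be 2-D (channels × samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise InvalidArgumentError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.sfreq > 0:
            raise InvalidArgumentError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sfreq, self.montage)


@dataclass
class EpochSet:
    """Segmented epochs: ``data`` is (n_epochs, n_channels, n_samples) in μV."""

    data: np.ndarray
    sfreq: float
    epoch_length: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("EpochSet data must be 3-D")
        n_expected = int(round(self.epoch_length * self.sfreq))
        if self.data.shape[0] > 0 and self.data.shape[2] != n_expected:
            raise InvalidArgumentError(
                f"epochs have {self.data.shape[2]} samples, expected {n_expected}"
            )
        if self.data.shape[1] != self.montage.n_channels:
            raise InvalidArgumentError("epoch channel count does not match montage")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class NeighborhoodGraph:
    """Symmetric, irreflexive channel adjacency used for spatial clustering."""

    adjacency: np.ndarray  # (n, n) bool
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = len(self.channel_names)
        if adj.shape != (n, n):
            raise InvalidArgumentError("adjacency shape does not match channel count")
        if not np.array_equal(adj, adj.T):
            raise InvalidArgumentError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise InvalidArgumentError("adjacency must be irreflexive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise InvalidArgumentError(
                f"band requires 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


# Canonical bands: six low-frequency phase bands and the gamma amplitude band.
DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA_LOW = BandDefinition("alpha_low", 8.0, 10.0)
ALPHA_HIGH = BandDefinition("alpha_high", 10.0, 13.0)
BETA_LOW = BandDefinition("beta_low", 13.0, 20.0)
BETA_HIGH = BandDefinition("beta_high", 20.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 45.0)

PHASE_BANDS: tuple[BandDefinition, ...] = (
    DELTA,
    THETA,
    ALPHA_LOW,
    ALPHA_HIGH,
    BETA_LOW,
    BETA_HIGH,
)
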