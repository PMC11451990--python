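"""Shared containers and errors.

Physical calibration follows wide-field imaging of yeast at the equatorial
focal plane: 65 nm effective pixel size and continuous acquisition at
1 frame per second are the package-wide defaults.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

DEFAULT_PIXEL_SIZE_NM = 65.0
DEFAULT_FRAME_INTERVAL_S = 1.0


class CmekymoError(Exception):
    """Base class for all package errors."""


class ConfigError(CmekymoError):
    """Invalid configuration or precondition violation."""


class GeometryError(CmekymoError):
    """Degenerate cell geometry (too small, over-excluded, unpaired...)."""


class FormatError(CmekymoError):
    """Unreadable or unsupported file content."""


@dataclass
class FrameStack:
    """A single-channel time-lapse: T x Y x X pixels plus calibration.

    Parameters
    ----------
    pixels : ndarray, shape (T, Y, X)
        Non-negative intensities (photon counts or camera counts).
    pixel_size_nm : float
        Lateral pixel size in nanometres.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    channel_name : str
        Free-text channel label (e.g. a tagged protein name).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    channel_name: str = "ch1"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ConfigError("FrameStack requires a T x Y x X array with T >= 1")
        if np.any(self.pixels < 0):
            raise ConfigError("FrameStack pixels must be non-negative")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ConfigError("physical calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from one top-level seed.

    Every module draws randomness from ``substream(seed, "module.purpose")``
    so that runs are reproducible from a single integer and substreams are
    statistically independent.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=(key,)))
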