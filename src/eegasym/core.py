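"""Shared domain types and constants.

The montage is the 14-channel consumer-headset subset of the 10-20 system
(CMS/DRL at P3/P4 act as the native reference and are not recorded). All
signal amplitudes are in microvolts, all times in seconds from run start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("eegasym")
if not logger.handlers:  # library default: quiet unless the app configures logging
    logger.addHandler(logging.NullHandler())

#: Channel labels in headset order.
MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Right/left hemisphere splits used to build contralateral pair universes.
ANTERIOR_RIGHT: tuple[str, ...] = ("AF4", "F4", "F8", "FC6")
ANTERIOR_LEFT: tuple[str, ...] = ("AF3", "F3", "F7", "FC5")
POSTERIOR_RIGHT: tuple[str, ...] = ("T8", "P8", "O2")
POSTERIOR_LEFT: tuple[str, ...] = ("T7", "P7", "O1")

#: The posterior sensor set that may be re-referenced to AF3 or F3.
POSTERIOR_SET: tuple[str, ...] = ("T7", "P7", "O1", "O2", "P8", "T8")

#: Scalp quadrants; the quadrant signal is the sample-wise mean of its members.
QUADRANTS: dict[str, tuple[str, ...]] = {
    "left_anterior": ("AF3", "F3", "F7", "FC5"),
    "right_anterior": ("AF4", "F4", "F8", "FC6"),
    "left_posterior": ("T7", "P7", "O1"),
    "right_posterior": ("T8", "P8", "O2"),
}

SWB_RATINGS: tuple[int, ...] = tuple(range(1, 11))


class EegasymError(Exception):
    """Base class for package errors."""


class ConfigurationError(EegasymError):
    """Invalid configuration or parameters."""


class ParseError(EegasymError):
    """Malformed input file."""


class DegenerateDataError(EegasymError):
    """Data too degenerate for the requested computation."""


@dataclass(frozen=True)
class BandDef:
    """A named frequency interval in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ConfigurationError(
                f"band {self.name}: need 0 < f_low < f_high, got "
                f"({self.f_low}, {self.f_high})"
            )


#: Canonical band table. ``non`` is the unfiltered control spanning all bands.
BANDS: dict[str, BandDef] = {
    "delta": BandDef("delta", 0.5, 3.0),
    "theta": BandDef("theta", 4.0, 7.0),
    "alpha": BandDef("alpha", 8.0, 13.0),
    "beta": BandDef("beta", 14.0, 30.0),
    "gamma": BandDef("gamma", 31.0, 100.0),
    "non": BandDef("non", 0.5, 100.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "non")


def get_band(band: "str | BandDef") -> BandDef:
    if isinstance(band, BandDef):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ConfigurationError(f"unknown band {band!r}; known: {sorted(BANDS)}")


@dataclass(frozen=True)
class SWBReport:
    """One timed subjective well-being rating (integer 1-10)."""

    time_s: float
    swb: int

    def __post_init__(self) -> None:
        if self.swb not in SWB_RATINGS:
            raise ConfigurationError(f"SWB rating must be in 1..10, got {self.swb}")


@dataclass
class Recording:
    """One participant-run of multi-channel EEG.

    ``samples`` is a (channels x time) float array in microvolts;
    ``reference`` tags the reference scheme ("original", "AF3" or "F3").
    """

    participant_id: str
    run_id: str
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    reference: str = "original"
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("duplicate channel labels")
        unknown = set(self.channel_labels) - set(MONTAGE)
        if unknown:
            raise ConfigurationError(f"labels outside the montage: {sorted(unknown)}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ConfigurationError(
                f"samples has {self.samples.shape[0]} rows for "
                f"{len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"channel {label!r} not in recording "
                f"{self.participant_id}/{self.run_id}"
            )

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.index_of(label)]

    def copy(self) -> "Recording":
        return Recording(
            participant_id=self.participant_id,
            run_id=self.run_id,
            fs=self.fs,
            channel_labels=self.channel_labels,
            samples=self.samples.copy(),
            reference=self.reference,
            bad_channels=set(self.bad_channels),
        )


@dataclass
class Epoch:
    """The analysis window ending at one SWB report.

    ``samples`` is the (channels x round(duration*fs)) slice of the parent
    recording over the half-open window [t_report - duration, t_report).
    """

    recording: Recording
    swb: int
    t_start: float
    t_end: float
    samples: np.ndarray

    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class AsymSample:
    """One per-epoch asymmetry value paired with its SWB rating.

    ``value`` is the mean over in-band frequency bins of the natural-log
    power-density ratio of ch1 (right) over ch2 (left); dimensionless.
    """

    band: str
    ch1: str
    ch2: str
    value: float
    swb: int
    participant_id: str = ""
    run_id: str = ""
    epoch_index: int = -1
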