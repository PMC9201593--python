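"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_AREAS = {"PMC", "M1", "RFA", "CFA", "other"}
VALID_LAYERS = {"L2/3", "L5", "L6", "n/a"}


@dataclass(frozen=True)
class Channel:
    """One recording contact with its anatomical assignment."""

    id: str
    area: str = "other"
    layer: str = "n/a"

    def __post_init__(self) -> None:
        if self.area not in VALID_AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {sorted(VALID_AREAS)}")
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {sorted(VALID_LAYERS)}")


@dataclass
class Recording:
    """Continuous multichannel signal (channels x samples, µV) with metadata.

    Invariants: all channels share the sample count, ``fs_hz`` is positive,
    and the signal contains no non-finite values.
    """

    signal: np.ndarray
    fs_hz: float
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.channels:
            self.channels = [Channel(id=f"ch{i}") for i in range(self.signal.shape[0])]
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for {self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def channel_ids(self) -> list[str]:
        return [c.id for c in self.channels]

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel with id {channel_id!r}") from None

    def copy_with(self, signal: np.ndarray, fs_hz: float | None = None) -> "Recording":
        return Recording(signal=signal, fs_hz=fs_hz or self.fs_hz, channels=list(self.channels))


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from a Recording.

    ``epochs`` is (epoch x channel x sample); the epoch count times the epoch
    length never exceeds the parent recording length.
    """

    epochs: np.ndarray
    epoch_length_s: float
    fs_hz: float
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D (epoch, channel, sample) array")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]
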