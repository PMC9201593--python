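"""Multitaper power spectra and frequency-band aggregation.

Power is estimated with DPSS (Slepian) tapers on short segments cut from the
epochs, averaged over tapers, segments and epochs, on a frequency grid finer
than the native segment resolution via zero-padding. Band aggregation uses a
configurable band table; the shipped presets follow the printed integer band
edges of laminar mouse recordings (delta 0-3 ... high gamma 76-100 Hz) and
human EEG (beta 14-30, gamma 31-100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .containers import Channel, EpochSet

__all__ = [
    "Band",
    "BandTable",
    "MOUSE_BANDS",
    "HUMAN_BANDS",
    "PowerSpectrum",
    "multitaper_power",
    "band_average",
    "band_lookup",
]


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low must be < high")


@dataclass(frozen=True)
class BandTable:
    """Ordered, non-overlapping frequency bands.

    Printed integer edges like "16-31 Hz" are interpreted half-open as
    [low, high + 1) so adjacent printed bands tile without overlap; a
    frequency in a genuine gap (e.g. exactly 50 Hz between low and medium
    gamma) belongs to no band.
    """

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        upper = None
        for b in self.bands:
            if upper is not None and b.low_hz < upper:
                raise ValueError(f"band {b.name} overlaps its predecessor")
            upper = b.high_hz + 1.0
        object.__setattr__(self, "_by_name", {b.name: b for b in self.bands})

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> Band:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


MOUSE_BANDS = BandTable(
    (
        Band("delta", 0.1, 3.0),  # lower edge at the 0.1-Hz high-pass
        Band("theta", 4.0, 7.0),
        Band("alpha", 8.0, 15.0),
        Band("beta", 16.0, 31.0),
        Band("low_gamma", 32.0, 49.0),
        Band("medium_gamma", 51.0, 75.0),
        Band("high_gamma", 76.0, 100.0),
    )
)

HUMAN_BANDS = BandTable(
    (
        Band("beta", 14.0, 30.0),
        Band("gamma", 31.0, 100.0),
    )
)


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density (µV²/Hz) on a regular grid."""

    freqs_hz: np.ndarray
    power: np.ndarray  # channel x frequency
    taper_count: int
    segment_length_s: float
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != self.freqs_hz.size:
            raise ValueError("power columns must match the frequency grid")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def freq_step_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0]) if self.freqs_hz.size > 1 else 0.0


def multitaper_power(
    epochs: EpochSet,
    segment_s: float = 0.05,
    freq_step_hz: float = 0.25,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    nw: float = 2.0,
) -> PowerSpectrum:
    """DPSS multitaper PSD averaged over tapers, segments and epochs.

    Each epoch is split into non-overlapping segments of ``segment_s``;
    spectra are evaluated on a grid of step ``freq_step_hz`` by zero-padding
    (NFFT = fs / step). With ``nw`` = 2 (default) 2*nw - 1 = 3 tapers are
    used. The one-sided PSD satisfies Parseval: integrating over
    [0, Nyquist] recovers the signal variance.
    """
    fs = epochs.fs_hz
    nyq = fs / 2.0
    fmax = nyq if fmax_hz is None else fmax_hz
    if not (0 <= fmin_hz < fmax <= nyq):
        raise ValueError(f"frequency range [{fmin_hz:g}, {fmax:g}] outside [0, {nyq:g}]")
    seg_len = int(round(segment_s * fs))
    if seg_len < 8:
        raise ValueError("segment_s too short: needs >= 8 samples")
    nfft = int(round(fs / freq_step_hz))
    if nfft < seg_len:
        raise ValueError("freq_step_hz too coarse for the segment length")
    n_tapers = max(1, int(2 * nw - 1))
    tapers = windows.dpss(seg_len, nw, Kmax=n_tapers)  # rows unit-energy

    n_seg = epochs.samples_per_epoch // seg_len
    if n_seg < 1:
        raise ValueError("epochs shorter than one segment")
    # collapse epochs and segments: (channel, epoch*segment, sample)
    x = epochs.epochs[:, :, : n_seg * seg_len].reshape(
        epochs.n_epochs, epochs.n_channels, n_seg, seg_len
    )
    x = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(
        epochs.n_channels, epochs.n_epochs * n_seg, seg_len
    )
    n_freq = nfft // 2 + 1
    psd = np.zeros((epochs.n_channels, n_freq))
    chunk = max(1, int(2_000_000 / (n_freq * n_tapers)))  # bound scratch memory
    for ch in range(epochs.n_channels):
        for start in range(0, x.shape[1], chunk):
            block = x[ch, start : start + chunk]  # (b, seg_len)
            spec = np.fft.rfft(block[:, None, :] * tapers[None, :, :], n=nfft, axis=-1)
            psd[ch] += (np.abs(spec) ** 2).sum(axis=(0, 1))
    psd /= fs * x.shape[1] * n_tapers
    # one-sided doubling (DC and Nyquist bins are unique)
    psd[:, 1:] *= 2.0
    if nfft % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = (freqs >= fmin_hz) & (freqs <= fmax + 1e-12)
    return PowerSpectrum(
        freqs_hz=freqs[keep],
        power=psd[:, keep],
        taper_count=n_tapers,
        segment_length_s=segment_s,
        channels=list(epochs.channels),
    )


def _band_bins(freqs: np.ndarray, band: Band, step: float) -> np.ndarray:
    return (freqs >= band.low_hz - 1e-12) & (freqs < band.high_hz + step - 1e-12)


def band_average(spec: PowerSpectrum, bands: BandTable) -> dict[str, np.ndarray]:
    """Mean PSD per channel inside each band.

    Bin membership is half-open [low, high + step): the bin at a band's
    printed upper edge is included, the next band's lower edge is not.
    Raises if a band covers no frequency bin of the spectrum's grid.
    """
    step = spec.freq_step_hz
    out: dict[str, np.ndarray] = {}
    for band in bands:
        mask = _band_bins(spec.freqs_hz, band, step)
        if not mask.any():
            raise ValueError(f"band {band.name} contains no frequency bin")
        out[band.name] = spec.power[:, mask].mean(axis=1)
    return out


def band_lookup(f_hz: float, bands: BandTable) -> str | None:
    """Name of the band containing ``f_hz`` under the [low, high + 1 Hz)
    convention for printed integer edges, or None inside a gap."""
    if f_hz < 0:
        raise ValueError("frequency must be >= 0")
    for band in bands:
        if band.low_hz - 1e-12 <= f_hz < band.high_hz + 1.0 - 1e-12:
            return band.name
    return None
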