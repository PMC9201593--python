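"""Pairwise magnitude-squared coherence with a Monte-Carlo surrogate null.

Coherence is a symmetric functional-connectivity measure in [0, 1]. Its
null distribution under "no interaction" is obtained by shuffling the order
of short (default 500-ms) blocks of one channel: block permutation keeps the
marginal mean, variance and histogram of the surrogate signal but destroys
any cross-channel temporal structure. A frequency (or band) is flagged
significant when the observed coherence exceeds the (1 - alpha) quantile of
its surrogate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Recording
from .spectral import BandTable, MOUSE_BANDS, _band_bins

__all__ = ["CoherencePair", "coherence", "surrogate_null", "flag_significant"]


@dataclass
class CoherencePair:
    """Coherence spectrum of one channel pair, optionally with its null."""

    pair: tuple[str, str]
    freqs_hz: np.ndarray
    coherence: np.ndarray
    band_table: BandTable = MOUSE_BANDS
    band_means: dict[str, float] = field(default_factory=dict)
    null: np.ndarray | None = None  # n_perm x n_freq
    null_band_means: np.ndarray | None = None  # n_perm x n_band
    significant: np.ndarray | None = None  # per frequency
    significant_bands: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coherence = np.asarray(self.coherence, dtype=float)
        if np.any(self.coherence < -1e-12) or np.any(self.coherence > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")
        self.coherence = np.clip(self.coherence, 0.0, 1.0)


def _band_means(freqs: np.ndarray, coh: np.ndarray, bands: BandTable) -> dict[str, float]:
    step = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    out = {}
    for band in bands:
        mask = _band_bins(freqs, band, step)
        if mask.any():
            out[band.name] = float(np.mean(coh[..., mask], axis=-1))
    return out


def _welch_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, segment_s: float, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(segment_s * fs))
    noverlap = nperseg // 2
    if x.size < nperseg + (nperseg - noverlap):
        raise ValueError("need at least 2 Welch segments for coherence")
    freqs, coh = sps.coherence(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    return freqs[keep], coh[keep]


def coherence(
    rec: Recording,
    pair: tuple[str, str],
    segment_s: float = 2.0,
    fmin_hz: float = 0.5,
    fmax_hz: float = 100.0,
    band_table: BandTable = MOUSE_BANDS,
) -> CoherencePair:
    """Welch magnitude-squared coherence |Sxy|^2 / (Sxx Syy) for one pair.

    2-s Hann segments with 50 % overlap give a native 0.5-Hz grid; the
    returned spectrum is restricted to [fmin_hz, fmax_hz]. The caller is
    expected to have band-passed the recording (0.5-250 Hz in the standard
    pipeline).
    """
    i, j = rec.channel_index(pair[0]), rec.channel_index(pair[1])
    freqs, coh = _welch_coherence(
        rec.signal[i], rec.signal[j], rec.fs_hz, segment_s, fmin_hz, fmax_hz
    )
    cp = CoherencePair(pair=tuple(pair), freqs_hz=freqs, coherence=coh, band_table=band_table)
    cp.band_means = _band_means(freqs, coh, band_table)
    return cp


def _permute_blocks(x: np.ndarray, block_len: int, rng: np.random.Generator) -> np.ndarray:
    n_blocks = x.size // block_len
    head = x[: n_blocks * block_len].reshape(n_blocks, block_len)
    perm = rng.permutation(n_blocks)
    return np.concatenate([head[perm].ravel(), x[n_blocks * block_len :]])


def surrogate_null(
    rec: Recording,
    pair: tuple[str, str],
    n_perm: int = 100,
    block_s: float = 0.5,
    seed: int = 0,
    segment_s: float = 2.0,
    fmin_hz: float = 0.5,
    fmax_hz: float = 100.0,
    band_table: BandTable = MOUSE_BANDS,
) -> CoherencePair:
    """Monte-Carlo surrogate null for one pair's coherence.

    Each of ``n_perm`` surrogates permutes the order of ``block_s`` blocks of
    the second channel only (shuffling both channels can preserve alignment
    classes) and recomputes the coherence spectrum. Returns a CoherencePair
    carrying the observed spectrum plus the per-frequency and per-band null.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives an unstable null tail", stacklevel=2)
    block_len = int(round(block_s * rec.fs_hz))
    if rec.n_samples < 2 * block_len:
        raise ValueError("recording must contain at least 2 surrogate blocks")
    i, j = rec.channel_index(pair[0]), rec.channel_index(pair[1])
    x, y = rec.signal[i], rec.signal[j]
    freqs, coh = _welch_coherence(x, y, rec.fs_hz, segment_s, fmin_hz, fmax_hz)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, freqs.size))
    step = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    band_masks = {
        b.name: _band_bins(freqs, b, step) for b in band_table if _band_bins(freqs, b, step).any()
    }
    null_bands = np.empty((n_perm, len(band_masks)))
    for p in range(n_perm):
        y_s = _permute_blocks(y, block_len, rng)
        _, c = _welch_coherence(x, y_s, rec.fs_hz, segment_s, fmin_hz, fmax_hz)
        null[p] = c
        null_bands[p] = [c[m].mean() for m in band_masks.values()]
    cp = CoherencePair(pair=tuple(pair), freqs_hz=freqs, coherence=coh, band_table=band_table)
    cp.band_means = _band_means(freqs, coh, band_table)
    cp.null = null
    cp.null_band_means = null_bands
    return cp


def flag_significant(pair: CoherencePair, alpha: float = 0.05) -> CoherencePair:
    """Mark frequencies/bands where observed coherence exceeds the
    (1 - alpha) surrogate quantile."""
    if pair.null is None:
        raise ValueError("surrogate null missing; run surrogate_null first")
    if alpha >= 1.0:  # degenerate request: everything clears a (1-1)=0 quantile
        pair.significant = np.ones_like(pair.coherence, dtype=bool)
        pair.significant_bands = {name: True for name in pair.band_means}
        return pair
    thresh = np.quantile(pair.null, 1.0 - alpha, axis=0)
    pair.significant = pair.coherence > thresh
    if pair.null_band_means is not None and pair.band_means:
        band_thresh = np.quantile(pair.null_band_means, 1.0 - alpha, axis=0)
        pair.significant_bands = {
            name: bool(pair.band_means[name] > band_thresh[k])
            for k, name in enumerate(pair.band_means)
        }
    return pair
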