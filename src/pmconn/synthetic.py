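"""Synthetic ground-truth generators for every pipeline input.

The pipeline is validated end-to-end on surrogate data whose generative
structure is known exactly: stable vector-autoregressive (VAR) processes for
the directed-influence estimators, 1/f-background field potentials with
band-limited strictly-causal coupling and optional instantaneous mixing
(volume conduction), wide-band traces with spike waveforms embedded at known
times, and per-subject feature tables drawn from a linear mediation model.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import Channel, Recording

__all__ = [
    "CouplingSpec",
    "SimulationConfig",
    "var_companion_radius",
    "generate_var_process",
    "one_over_f_noise",
    "generate_band_coupled_lfp",
    "apply_instantaneous_mixing",
    "default_spike_template",
    "generate_spiking_trace",
    "generate_mediation_dataset",
    "mediation_population_covariance",
]

MEDIATION_VARIABLES = ("input", "m1", "m2", "output")


@dataclass(frozen=True)
class CouplingSpec:
    """Directed band-limited coupling: target receives a delayed, band-passed,
    scaled copy of the source channel. ``lag_samples >= 1`` keeps the link
    strictly causal."""

    source_channel: str
    target_channel: str
    band_hz: tuple[float, float]
    lag_samples: int
    gain: float

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError(f"band_hz must satisfy 0 < low < high, got {self.band_hz}")
        if self.lag_samples < 1:
            raise ValueError("lag_samples must be >= 1 (strictly causal)")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


@dataclass
class SimulationConfig:
    """Parameters of one band-coupled LFP simulation."""

    fs_hz: float
    duration_s: float
    n_channels: int
    channel_labels: list[tuple[str, str]] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    noise_exponent: float = 1.0
    mixing_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.channel_labels:
            self.channel_labels = [("other", "n/a")] * self.n_channels
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing_matrix must be square n_channels x n_channels")
            if np.linalg.matrix_rank(m) < self.n_channels:
                raise ValueError("mixing_matrix must have full rank")
            self.mixing_matrix = m

    @property
    def channels(self) -> list[Channel]:
        return [
            Channel(id=f"ch{i}", area=a, layer=l) for i, (a, l) in enumerate(self.channel_labels)
        ]


def var_companion_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of VAR coefficients [p, k, k]."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, k2 = coeffs.shape
    if k != k2:
        raise ValueError("coeffs must have shape (order, k, k)")
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def generate_var_process(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    seed: int,
    burn_in: int = 1000,
) -> np.ndarray:
    """Simulate a stable VAR(p) process.

    Parameters
    ----------
    coeffs : (p, k, k) coefficient tensor; ``coeffs[r]`` multiplies x[t-r-1].
    noise_cov : (k, k) SPD innovation covariance.
    n_samples : length of the returned series.
    seed : RNG seed; fixed seed gives a bit-identical series.

    Returns a (k, n_samples) array. Raises ``ValueError`` with the companion
    spectral radius when the coefficients are unstable.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError("coeffs must have shape (order, k, k)")
    p, k, _ = coeffs.shape
    radius = var_companion_radius(coeffs) if p else 0.0
    if radius >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {radius:.4f} >= 1")
    noise_cov = np.asarray(noise_cov, dtype=float)
    chol = np.linalg.cholesky(noise_cov)
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    eps = rng.standard_normal((total, k)) @ chol.T
    x = np.zeros((total, k))
    for t in range(total):
        acc = eps[t].copy()
        for r in range(min(p, t)):
            acc += coeffs[r] @ x[t - r - 1]
        x[t] = acc
    return x[burn_in:].T.copy()


def one_over_f_noise(
    n_samples: int, alpha: float, fs_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise with power spectral density proportional to 1/f^alpha.

    Synthesized by spectral shaping: white-noise Fourier amplitudes are scaled
    by f^(-alpha/2), which controls the log-log slope exactly (the DC bin is
    zeroed).
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _causal_band_component(x: np.ndarray, band: tuple[float, float], fs_hz: float) -> np.ndarray:
    """Band component of x through a causal 4th-order Butterworth bandpass."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfilt(sos, x)


def generate_band_coupled_lfp(config: SimulationConfig) -> Recording:
    """Simulate multichannel LFP: 1/f^alpha backgrounds plus band-limited
    directed coupling, optionally followed by instantaneous mixing.

    Each coupling adds ``gain`` times the causally band-passed source
    background, delayed by ``lag_samples``, to the target channel, so the
    ground-truth direction is unambiguous and strictly causal.
    """
    nyq = config.fs_hz / 2.0
    for c in config.couplings:
        if c.band_hz[1] >= nyq:
            raise ValueError(
                f"coupling band {c.band_hz} reaches Nyquist ({nyq:g} Hz) at fs={config.fs_hz:g}"
            )
    n = int(round(config.duration_s * config.fs_hz))
    rng = np.random.default_rng(config.seed)
    channels = config.channels
    ids = [ch.id for ch in channels]
    background = np.vstack(
        [one_over_f_noise(n, config.noise_exponent, config.fs_hz, rng) for _ in range(config.n_channels)]
    )
    out = background.copy()
    for c in config.couplings:
        si, ti = ids.index(c.source_channel), ids.index(c.target_channel)
        comp = _causal_band_component(background[si], c.band_hz, config.fs_hz)
        delayed = np.zeros(n)
        delayed[c.lag_samples :] = comp[: n - c.lag_samples]
        out[ti] += c.gain * delayed
    rec = Recording(signal=out, fs_hz=config.fs_hz, channels=channels)
    if config.mixing_matrix is not None:
        rec = apply_instantaneous_mixing(rec, config.mixing_matrix)
    return rec


def apply_instantaneous_mixing(rec: Recording, mixing: np.ndarray) -> Recording:
    """Zero-lag linear mixing of channels (volume-conduction surrogate).

    ``mixing`` must be a full-rank k x k matrix; channel metadata is kept.
    """
    mixing = np.asarray(mixing, dtype=float)
    k = rec.n_channels
    if mixing.shape != (k, k):
        raise ValueError(f"mixing must be {k}x{k}, got {mixing.shape}")
    if np.linalg.matrix_rank(mixing) < k:
        raise ValueError("mixing matrix is singular")
    return rec.copy_with(signal=mixing @ rec.signal)


def default_spike_template(
    fs_hz: float, width_ms: float = 1.5, amplitude: float = 1.0
) -> np.ndarray:
    """Biphasic negative-dominant extracellular waveform.

    A sharp negative lobe followed by a slower, smaller positive rebound;
    the default 1.5-ms width sits well inside the -0.5/+3-ms extraction
    window. Peak (most negative sample) equals -amplitude.
    """
    n = int(round(width_ms * 1e-3 * fs_hz))
    tau = np.arange(n) / max(n - 1, 1)  # normalized 0..1 across the template
    shape = -np.exp(-(((tau - 0.27) / 0.08) ** 2)) + 0.35 * np.exp(-(((tau - 0.60) / 0.17) ** 2))
    return amplitude * shape / abs(shape.min())


def generate_spiking_trace(
    fs_hz: float,
    duration_s: float,
    spike_times_s: list[np.ndarray],
    waveform_templates: list[np.ndarray],
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Wide-band trace = Gaussian noise + templates inserted at stated times.

    ``spike_times_s[u]`` lists event times of unit ``u``; the matching
    template's negative peak is aligned to each stated time. Returns the
    trace and the ground-truth times, keyed by unit index.

    Raises if fs < 20 kHz, a template exceeds 3.5 ms (incompatible with the
    -0.5/+3-ms extraction window), a template is not negative-dominant, or
    two spikes of one unit fall closer than 1 ms.
    """
    if fs_hz < 20000:
        raise ValueError("spiking traces require fs_hz >= 20000")
    if len(spike_times_s) != len(waveform_templates):
        raise ValueError("one template per unit required")
    max_len = int(round(3.5e-3 * fs_hz))
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)
    trace = noise_sd * rng.standard_normal(n)
    truth: dict[int, np.ndarray] = {}
    for u, (times, tmpl) in enumerate(zip(spike_times_s, waveform_templates)):
        tmpl = np.asarray(tmpl, dtype=float)
        if tmpl.size > max_len:
            raise ValueError(
                f"template {u} spans {tmpl.size / fs_hz * 1e3:.2f} ms > 3.5 ms at fs={fs_hz:g}"
            )
        if tmpl.min() >= 0 or abs(tmpl.min()) <= abs(tmpl.max()):
            raise ValueError(f"template {u} must have a dominant negative peak")
        times = np.sort(np.asarray(times, dtype=float))
        if times.size > 1 and np.min(np.diff(times)) < 1e-3:
            raise ValueError(f"unit {u} spike times closer than 1 ms")
        peak_off = int(np.argmin(tmpl))
        kept = []
        for t_s in times:
            start = int(round(t_s * fs_hz)) - peak_off
            if start < 0 or start + tmpl.size > n:
                continue
            trace[start : start + tmpl.size] += tmpl
            kept.append((start + peak_off) / fs_hz)
        truth[u] = np.asarray(kept)
    return trace, truth


def _mediation_matrices(
    path_coeffs: dict[tuple[str, str], float], resid_sd: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    k = len(MEDIATION_VARIABLES)
    idx = {v: i for i, v in enumerate(MEDIATION_VARIABLES)}
    b = np.zeros((k, k))
    for (src, dst), val in path_coeffs.items():
        if src not in idx or dst not in idx:
            raise ValueError(f"unknown variable in path {src}->{dst}")
        if idx[src] >= idx[dst]:
            raise ValueError(f"path {src}->{dst} violates the input->mediators->output order")
        b[idx[dst], idx[src]] = val
    psi = np.diag([resid_sd.get(v, 1.0) ** 2 for v in MEDIATION_VARIABLES])
    return b, psi


def mediation_population_covariance(
    path_coeffs: dict[tuple[str, str], float], resid_sd: dict[str, float]
) -> pd.DataFrame:
    """Population covariance of (input, m1, m2, output) implied by the linear
    structural equations: Sigma = (I-B)^-1 Psi (I-B)^-T."""
    b, psi = _mediation_matrices(path_coeffs, resid_sd)
    inv = np.linalg.inv(np.eye(b.shape[0]) - b)
    cov = inv @ psi @ inv.T
    return pd.DataFrame(cov, index=MEDIATION_VARIABLES, columns=MEDIATION_VARIABLES)


def generate_mediation_dataset(
    n: int,
    path_coeffs: dict[tuple[str, str], float],
    noise_sds: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject feature table (input, m1, m2, output) from a two-mediator
    linear mediation model with independent Gaussian disturbances.

    Path keys use the variable names ``input``, ``m1``, ``m2``, ``output``
    (unused mediators simply keep zero inbound/outbound paths). When
    ``noise_sds`` is None, disturbance variances are chosen so every variable
    has unit population variance, making ``path_coeffs`` the population
    standardized coefficients (requires each implied explained variance < 1).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    for (src, dst), val in path_coeffs.items():
        if not math.isfinite(val):
            raise ValueError(f"non-finite coefficient on path {src}->{dst}")
    if noise_sds is None:
        key = lambda a, b: tuple(sorted((a, b)))  # noqa: E731
        noise_sds = {}
        cov: dict[tuple[str, str], float] = {}
        order = MEDIATION_VARIABLES
        for i, v in enumerate(order):
            preds = [(u, path_coeffs.get((u, v), 0.0)) for u in order[:i]]
            explained = sum(
                wu * ww * cov[key(u, w)] for u, wu in preds for w, ww in preds if wu and ww
            )
            if explained >= 1.0:
                raise ValueError(f"paths into {v} imply explained variance >= 1; cannot standardize")
            noise_sds[v] = math.sqrt(1.0 - explained)
            cov[key(v, v)] = 1.0
            for u in order[:i]:
                cov[key(v, u)] = sum(wq * cov[key(q, u)] for q, wq in preds if wq)
    b, _ = _mediation_matrices(path_coeffs, {v: noise_sds.get(v, 1.0) for v in MEDIATION_VARIABLES})
    rng = np.random.default_rng(seed)
    data = np.zeros((n, len(MEDIATION_VARIABLES)))
    for i, v in enumerate(MEDIATION_VARIABLES):
        data[:, i] = data @ b[i] + noise_sds.get(v, 1.0) * rng.standard_normal(n)
    return pd.DataFrame(data, columns=list(MEDIATION_VARIABLES))
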