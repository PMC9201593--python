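"""Spike detection, wavelet features, super-paramagnetic clustering (SPC),
unit quality screening and firing rates.

Detection thresholds the negative range of the 0.3-3 kHz band-passed trace
at 5 estimated noise SDs; deflections beyond 30 SD are treated as artifacts
and discarded outright. The noise SD is estimated robustly as
median(|x|)/0.6745 by default, because the raw SD is inflated by the spikes
themselves. Waveforms span -0.5 to +3 ms around the negative peak.

Features are Haar wavelet coefficients (4 decomposition levels) ranked by a
Kolmogorov-Smirnov deviation from normality: coefficients that separate
units are multimodal across events and therefore maximally non-Gaussian.
Clustering runs a Potts-model Monte Carlo (Swendsen-Wang) over a temperature
grid on the K-nearest-neighbour graph; clusters are read from pair
correlations exceeding 1/2, and the working temperature is the largest one
at which the biggest non-trivial cluster still exceeds ``min_cluster``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "DetectedSpikes",
    "UnitCluster",
    "SPCResult",
    "spike_bandpass",
    "robust_sigma",
    "detect_spikes",
    "extract_features",
    "spc_cluster",
    "quality_filter",
    "firing_rate",
    "sort_spikes",
]

PRE_MS = 0.5
POST_MS = 3.0


@dataclass
class DetectedSpikes:
    """Threshold crossings on one channel with extracted waveforms.

    ``waveforms[e]`` spans -0.5...+3 ms around the negative peak of event e,
    so the peak sits at sample round(0.5 ms * fs).
    """

    channel: str
    times_s: np.ndarray
    waveforms: np.ndarray  # n_events x window
    fs_hz: float
    sigma: float

    @property
    def n_events(self) -> int:
        return self.times_s.size

    @property
    def peak_amplitudes(self) -> np.ndarray:
        return self.waveforms.min(axis=1) if self.n_events else np.empty(0)


@dataclass
class UnitCluster:
    """One putative single unit."""

    unit_id: int
    times_s: np.ndarray
    waveforms: np.ndarray
    firing_rate_hz: float
    mean_waveform: np.ndarray = field(default_factory=lambda: np.empty(0))
    quality: dict = field(default_factory=dict)
    kept: bool = True

    def __post_init__(self) -> None:
        if self.mean_waveform.size == 0 and self.waveforms.size:
            self.mean_waveform = self.waveforms.mean(axis=0)


@dataclass
class SPCResult:
    labels: np.ndarray  # -1 = unassigned
    temperature: float
    cluster_sizes: dict[int, int]


def spike_bandpass(trace: np.ndarray, fs_hz: float, low_hz: float = 300.0, high_hz: float = 3000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass for the spike band."""
    sos = sps.butter(4, (low_hz, high_hz), btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, trace)


def robust_sigma(trace: np.ndarray) -> float:
    """Noise SD estimate median(|x|)/0.6745, insensitive to embedded spikes."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    fs_hz: float,
    threshold_sd: float = 5.0,
    artifact_sd: float = 30.0,
    refractory_ms: float = 1.0,
    noise_estimator: str = "robust",
    channel: str = "ch0",
) -> DetectedSpikes:
    """Negative-threshold spike detection with artifact rejection.

    Local minima below -threshold_sd * sigma are detected with a 1-ms dead
    time; any event whose peak magnitude exceeds artifact_sd * sigma is
    dropped as an artifact. Events within one waveform window of the trace
    edge are discarded. The input is expected to be band-passed to the spike
    band already (see ``spike_bandpass``).
    """
    trace = np.asarray(trace, dtype=float)
    pre = int(round(PRE_MS * 1e-3 * fs_hz))
    post = int(round(POST_MS * 1e-3 * fs_hz))
    if trace.size < pre + post:
        raise ValueError("trace shorter than one waveform window")
    sigma = robust_sigma(trace) if noise_estimator == "robust" else float(trace.std())
    if sigma == 0:
        return DetectedSpikes(channel, np.empty(0), np.empty((0, pre + post)), fs_hz, 0.0)
    distance = max(1, int(round(refractory_ms * 1e-3 * fs_hz)))
    peaks, _ = sps.find_peaks(-trace, height=threshold_sd * sigma, distance=distance)
    # sub-sample peak alignment: waveforms are re-sampled on a 4x grid around
    # the interpolated minimum, otherwise +-1 sample of alignment jitter
    # dominates the waveform variability of sharp spikes
    up = 4
    margin = 2
    keep_t, keep_w = [], []
    for p in peaks:
        if abs(trace[p]) > artifact_sd * sigma:
            continue  # artifact
        lo, hi = p - pre - margin, p + post + margin
        if lo < 0 or hi > trace.size:
            continue
        seg_u = sps.resample_poly(trace[lo:hi], up, 1)
        center = (pre + margin) * up
        offset = int(np.argmin(seg_u[center - margin * up : center + margin * up + 1]))
        pk = center - margin * up + offset
        start = pk - pre * up
        if start < 0 or start + (pre + post - 1) * up >= seg_u.size:
            continue
        keep_w.append(seg_u[start : start + (pre + post) * up : up])
        keep_t.append((lo + pk / up) / fs_hz)
    waveforms = np.vstack(keep_w) if keep_w else np.empty((0, pre + post))
    return DetectedSpikes(channel, np.asarray(keep_t), waveforms, fs_hz, sigma)


def extract_features(
    waveforms: np.ndarray, n_features: int = 10, levels: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KS-selected Haar wavelet features.

    Each waveform is decomposed with a ``levels``-level Haar transform; every
    coefficient is scored by the KS statistic of its z-scored distribution
    across events against a standard normal, and the ``n_features`` highest-
    scoring coefficients are kept. Returns (features, selected_indices,
    ks_statistics) where ks_statistics covers all coefficients.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n_events = waveforms.shape[0]
    if n_events < 2 * n_features:
        raise ValueError(f"need >= {2 * n_features} events for {n_features} features")
    coeffs = np.hstack(pywt.wavedec(waveforms, "haar", level=levels, axis=1))
    sds = coeffs.std(axis=0)
    ks = np.zeros(coeffs.shape[1])
    for c in range(coeffs.shape[1]):
        if sds[c] < 1e-12:
            continue  # constant coefficient: deviation 0, never selected
        z = (coeffs[:, c] - coeffs[:, c].mean()) / sds[c]
        ks[c] = stats.kstest(z, "norm").statistic
    if np.all(ks == 0):
        warnings.warn("degenerate features: all waveforms identical", stacklevel=2)
    order = np.lexsort((np.arange(ks.size), -ks))  # deterministic tie-break
    selected = np.sort(order[:n_features])
    return coeffs[:, selected], selected, ks


def _knn_graph(features: np.ndarray, k_neighbors: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric union K-nearest-neighbour edge list with distances."""
    n = features.shape[0]
    tree = cKDTree(features)
    dist, idx = tree.query(features, k=min(k_neighbors + 1, n))
    pairs = set()
    for i in range(n):
        for j_pos in range(1, idx.shape[1]):
            j = int(idx[i, j_pos])
            pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs))
    d = np.linalg.norm(features[edges[:, 0]] - features[edges[:, 1]], axis=1)
    return edges, d


def _sw_pair_correlations(
    edges: np.ndarray,
    j_int: np.ndarray,
    n: int,
    temperature: float,
    rng: np.random.Generator,
    n_sweeps: int,
    burn_in: int,
    q: int = 20,
) -> np.ndarray:
    """Swendsen-Wang Monte Carlo of a q-state Potts model; returns the
    fraction of post-burn-in sweeps on which each edge's endpoints share a
    spin."""
    if temperature <= 0:
        return np.ones(len(edges))
    p_freeze = 1.0 - np.exp(-j_int / temperature)
    spins = rng.integers(0, q, size=n)
    counts = np.zeros(len(edges))
    for sweep in range(burn_in + n_sweeps):
        same = spins[edges[:, 0]] == spins[edges[:, 1]]
        frozen = same & (rng.random(len(edges)) < p_freeze)
        sub = edges[frozen]
        graph = coo_matrix(
            (np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(n, n)
        )
        n_comp, comp = connected_components(graph, directed=False)
        spins = rng.integers(0, q, size=n_comp)[comp]
        if sweep >= burn_in:
            counts += spins[edges[:, 0]] == spins[edges[:, 1]]
    return counts / n_sweeps


def spc_cluster(
    features: np.ndarray,
    temperatures: np.ndarray | None = None,
    k_neighbors: int = 11,
    min_cluster: int = 20,
    seed: int = 0,
    n_sweeps: int = 80,
    burn_in: int = 20,
) -> SPCResult:
    """Super-paramagnetic clustering of spike features.

    Potts interactions J_ij = (1/K) exp(-d_ij^2 / 2 a^2) (a = mean
    neighbour distance) live on the KNN graph; at each temperature of the
    grid (default 0...0.2 in steps of 0.01) Swendsen-Wang pair correlations
    above 1/2 define clusters. The working temperature is the one inside the
    super-paramagnetic plateau that maximizes the number of clusters with at
    least ``min_cluster`` members (ties broken toward the most assigned
    events, then toward the colder temperature): hotter temperatures that
    merely retain an eroding fragment of a cluster sit past the plateau and
    under-assign. A single compact cloud resolves to one cluster at the
    coldest temperature. Events outside retained clusters get label -1.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if n < min_cluster:
        return SPCResult(labels=-np.ones(n, dtype=int), temperature=np.nan, cluster_sizes={})
    if temperatures is None:
        temperatures = np.arange(0.0, 0.2001, 0.01)
    edges, dists = _knn_graph(features, k_neighbors)
    a = dists.mean()
    j_int = np.exp(-(dists**2) / (2.0 * a**2)) / k_neighbors
    rng = np.random.default_rng(seed)

    best = None  # (n_clusters, smallest cluster, n_assigned, -t) maximized
    for t in temperatures:
        corr = _sw_pair_correlations(edges, j_int, n, float(t), rng, n_sweeps, burn_in)
        sub = edges[corr > 0.5]
        graph = coo_matrix((np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(n, n))
        _, comp = connected_components(graph, directed=False)
        sizes = np.bincount(comp)
        valid = sizes[sizes >= min_cluster]
        key = (valid.size, int(valid.min()) if valid.size else 0, int(valid.sum()), -float(t))
        if best is None or key > best[0]:
            best = (key, float(t), comp)
    _, t_star, comp = best
    comp = _merge_close_clusters(features, comp, min_cluster)
    sizes = np.bincount(comp)
    labels = -np.ones(n, dtype=int)
    cluster_sizes: dict[int, int] = {}
    next_id = 0
    for cid in np.argsort(sizes)[::-1]:
        if sizes[cid] < min_cluster:
            break
        labels[comp == cid] = next_id
        cluster_sizes[next_id] = int(sizes[cid])
        next_id += 1
    return SPCResult(labels=labels, temperature=t_star, cluster_sizes=cluster_sizes)


def quality_filter(
    cluster: UnitCluster,
    refractory_ms: float = 1.0,
    max_violation_frac: float = 0.02,
    max_drift_frac: float = 0.30,
) -> bool:
    """Keep/drop screen for incompletely separated or unstable units.

    Drops a unit when more than ``max_violation_frac`` of inter-spike
    intervals violate the refractory period (contamination by another unit)
    or when the mean peak amplitude changes by more than ``max_drift_frac``
    between the first and second half of the recording (instability/drift).
    """
    times = np.sort(cluster.times_s)
    flags: dict[str, float] = {}
    keep = True
    if times.size >= 2:
        isi = np.diff(times)
        viol = float(np.mean(isi < refractory_ms * 1e-3))
        flags["isi_violation_frac"] = viol
        if viol > max_violation_frac:
            keep = False
    if cluster.waveforms.shape[0] >= 4:
        amps = np.abs(cluster.waveforms.min(axis=1))
        order = np.argsort(cluster.times_s)
        half = order.size // 2
        a1 = amps[order[:half]].mean()
        a2 = amps[order[half:]].mean()
        drift = float(abs(a2 - a1) / max(a1, 1e-12))
        flags["amplitude_drift_frac"] = drift
        if drift > max_drift_frac:
            keep = False
    cluster.quality = flags
    cluster.kept = keep
    return keep


def _merge_close_clusters(features: np.ndarray, comp: np.ndarray, min_cluster: int,
                          factor: float = 1.0) -> np.ndarray:
    """Merge clusters whose centroids are closer than ``factor`` times the
    larger of their rms radii: SPC can carve one cloud in two at a sparse
    KNN-graph bottleneck even when the parts are statistically identical."""
    comp = comp.copy()
    while True:
        ids = [c for c in np.unique(comp) if (comp == c).sum() >= min_cluster]
        if len(ids) < 2:
            return comp
        cents = {c: features[comp == c].mean(axis=0) for c in ids}
        radii = {
            c: np.sqrt(np.mean(np.sum((features[comp == c] - cents[c]) ** 2, axis=1)))
            for c in ids
        }
        merged = False
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = np.linalg.norm(cents[a] - cents[b])
                if d < factor * max(radii[a], radii[b]):
                    comp[comp == b] = a
                    merged = True
                    break
            if merged:
                break
        if not merged:
            return comp


def force_assign(
    features: np.ndarray, labels: np.ndarray, max_radii: float = 3.0
) -> np.ndarray:
    """Assign leftover events to the nearest cluster centroid.

    An unassigned event joins the cluster whose centroid is closest in
    feature space, provided the distance is within ``max_radii`` times that
    cluster's rms member-to-centroid radius; otherwise it stays unassigned.
    Mirrors the force-membership step of template-matching sorters.
    """
    labels = labels.copy()
    ids = np.unique(labels[labels >= 0])
    if ids.size == 0:
        return labels
    centroids = np.stack([features[labels == u].mean(axis=0) for u in ids])
    radii = np.array(
        [
            np.sqrt(np.mean(np.sum((features[labels == u] - centroids[k]) ** 2, axis=1)))
            for k, u in enumerate(ids)
        ]
    )
    for e in np.flatnonzero(labels < 0):
        d = np.linalg.norm(centroids - features[e], axis=1)
        k = int(np.argmin(d))
        if d[k] <= max_radii * max(radii[k], 1e-12):
            labels[e] = ids[k]
    return labels


def firing_rate(n_events: int, duration_s: float) -> float:
    """Event count divided by recording duration (Hz)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return n_events / duration_s


def sort_spikes(
    trace: np.ndarray,
    fs_hz: float,
    duration_s: float | None = None,
    threshold_sd: float = 5.0,
    artifact_sd: float = 30.0,
    n_features: int = 10,
    min_cluster: int = 20,
    seed: int = 0,
    bandpass: bool = True,
    apply_quality: bool = True,
    force_membership: bool = True,
) -> tuple[list[UnitCluster], DetectedSpikes, SPCResult]:
    """Full single-channel sorting pipeline: band-pass, detect, featurize,
    SPC-cluster, force-assign stragglers, quality-screen. Returns retained
    units plus the raw detection and clustering results (unassigned +
    assigned = detected)."""
    trace = np.asarray(trace, dtype=float)
    duration = duration_s if duration_s is not None else trace.size / fs_hz
    filtered = spike_bandpass(trace, fs_hz) if bandpass else trace
    det = detect_spikes(filtered, fs_hz, threshold_sd, artifact_sd)
    if det.n_events < max(min_cluster, 2 * n_features):
        return [], det, SPCResult(-np.ones(det.n_events, dtype=int), np.nan, {})
    feats, _, _ = extract_features(det.waveforms, n_features=n_features)
    spc = spc_cluster(feats, min_cluster=min_cluster, seed=seed)
    if force_membership:
        spc.labels = force_assign(feats, spc.labels)
        spc.cluster_sizes = {
            u: int((spc.labels == u).sum()) for u in sorted(spc.cluster_sizes)
        }
    units = []
    for uid in sorted(spc.cluster_sizes):
        sel = spc.labels == uid
        unit = UnitCluster(
            unit_id=uid,
            times_s=det.times_s[sel],
            waveforms=det.waveforms[sel],
            firing_rate_hz=firing_rate(int(sel.sum()), duration),
        )
        if not apply_quality or quality_filter(unit):
            units.append(unit)
    return units, det, spc
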