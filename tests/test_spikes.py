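"""Spike detection, features, SPC clustering, quality screen."""

import numpy as np
import pytest

from pmconn.spikes import (
    UnitCluster,
    detect_spikes,
    extract_features,
    firing_rate,
    quality_filter,
    sort_spikes,
    spc_cluster,
    spike_bandpass,
)
from pmconn.synthetic import default_spike_template, generate_spiking_trace

FS = 20000.0


def _labeled_trace(seed=0, amp=8.0, duration=20.0, rate=5.0):
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.05, duration - 0.05, size=int(rate * duration)))
    times = times[np.insert(np.diff(times) > 2.5e-3, 0, True)]
    tmpl = default_spike_template(FS, amplitude=amp)
    return generate_spiking_trace(FS, duration, [times], [tmpl], noise_sd=1.0, seed=seed)


class TestDetection:
    def test_embedded_spikes_recovered(self):
        trace, truth = _labeled_trace(seed=2)
        det = detect_spikes(spike_bandpass(trace, FS), FS)
        hits = sum(np.any(np.abs(det.times_s - t) < 0.2e-3) for t in truth[0])
        assert hits >= 0.95 * truth[0].size
        spurious = sum(not np.any(np.abs(truth[0] - t) < 0.5e-3) for t in det.times_s)
        assert spurious <= 0.05 * det.n_events + 1

    def test_constant_trace_no_events(self):
        det = detect_spikes(np.zeros(10000), FS)
        assert det.n_events == 0

    def test_pure_noise_rarely_crosses_5sd(self):
        clean = 0
        for seed in range(10):
            noise = np.random.default_rng(seed).standard_normal(int(FS))
            if detect_spikes(noise, FS).n_events == 0:
                clean += 1
        assert clean >= 9

    def test_artifact_rule_drops_large_deflection(self):
        rng = np.random.default_rng(5)
        trace = rng.standard_normal(int(FS))
        trace[10000:10004] -= 40.0  # single 40-sigma artifact
        det = detect_spikes(trace, FS)
        assert not np.any(np.abs(det.times_s - 0.5) < 1e-3)
        if det.n_events:
            assert np.all(np.abs(det.peak_amplitudes) <= 30 * det.sigma)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="waveform window"):
            detect_spikes(np.zeros(10), FS)

    def test_waveform_window_shape(self):
        trace, _ = _labeled_trace(seed=3)
        det = detect_spikes(spike_bandpass(trace, FS), FS)
        assert det.waveforms.shape[1] == round(3.5e-3 * FS)
        peak_at = round(0.5e-3 * FS)
        assert np.all(det.waveforms.argmin(axis=1) == peak_at)


class TestFeatures:
    def test_two_templates_give_high_ks_feature(self, rng):
        a = default_spike_template(FS, width_ms=1.0)
        b = default_spike_template(FS, width_ms=2.2)
        w = np.zeros((200, 70))
        w[:100, : a.size] = a
        w[100:, : b.size] = b
        w += 0.3 * rng.standard_normal(w.shape)
        feats, sel, ks = extract_features(w)
        # null KS for n=200 Gaussian values is ~<0.1; a 50/50 mixture is far above
        assert ks[sel].max() > 0.2
        assert feats.shape == (200, 10)

    def test_gaussian_waveforms_match_ks_null(self, rng):
        w = rng.standard_normal((300, 64))
        _, sel, ks = extract_features(w)
        assert ks[sel].max() < 1.63 / np.sqrt(300)  # 1% KS critical value

    def test_constant_coefficient_never_selected(self, rng):
        w = rng.standard_normal((100, 64))
        w[:, 0] = 5.0  # a constant approximation coefficient contribution
        feats, sel, ks = extract_features(np.cumsum(w * 0, axis=1) + w)
        assert np.all(ks >= 0)

    def test_identical_waveforms_warn(self):
        w = np.tile(default_spike_template(FS), (40, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            extract_features(w)

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError, match="events"):
            extract_features(rng.standard_normal((10, 64)))


class TestSpc:
    def test_two_separated_clouds(self, rng):
        a = rng.standard_normal((250, 5))
        b = rng.standard_normal((250, 5)) + 10.0  # 10x the within-cloud SD
        feats = np.vstack([a, b])
        res = spc_cluster(feats, seed=1)
        assert len(res.cluster_sizes) == 2
        la = res.labels[:250]
        lb = res.labels[250:]
        majority_a = np.bincount(la[la >= 0]).argmax()
        majority_b = np.bincount(lb[lb >= 0]).argmax()
        assert majority_a != majority_b
        acc = (np.sum(la == majority_a) + np.sum(lb == majority_b)) / 500
        assert acc >= 0.95

    def test_single_cloud_one_cluster(self, rng):
        res = spc_cluster(rng.standard_normal((300, 5)), seed=2)
        assert len(res.cluster_sizes) == 1

    def test_fewer_than_min_cluster_all_unassigned(self, rng):
        res = spc_cluster(rng.standard_normal((10, 5)), min_cluster=20, seed=0)
        assert np.all(res.labels == -1)

    def test_conservation_assigned_plus_unassigned(self):
        trace, _ = _labeled_trace(seed=11, duration=30.0)
        units, det, spc = sort_spikes(trace, FS, seed=0, apply_quality=False)
        assert sum(u.times_s.size for u in units) + int((spc.labels == -1).sum()) == det.n_events


class TestQualityAndRates:
    def _unit(self, times, amps):
        wf = np.tile(default_spike_template(FS), (len(times), 1)) * np.asarray(amps)[:, None]
        return UnitCluster(unit_id=0, times_s=np.asarray(times), waveforms=wf,
                           firing_rate_hz=len(times) / 10.0)

    def test_clean_refractory_train_kept(self, rng):
        times = np.cumsum(rng.exponential(0.2, size=100)) + 0.002
        unit = self._unit(times, np.ones(100) * 8)
        assert quality_filter(unit)

    def test_contaminated_unit_dropped(self, rng):
        base = np.sort(rng.uniform(0, 10, size=200))
        doubles = base[::10] + 0.0005  # 10% sub-refractory intervals
        unit = self._unit(np.sort(np.concatenate([base, doubles])), np.ones(220) * 8)
        assert not quality_filter(unit)

    def test_drifting_amplitude_dropped(self, rng):
        times = np.linspace(0.01, 10, 100)
        amps = np.where(times < 5, 8.0, 4.0)  # 50% amplitude drop mid-recording
        unit = self._unit(times, amps)
        assert not quality_filter(unit)

    @pytest.mark.parametrize(
        "count,duration,expected",
        [(100, 10.0, 10.0), (0, 10.0, 0.0), (436, 600.0, 0.72667)],
    )
    def test_firing_rate_arithmetic(self, count, duration, expected):
        assert firing_rate(count, duration) == pytest.approx(expected, abs=1e-4)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(10, 0.0)
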