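"""Generators: VAR processes, 1/f LFP with directed coupling, spike traces,
mediation tables. Oracles: Yule-Walker closed forms via the discrete
Lyapunov equation, path-tracing covariance algebra."""

import numpy as np
import pytest
from scipy import linalg

from pmconn.containers import Recording
from pmconn.coherence import coherence
from pmconn.preprocess import epoch_segments
from pmconn.spectral import multitaper_power
from pmconn.synthetic import (
    CouplingSpec,
    SimulationConfig,
    apply_instantaneous_mixing,
    default_spike_template,
    generate_band_coupled_lfp,
    generate_mediation_dataset,
    generate_spiking_trace,
    generate_var_process,
    mediation_population_covariance,
    var_companion_radius,
)


class TestVarProcess:
    def test_degenerate_var_is_white_noise(self):
        x = generate_var_process(np.zeros((1, 2, 2)), np.eye(2), 100000, seed=7)
        assert x.shape == (2, 100000)
        assert np.allclose(x.var(axis=1), 1.0, rtol=0.05)

    def test_lag1_cross_covariance_matches_yule_walker(self):
        # oracle: Gamma0 solves the discrete Lyapunov equation, Gamma1 = A Gamma0
        a = np.array([[0.5, 0.0], [0.4, 0.3]])
        gamma0 = linalg.solve_discrete_lyapunov(a, np.eye(2))
        gamma1 = a @ gamma0
        n = 200000
        x = generate_var_process(a[None], np.eye(2), n, seed=3)
        sample_gamma1 = (x[:, 1:] @ x[:, :-1].T) / (n - 1)  # E[x_t x_{t-1}^T]
        se = 3.0 * np.sqrt(np.outer(np.diag(gamma0), np.diag(gamma0))) / np.sqrt(n)
        assert np.all(np.abs(sample_gamma1 - gamma1) < 3 * se)

    def test_same_seed_is_bit_identical(self):
        a = np.array([[[0.5, 0.1], [0.0, 0.3]]])
        x1 = generate_var_process(a, np.eye(2), 5000, seed=11)
        x2 = generate_var_process(a, np.eye(2), 5000, seed=11)
        assert np.array_equal(x1, x2)

    def test_unstable_coefficients_rejected(self):
        a = np.array([[[1.05, 0.0], [0.0, 0.5]]])
        assert var_companion_radius(a) > 1
        with pytest.raises(ValueError, match="spectral radius"):
            generate_var_process(a, np.eye(2), 100, seed=0)


class TestBandCoupledLfp:
    def test_one_over_f_slope(self):
        cfg = SimulationConfig(fs_hz=500.0, duration_s=100.0, n_channels=1,
                               noise_exponent=1.0, seed=5)
        rec = generate_band_coupled_lfp(cfg)
        # 4-s multitaper segments resolve the low-frequency end
        spec = multitaper_power(epoch_segments(rec, 4.0), segment_s=4.0,
                                freq_step_hz=0.25, fmin_hz=1.0, fmax_hz=80.0)
        logf = np.log10(spec.freqs_hz)
        logp = np.log10(spec.power[0])
        slope = np.polyfit(logf, logp, 1)[0]
        assert abs(slope - (-1.0)) < 0.15

    def test_beta_coupling_raises_beta_coherence(self):
        cfg = SimulationConfig(
            fs_hz=500.0, duration_s=60.0, n_channels=2,
            couplings=[CouplingSpec("ch0", "ch1", (16.0, 31.0), lag_samples=10, gain=1.0)],
            seed=2,
        )
        rec = generate_band_coupled_lfp(cfg)
        cp = coherence(rec, ("ch0", "ch1"))
        assert cp.band_means["beta"] > cp.band_means["medium_gamma"]

    def test_gain_zero_means_independent(self):
        cfg = SimulationConfig(
            fs_hz=500.0, duration_s=60.0, n_channels=2,
            couplings=[CouplingSpec("ch0", "ch1", (16.0, 31.0), lag_samples=10, gain=0.0)],
            seed=2,
        )
        cp = coherence(generate_band_coupled_lfp(cfg), ("ch0", "ch1"))
        # ~1/K estimator bias for K Welch segments; far below any real coupling
        assert cp.band_means["beta"] < 0.15

    def test_coupling_band_above_nyquist_rejected(self):
        cfg = SimulationConfig(
            fs_hz=100.0, duration_s=10.0, n_channels=2,
            couplings=[CouplingSpec("ch0", "ch1", (40.0, 60.0), lag_samples=5, gain=1.0)],
            seed=0,
        )
        with pytest.raises(ValueError, match="Nyquist"):
            generate_band_coupled_lfp(cfg)

    def test_strictly_causal_lag_required(self):
        with pytest.raises(ValueError, match="strictly causal"):
            CouplingSpec("a", "b", (16.0, 31.0), lag_samples=0, gain=1.0)


class TestMixing:
    def test_identity_mixing_is_identity(self, white_recording):
        out = apply_instantaneous_mixing(white_recording, np.eye(2))
        assert np.array_equal(out.signal, white_recording.signal)

    def test_singular_matrix_rejected(self, white_recording):
        with pytest.raises(ValueError, match="singular"):
            apply_instantaneous_mixing(white_recording, np.ones((2, 2)))

    def test_dimension_mismatch_rejected(self, white_recording):
        with pytest.raises(ValueError):
            apply_instantaneous_mixing(white_recording, np.eye(3))

    def test_mixing_raises_low_frequency_coherence(self):
        cfg = SimulationConfig(fs_hz=500.0, duration_s=60.0, n_channels=2,
                               noise_exponent=1.0, seed=9)
        rec = generate_band_coupled_lfp(cfg)
        mixed = apply_instantaneous_mixing(rec, np.array([[1.0, 0.6], [0.6, 1.0]]))
        cp = coherence(mixed, ("ch0", "ch1"))
        assert cp.band_means["delta"] > 0.5


class TestSpikingTrace:
    def test_trace_is_noise_plus_templates_and_reproducible(self):
        fs = 20000.0
        tmpl = default_spike_template(fs, amplitude=8.0)
        times = [np.array([0.1, 0.35, 0.8])]
        tr1, truth = generate_spiking_trace(fs, 1.0, times, [tmpl], noise_sd=1.0, seed=4)
        tr2, _ = generate_spiking_trace(fs, 1.0, times, [tmpl], noise_sd=1.0, seed=4)
        assert np.array_equal(tr1, tr2)
        assert truth[0].size == 3
        # peak is where we said it would be
        k = int(round(0.35 * fs))
        assert tr1[k] < -5.0

    def test_template_longer_than_window_rejected(self):
        fs = 20000.0
        long_tmpl = default_spike_template(fs, width_ms=4.0)
        with pytest.raises(ValueError, match="3.5 ms"):
            generate_spiking_trace(fs, 1.0, [np.array([0.5])], [long_tmpl], 1.0, seed=0)

    def test_positive_template_rejected(self):
        fs = 20000.0
        with pytest.raises(ValueError, match="negative peak"):
            generate_spiking_trace(fs, 1.0, [np.array([0.5])],
                                   [np.abs(default_spike_template(fs))], 1.0, seed=0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="20000"):
            generate_spiking_trace(1000.0, 1.0, [], [], 1.0, seed=0)


class TestMediationDataset:
    def test_zero_paths_give_zero_correlations(self):
        n = 4000
        df = generate_mediation_dataset(n, {("input", "m1"): 0.0}, seed=6)
        corr = df.corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_input_output_covariance_matches_path_tracing(self):
        # a * b on the standardized scale with no direct path
        paths = {("input", "m1"): 0.7, ("m1", "output"): 0.6}
        n = 10000
        df = generate_mediation_dataset(n, paths, seed=8)
        cov = df["input"].cov(df["output"])
        assert abs(cov - 0.7 * 0.6) < 0.03
        pop = mediation_population_covariance(
            paths, {"input": 1.0, "m1": np.sqrt(1 - 0.49), "m2": 1.0,
                    "output": np.sqrt(1 - 0.36)}
        )
        assert abs(pop.loc["input", "output"] - 0.42) < 1e-12

    def test_fixed_seed_reproducible(self):
        paths = {("input", "m1"): 0.5, ("m1", "output"): 0.5}
        d1 = generate_mediation_dataset(100, paths, seed=3)
        d2 = generate_mediation_dataset(100, paths, seed=3)
        assert d1.equals(d2)

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            generate_mediation_dataset(100, {("input", "m1"): np.nan}, seed=0)
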