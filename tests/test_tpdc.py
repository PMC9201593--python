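"""Sliding-window VAR, PDC, TPDC and the time-reversal screen.

Oracles: statsmodels VAR (least-squares fit on one window), a brute-force
PDC evaluation, and simulation from known coefficient tensors.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.tsa.api import VAR as SmVAR

from pmconn.containers import Channel, Recording
from pmconn.evaluation import pdc_bruteforce
from pmconn.preprocess import epoch_segments
from pmconn.spectral import MOUSE_BANDS, multitaper_power
from pmconn.synthetic import (
    CouplingSpec,
    SimulationConfig,
    generate_band_coupled_lfp,
    generate_var_process,
)
from pmconn.tpdc import (
    fit_tvar,
    pdc_from_coefficients,
    pdc_spectrum,
    select_channel_by_theta,
    select_var_order,
    time_reversal_test,
    tpdc,
)

from conftest import sinusoid

A_TRUE = np.array([[[0.5, 0.0], [0.4, 0.3]]])  # VAR(1), influence 1 -> 2 only


class TestChannelSelection:
    def _power(self, signals, fs=1000.0, channels=None):
        rec = Recording(signal=np.vstack(signals), fs_hz=fs, channels=channels)
        return multitaper_power(epoch_segments(rec, 1.0), segment_s=1.0, freq_step_hz=0.25)

    def test_theta_rich_channel_wins(self, rng):
        fs, dur = 1000.0, 20.0
        noise = [0.5 * rng.standard_normal(int(fs * dur)) for _ in range(3)]
        noise[1] = noise[1] + sinusoid(6.0, fs, dur)
        chans = [Channel(f"ch{i}", "RFA", "L5") for i in range(3)]
        spec = self._power(noise, fs, chans)
        assert select_channel_by_theta(spec, ("RFA", "L5")) == "ch1"

    def test_single_member_group(self, rng):
        chans = [Channel("only", "CFA", "L6")]
        spec = self._power([rng.standard_normal(10000)], channels=chans)
        assert select_channel_by_theta(spec, ("CFA", "L6")) == "only"

    def test_exact_tie_goes_to_lowest_id(self):
        x = sinusoid(6.0, 1000.0, 10.0)
        chans = [Channel("b", "RFA", "L5"), Channel("a", "RFA", "L5")]
        spec = self._power([x, x.copy()], channels=chans)
        assert select_channel_by_theta(spec, ("RFA", "L5")) == "a"

    def test_empty_group_rejected(self, rng):
        spec = self._power([rng.standard_normal(10000)])
        with pytest.raises(ValueError, match="no channels"):
            select_channel_by_theta(spec, ("RFA", "L5"))


class TestTvarFit:
    def test_matches_statsmodels_on_one_window(self):
        series = generate_var_process(A_TRUE, np.eye(2), 4000, seed=17)
        model = fit_tvar(series, order=1, window_s=20.0, step_s=20.0, fs_hz=200.0)
        sm_fit = SmVAR(series.T).fit(maxlags=1, trend="n")
        # statsmodels stacks lags the same way: coefs[lag] multiplies x_{t-lag-1}
        assert np.allclose(model.coeffs[0, 0], sm_fit.coefs[0], atol=1e-8)

    def test_long_window_consistency(self):
        series = generate_var_process(
            np.array([[[0.4, 0.1], [0.2, 0.3]], [[-0.15, 0.0], [0.05, -0.1]]]),
            np.eye(2), 60000, seed=23,
        )
        model = fit_tvar(series, order=2, window_s=50.0, step_s=25.0, fs_hz=200.0)
        mean_a = model.coeffs.mean(axis=0)
        assert np.max(np.abs(mean_a - np.array(
            [[[0.4, 0.1], [0.2, 0.3]], [[-0.15, 0.0], [0.05, -0.1]]]))) < 0.05

    def test_white_noise_coefficients_near_zero(self, rng):
        series = rng.standard_normal((2, 8000))
        model = fit_tvar(series, order=1, window_s=40.0, step_s=40.0, fs_hz=200.0)
        se = 1.0 / np.sqrt(8000)
        assert np.all(np.abs(model.coeffs[0, 0]) < 3 * se)

    def test_order_selection_recovers_true_order(self):
        series = generate_var_process(A_TRUE, np.eye(2), 20000, seed=29)
        p = select_var_order(series, p_max=8)
        assert p in (1, 2)  # AIC occasionally adds one noisy lag

    def test_coupling_switch_changes_coefficient_track(self):
        first = generate_var_process(np.zeros((1, 2, 2)), np.eye(2), 10000, seed=31)
        second = generate_var_process(A_TRUE, np.eye(2), 10000, seed=37)
        series = np.hstack([first, second])
        model = fit_tvar(series, order=1, window_s=10.0, step_s=5.0, fs_hz=200.0)
        n_win = model.n_windows
        track = model.coeffs[:, 0, 1, 0]  # entry A[1,0]: influence 1 -> 2
        assert track[n_win // 2 + 1 :].mean() - track[: n_win // 2 - 1].mean() > 0.2

    def test_window_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            fit_tvar(rng.standard_normal((2, 4000)), order=10, window_s=0.2,
                     step_s=0.1, fs_hz=200.0)


class TestPdc:
    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            a = rng.uniform(-0.4, 0.4, size=(2, 3, 3))
            for f in (1.0, 12.0, 47.5):
                assert np.allclose(
                    pdc_from_coefficients(a, f, 200.0), pdc_bruteforce(a, f, 200.0),
                    atol=1e-12,
                )

    def test_diagonal_coefficients_no_cross_influence(self):
        a = np.array([[[0.5, 0.0], [0.0, -0.3]]])
        for f in (2.0, 20.0, 80.0):
            pdc = pdc_from_coefficients(a, f, 200.0)
            assert pdc[0, 1] == 0.0 and pdc[1, 0] == 0.0

    def test_unidirectional_var_closed_form(self):
        for f in (1.0, 10.0, 40.0, 99.0):
            pdc = pdc_from_coefficients(A_TRUE, f, 200.0)
            assert pdc[0, 1] == 0.0  # no influence 2 -> 1
            assert pdc[1, 0] > 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_columns_normalized_for_random_coefficients(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1.0, 1.0, size=(rng.integers(1, 4), 3, 3))
        spec = pdc_spectrum(a, np.arange(0.5, 100.0, 7.3), 200.0)
        colsums = (spec**2).sum(axis=1)
        assert np.allclose(colsums, 1.0, atol=1e-12)
        assert np.all((spec >= 0) & (spec <= 1 + 1e-12))


class TestTpdc:
    def test_stationary_tpdc_matches_static_pdc(self):
        series = generate_var_process(A_TRUE, np.eye(2), 24000, seed=41)
        model = fit_tvar(series, order=1, window_s=10.0, step_s=5.0, fs_hz=200.0)
        static = fit_tvar(series, order=1, window_s=120.0, step_s=120.0, fs_hz=200.0)
        for win_res, stat_res in zip(tpdc(model, MOUSE_BANDS), tpdc(static, MOUSE_BANDS)):
            for band in win_res.band_values:
                assert abs(win_res.band_values[band] - stat_res.band_values[band]) < 0.02

    def test_band_above_100hz_rejected(self):
        from pmconn.spectral import Band, BandTable

        series = generate_var_process(A_TRUE, np.eye(2), 4000, seed=1)
        model = fit_tvar(series, order=1, window_s=10.0, step_s=10.0, fs_hz=200.0)
        with pytest.raises(ValueError, match="outside"):
            tpdc(model, BandTable((Band("too_high", 100.0, 140.0),)))


class TestTimeReversal:
    def test_causal_coupling_called_in_true_direction(self):
        cfg = SimulationConfig(
            fs_hz=200.0, duration_s=120.0, n_channels=2,
            couplings=[CouplingSpec("ch0", "ch1", (16.0, 31.0), lag_samples=5, gain=1.0)],
            seed=43,
        )
        rec = generate_band_coupled_lfp(cfg)
        results = time_reversal_test(rec.signal, 200.0, n_runs=20, seed=7,
                                     channel_ids=["ch0", "ch1"])
        fwd = next(r for r in results if r.source == "ch0")
        rev = next(r for r in results if r.source == "ch1")
        assert fwd.band_values["beta"] > rev.band_values["beta"]
        assert fwd.significant["beta"] and not rev.significant["beta"]

    def test_white_noise_not_called(self, rng):
        series = rng.standard_normal((2, 12000))
        results = time_reversal_test(series, 200.0, n_runs=20, seed=3)
        assert not any(r.significant["beta"] for r in results)
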