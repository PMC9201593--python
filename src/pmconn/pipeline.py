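"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes, per synthetic subject, the stages
preprocess -> spectral power -> coherence (+ surrogate null) -> TPDC (+ TRT)
-> spike sorting, then pools per-subject features into the SEM and group
statistics stages. Every stage's key outputs are hashed (SHA-256) into a
manifest keyed by config and seed, so identical inputs give a bit-identical
manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json

import numpy as np
import pandas as pd

from .coherence import flag_significant as _flag_significant, surrogate_null as _surrogate_null
from . import io as pio
from . import preprocess as pp
from . import sem as psem
from . import spikes as spk
from . import stats as pstats
from . import synthetic as syn
from .tpdc import time_reversal_test as _time_reversal_test
from .spectral import MOUSE_BANDS, band_average, multitaper_power

__all__ = ["default_config", "run_pipeline"]

ALL_STAGES = ("preprocess", "power", "coherence", "tpdc", "spikes", "sem", "stats")


def default_config() -> dict:
    """A small but complete demo configuration (minutes on one CPU)."""
    return {
        "seed": 0,
        "n_subjects": 10,
        "stages": list(ALL_STAGES),
        "lfp": {
            "fs_hz": 1000.0,
            "duration_s": 30.0,
            "noise_exponent": 1.0,
            "coupling_band": (16.0, 31.0),
            "coupling_gain": 1.0,
            "lag_samples": 25,
        },
        "preprocess": {"band_hz": (0.5, 250.0), "notch_hz": [50.0]},
        "power": {"segment_s": 0.05, "freq_step_hz": 0.25, "epoch_s": 1.0},
        "coherence": {"segment_s": 2.0, "n_perm": 100, "alpha": 0.05, "block_s": 0.5},
        "tpdc": {
            "fs_hz": 200.0,
            "window_s": 2.0,
            "step_s": 0.5,
            "order": "auto",
            "p_max": 10,
            "n_runs": 20,
            "alpha": 0.05,
        },
        "spikes": {
            "fs_hz": 20000.0,
            "duration_s": 8.0,
            "n_units": 2,
            "rate_hz": 5.0,
            "amplitude": 8.0,
            "noise_sd": 1.0,
            "min_cluster": 15,
        },
    }


def _stage_seed(seed: int, subject: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}|{subject}|{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _hash_arrays(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


_LABELS = [("RFA", "L5"), ("RFA", "L2/3"), ("CFA", "L2/3"), ("CFA", "L5")]


def _simulate_subject_lfp(cfg: dict, seed: int) -> "syn.Recording":
    lfp = cfg["lfp"]
    coupling = syn.CouplingSpec(
        source_channel="ch0",  # RFA L5
        target_channel="ch2",  # CFA L2/3
        band_hz=tuple(lfp["coupling_band"]),
        lag_samples=int(lfp["lag_samples"]),
        gain=float(lfp["coupling_gain"]),
    )
    sim = syn.SimulationConfig(
        fs_hz=lfp["fs_hz"],
        duration_s=lfp["duration_s"],
        n_channels=len(_LABELS),
        channel_labels=list(_LABELS),
        couplings=[coupling],
        noise_exponent=lfp["noise_exponent"],
        seed=seed,
    )
    return syn.generate_band_coupled_lfp(sim)


def _simulate_subject_spikes(cfg: dict, seed: int):
    sp = cfg["spikes"]
    fs = sp["fs_hz"]
    rng = np.random.default_rng(seed)
    times, templates = [], []
    for u in range(sp["n_units"]):
        n_ev = rng.poisson(sp["rate_hz"] * sp["duration_s"])
        t = np.sort(rng.uniform(0.01, sp["duration_s"] - 0.01, size=n_ev))
        t = t[np.insert(np.diff(t) > 2e-3, 0, True)]  # enforce separation
        times.append(t)
        templates.append(
            syn.default_spike_template(fs, amplitude=sp["amplitude"] * sp["noise_sd"] * (1 + 0.3 * u))
        )
    return syn.generate_spiking_trace(
        fs, sp["duration_s"], times, templates, sp["noise_sd"], seed=seed
    )


def run_pipeline(config: dict | None = None) -> dict:
    """Run the enabled stages over all synthetic subjects.

    Returns a bundle with per-stage DataFrames, the SEM fit (when enabled)
    and the manifest. Raises with the failing stage's name on any error; the
    SEM stage requires the spikes stage (single-unit rates are its outcome
    variable).
    """
    cfg = copy.deepcopy(default_config())
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and key in cfg:
                cfg[key].update(val)
            else:
                cfg[key] = val
    stages = list(cfg["stages"])
    if "sem" in stages and "spikes" not in stages:
        raise RuntimeError("stage sem: missing SU input (enable the spikes stage)")
    seed = int(cfg["seed"])
    bands = MOUSE_BANDS

    subject_rows = []
    power_rows = []
    stage_hashes: dict[str, list[str]] = {s: [] for s in stages}
    for subj in range(int(cfg["n_subjects"])):
        rec = _simulate_subject_lfp(cfg, _stage_seed(seed, subj, "lfp"))
        feats: dict[str, float] = {"subject": subj}

        if "preprocess" in stages:
            try:
                spec = pp.FilterSpec("bandpass", tuple(cfg["preprocess"]["band_hz"]))
                rec = pp.butterworth_filter(rec, spec)
                if cfg["preprocess"]["notch_hz"]:
                    rec = pp.notch_filter(rec, cfg["preprocess"]["notch_hz"])
            except Exception as exc:
                raise RuntimeError(f"stage preprocess failed: {exc}") from exc
            stage_hashes["preprocess"].append(_hash_arrays(rec.signal))

        power_spec = None
        if "power" in stages:
            try:
                epochs = pp.epoch_segments(rec, cfg["power"]["epoch_s"])
                power_spec = multitaper_power(
                    epochs,
                    segment_s=cfg["power"]["segment_s"],
                    freq_step_hz=cfg["power"]["freq_step_hz"],
                    fmin_hz=0.0,
                    fmax_hz=100.0,
                )
                band_power = band_average(power_spec, bands)
            except Exception as exc:
                raise RuntimeError(f"stage power failed: {exc}") from exc
            for ci, ch in enumerate(power_spec.channels):
                row = {"subject": subj, "channel": ch.id, "area": ch.area, "layer": ch.layer}
                row.update({b: float(band_power[b][ci]) for b in bands.names})
                power_rows.append(row)
            feats["power_beta_cfa"] = float(band_power["beta"][2])  # CFA L2/3 channel
            stage_hashes["power"].append(_hash_arrays(power_spec.power))

        if "coherence" in stages:
            try:
                cp = _surrogate_null(
                    rec,
                    ("ch0", "ch2"),
                    n_perm=cfg["coherence"]["n_perm"],
                    block_s=cfg["coherence"]["block_s"],
                    seed=_stage_seed(seed, subj, "coherence"),
                    segment_s=cfg["coherence"]["segment_s"],
                    band_table=bands,
                )
                cp = _flag_significant(cp, cfg["coherence"]["alpha"])
            except Exception as exc:
                raise RuntimeError(f"stage coherence failed: {exc}") from exc
            feats["coherence_beta"] = cp.band_means["beta"]
            feats["coherence_beta_significant"] = float(cp.significant_bands["beta"])
            stage_hashes["coherence"].append(_hash_arrays(cp.coherence, cp.null))

        if "tpdc" in stages:
            try:
                low = pp.downsample(rec, cfg["tpdc"]["fs_hz"])
                results = _time_reversal_test(
                    low.signal[[0, 2]],
                    low.fs_hz,
                    bands=bands,
                    order=cfg["tpdc"]["order"],
                    window_s=cfg["tpdc"]["window_s"],
                    step_s=cfg["tpdc"]["step_s"],
                    n_runs=cfg["tpdc"]["n_runs"],
                    alpha=cfg["tpdc"]["alpha"],
                    seed=_stage_seed(seed, subj, "tpdc"),
                    channel_ids=["RFA_L5", "CFA_L2/3"],
                )
            except Exception as exc:
                raise RuntimeError(f"stage tpdc failed: {exc}") from exc
            fwd = next(r for r in results if r.source == "RFA_L5")
            feats["tpdc_beta"] = fwd.band_values["beta"]
            feats["tpdc_beta_significant"] = float(fwd.significant["beta"])
            stage_hashes["tpdc"].append(_hash_arrays(fwd.pdc))

        if "spikes" in stages:
            try:
                trace, truth = _simulate_subject_spikes(cfg, _stage_seed(seed, subj, "spikes"))
                units, det, spc = spk.sort_spikes(
                    trace,
                    cfg["spikes"]["fs_hz"],
                    duration_s=cfg["spikes"]["duration_s"],
                    min_cluster=cfg["spikes"]["min_cluster"],
                    seed=_stage_seed(seed, subj, "sorting"),
                )
            except Exception as exc:
                raise RuntimeError(f"stage spikes failed: {exc}") from exc
            feats["n_units"] = len(units)
            feats["su_rate"] = float(np.mean([u.firing_rate_hz for u in units])) if units else 0.0
            stage_hashes["spikes"].append(_hash_arrays(det.times_s, spc.labels))

        subject_rows.append(feats)

    bundle: dict = {"subjects": pd.DataFrame(subject_rows)}
    if power_rows:
        bundle["band_power"] = pd.DataFrame(power_rows)

    if "sem" in stages:
        try:
            table = bundle["subjects"].rename(
                columns={
                    "tpdc_beta": "tpdc",
                    "coherence_beta": "coh",
                    "power_beta_cfa": "pow",
                    "su_rate": "su",
                }
            )
            spec = psem.build_mediation_spec("tpdc", ["coh", "pow"], "su")
            fit = psem.fit_ml(spec, table)
        except Exception as exc:
            raise RuntimeError(f"stage sem failed: {exc}") from exc
        bundle["sem"] = {
            "standardized": {f"{a}->{b}": v for (a, b), v in fit.standardized.items()},
            "chi2": fit.chi2,
            "df": fit.df,
            "rmsea": fit.rmsea,
            "aic": fit.aic,
        }
        stage_hashes["sem"].append(
            _hash_arrays(np.array(sorted(fit.standardized.values())))
        )

    if "stats" in stages and power_rows:
        try:
            bp = bundle["band_power"]
            g_a = bp[bp["area"] == "CFA"][bands.names]
            g_b = bp[bp["area"] == "RFA"][bands.names]
            comps = pstats.pairwise_band_tests(g_a, g_b, m=len(bands.names))
        except Exception as exc:
            raise RuntimeError(f"stage stats failed: {exc}") from exc
        bundle["band_tests"] = pd.DataFrame([c.__dict__ for c in comps])
        stage_hashes["stats"].append(
            _hash_arrays(np.array([c.p_adjusted for c in comps]))
        )

    manifest = {
        "config": json.loads(json.dumps(cfg, default=str)),
        "seed": seed,
        "stage_hashes": {
            s: hashlib.sha256("".join(h).encode()).hexdigest() for s, h in stage_hashes.items() if h
        },
    }
    manifest["bundle_hash"] = hashlib.sha256(
        json.dumps(manifest["stage_hashes"], sort_keys=True).encode()
    ).hexdigest()
    bundle["manifest"] = manifest
    return bundle


def write_bundle(bundle: dict, out_dir) -> None:
    pio.write_results(bundle, out_dir)
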