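#!/usr/bin/env python
"""Generate the synthetic study data: a laminar two-area LFP recording with a
known beta-band RFA L5 -> CFA L2/3 coupling, a wide-band trace with three
embedded spike units, and a per-subject mediation feature table.

Writes results/data/{lfp.h5, spikes.npz -> stored as TSV, mediation.tsv} and
a ground-truth sidecar JSON.
"""

import json
from pathlib import Path

import numpy as np

from pmconn.evaluation import SEM_TRUTH, _three_unit_trace
from pmconn.io import write_recording
from pmconn.synthetic import (
    CouplingSpec,
    SimulationConfig,
    generate_band_coupled_lfp,
    generate_mediation_dataset,
)

SEED = 7
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

# --- laminar LFP with directed beta coupling -------------------------------
config = SimulationConfig(
    fs_hz=1000.0,
    duration_s=60.0,
    n_channels=4,
    channel_labels=[("RFA", "L5"), ("RFA", "L2/3"), ("CFA", "L2/3"), ("CFA", "L5")],
    couplings=[CouplingSpec("ch0", "ch2", (16.0, 31.0), lag_samples=25, gain=1.0)],
    noise_exponent=1.0,
    seed=SEED,
)
rec = generate_band_coupled_lfp(config)
write_recording(OUT / "lfp.h5", rec)
truth = {
    "coupling": "RFA L5 (ch0) -> CFA L2/3 (ch2), 16-31 Hz, lag 25 ms, gain 1.0",
    "fs_hz": config.fs_hz,
    "duration_s": config.duration_s,
}

# --- wide-band spiking trace (regenerated from the seed by 05, only the
# ground-truth times are persisted) ------------------------------------------
trace, spike_truth = _three_unit_trace(SEED, duration_s=40.0)
truth["spike_seed"] = SEED
truth["spike_units"] = {str(u): np.round(t, 6).tolist() for u, t in spike_truth.items()}

# --- mediation feature table -------------------------------------------------
table = generate_mediation_dataset(500, SEM_TRUTH, seed=SEED)
table.to_csv(OUT / "mediation.tsv", sep="\t", index=False)
truth["mediation_paths"] = {f"{a}->{b}": v for (a, b), v in SEM_TRUTH.items()}

(OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))
print(f"LFP: {rec.n_channels} channels x {rec.duration_s:.0f} s at {rec.fs_hz:.0f} Hz")
print(f"spike trace: {trace.size} samples, {sum(t.size for t in spike_truth.values())} true spikes")
print(f"mediation table: {len(table)} subjects; wrote everything to {OUT}/")
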