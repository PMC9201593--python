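#!/usr/bin/env python
"""Group comparison across a synthetic cohort: CFA vs RFA band power with
Bonferroni-corrected Welch t-tests over the seven frequency bands.

Runs the full multi-subject pipeline (simulate -> preprocess -> power ->
coherence -> TPDC -> spikes -> SEM -> stats) on a small cohort and writes
the per-band comparison table plus the reproducibility manifest.
"""

import json
from pathlib import Path

from pmconn.io import write_results
from pmconn.pipeline import run_pipeline

OUT = Path("results")
cfg = {
    "seed": 7,
    "n_subjects": 10,
    "lfp": {"duration_s": 20.0},
    "coherence": {"n_perm": 50},
    "tpdc": {"n_runs": 12, "p_max": 8},
    "spikes": {"duration_s": 8.0, "rate_hz": 6.0},
}
bundle = run_pipeline(cfg)
write_results(bundle, OUT / "pipeline")

tests = bundle["band_tests"]
print(tests[["factor", "mean_a", "mean_b", "t_statistic", "p_raw", "p_adjusted"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
sig = tests[tests.p_adjusted < 0.05].factor.tolist()
print(f"bands with CFA != RFA after Bonferroni (m={tests.m.iloc[0]}): {sig or 'none'}")
print(f"SEM on cohort features: {json.dumps(bundle['sem'], indent=2)}")
print(f"manifest hash: {bundle['manifest']['bundle_hash'][:16]}... "
      "(re-running with the same config reproduces it bit-exactly)")
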