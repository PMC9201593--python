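"""File I/O: the HDF5 Recording container, TSV/JSON result exports, EDF.

HDF5 layout: ``/signal`` (channels x samples, float64), ``/fs`` (scalar Hz),
``/channels`` group with string datasets ``id``, ``area``, ``layer``.
Round trips are bit-exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Channel, Recording
from .coherence import CoherencePair
from .spectral import PowerSpectrum
from .tpdc import TPDCResult

__all__ = [
    "SchemaError",
    "write_recording",
    "read_recording",
    "read_edf",
    "power_to_frame",
    "coherence_to_frame",
    "tpdc_to_frame",
    "write_results",
]


class SchemaError(ValueError):
    """A required field is missing or malformed in an input container."""


def write_recording(path: str | Path, rec: Recording) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=float(rec.fs_hz))
        grp = f.create_group("channels")
        sd = h5py.string_dtype()
        grp.create_dataset("id", data=[c.id for c in rec.channels], dtype=sd)
        grp.create_dataset("area", data=[c.area for c in rec.channels], dtype=sd)
        grp.create_dataset("layer", data=[c.layer for c in rec.channels], dtype=sd)
    return path


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        for fieldname in ("signal", "fs", "channels"):
            if fieldname not in f:
                raise SchemaError(f"missing required field /{fieldname} in {path}")
        grp = f["channels"]
        for sub in ("id", "area", "layer"):
            if sub not in grp:
                raise SchemaError(f"missing required field /channels/{sub} in {path}")
        channels = [
            Channel(id=i.decode(), area=a.decode(), layer=l.decode())
            for i, a, l in zip(grp["id"][()], grp["area"][()], grp["layer"][()])
        ]
        return Recording(signal=f["signal"][()], fs_hz=float(f["fs"][()]), channels=channels)


def read_edf(path: str | Path, area_patterns: dict[str, str] | None = None) -> Recording:
    """Read an EDF file into a Recording (requires the optional ``mne``
    dependency). ``area_patterns`` maps area names to regexes matched against
    channel labels; unmatched channels get area ``other``."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support needs the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    channels = []
    for name in raw.ch_names:
        area = "other"
        for cand, pattern in (area_patterns or {}).items():
            if re.search(pattern, name):
                area = cand
                break
        channels.append(Channel(id=name, area=area, layer="n/a"))
    return Recording(signal=raw.get_data(), fs_hz=float(raw.info["sfreq"]), channels=channels)


def power_to_frame(spec: PowerSpectrum) -> pd.DataFrame:
    rows = []
    for ch, channel in enumerate(spec.channels):
        for fi, f in enumerate(spec.freqs_hz):
            rows.append((channel.id, f, spec.power[ch, fi]))
    return pd.DataFrame(rows, columns=["channel", "freq_hz", "power"])


def coherence_to_frame(pair: CoherencePair, alpha: float = 0.05) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "pair": f"{pair.pair[0]}|{pair.pair[1]}",
            "freq_hz": pair.freqs_hz,
            "coherence": pair.coherence,
        }
    )
    if pair.null is not None:
        df["null_q95"] = np.quantile(pair.null, 1 - alpha, axis=0)
    if pair.significant is not None:
        df["significant"] = pair.significant
    return df


def tpdc_to_frame(results: list[TPDCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for band, val in r.band_values.items():
            rows.append(
                (
                    r.source,
                    r.target,
                    band,
                    val,
                    r.direction_delta.get(band, np.nan),
                    r.significant.get(band, None),
                )
            )
    return pd.DataFrame(
        rows, columns=["source", "target", "band", "tpdc", "delta", "significant"]
    )


def write_results(bundle: dict, out_dir: str | Path) -> Path:
    """Write a pipeline result bundle: DataFrames as TSV, dicts as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        elif isinstance(obj, (dict, list)):
            (out / f"{name}.json").write_text(json.dumps(obj, indent=2, default=str))
    return out
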