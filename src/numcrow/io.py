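"""Dataset persistence: delimited trial tables, JSON stimulus sidecars,
HDF5 spike containers and a hashed manifest.

A bundle directory contains::

    trials.csv      one row per trial (ms columns, documented header)
    stimuli.json    per-trial timing / dot-display realizations
    neurons.csv     ground-truth neuron parameters (synthetic data only)
    spikes.h5       /neurons/<id>/<trial_id> spike-time arrays (ms)
    config.yaml     simulator configuration
    manifest.json   schema version, seed, SHA-256 per file

``read_bundle`` verifies file hashes and that every spike train references an
existing trial before handing back a reconstructed dataset.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from numcrow import stimgen
from numcrow.synthdata import Dataset, NeuronSpec, Population, SimConfig

SCHEMA_VERSION = 1


class BundleError(Exception):
    """Base class for bundle problems."""


class IntegrityError(BundleError):
    """Manifest hash does not match file content."""


class SchemaError(BundleError):
    """Missing file or unsupported schema version."""


class CrossReferenceError(BundleError):
    """Spike data references trials that do not exist."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset.trials.to_csv(out / "trials.csv", index=False)

    stimuli = {
        str(tid): {"timing": t.to_dict()} for tid, t in dataset.timings.items()
    }
    for tid, d in dataset.displays.items():
        stimuli[str(tid)] = {"display": d.to_dict()}
    with open(out / "stimuli.json", "w") as fh:
        json.dump(stimuli, fh, sort_keys=True)

    dataset.neuron_frame().to_csv(out / "neurons.csv", index=False)

    with h5py.File(out / "spikes.h5", "w", track_order=False) as f:
        grp = f.create_group("neurons")
        for nid in sorted(dataset.spikes):
            g = grp.create_group(str(nid))
            for tid in sorted(dataset.spikes[nid]):
                g.create_dataset(
                    str(tid), data=dataset.spikes[nid][tid], track_times=False
                )

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)

    files = ["trials.csv", "stimuli.json", "neurons.csv", "spikes.h5", "config.yaml"]
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": dataset.seed,
        "files": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def read_bundle(path: str | Path) -> Dataset:
    """Load and validate a bundle written by :func:`write_bundle`."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {manifest.get('schema_version')}")
    for name, digest in manifest["files"].items():
        fp = root / name
        if not fp.exists():
            raise SchemaError(f"missing bundle file: {name}")
        if _sha256(fp) != digest:
            raise IntegrityError(f"hash mismatch for {name}")

    trials = pd.read_csv(
        root / "trials.csv",
        dtype={"choice": str, "seq_condition": str},
        keep_default_na=False,
        na_values=[""],
    )
    trials["choice"] = trials["choice"].fillna("")
    trials["seq_condition"] = trials["seq_condition"].fillna("")
    for col in ("correct", "is_match"):
        if trials[col].dtype == object:
            trials[col] = trials[col].map({"True": True, "False": False})
        trials[col] = trials[col].astype(bool)

    stimuli = json.loads((root / "stimuli.json").read_text())
    timings: dict[int, stimgen.SequentialTiming] = {}
    displays: dict[int, stimgen.DotDisplay] = {}
    for tid, entry in stimuli.items():
        if "timing" in entry:
            timings[int(tid)] = stimgen.SequentialTiming.from_dict(entry["timing"])
        if "display" in entry:
            displays[int(tid)] = stimgen.DotDisplay.from_dict(entry["display"])

    nf = pd.read_csv(root / "neurons.csv")
    neurons = [
        NeuronSpec(
            neuron_id=int(r["neuron_id"]),
            population=Population(r["population"]),
            preferred_numerosity=(
                None if pd.isna(r["preferred_numerosity"]) else int(r["preferred_numerosity"])
            ),
            baseline_rate=float(r["baseline_rate"]),
            gain=float(r["gain"]),
            tuning_width_sigma=float(r["tuning_width_sigma"]),
            format_signal_amp=float(r["format_signal_amp"]),
            latency_ms=float(r["latency_ms"]),
        )
        for _, r in nf.iterrows()
    ]

    valid_ids = set(int(t) for t in trials["trial_id"])
    spikes: dict[int, dict[int, np.ndarray]] = {}
    with h5py.File(root / "spikes.h5", "r") as f:
        for nid, grp in f["neurons"].items():
            per = {}
            for tid, ds in grp.items():
                if int(tid) not in valid_ids:
                    raise CrossReferenceError(
                        f"spike train references unknown trial {tid} (neuron {nid})"
                    )
                per[int(tid)] = np.asarray(ds[...], dtype=float)
            spikes[int(nid)] = per

    config = SimConfig.from_dict(yaml.safe_load((root / "config.yaml").read_text()))

    return Dataset(
        trials=trials,
        trial_records=[],  # records are not rehydrated; analyses read the frame
        timings=timings,
        displays=displays,
        neurons=neurons,
        spikes=spikes,
        config=config,
        seed=int(manifest["seed"]),
    )
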