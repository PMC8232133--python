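"""Dataset and model persistence.

Datasets are stored as a human-inspectable pair: ``samples.csv`` (header
row, ``strip_id`` plus 1250 integer-µV sample columns) and
``manifest.json`` (per-strip rhythm, shockable flag, achieved SNR,
compression rate and seed, plus dataset-level generator version and
master seed).  Models are stored as an ``.npz`` of weight arrays next to
a ``.json`` sidecar holding the architecture, seeds and training
configuration, so every saved model is reconstructible from the files
alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arch import ConvNet, HPConfig
from .exceptions import (
    CorruptDatasetError,
    DatasetFormatError,
    UnloadableModelError,
)
from .metrics import STRIP_SAMPLES
from .sim import Dataset, EcgStrip, GENERATOR_VERSION, LSB_UV, Rhythm, SHOCKABLE

_SAMPLES_FILE = "samples.csv"
_MANIFEST_FILE = "manifest.json"
_MODEL_FORMAT = "ccecg-model-1"


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset directory (samples CSV + JSON manifest)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = [f"s{i:04d}" for i in range(STRIP_SAMPLES)]
    frame = pd.DataFrame(
        np.stack([s.samples for s in dataset.strips]).astype(np.int64),
        columns=cols,
    )
    frame.insert(0, "strip_id", dataset.ids)
    frame.to_csv(path / _SAMPLES_FILE, index=False)
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "master_seed": dataset.master_seed,
        "n_strips": len(dataset),
        "strips": dataset.manifest().to_dict(orient="records"),
    }
    _atomic_write(path / _MANIFEST_FILE, json.dumps(manifest, indent=1))


def read_dataset(path) -> Dataset:
    """Read a dataset directory; raises on any inconsistency.

    Raises
    ------
    CorruptDatasetError
        Missing files or row-count mismatch between CSV and manifest.
    DatasetFormatError
        Samples that are not integers or not multiples of 5 µV.
    """
    path = Path(path)
    csv_path = path / _SAMPLES_FILE
    man_path = path / _MANIFEST_FILE
    if not csv_path.exists() or not man_path.exists():
        raise CorruptDatasetError(f"dataset files missing under {path}")
    manifest = json.loads(man_path.read_text())
    try:
        frame = pd.read_csv(csv_path)
    except Exception as exc:  # malformed CSV
        raise CorruptDatasetError(f"unreadable samples CSV: {exc}") from exc
    if frame.isna().any().any() or len(frame.columns) != STRIP_SAMPLES + 1:
        raise CorruptDatasetError("samples CSV is truncated or ragged")
    rows = manifest.get("strips", [])
    if len(frame) != len(rows) or manifest.get("n_strips") != len(rows):
        raise CorruptDatasetError("manifest/CSV row-count mismatch")
    sample_cols = frame.columns[1:]
    values = frame[sample_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise DatasetFormatError("samples must be integers")
    if np.any(values % LSB_UV != 0):
        raise DatasetFormatError("samples must be multiples of 5 µV")
    strips, ids = [], []
    for samples, meta, sid in zip(values, rows, frame["strip_id"]):
        if meta["strip_id"] != sid:
            raise CorruptDatasetError("manifest/CSV strip id mismatch")
        rhythm = Rhythm(meta["rhythm"])
        strips.append(
            EcgStrip(
                samples=samples.astype(np.int64),
                rhythm=rhythm,
                shockable=SHOCKABLE[rhythm],
                snr_db=meta.get("snr_db"),
                cc_rate_cpm=meta.get("cc_rate_cpm"),
                seed=meta.get("seed"),
            )
        )
        ids.append(sid)
    return Dataset(strips=strips, ids=ids, master_seed=manifest.get("master_seed"))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def save_model(model: ConvNet, path, train_cfg=None) -> None:
    """Save weights (.npz) plus a JSON sidecar (architecture, seeds, config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = {f"p{i:03d}": p for i, p in enumerate(model.parameters)}
    np.savez(path.with_suffix(".npz"), **weights)
    sidecar = {
        "format": _MODEL_FORMAT,
        "hp": {
            "n_blocks": model.hp.n_blocks,
            "filters": list(model.hp.filters),
            "kernels": list(model.hp.kernels),
        },
        "input_len": model.input_len,
        "init_seed": model.init_seed,
        "train_cfg": dataclasses.asdict(train_cfg) if train_cfg is not None else None,
    }
    _atomic_write(path.with_suffix(".json"), json.dumps(sidecar, indent=1))


def load_model(path) -> ConvNet:
    """Restore a saved model; the sidecar must match the weight shapes."""
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    side_path = path.with_suffix(".json")
    if not npz_path.exists() or not side_path.exists():
        raise UnloadableModelError(f"missing model files at {path}")
    sidecar = json.loads(side_path.read_text())
    if sidecar.get("format") != _MODEL_FORMAT:
        raise UnloadableModelError("unknown model format")
    hp = HPConfig(
        n_blocks=sidecar["hp"]["n_blocks"],
        filters=tuple(sidecar["hp"]["filters"]),
        kernels=tuple(sidecar["hp"]["kernels"]),
    )
    model = ConvNet(hp, init_seed=sidecar.get("init_seed", 0),
                    input_len=sidecar.get("input_len", STRIP_SAMPLES))
    with np.load(npz_path) as data:
        weights = [data[f"p{i:03d}"] for i in range(len(data.files))]
    try:
        model.set_weights(weights)
    except Exception as exc:
        raise UnloadableModelError(f"sidecar/weights shape mismatch: {exc}") from exc
    return model


def load_train_cfg(path) -> Optional[dict]:
    """Training configuration recorded in a model sidecar, if any."""
    sidecar = json.loads(Path(path).with_suffix(".json").read_text())
    return sidecar.get("train_cfg")
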