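"""Persistence helpers: PlaneSet containers and labels manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocessing import PlaneSet


def save_planeset(ps: PlaneSet, path) -> None:
    """Write a PlaneSet as a compressed multi-array container + JSON sidecar.

    The sidecar ``<path>.json`` records the label and preprocessing
    provenance so a saved case is self-describing.
    """
    path = Path(path)
    np.savez_compressed(path, axial=ps.axial, sagittal=ps.sagittal,
                        coronal=ps.coronal)
    sidecar = {"label": ps.label, "provenance": _jsonable(ps.provenance)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_planeset(path) -> PlaneSet:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        arrays = {k: data[k] for k in ("axial", "sagittal", "coronal")}
    sidecar_path = path.with_suffix(path.suffix + ".json")
    label, provenance = None, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        label, provenance = sidecar.get("label"), sidecar.get("provenance", {})
    return PlaneSet(label=label, provenance=provenance, **arrays)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
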