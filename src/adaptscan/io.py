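"""Plain-text serialisation of designs, measures and results.

Tables are written as tab-separated values and scalar summaries as JSON;
both are chosen so that every artifact of a pipeline run is diffable and
inspectable without special tooling.  NIfTI export of β volumes is available
when ``nibabel`` is installed (the ``[nifti]`` extra) and is never required
by the core pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .glm import BetaMap
from .simcortex.designs import ExperimentDesign

__all__ = [
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "write_events_tsv",
    "betas_to_nifti",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: Mapping[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_events_tsv(design: ExperimentDesign, path: str | Path) -> Path:
    """BIDS-style events table (onset, duration, trial_type, exemplar)."""
    return write_table(design.events_table(), path)


def betas_to_nifti(betas: BetaMap, path: str | Path):
    """Write condition β volumes as a 4-D NIfTI image (requires nibabel)."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "NIfTI export requires the optional 'nifti' extra (nibabel)"
        ) from exc
    if betas.voxel_coords is None or betas.grid_shape is None:
        raise ValueError("BetaMap lacks voxel coordinates for volume export")
    vol = np.zeros((*betas.grid_shape, len(betas.conditions)))
    coords = tuple(betas.voxel_coords.T)
    for c in range(len(betas.conditions)):
        vol[coords + (c,)] = betas.betas[:, c]
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
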