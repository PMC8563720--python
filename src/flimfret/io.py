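"""File formats for the pipeline: TCSPC cubes, float maps, class maps, tables.

A cube is stored as a multi-page TIFF (one page per time bin, time order)
plus a JSON sidecar with the same basename carrying acquisition metadata and
provenance.  Scalar maps are 32-bit float single-page TIFFs; class maps are
rendered to 8-bit RGB PNGs with a JSON legend.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .models import AcquisitionConfig

__all__ = ["TcspcCube", "FormatError", "write_cube", "read_cube",
           "write_float_map", "read_float_map", "config_digest"]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the cube/map contracts."""


@dataclass
class TcspcCube:
    """3-D photon-count histogram indexed ``(time_bin, row, col)``.

    ``provenance`` records how the cube came to be (generator seed, config
    digest, pile-up check) or the source path when read from disk.
    """

    counts: np.ndarray
    acq: AcquisitionConfig
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError(f"counts must be 3-D, got shape {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError(f"counts must be integer, got dtype {c.dtype}")
        if c.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if c.shape[0] != self.acq.n_bins:
            raise ValueError(
                f"first axis length {c.shape[0]} != acq.n_bins {self.acq.n_bins}"
            )
        self.counts = c

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def pixel_totals(self) -> np.ndarray:
        """Per-pixel total photon counts, shape (rows, cols)."""
        return self.counts.sum(axis=0)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: TcspcCube, path: str | Path) -> tuple[Path, Path]:
    """Write a cube as multi-page TIFF + JSON sidecar; returns both paths.

    Pages are 16-bit unsigned unless any count exceeds the 16-bit range, in
    which case 32-bit pages are written and flagged in the sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    promoted = bool(cube.counts.max(initial=0) > np.iinfo(np.uint16).max)
    dtype = np.uint32 if promoted else np.uint16
    tifffile.imwrite(path, cube.counts.astype(dtype), photometric="minisblack")
    meta = {
        "format": "flimfret.tcspc_cube",
        "version": 1,
        "acq": {
            "n_bins": cube.acq.n_bins,
            "bin_width": cube.acq.bin_width,
            "period": cube.acq.period,
            "pileup_budget": cube.acq.pileup_budget,
        },
        "shape": list(cube.shape),
        "dtype": np.dtype(dtype).name,
        "promoted_to_32bit": promoted,
        "provenance": cube.provenance,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path, sidecar


def read_cube(path: str | Path) -> TcspcCube:
    """Read a cube written by :func:`write_cube`, validating its invariants."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"cube TIFF not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"cube sidecar not found (expected {sidecar})")
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != "flimfret.tcspc_cube":
        raise FormatError(f"{sidecar} is not a cube sidecar")
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None]
    if not np.issubdtype(counts.dtype, np.integer):
        raise FormatError(f"cube pages must be integer, got {counts.dtype}")
    if counts.min(initial=0) < 0:
        bad = int(np.argwhere(counts.min(axis=(1, 2)) < 0)[0, 0])
        raise FormatError(f"negative counts on page {bad}")
    acq = AcquisitionConfig(**meta["acq"])
    if list(counts.shape) != meta["shape"]:
        raise FormatError(
            f"shape mismatch: TIFF {counts.shape} vs sidecar {meta['shape']}"
        )
    prov = dict(meta.get("provenance", {}))
    prov.setdefault("source_path", str(path))
    return TcspcCube(counts=counts, acq=acq, provenance=prov)


def write_float_map(arr: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D scalar map as a 32-bit float TIFF (NaN marks masked pixels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    return path


def read_float_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"expected a single-page 2-D map in {path}")
    return np.asarray(arr, dtype=np.float32)


def config_digest(obj: Any) -> str:
    """Stable sha256 digest of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=_jsonify)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonify(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
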