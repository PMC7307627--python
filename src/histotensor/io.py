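"""Image, table and configuration I/O shared by the pipeline stages.

Images are read through imageio/tifffile and normalised to float in [0, 1]
according to their bit depth; physical pixel size comes from an explicit
argument, a JSON sidecar (``<image>.json`` with a ``pixel_area_um2`` key) or
the package default of 0.013 um^2/pixel, in that order of precedence.

NIfTI volumes go through nibabel; b-values/b-vectors use the FSL text layout
(bvals: one row, bvecs: three rows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .cell_counting import CellCountConfig
from .dti_metrics import DWIProtocol
from .st_analysis import DEFAULT_PIXEL_AREA, HistoImage, STConfig
from .roi_stats import StatsConfig

__all__ = [
    "load_image", "save_image", "load_nifti", "save_nifti",
    "load_bvals_bvecs", "save_bvals_bvecs",
    "RunConfig", "load_config", "save_config", "config_hash",
]

_BIT_SCALE = {np.uint8: 255.0, np.uint16: 65535.0}


def load_image(path: str | Path, pixel_area: float | None = None,
               stain: str = "other") -> HistoImage:
    """Read a TIFF/PNG photomicrograph as a ``HistoImage`` in [0, 1].

    ``pixel_area`` (um^2/pixel) overrides any ``<path>.json`` sidecar, which
    in turn overrides the default of 0.013.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        pixels = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(float)
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype}")
    if pixels.ndim == 3 and pixels.shape[-1] == 4:
        pixels = pixels[..., :3]  # drop alpha
    if pixel_area is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            pixel_area = float(json.loads(sidecar.read_text())["pixel_area_um2"])
        else:
            pixel_area = DEFAULT_PIXEL_AREA
    return HistoImage(pixels=pixels, pixel_area=pixel_area, stain=stain)


def save_image(path: str | Path, img: HistoImage | np.ndarray,
               bit_depth: int = 16) -> None:
    """Write an image as 8/16-bit TIFF or PNG; writes a pixel-size sidecar
    for ``HistoImage`` inputs."""
    path = Path(path)
    pixels = img.pixels if isinstance(img, HistoImage) else np.asarray(img)
    pixels = np.clip(pixels, 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(pixels * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    if isinstance(img, HistoImage):
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"pixel_area_um2": img.pixel_area}))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a .nii/.nii.gz volume."""
    vol = nib.load(str(path))
    return np.asarray(vol.get_fdata()), vol.affine


def save_nifti(path: str | Path, data: np.ndarray,
               affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                             np.eye(4) if affine is None else affine), str(path))


def load_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path) -> DWIProtocol:
    """FSL-layout gradient table: bvals 1xN, bvecs 3xN whitespace text."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] != 3:
        raise ValueError("bvecs file must have three rows (FSL layout)")
    return DWIProtocol(bvals=bvals, bvecs=bvecs.T)


def save_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path,
                     protocol: DWIProtocol) -> None:
    np.savetxt(bvals_path, protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, protocol.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Nested stage configuration with strict JSON round-tripping."""

    st: STConfig = dataclasses.field(default_factory=STConfig)
    cells: CellCountConfig = dataclasses.field(default_factory=CellCountConfig)
    stats: StatsConfig = dataclasses.field(default_factory=StatsConfig)
    seed: int = 0
    out_dir: str = "histotensor_out"
    log_level: str = "INFO"

    def substream(self, stage: str) -> int:
        """Derive a stable per-stage seed from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


_SECTIONS = {"st": STConfig, "cells": CellCountConfig, "stats": StatsConfig}


def _to_dict(cfg: RunConfig) -> dict:
    out: dict = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return out


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(json.dumps(_to_dict(cfg), indent=2, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON; unknown keys raise."""
    raw = json.loads(Path(path).read_text())
    kwargs: dict = {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for name, value in raw.items():
        if name in _SECTIONS:
            cls = _SECTIONS[name]
            extra = set(value) - {f.name for f in dataclasses.fields(cls)}
            if extra:
                raise ValueError(f"unknown keys in '{name}': {sorted(extra)}")
            value = cls(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in value.items()})
        kwargs[name] = value
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
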