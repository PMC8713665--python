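"""Disk formats: multi-page TIFF datacubes with YAML sidecar metadata,
map/overlay export, and plain-text configs for filter banks and profiles."""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import tifffile
import yaml

from .calibration import CubeMeta, Datacube
from .profiling import ProfileSpec
from .unmixing import TissueMaps

__all__ = [
    "write_datacube",
    "read_datacube",
    "write_tissue_maps",
    "read_so2_map",
    "load_profile_spec",
    "write_profile_spec",
]


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".yaml"


def write_datacube(path: str, cube: Datacube) -> None:
    """One grayscale page per band (float32), band order = filter order,
    plus a YAML sidecar carrying the acquisition metadata."""
    tifffile.imwrite(path, cube.values.astype(np.float32))
    meta = {
        "band_centres_nm": list(cube.meta.band_centres_nm),
        "band_fwhm_nm": list(cube.meta.band_fwhm_nm),
        "exposure_ms": cube.meta.exposure_ms,
        "gain_db": cube.meta.gain_db,
        "timestamp": cube.meta.timestamp,
        "sensor_max": cube.meta.sensor_max,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_datacube(path: str) -> Datacube:
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim == 2:
        values = values[None]
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            m = yaml.safe_load(fh)
        meta = CubeMeta(
            band_centres_nm=tuple(m["band_centres_nm"]),
            band_fwhm_nm=tuple(m["band_fwhm_nm"]),
            exposure_ms=float(m.get("exposure_ms", 33.0)),
            gain_db=float(m.get("gain_db", 0.0)),
            timestamp=float(m.get("timestamp", 0.0)),
            sensor_max=float(m.get("sensor_max", 4095.0)),
        )
    else:  # minimal metadata when no sidecar accompanies the stack
        meta = CubeMeta(
            band_centres_nm=tuple(float(i) for i in range(values.shape[0])),
            band_fwhm_nm=tuple(1.0 for _ in range(values.shape[0])),
        )
    return Datacube(values, meta)


def write_tissue_maps(out_dir: str, maps: TissueMaps) -> None:
    """Export each map as a grayscale TIFF (SO2 on its 0-100 scale, CoD 0-1)
    plus the validity mask; invalid pixels carry the 0 sentinel."""
    os.makedirs(out_dir, exist_ok=True)
    for name in ("hbo2", "hb", "fat", "g_offset", "cod", "so2", "thb"):
        tifffile.imwrite(
            os.path.join(out_dir, f"{name}.tif"),
            getattr(maps, name).astype(np.float32),
        )
    tifffile.imwrite(
        os.path.join(out_dir, "valid.tif"), maps.valid.astype(np.uint8)
    )


def read_so2_map(maps_dir: str) -> TissueMaps:
    """Re-load exported maps into a TissueMaps container."""
    load = lambda n: np.asarray(
        tifffile.imread(os.path.join(maps_dir, f"{n}.tif")), dtype=float
    )
    return TissueMaps(
        hbo2=load("hbo2"),
        hb=load("hb"),
        fat=load("fat"),
        g_offset=load("g_offset"),
        cod=load("cod"),
        valid=load("valid").astype(bool),
        so2=load("so2"),
        thb=load("thb"),
    )


def load_profile_spec(path: str) -> tuple[ProfileSpec, Optional[float]]:
    """Read a profile definition (and optional decision position, cm) from
    a YAML config block."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec = ProfileSpec(
        start_point=tuple(cfg["start_point"]),
        end_point=tuple(cfg["end_point"]),
        n_divisions=int(cfg.get("n_divisions", 10)),
        roi_width=float(cfg.get("roi_width", 40.0)),
        roi_length=(
            float(cfg["roi_length"]) if cfg.get("roi_length") is not None else None
        ),
        mm_per_pixel=float(cfg.get("mm_per_pixel", 1.0)),
    )
    decision = cfg.get("decision_cm")
    return spec, (float(decision) if decision is not None else None)


def write_profile_spec(
    path: str, spec: ProfileSpec, decision_cm: Optional[float] = None
) -> None:
    cfg = {
        "start_point": list(spec.start_point),
        "end_point": list(spec.end_point),
        "n_divisions": spec.n_divisions,
        "roi_width": spec.roi_width,
        "roi_length": spec.roi_length,
        "mm_per_pixel": spec.mm_per_pixel,
    }
    if decision_cm is not None:
        cfg["decision_cm"] = decision_cm
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
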