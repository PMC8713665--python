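"""Raw-count calibration: dark subtraction, white-reference normalisation,
and conversion to absorbance.

A multispectral acquisition is a stack of B grayscale images, one per filter,
in detector counts.  A dark stack (illumination off) captures the sensor
offset and a white stack (diffuse reflectance standard) captures the combined
illuminant spectrum and system sensitivity.  Reflectance is

    R = (I_raw - I_dark) / (I_white - I_dark)

per pixel per band, and absorbance A = -log10(R), which under the modified
Beer-Lambert law is linear in chromophore concentrations plus a scattering
offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import CalibrationError, StructuralError

__all__ = [
    "CubeMeta",
    "Datacube",
    "ReflectanceCube",
    "AbsorbanceCube",
    "dark_correct",
    "to_reflectance",
    "to_absorbance",
    "DEFAULT_R_FLOOR",
    "DEFAULT_DENOM_EPS",
    "SENSOR_MAX_12BIT",
]

#: Reflectance floor before the log, keeping absorbance finite.
DEFAULT_R_FLOOR = 1e-4
#: Minimum white-minus-dark denominator (counts) for a valid pixel.
DEFAULT_DENOM_EPS = 1.0
#: Full-scale count of the 12-bit sensor; pixels at this value are saturated.
SENSOR_MAX_12BIT = 4095.0


@dataclass(frozen=True)
class CubeMeta:
    """Acquisition metadata travelling with a stack."""

    band_centres_nm: tuple[float, ...]
    band_fwhm_nm: tuple[float, ...]
    exposure_ms: float = 33.0
    gain_db: float = 0.0
    timestamp: float = 0.0
    sensor_max: float = SENSOR_MAX_12BIT


@dataclass(frozen=True)
class Datacube:
    """B x H x W stack of raw (or dark-corrected) intensities in counts."""

    values: np.ndarray
    meta: CubeMeta

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise StructuralError("datacube must be B x H x W")
        if len(self.meta.band_centres_nm) != v.shape[0]:
            raise StructuralError(
                f"{v.shape[0]} bands but {len(self.meta.band_centres_nm)} band centres"
            )
        if np.any(v < 0):
            raise StructuralError("raw intensities must be >= 0")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass(frozen=True)
class ReflectanceCube:
    """Dimensionless reflectance per band, with a per-pixel validity mask
    (False where the white-reference denominator vanished or the sensor
    saturated)."""

    values: np.ndarray
    meta: CubeMeta
    valid: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass(frozen=True)
class AbsorbanceCube:
    """Base-10 absorbance per band; finite everywhere by construction."""

    values: np.ndarray
    meta: CubeMeta
    valid: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


def _check_compatible(a: Datacube, b: Datacube, what: str) -> None:
    if a.values.shape != b.values.shape:
        raise StructuralError(f"{what}: shape {b.values.shape} != {a.values.shape}")
    if a.meta.band_centres_nm != b.meta.band_centres_nm:
        raise StructuralError(f"{what}: band order differs")


def dark_correct(raw: Datacube, dark: Datacube) -> Datacube:
    """Subtract the dark stack per pixel per band, clipping negatives to 0."""
    _check_compatible(raw, dark, "dark_correct")
    return Datacube(np.clip(raw.values - dark.values, 0.0, None), raw.meta)


def to_reflectance(
    raw: Datacube,
    white: Datacube,
    dark: Optional[Datacube] = None,
    *,
    denom_eps: float = DEFAULT_DENOM_EPS,
) -> ReflectanceCube:
    """White-reference normalisation to dimensionless reflectance.

    R = (I_raw - I_dark) / (I_white - I_dark) per pixel per band.  When
    ``dark`` is None both stacks are taken as already dark-corrected.
    Pixels whose denominator falls at or below ``denom_eps`` counts, and
    pixels saturated in the raw stack, are marked invalid (R set to 0 there).
    Values above 1 are possible from noise and are left as-is.
    """
    _check_compatible(raw, white, "to_reflectance")
    if dark is not None:
        _check_compatible(raw, dark, "to_reflectance")
        num = raw.values - dark.values
        den = white.values - dark.values
    else:
        num = raw.values.copy()
        den = white.values.copy()
    if np.all(den <= denom_eps):
        raise CalibrationError("white reference carries no signal above dark")
    bad = den <= denom_eps
    saturated = raw.values >= raw.meta.sensor_max
    den = np.where(bad, 1.0, den)
    r = np.clip(num, 0.0, None) / den
    valid = ~(bad | saturated)
    r = np.where(valid, r, 0.0)
    return ReflectanceCube(r, raw.meta, valid)


def to_absorbance(
    r: ReflectanceCube, *, r_floor: float = DEFAULT_R_FLOOR
) -> AbsorbanceCube:
    """A = -log10(max(R, r_floor)); the floor keeps A finite everywhere."""
    a = -np.log10(np.clip(r.values, r_floor, None))
    return AbsorbanceCube(a, r.meta, r.valid.copy())
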