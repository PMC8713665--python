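"""Per-pixel spectral unmixing of absorbance into chromophore maps.

Each pixel's B-band absorbance vector is regressed (ordinary, unconstrained
least squares) on the band-convolved extinction spectra of HbO2, Hb and fat
plus a constant scattering offset G:

    A_b = [HbO2] e_HbO2,b + [Hb] e_Hb,b + [Fat] e_Fat,b + G

Fit quality is the coefficient of determination (CoD).  Pixels with CoD
below threshold (default 0.9) or any negative concentration are assigned the
sentinel 0 and excluded from quantitative analysis via a boolean validity
mask; downstream statistics always consult the mask, never the sentinel.
Derived maps are total haemoglobin THb = HbO2 + Hb and oxygen saturation
SO2 = 100 * HbO2 / THb (percent).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .calibration import AbsorbanceCube, Datacube, ReflectanceCube, dark_correct, to_absorbance, to_reflectance
from .errors import FitError
from .spectra import (
    DesignMatrix,
    ExtinctionSpectrum,
    FilterBank,
    build_design_matrix,
    default_filter_bank,
    load_default_spectra,
)

__all__ = [
    "TissueMaps",
    "fit_pixel",
    "fit_cube",
    "apply_validity_filter",
    "derive_so2_thb",
    "rgb_from_cube",
    "overlay_so2",
    "process_cube",
    "DEFAULT_COD_THRESHOLD",
]

DEFAULT_COD_THRESHOLD = 0.9

_TINY_SS = 1e-12


@dataclass(frozen=True)
class TissueMaps:
    """Per-pixel chromophore maps plus derived SO2/THb and validity mask.

    Invalid pixels carry 0 in every map except ``g_offset``; ``so2`` is in
    percent (0-100) where valid.
    """

    hbo2: np.ndarray
    hb: np.ndarray
    fat: np.ndarray
    g_offset: np.ndarray
    cod: np.ndarray
    valid: np.ndarray
    so2: np.ndarray
    thb: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hbo2.shape


def _fit_arrays(y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of B x N absorbance columns; returns (4 x N coeffs,
    N-vector CoD)."""
    x = design.values
    if x.shape[0] < x.shape[1]:
        raise FitError(
            f"{x.shape[0]} bands cannot identify {x.shape[1]} components"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise FitError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    ss_res = np.einsum("bn,bn->n", resid, resid)
    centred = y - y.mean(axis=0, keepdims=True)
    ss_tot = np.einsum("bn,bn->n", centred, centred)
    cod = np.where(
        ss_tot > _TINY_SS,
        1.0 - ss_res / np.where(ss_tot > _TINY_SS, ss_tot, 1.0),
        np.where(ss_res <= _TINY_SS, 1.0, 0.0),
    )
    return coef, np.clip(cod, 0.0, 1.0)


def fit_pixel(
    absorbance_vector: np.ndarray, design: DesignMatrix
) -> tuple[float, float, float, float, float]:
    """Fit one pixel; returns (hbo2, hb, fat, g, cod)."""
    y = np.asarray(absorbance_vector, dtype=float).reshape(-1, 1)
    if y.shape[0] != design.n_bands:
        raise FitError(f"expected {design.n_bands} bands, got {y.shape[0]}")
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite absorbance vector")
    coef, cod = _fit_arrays(y, design)
    return (*(float(c) for c in coef[:, 0]), float(cod[0]))


def fit_cube(a: AbsorbanceCube, design: DesignMatrix) -> TissueMaps:
    """Run the per-pixel regression at every spatial location.

    Pixels with any non-finite band, or flagged invalid by calibration, are
    fitted where possible but marked invalid in the returned maps.
    """
    if a.n_bands != design.n_bands:
        raise FitError(
            f"cube has {a.n_bands} bands but design has {design.n_bands} rows"
        )
    h, w = a.shape
    y = a.values.reshape(a.n_bands, -1)
    finite = np.all(np.isfinite(y), axis=0)
    y_safe = np.where(finite[None, :], y, 0.0)
    coef, cod = _fit_arrays(y_safe, design)
    valid = finite & np.all(a.valid.reshape(a.n_bands, -1), axis=0)
    shape = (h, w)
    return TissueMaps(
        hbo2=coef[0].reshape(shape),
        hb=coef[1].reshape(shape),
        fat=coef[2].reshape(shape),
        g_offset=coef[3].reshape(shape),
        cod=np.where(finite, cod, 0.0).reshape(shape),
        valid=valid.reshape(shape),
        so2=np.zeros(shape),
        thb=np.zeros(shape),
    )


def apply_validity_filter(
    maps: TissueMaps,
    cod_threshold: float = DEFAULT_COD_THRESHOLD,
    *,
    neg_tol: float = 1e-9,
) -> TissueMaps:
    """Exclude poorly-fitted pixels: CoD below threshold or any negative
    concentration.  Excluded pixels get the 0 sentinel in every
    concentration-derived map; the scattering offset is left untouched.

    ``neg_tol`` is the round-off allowance for the negativity test: an
    exactly-zero true concentration is recovered as +/- machine noise by the
    least-squares fit and must not be excluded for it.  Concentrations in
    (-neg_tol, 0) are clamped to 0 rather than rejected.
    """
    if not 0.0 <= cod_threshold <= 1.0:
        raise ValueError("cod_threshold must lie in [0, 1]")
    valid = (
        maps.valid
        & (maps.cod >= cod_threshold)
        & (maps.hbo2 >= -neg_tol)
        & (maps.hb >= -neg_tol)
        & (maps.fat >= -neg_tol)
    )
    z = lambda m: np.where(valid, np.clip(m, 0.0, None), 0.0)
    return replace(
        maps,
        hbo2=z(maps.hbo2),
        hb=z(maps.hb),
        fat=z(maps.fat),
        so2=z(maps.so2),
        thb=z(maps.thb),
        valid=valid,
    )


def derive_so2_thb(maps: TissueMaps, *, thb_eps: float = 1e-9) -> TissueMaps:
    """Compute THb = HbO2 + Hb and SO2 = 100 * HbO2 / THb (percent).

    Valid pixels with THb = 0 carry no haemoglobin signal and become
    invalid (their SO2 is undefined); ``thb_eps`` is the numerical zero for
    that test, so round-off dust in a haemoglobin-free pixel does not
    produce a spurious saturation value."""
    thb = maps.hbo2 + maps.hb
    valid = maps.valid & (thb > thb_eps)
    so2 = np.zeros_like(thb)
    np.divide(100.0 * maps.hbo2, thb, out=so2, where=valid)
    return replace(
        maps,
        so2=np.where(valid, so2, 0.0),
        thb=np.where(valid, thb, 0.0),
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Colour synthesis


def _camera_rgb_response(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth approximation of a typical colour-camera Bayer response,
    rows = (R, G, B), evaluated at the given wavelengths."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    r = np.exp(-(((wl - 610.0) / 45.0) ** 2))
    g = np.exp(-(((wl - 540.0) / 45.0) ** 2))
    b = np.exp(-(((wl - 465.0) / 35.0) ** 2))
    return np.stack([r, g, b])


def rgb_from_cube(
    r: ReflectanceCube,
    bank: FilterBank,
    response: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Reconstruct an H x W x 3 colour image from the reflectance cube.

    Each colour plane is a weighted sum of the bands, the weights being a
    colour-camera spectral response evaluated at the band centres and
    normalised per channel so a unit-reflectance cube maps to white.
    Output is clipped to [0, 1].
    """
    if r.n_bands != len(bank):
        raise ValueError("band count does not match filter bank")
    weights = (
        np.asarray(response, dtype=float)
        if response is not None
        else _camera_rgb_response(bank.centres)
    )
    weights = weights / weights.sum(axis=1, keepdims=True)
    img = np.tensordot(weights, r.values, axes=(1, 0))  # 3 x H x W
    return np.clip(np.moveaxis(img, 0, -1), 0.0, 1.0)


def overlay_so2(
    rgb: np.ndarray,
    maps: TissueMaps,
    *,
    cmap: str = "viridis",
    thb_ref: Optional[float] = None,
) -> np.ndarray:
    """Blend the SO2 map over the colour image with THb-weighted opacity.

    Per pixel: out = alpha * colormap(SO2) + (1 - alpha) * rgb, with
    alpha = clip(THb / thb_ref, 0, 1) and thb_ref the 99th percentile of
    valid THb (strong haemoglobin signal shows the oximetry colour, weak
    signal falls back to the anatomy).  Invalid pixels show pure rgb.
    """
    import matplotlib

    if rgb.shape[:2] != maps.shape:
        raise ValueError("rgb and maps shapes differ")
    if thb_ref is None:
        if maps.valid.any():
            thb_ref = float(np.percentile(maps.thb[maps.valid], 99))
        else:
            thb_ref = 0.0
    if thb_ref <= 0:
        return rgb.copy()
    alpha = np.clip(maps.thb / thb_ref, 0.0, 1.0) * maps.valid
    colours = matplotlib.colormaps[cmap](np.clip(maps.so2 / 100.0, 0.0, 1.0))[..., :3]
    return alpha[..., None] * colours + (1.0 - alpha[..., None]) * rgb


# ---------------------------------------------------------------------------
# Convenience pipeline


def process_cube(
    raw: Datacube,
    dark: Datacube,
    white: Datacube,
    *,
    bank: Optional[FilterBank] = None,
    spectra: Optional[tuple[ExtinctionSpectrum, ...]] = None,
    cod_threshold: float = DEFAULT_COD_THRESHOLD,
) -> tuple[TissueMaps, ReflectanceCube]:
    """Full single-stack pipeline: calibrate, unmix, filter, derive SO2/THb.

    Returns the finished tissue maps together with the reflectance cube
    (useful for RGB reconstruction and overlays).
    """
    bank = bank or default_filter_bank()
    spectra = spectra or load_default_spectra()
    design = build_design_matrix(bank, spectra)
    refl = to_reflectance(raw, white, dark)
    absorb = to_absorbance(refl)
    maps = fit_cube(absorb, design)
    maps = apply_validity_filter(maps, cod_threshold)
    maps = derive_so2_thb(maps)
    return maps, refl
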