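"""Chromophore extinction spectra, the camera's Gaussian filter bank, and the
band-convolved design matrix.

The camera samples tissue reflectance through a wheel of narrow-band filters
with Gaussian transmission profiles.  What the detector sees in band *b* is
not the extinction coefficient at the filter's centre wavelength but the
passband-weighted average of the wavelength-resolved spectrum.  This module
computes those band coefficients and assembles them, together with a constant
column for the wavelength-independent scattering offset G, into the B x 4
design matrix used both by the per-pixel unmixing fit and (through its own
fine-grid code path) by the synthetic forward model.

The packaged extinction tables are smooth synthetic approximations of the
visible-band spectra of oxyhaemoglobin, deoxyhaemoglobin and white adipose
tissue, in relative units on a common 450-650 nm grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateFilterError,
    DomainCoverageError,
    IllConditionedBankWarning,
)

__all__ = [
    "ExtinctionSpectrum",
    "SpectralFilter",
    "FilterBank",
    "DesignMatrix",
    "gaussian_transmission",
    "band_convolve",
    "build_design_matrix",
    "load_extinction",
    "load_default_spectra",
    "default_filter_bank",
    "load_filter_bank",
    "DEFAULT_CENTRES_NM",
]

#: Default 8-filter octet (nm).  470, 520 and 645 nm are fixed by the
#: instrument description; the remainder straddle the oxy/deoxy-haemoglobin
#: difference features (546/560/577 nm isosbestic and alpha/beta bands).
DEFAULT_CENTRES_NM: tuple[float, ...] = (470, 500, 520, 546, 560, 577, 600, 645)
DEFAULT_FWHM_NM = 20.0
DEFAULT_PEAK = 0.9

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Wavelength-resolved extinction coefficient of one chromophore.

    ``wavelengths`` must be a strictly increasing uniform grid (nm) and
    ``epsilon`` finite and non-negative, in relative units consistent
    across chromophores.
    """

    chromophore_name: str
    wavelengths: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array of >= 2 points")
        steps = np.diff(wl)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("wavelength grid must be strictly increasing and uniform")
        if eps.shape != wl.shape:
            raise ValueError("epsilon and wavelengths must have the same shape")
        if not np.all(np.isfinite(eps)) or np.any(eps < 0):
            raise ValueError("epsilon must be finite and >= 0 everywhere")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass(frozen=True)
class SpectralFilter:
    """One Gaussian band-pass filter of the wheel."""

    centre_wavelength: float
    fwhm: float
    peak_transmission: float = DEFAULT_PEAK

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0 < self.peak_transmission <= 1:
            raise ValueError("peak_transmission must lie in (0, 1]")


@dataclass(frozen=True)
class FilterBank:
    """Ordered set of spectral filters; order equals band order in a datacube."""

    filters: tuple[SpectralFilter, ...]

    def __post_init__(self) -> None:
        filters = tuple(self.filters)
        object.__setattr__(self, "filters", filters)
        if not filters:
            raise ValueError("filter bank must contain at least one filter")
        centres = [f.centre_wavelength for f in filters]
        if any(b <= a for a, b in zip(centres, centres[1:])):
            raise ValueError("centre wavelengths must be strictly increasing")
        if len(set(filters)) != len(filters):
            raise ValueError("filters must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)

    @property
    def centres(self) -> np.ndarray:
        return np.array([f.centre_wavelength for f in self.filters])


@dataclass(frozen=True)
class DesignMatrix:
    """B x 4 matrix: band-convolved epsilon for HbO2, Hb, fat, plus a ones
    column absorbing the scattering offset G."""

    values: np.ndarray
    chromophores: tuple[str, ...] = ("hbo2", "hb", "fat", "g")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))


def gaussian_transmission(
    filt: SpectralFilter, wavelengths: np.ndarray
) -> np.ndarray:
    """Transmission of a Gaussian filter evaluated on a wavelength grid.

    T(lambda) = peak * exp(-4 ln2 (lambda - centre)^2 / fwhm^2), so that
    T(centre +/- fwhm/2) = peak / 2.  The filter centre must lie inside the
    grid span or a :class:`DomainCoverageError` is raised; band edges may be
    truncated by the grid (the convolution weights are defined over the
    grid, and :func:`band_convolve` separately checks that the grid captures
    the bulk of the passband weight).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if not wl.min() <= filt.centre_wavelength <= wl.max():
        raise DomainCoverageError(
            f"grid [{wl.min():g}, {wl.max():g}] nm does not contain the "
            f"{filt.centre_wavelength:g} nm filter centre"
        )
    z = (wl - filt.centre_wavelength) / filt.fwhm
    return filt.peak_transmission * np.exp(-_FOUR_LN2 * z * z)


def band_convolve(spectrum: ExtinctionSpectrum, filt: SpectralFilter) -> float:
    """Transmission-weighted mean of a spectrum over one filter passband.

    Returns the composite-trapezoid quadrature of eps * T over the grid,
    normalised by that of T (for a uniform grid: sum(eps * T) / sum(T) with
    half-weighted endpoints, second-order accurate in the grid step even
    when the grid truncates an edge filter's tail).  White-reference
    normalisation cancels illuminant and throughput scale, so only the
    passband *shape* matters and the result is independent of the filter's
    peak transmission.

    The grid must capture at least half of the filter's total transmission
    weight (edge filters may have mildly truncated tails); a grid carrying
    essentially no passband weight raises a degenerate-filter error.
    """
    t = gaussian_transmission(filt, spectrum.wavelengths)
    quad = np.ones_like(t)
    quad[0] = quad[-1] = 0.5  # trapezoid endpoint weights (uniform grid)
    t = t * quad
    total = t.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateFilterError("zero total transmission weight on the grid")
    # fraction of the analytic Gaussian weight falling inside the grid span
    from scipy.special import erf

    sigma = filt.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    wl = spectrum.wavelengths
    lo = (wl.min() - filt.centre_wavelength) / (sigma * np.sqrt(2.0))
    hi = (wl.max() - filt.centre_wavelength) / (sigma * np.sqrt(2.0))
    captured = 0.5 * (erf(hi) - erf(lo))
    if captured < 0.5:
        raise DomainCoverageError(
            f"grid captures only {captured:.0%} of the "
            f"{filt.centre_wavelength:g} nm passband weight"
        )
    return float(np.dot(spectrum.epsilon, t) / total)


def build_design_matrix(
    bank: FilterBank, spectra: Sequence[ExtinctionSpectrum]
) -> DesignMatrix:
    """Assemble the unmixing design matrix for a filter bank.

    ``spectra`` are the three chromophore spectra (HbO2, Hb, fat) on a common
    grid; row *b* of the result is their band coefficients at filter *b*
    followed by the constant 1 for the scattering offset.  A rank-deficient
    result raises an :class:`IllConditionedBankWarning` for the caller.
    """
    if len(spectra) != 3:
        raise ValueError("exactly three chromophore spectra are required")
    ref = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != ref.shape or not np.allclose(s.wavelengths, ref):
            raise ValueError("all spectra must share a common wavelength grid")
    rows = [
        [band_convolve(s, f) for s in spectra] + [1.0] for f in bank
    ]
    design = DesignMatrix(
        values=np.asarray(rows, dtype=float),
        chromophores=tuple(s.chromophore_name for s in spectra) + ("g",),
    )
    if design.rank < 4:
        warnings.warn(
            f"design matrix rank {design.rank} < 4: "
            "filter bank cannot separate the chromophores",
            IllConditionedBankWarning,
            stacklevel=2,
        )
    return design


# ---------------------------------------------------------------------------
# Packaged data and configuration


def _read_extinction_table(text: str, name: str) -> ExtinctionSpectrum:
    wl, eps = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("wavelength"):
            continue
        a, b = line.split("\t")
        wl.append(float(a))
        eps.append(float(b))
    return ExtinctionSpectrum(name, np.array(wl), np.array(eps))


def load_extinction(path_or_name: str) -> ExtinctionSpectrum:
    """Load an extinction table from a TSV file, or one of the packaged
    synthetic tables by short name ('hbo2', 'hb', 'fat')."""
    if path_or_name in ("hbo2", "hb", "fat"):
        ref = resources.files("oxymap.data") / f"{path_or_name}_extinction_synthetic.tsv"
        return _read_extinction_table(ref.read_text(), path_or_name)
    with open(path_or_name) as fh:
        name = path_or_name.rsplit("/", 1)[-1].split(".")[0]
        return _read_extinction_table(fh.read(), name)


def load_default_spectra() -> tuple[ExtinctionSpectrum, ExtinctionSpectrum, ExtinctionSpectrum]:
    """The packaged (HbO2, Hb, fat) synthetic extinction spectra."""
    return load_extinction("hbo2"), load_extinction("hb"), load_extinction("fat")


def default_filter_bank() -> FilterBank:
    """The default 8-filter Gaussian bank (see :data:`DEFAULT_CENTRES_NM`)."""
    return FilterBank(
        tuple(
            SpectralFilter(c, DEFAULT_FWHM_NM, DEFAULT_PEAK)
            for c in DEFAULT_CENTRES_NM
        )
    )


def load_filter_bank(path: str) -> FilterBank:
    """Read a filter bank from a YAML config: a list of mappings with keys
    ``centre_nm``, ``fwhm_nm`` and optional ``peak``; list order = band order."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if isinstance(entries, dict):
        entries = entries["filters"]
    return FilterBank(
        tuple(
            SpectralFilter(
                float(e["centre_nm"]),
                float(e["fwhm_nm"]),
                float(e.get("peak", DEFAULT_PEAK)),
            )
            for e in entries
        )
    )
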