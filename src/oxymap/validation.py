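"""Spectral validation against ground-truth reflectance curves.

The imaging system is validated by imaging a colour-checker card whose
panels have known wavelength-resolved reflectance (measured independently
with a spectrometer).  The truth curve of each panel is convolved with each
filter passband — exactly as the chromophore spectra are — so that it can be
compared band-by-band with the mean reflectance the camera reports for that
panel.  Agreement is summarised with a Bland-Altman analysis: mean paired
difference and ±1.96·SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import ReflectanceCube
from .spectra import ExtinctionSpectrum, FilterBank, band_convolve

__all__ = [
    "PanelMeasurement",
    "AgreementSummary",
    "truth_to_bands",
    "panel_mean_reflectance",
    "bland_altman",
    "validate_card",
]


@dataclass(frozen=True)
class PanelMeasurement:
    """Band reflectances measured for one panel, with its truth curve."""

    panel_id: str
    msi_reflectance: np.ndarray  # B values
    truth_wavelengths: np.ndarray
    truth_reflectance: np.ndarray


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman agreement between paired measurements."""

    mean_difference: float
    limits_of_agreement: float  # 1.96 * sample SD of the differences
    table: pd.DataFrame  # columns: pair_mean, difference, band, wavelength_nm

    @property
    def lower(self) -> float:
        return self.mean_difference - self.limits_of_agreement

    @property
    def upper(self) -> float:
        return self.mean_difference + self.limits_of_agreement


def truth_to_bands(
    wavelengths: np.ndarray, reflectance: np.ndarray, bank: FilterBank
) -> np.ndarray:
    """Convolve a wavelength-resolved reflectance curve with every filter
    passband; shares the band-convolution implementation of the spectral
    model, so the comparison uses exactly the camera's spectral sampling."""
    spec = ExtinctionSpectrum("truth", np.asarray(wavelengths), np.asarray(reflectance))
    return np.array([band_convolve(spec, f) for f in bank])


def panel_mean_reflectance(r: ReflectanceCube, panel_mask: np.ndarray) -> np.ndarray:
    """Per-band mean reflectance over one panel's pixels."""
    mask = np.asarray(panel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty panel mask")
    return np.array([band[mask].mean() for band in r.values])


def bland_altman(
    x: np.ndarray,
    y: np.ndarray,
    *,
    bands: Optional[np.ndarray] = None,
    wavelengths: Optional[np.ndarray] = None,
) -> AgreementSummary:
    """Bland-Altman agreement of paired measurements x and y.

    Differences d = x - y; limits of agreement are 1.96 times the sample
    (n-1) standard deviation of d.  Optional ``bands``/``wavelengths`` label
    each pair for the per-wavelength difference view.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired arrays must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean_diff = float(d.mean())
    loa = float(1.96 * d.std(ddof=1))
    table = pd.DataFrame(
        {
            "pair_mean": (x + y) / 2.0,
            "difference": d,
            "band": np.asarray(bands).ravel() if bands is not None else np.arange(x.size),
            "wavelength_nm": (
                np.asarray(wavelengths, dtype=float).ravel()
                if wavelengths is not None
                else np.full(x.size, np.nan)
            ),
        }
    )
    return AgreementSummary(mean_diff, loa, table)


def validate_card(
    r: ReflectanceCube,
    panel_masks: Sequence[np.ndarray],
    truth_curves: Sequence[tuple[np.ndarray, np.ndarray]],
    bank: FilterBank,
) -> tuple[AgreementSummary, list[PanelMeasurement]]:
    """Full colour-card validation: panel means vs band-convolved truths.

    ``truth_curves`` is one (wavelengths, reflectance) pair per panel, in
    panel order.  Returns the pooled Bland-Altman summary across all panels
    and bands, plus the per-panel measurements.
    """
    if len(panel_masks) != len(truth_curves):
        raise ValueError("one truth curve per panel mask is required")
    centres = bank.centres
    msi_all, truth_all, band_idx, wl_all = [], [], [], []
    panels = []
    for i, (mask, (wl, refl)) in enumerate(zip(panel_masks, truth_curves)):
        msi = panel_mean_reflectance(r, mask)
        truth = truth_to_bands(wl, refl, bank)
        panels.append(PanelMeasurement(f"panel_{i + 1}", msi, np.asarray(wl), np.asarray(refl)))
        msi_all.append(msi)
        truth_all.append(truth)
        band_idx.append(np.arange(len(bank)))
        wl_all.append(centres)
    summary = bland_altman(
        np.concatenate(msi_all),
        np.concatenate(truth_all),
        bands=np.concatenate(band_idx),
        wavelengths=np.concatenate(wl_all),
    )
    return summary, panels
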