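"""Forward-model phantom generator.

Builds scenes with known chromophore concentration maps, runs the
Beer-Lambert model forwards through the filter bank to raw detector counts
(with dark/white calibration stacks), and optionally adds signal-proportional
Gaussian noise and inter-stack translation jitter emulating respiration.

The forward path deliberately does NOT use the unmixing design matrix: band
absorbances are obtained by mixing the wavelength-resolved extinction
spectra on their fine grid per pixel and convolving the mixed spectrum with
each filter passband.  The unmixing fit works from per-band coefficients, so
round-trip recovery is an integration test of both code paths, not a
tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .calibration import CubeMeta, Datacube
from .errors import StructuralError
from .spectra import (
    ExtinctionSpectrum,
    FilterBank,
    SpectralFilter,
    band_convolve,
    default_filter_bank,
    load_default_spectra,
)

__all__ = [
    "PhantomScene",
    "AcquisitionModel",
    "forward_cube",
    "bowel_phantom",
    "uniform_phantom",
    "noisy_sequence",
    "synthetic_colour_card",
    "axis_division_index",
]

DEFAULT_WHITE_LEVEL = 3500.0
DEFAULT_DARK_LEVEL = 100.0


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth scene: non-negative concentration maps, scattering
    offset, tissue mask, labels, and (for bowel phantoms) the segment axis."""

    hbo2: np.ndarray
    hb: np.ndarray
    fat: np.ndarray
    g_map: np.ndarray
    tissue_mask: np.ndarray
    labels: np.ndarray  # 0 background, 1 serosa, 2 fat border
    axis_start: Optional[tuple[float, float]] = None  # (row, col)
    axis_end: Optional[tuple[float, float]] = None
    so2_profile: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        for name in ("hbo2", "hb", "fat"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} map must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hbo2.shape

    @property
    def so2(self) -> np.ndarray:
        """Ground-truth SO2 (%) where THb > 0, else 0."""
        thb = self.hbo2 + self.hb
        out = np.zeros_like(thb)
        np.divide(100.0 * self.hbo2, thb, out=out, where=thb > 0)
        return out


@dataclass(frozen=True)
class AcquisitionModel:
    """Stochastic acquisition parameters for a simulated sequence."""

    bank: FilterBank = field(default_factory=default_filter_bank)
    white_level: float = DEFAULT_WHITE_LEVEL
    dark_level: float = DEFAULT_DARK_LEVEL
    noise_sigma_rel: float = 0.01
    jitter_sigma_px: float = 2.0
    n_stacks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_rel < 0 or self.jitter_sigma_px < 0:
            raise ValueError("noise and jitter must be >= 0")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")


def _meta(bank: FilterBank, timestamp: float = 0.0) -> CubeMeta:
    return CubeMeta(
        band_centres_nm=tuple(f.centre_wavelength for f in bank),
        band_fwhm_nm=tuple(f.fwhm for f in bank),
        timestamp=timestamp,
    )


def forward_cube(
    scene: PhantomScene,
    bank: Optional[FilterBank] = None,
    spectra: Optional[Sequence[ExtinctionSpectrum]] = None,
    white_level: float = DEFAULT_WHITE_LEVEL,
    dark_level: float = DEFAULT_DARK_LEVEL,
) -> tuple[Datacube, Datacube, Datacube]:
    """Noise-free raw/dark/white stacks for a scene.

    Per pixel the mixed absorbance spectrum
    A(lambda) = [HbO2] e1 + [Hb] e2 + [Fat] e3 + G is formed on the fine
    wavelength grid and convolved with each filter passband; then
    R_b = 10^(-A_b) and counts = dark + R_b * (white - dark).  Concentration
    maps are typically piecewise constant, so the spectral mixing is done
    once per unique concentration tuple.
    """
    bank = bank or default_filter_bank()
    spectra = tuple(spectra) if spectra is not None else load_default_spectra()
    grid = spectra[0].wavelengths
    eps = np.stack([s.epsilon for s in spectra])  # 3 x L

    conc = np.stack(
        [m.ravel() for m in (scene.hbo2, scene.hb, scene.fat, scene.g_map)], axis=1
    )
    if not np.all(np.isfinite(conc)):
        raise ValueError("scene maps must be finite")
    uniq, inverse = np.unique(conc, axis=0, return_inverse=True)

    # mixed fine-grid spectra per unique tuple, then per-band convolution
    mixed = uniq[:, :3] @ eps + uniq[:, 3:4]  # U x L
    a_bands = np.empty((len(bank), len(uniq)))
    for b, filt in enumerate(bank):
        for u in range(len(uniq)):
            a_bands[b, u] = band_convolve(
                ExtinctionSpectrum("mix", grid, np.clip(mixed[u], 0, None)), filt
            )
    h, w = scene.shape
    a_cube = a_bands[:, inverse].reshape(len(bank), h, w)
    r_cube = 10.0 ** (-a_cube)
    raw = dark_level + r_cube * (white_level - dark_level)
    meta = _meta(bank)
    dark = Datacube(np.full_like(raw, dark_level), meta)
    white = Datacube(np.full_like(raw, white_level), meta)
    return Datacube(raw, meta), dark, white


def axis_division_index(
    t: np.ndarray, length: float, n_divisions: int
) -> np.ndarray:
    """Half-open division binning along the axis: position t in
    [k*L/n, (k+1)*L/n) falls in division k; t == L is assigned to the last
    division."""
    k = np.floor(np.asarray(t, dtype=float) * n_divisions / length).astype(int)
    return np.clip(k, 0, n_divisions - 1)


def bowel_phantom(
    so2_profile: Sequence[float],
    thb_level: float = 1.0,
    fat_border: bool = True,
    shape: tuple[int, int] = (256, 512),
    *,
    g_level: float = 0.1,
    tube_halfwidth: Optional[int] = None,
    margin: int = 16,
    fat_level: float = 0.8,
) -> PhantomScene:
    """Tube-shaped bowel-segment scene with a longitudinal SO2 gradient.

    The serosal tube runs horizontally; its extent along the axis is split
    into ``len(so2_profile)`` equal divisions and within division k the
    haemoglobin maps satisfy hbo2 = thb * so2_k/100, hb = thb - hbo2.
    Optional fat-rich strips flank the tube (zero haemoglobin, high fat),
    emulating mesenteric adipose borders; the background carries no
    chromophores.
    """
    profile = np.asarray(so2_profile, dtype=float)
    if np.any((profile < 0) | (profile > 100)):
        raise ValueError("so2_profile values must lie in [0, 100]")
    h, w = shape
    if tube_halfwidth is None:
        tube_halfwidth = h // 4
    cy = h // 2
    x0, x1 = margin, w - margin
    length = float(x1 - x0)
    n_div = len(profile)

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    in_tube = (np.abs(rows - cy) <= tube_halfwidth) & (cols >= x0) & (cols < x1)

    hbo2 = np.zeros(shape)
    hb = np.zeros(shape)
    fat = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[in_tube] = 1

    col_t = np.clip(cols - x0, 0, length - 1e-9)
    div = axis_division_index(np.broadcast_to(col_t, shape), length, n_div)
    so2_map = profile[div] / 100.0
    hbo2 = np.where(in_tube, thb_level * so2_map, 0.0)
    hb = np.where(in_tube, thb_level * (1.0 - so2_map), 0.0)

    if fat_border:
        border = (
            (np.abs(rows - cy) > tube_halfwidth)
            & (np.abs(rows - cy) <= tube_halfwidth + max(4, h // 16))
            & (cols >= x0)
            & (cols < x1)
        )
        fat[border] = fat_level
        labels[border] = 2

    return PhantomScene(
        hbo2=hbo2,
        hb=hb,
        fat=fat,
        g_map=np.full(shape, g_level),
        tissue_mask=in_tube,
        labels=labels,
        axis_start=(float(cy), float(x0)),
        axis_end=(float(cy), float(x1)),
        so2_profile=tuple(profile),
    )


def uniform_phantom(
    so2_percent: float = 75.0,
    thb_level: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    g_level: float = 0.1,
) -> PhantomScene:
    """Spatially uniform tissue slab at the given oxygen saturation."""
    return bowel_phantom(
        [so2_percent],
        thb_level=thb_level,
        fat_border=False,
        shape=shape,
        g_level=g_level,
        tube_halfwidth=max(shape[0], shape[1]),
        margin=0,
    )


def noisy_sequence(
    scene: PhantomScene,
    model: AcquisitionModel,
    spectra: Optional[Sequence[ExtinctionSpectrum]] = None,
) -> tuple[list[Datacube], Datacube, Datacube, np.ndarray]:
    """Simulate a jittered, noisy acquisition sequence.

    Returns (stacks, dark, white, shifts) where ``shifts`` is the
    n_stacks x 2 array of (row, col) scene displacements actually applied —
    the ground truth for registration tests.  Noise is multiplicative
    Gaussian on the above-dark signal (sigma = noise_sigma_rel * signal),
    approximating shot noise at high counts.  All randomness comes from the
    model's seed.
    """
    rng = np.random.default_rng(model.seed)
    clean, dark, white = forward_cube(
        scene, model.bank, spectra, model.white_level, model.dark_level
    )
    signal = clean.values - model.dark_level
    shifts = (
        rng.normal(0.0, model.jitter_sigma_px, size=(model.n_stacks, 2))
        if model.jitter_sigma_px > 0
        else np.zeros((model.n_stacks, 2))
    )
    stacks = []
    for i in range(model.n_stacks):
        sig = signal
        if shifts[i].any():
            sig = np.stack(
                [
                    ndimage.shift(band, shifts[i], order=1, mode="nearest")
                    for band in signal
                ]
            )
        if model.noise_sigma_rel > 0:
            sig = sig * (1.0 + rng.normal(0.0, model.noise_sigma_rel, sig.shape))
        counts = np.clip(model.dark_level + sig, 0.0, None)
        stacks.append(Datacube(counts, _meta(model.bank, timestamp=i * 0.3)))
    return stacks, dark, white, shifts


def synthetic_colour_card(
    n_panels: int = 12,
    seed: int = 0,
    *,
    panel_px: int = 16,
    n_cols: int = 4,
    wavelengths: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Synthetic colour-checker: a grid of uniform panels with smooth random
    reflectance curves bounded to [0.05, 0.95].

    Returns (reflectance_curves [n_panels x L], panel_label_image,
    panel_masks).  The label image is 0 for background and k for panel k
    (1-based).  Seed-deterministic.
    """
    if n_panels < 1:
        raise ValueError("n_panels must be >= 1")
    rng = np.random.default_rng(seed)
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(450.0, 651.0, 1.0)
    )
    curves = np.empty((n_panels, wl.size))
    for i in range(n_panels):
        base = rng.uniform(0.15, 0.85)
        curve = np.full(wl.size, base)
        for _ in range(3):
            c = rng.uniform(wl.min(), wl.max())
            width = rng.uniform(25.0, 80.0)
            amp = rng.uniform(-0.35, 0.35)
            curve = curve + amp * np.exp(-(((wl - c) / width) ** 2))
        curves[i] = np.clip(curve, 0.05, 0.95)

    n_rows = int(np.ceil(n_panels / n_cols))
    gap = 4
    h = n_rows * (panel_px + gap) + gap
    w = n_cols * (panel_px + gap) + gap
    labels = np.zeros((h, w), dtype=np.int32)
    masks = []
    for k in range(n_panels):
        r, c = divmod(k, n_cols)
        r0 = gap + r * (panel_px + gap)
        c0 = gap + c * (panel_px + gap)
        labels[r0 : r0 + panel_px, c0 : c0 + panel_px] = k + 1
        masks.append(labels == k + 1)
    return curves, labels, masks


def card_reflectance_cube(
    curves: np.ndarray,
    labels: np.ndarray,
    bank: Optional[FilterBank] = None,
    *,
    wavelengths: Optional[np.ndarray] = None,
    noise_sigma_rel: float = 0.0,
    seed: int = 0,
):
    """Ideal (optionally noisy) camera view of a synthetic colour card.

    Each panel's band reflectance is the passband-weighted mean of its truth
    curve — what a perfectly calibrated camera would report — placed
    uniformly over the panel's pixels.  Background pixels get reflectance
    0.5.  Returns a :class:`~oxymap.calibration.ReflectanceCube`.
    """
    from .calibration import ReflectanceCube

    bank = bank or default_filter_bank()
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(450.0, 651.0, 1.0)
    )
    band_truths = np.stack(
        [
            [
                band_convolve(ExtinctionSpectrum("panel", wl, c), f)
                for f in bank
            ]
            for c in curves
        ]
    )  # n_panels x B
    h, w = labels.shape
    cube = np.full((len(bank), h, w), 0.5)
    for k in range(curves.shape[0]):
        cube[:, labels == k + 1] = band_truths[k][:, None]
    if noise_sigma_rel > 0:
        rng = np.random.default_rng(seed)
        cube = np.clip(cube * (1.0 + rng.normal(0.0, noise_sigma_rel, cube.shape)), 0.0, None)
    return ReflectanceCube(cube, _meta(bank), np.ones((len(bank), h, w), dtype=bool))
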