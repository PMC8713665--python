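# oxymap

Multispectral tissue oximetry for surgical imaging: turn stacks of
narrow-band reflectance images of exposed organs into per-pixel maps of
oxygen saturation (SO₂) and total haemoglobin (THb), and summarise perfusion
along a bowel segment to support intraoperative decisions such as the choice
of a transection point for an anastomosis.

The package is aimed at researchers working with filter-wheel or similar
multispectral laparoscopes who need a transparent, testable implementation
of the classic visible-band unmixing pipeline — and at anyone who wants to
evaluate such a pipeline end to end without clinical data, using the bundled
forward-model phantom generator.

## The model

A camera behind a wheel of B Gaussian band-pass filters measures reflectance
R_b per band. With a dark stack (sensor offset) and a white-reference stack
(illuminant × system sensitivity):

    R_b = (I_raw,b − I_dark,b) / (I_white,b − I_dark,b),     A_b = −log₁₀ R_b

Under the modified Beer-Lambert law — absorbers limited to oxyhaemoglobin,
deoxyhaemoglobin and fat, wavelength-independent scattering, equal photon
pathlengths — the band absorbance is linear in the relative concentrations:

    A_b = [HbO₂] ε̃_HbO₂,b + [Hb] ε̃_Hb,b + [Fat] ε̃_Fat,b + G

where ε̃_·,b is the chromophore's extinction spectrum convolved with filter
b's passband and G absorbs scattering losses. Each pixel's B-vector of
absorbances is fitted by ordinary least squares; fit quality is the
coefficient of determination (CoD). Pixels with CoD < 0.9 or a negative
concentration are excluded (zero sentinel plus a boolean mask), and the
derived maps are THb = HbO₂ + Hb and SO₂ = 100·HbO₂/THb (%).

Around that core the package provides temporal averaging with translation
registration (respiration-scale motion), longitudinal SO₂ profiling of a
segment through perpendicular ROIs along a user-defined axis, colour-card
spectral validation with Bland-Altman agreement statistics, and a phantom
generator that runs the model forwards from known concentration maps to raw
detector counts (with noise and inter-frame jitter if requested).

## Worked example

Simulate a bowel segment whose axial SO₂ falls from 80% to 65%, unmix it,
and profile it:

```bash
oxymap simulate --scene bowel --profile 80,75,70,65 --shape 24 64 --out sim/
oxymap unmix --input sim/raw_00.tif --dark sim/dark.tif --white sim/white.tif --out maps/
```

which prints

```
valid pixels: 312; mean SO2: 71.67%
```

(312 of the 24×64 pixels carry haemoglobin signal and survive the CoD
filter; their mean SO₂ is the average of the four division values weighted
by visible area.) The same flow through the Python API:

```python
from oxymap.synthetic import bowel_phantom, forward_cube
from oxymap.unmixing import process_cube
from oxymap.profiling import ProfileSpec, build_rois, profile_statistics

scene = bowel_phantom([80, 75, 70, 65], shape=(24, 64))
raw, dark, white = forward_cube(scene)
maps, _ = process_cube(raw, dark, white)
spec = ProfileSpec(scene.axis_start, scene.axis_end, n_divisions=4, roi_width=13)
print(profile_statistics(maps, build_rois(spec, maps.shape), scene.tissue_mask).table)
```

```
   roi  mean  median    q1    q3    n
0    1  80.0    80.0  80.0  80.0  104
1    2  75.0    75.0  75.0  75.0  104
2    3  70.0    70.0  70.0  70.0  104
3    4  65.0    65.0  65.0  65.0  104
```

On a noise-free phantom the pipeline recovers every division's SO₂ exactly:
the forward model mixes the wavelength-resolved spectra and convolves them
per band, while the fit inverts band coefficients, so this is a genuine
round trip of two independent code paths.

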