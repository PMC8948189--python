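# cyclescope

Automation and image-processing toolkit for **cyclic
stain/image/elute (4i) fluorescence experiments** run on a repurposed
line-scan sequencing microscope. It is aimed at labs that drive
iterative indirect immunofluorescence — repeated rounds of antibody
staining, imaging, and antibody elution on one tissue section — and
want the whole pipeline testable without hardware: the package pairs a
discrete-event **virtual instrument** (fluidics, stages, temperature,
TDI cameras) with the image-formation, autofocus, correction, spectral
unmixing, and clustering algorithms the real runs need, all exercised
on synthetic phantoms with known ground truth.

## What's inside

| module | contents |
| --- | --- |
| `cyclescope.protocol` | the six-command recipe language (PORT, PUMP, TEMP, IMAG, HOLD, WAIT), INI-style experiment configs, 4i recipe generation |
| `cyclescope.instrument` | digital twin: 24-port valve, 8×250 µL syringe pump, flowcell temperature dynamics, dual-flowcell scheduler with WAIT sync and a single shared imaging head, TDI line-scan image formation |
| `cyclescope.imaging` | ROI tile planning, JPEG-compressed-size sharpness, the `full` / `partial` / `*_once` / `manual` autofocus routines |
| `cyclescope.correction` | per-readout-group dark offsets, chromatic registration, phase-correlation cycle registration |
| `cyclescope.unmixing` | blind (mutual-information) and linear (weighted-slope) crosstalk estimation and removal, Pearson diagnostics |
| `cyclescope.synthetic` | tissue-like phantoms with planted crosstalk, defocus, dark patterns, and inter-cycle drift |
| `cyclescope.analysis` | 12→16-bit rescaling, histogram adjustment, region histograms, k-means tissue-domain maps |

## The core model: single-coefficient spectral unmixing

Emission from a fluorophore detected in its primary channel
(AF532→558 nm, AF594→610 nm, Cy5→687 nm, AF700→740 nm) partially leaks
into the adjacent channel. With `D_i` the source image and `D_j` the
contaminated image, the unmixed image is

```
D_j_unmixed = D_j − x · D_i
```

The leakage coefficient `x` is estimated two ways:

* **blind** — evaluate the mutual information `I(D_j − x·D_i ; D_i)` on
  a 41-point grid over `x ∈ [0, 2]` and take the minimum of a parabola
  through the grid minimum (a non-iterative mutual-information
  minimization; no reference images needed);
* **linear** — from singleplex reference images,
  `x_l = Σ w·D_i·D_j / Σ w·D_i²` with weights `w = D_i`.

Both run after background subtraction (mode of pixel intensities + 1 SD,
or a registered pre-stain autofluorescence image).

## Worked example

Estimate and remove a planted 30 % leak between two channels of a
synthetic phantom:

```python
import numpy as np
from cyclescope import (PhantomSpec, make_phantom, estimate_leakage_blind,
                        unmix, crosstalk_correlation)

m = np.eye(2); m[1, 0] = 0.3          # 30% leakage, 558 -> 610 nm
spec = PhantomSpec(shape=(256, 256), n_channels=2,
                   structures=("blobs", "rings"), mixing_matrix=m,
                   background_level=20.0, shot_noise=True,
                   read_noise_dn=3.0, rng_seed=42)
ph = make_phantom(spec)
D_i = np.maximum(ph.observed[0].astype(float) - 20.0, 0.0)
D_j = np.maximum(ph.observed[1].astype(float) - 20.0, 0.0)

est = estimate_leakage_blind(D_i, D_j)
print(f"blind leakage estimate x = {est.x:.3f}")
r_pre = crosstalk_correlation(D_i, D_j, background_level=100, rng_seed=0)
r_post = crosstalk_correlation(D_i, unmix(D_j, D_i, est.x),
                               background_level=100, rng_seed=0)
print(f"Pearson r before unmixing: {r_pre:.3f}")
print(f"Pearson r after unmixing:  {r_post:.3f}")
```

Output:

```
blind leakage estimate x = 0.286
Pearson r before unmixing: 0.303
Pearson r after unmixing:  -0.023
```

The blind estimate lands within 0.015 of the planted 0.30, and the
correlation between the channel pair — the standard spillover
diagnostic, sampled at 10,000 above-background pixels — collapses to
zero after unmixing.

The command line drives the virtual instrument directly:

```sh
cyclescope recipe-4i mouse --cycles 2 --out mouse.recipe
cyclescope validate mouse.recipe src/cyclescope/fixtures/example_mouse.cfg
cyclescope run src/cyclescope/fixtures/example_mouse.cfg --recipe-a mouse.recipe
```

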