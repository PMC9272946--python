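# dividemri

Tensor-valued diffusion MRI analysis: separating **microscopic anisotropy**
from **isotropic heterogeneity** with linear and spherical b-tensor encoding.

## The problem

Conventional diffusion-weighted imaging summarizes a voxel by its apparent
diffusion coefficient, and diffusional kurtosis imaging adds a single
non-Gaussianity index MK. But MK conflates two distinct microstructural
sources: *microscopic anisotropy* (elongated cellular structures, even when
their orientations are fully dispersed within the voxel) and *isotropic
heterogeneity* (a spread of diffusivities between sub-voxel environments,
e.g. mixed stroma and lumen). The two are indistinguishable with
conventional (linear) encoding alone.

Varying the *shape* of the b-tensor resolves the ambiguity. Linear tensor
encoding (LTE, b-tensor shape b<sub>Δ</sub> = 1) is sensitive to both
sources; spherical tensor encoding (STE, b<sub>Δ</sub> = 0) is blind to
anisotropy. After powder averaging (arithmetic averaging over encoding
directions per shell), the gamma-distribution signal model is fitted jointly
to both shapes:

```
S(b, bΔ) / S0 = (1 + (1/3) · b · MD · MK)^(−3/MK),   MK = MK_I + bΔ² · MK_A
```

yielding the mean diffusivity MD (μm²/ms), the isotropic kurtosis MK_I and
the anisotropic kurtosis MK_A. In prostate imaging — the application this
package is modelled on — tumors show low MD and high MK_I, while the
smooth-muscle-rich stroma drives MK_A.

The package provides, for researchers working with multi-shell LTE+STE
acquisitions (or simulations of them):

- **`encoding`** — b-tensor acquisition schemes (default: 5 b-values
  {0.2, 0.5, 0.8, 1.2, 1.5} ms/μm² × {LTE, STE} × 8 directions = 80
  volumes), b-tensor construction, scheme-file I/O;
- **`synthetic`** — multi-Gaussian signal simulation from explicit diffusion
  tensor distributions, closed-form ground-truth moments with an independent
  cumulant-fit cross-check, Rician noise, and a seeded digital phantom with
  tumor/PZ/TZ-like tissue classes;
- **`powder`** — powder averaging into per-shell means;
- **`gamma`** — the `GammaDiffusionModel` / `GammaFitResults` pair (the core
  fit), plus the conventional low-b monoexponential ADC for comparison;
- **`mapping`** — voxelwise fitting of 4D NIfTI volumes into parameter maps
  and ROI extraction;
- **`stats`** — Wilcoxon rank-sum group comparisons between tissue classes
  (cancer grades, pooled cancer vs normal, PZ vs TZ) at the 0.05 threshold.

## Worked example

Simulate one voxel with known ground truth (MD = 1.1 μm²/ms, MK_I = 0.8,
MK_A = 0.6), acquire it with the default 80-volume protocol at SNR 30, and
fit:

```python
import numpy as np
import dividemri as dm

scheme = dm.build_protocol([0.2, 0.5, 0.8, 1.2, 1.5], shapes=(1.0, 0.0), n_directions=8)
dtd = dm.TensorDistribution.from_moment_targets(md=1.1, mk_i=0.8, mk_a=0.6,
                                                rng=np.random.default_rng(0))
signal = dm.simulate_signal(dtd, scheme, s0=100.0)
noisy = dm.add_rician_noise(signal, sigma=100.0 / 30, rng=1)
shells = dm.powder_average(noisy, scheme)
res = dm.GammaDiffusionModel(shells).fit()
print(res.summary())
print("low-b ADC:", round(dm.fit_adc_monoexp(shells), 4))
```

prints

```
Gamma diffusion model fit
=========================================
S0 (signal)                      99.8124
MD (um^2/ms)                     1.09841
MK_I                            0.750308
MK_A                            0.763738
-----------------------------------------
shells                                10
residual norm                  2.300e+00
converged                           True
function evals                        13
MK_A identifiable                   True

low-b ADC: 0.921
```

The fit recovers the generating parameters (MD 1.098 vs 1.1, MK_I 0.75 vs
0.8, MK_A 0.76 vs 0.6 — the kurtosis estimates carry the model's documented
approximation bias plus noise). The monoexponential ADC over b ≤ 0.8 ms/μm²
is 0.92, *below* the gamma MD, illustrating the systematic gap between
conventional ADC analysis and kurtosis-aware models on heterogeneous tissue.

A command-line interface covers the pipeline on files:

```sh
dividemri simulate phantom/ --seed 1          # phantom + scheme (NIfTI + text)
dividemri fit phantom/signal.nii phantom/scheme.txt maps/
dividemri roi-stats maps/ rois.nii labelmap.json --out stats
```

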