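# psidenoise

Gray-level-faithful denoising and quantitation for quantum-dot /
porous-silicon (QD/PSi) biosensor fluorescence images.

PSi biosensors read out target-DNA concentration through the **average
gray level (AGL)** of the QD fluorescence image: the rough nanoporous
surface corrupts the micrograph with multiplicative gamma ("speckle-like")
noise, `F = U·N` with `E[N] = 1`, `Var[N] = 1/L`. Ordinary denoisers
optimize visual quality but shift the mean gray; here the mean *is* the
measurement, and a small AGL bias propagates directly into the calibration
slope and the detection limit. This package implements a denoiser built
around gray-level fidelity:

1. **GVC — gray-value compression.** Every pixel is shrunk toward a
   non-local-means reference `Ĩ` (21×21 search, 7×7 patches) in steps of
   `γ·I/10`, `γ = exp(−I/Ĩ)`; the iteration count is driven by the image's
   coefficient of variation through a shipped, regenerable calibration
   curve, so the gray histogram collapses onto the true level (peak within
   ±0.5 gray).
2. **CNLAD — cosine-distance nonlocal anisotropic diffusion.** Explicit
   diffusion `I⁺ = I + dt(1−U)/4·Σ c_nb(I_nb − I)` whose edge statistic
   `q` is a ring-weighted mean cosine similarity between 3×3 patches in a
   9×9 search box, `c(q) = 1/(1+(q−T)²)` with `T = mean(q)`, gated by a
   type-2 fuzzy membership `U` (two Gaussians, σ = 0.2/0.1, centered on
   the 3×3 window's mean-of-2-middle).

Around the core pipeline the package provides the noise simulator (10
labelled noise families), homogeneous-region selection and CV estimation,
AGL/RMSE/SSIM benchmarking, a PSi-array quantitation chain (segmentation →
per-unit denoising → concentration fit → 3σ/slope detection limit), and an
optional histogram-based noise-type classifier.

## Worked example

```python
import numpy as np
from psidenoise import apply_multiplicative_noise, denoise, agl, rmse, ssim

clean = np.full((256, 256), 50.0)                      # constant gray 50
noisy = apply_multiplicative_noise(clean, 0.5, seed=1) # gamma noise, v = 0.5
out   = denoise(noisy)

print(f"noisy : AGL {agl(noisy):6.2f}  RMSE {rmse(noisy, clean):6.2f}  SSIM {ssim(noisy, clean):.3f}")
print(f"denoised: AGL {agl(out):6.2f}  RMSE {rmse(out, clean):6.2f}  SSIM {ssim(out, clean):.3f}")
```

```
noisy : AGL  49.83  RMSE  35.18  SSIM 0.049
denoised: AGL  49.96  RMSE   1.26  SSIM 0.998
```

The noisy image's root-mean-square error of ≈ 50·√0.5 ≈ 35 gray levels
collapses to about one gray level, while the mean gray — the biosensing
readout — stays within a fraction of a gray level of the truth.

Detection-limit arithmetic (slopes in gray/nM, σ from 10 blank repeats):

```python
from psidenoise import detection_limit
detection_limit(0.27, 9.21)    # 87.9  pM  (before denoising)
detection_limit(0.27, 17.62)   # 46.0  pM  (after denoising)
```

Command line (same functionality, `psidenoise --help` for all
subcommands: simulate, denoise, gvc, benchmark, classify, biosensor,
biosensor-fit, calibrate-gvc):

```bash
psidenoise simulate --gray 50 --variance 0.5 --size 256x256 --seed 1 --out noisy.tiff
psidenoise denoise --in noisy.tiff --out clean.tiff
psidenoise benchmark --variances 0.1,0.5,0.9 --seeds 10 --out bench.csv
```

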