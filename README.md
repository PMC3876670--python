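# mammopyr

Multiscale contrast and feature enhancement for mammographic (and general
grayscale medical) images.

Mammograms are acquired with low-dose X-rays and are characteristically poor
in contrast: masses sit a few percent above the surrounding fibroglandular
background, and microcalcifications are tiny bright points easily lost in
noise. `mammopyr` implements a multiscale enhancement method that treats the
frequency bands of the image differently, together with the standard metrics
used to quantify the result and a synthetic phantom generator for testing
without clinical data.

## The method

An input image *I* is processed in five stages:

1. **Laplacian Gaussian pyramid decomposition.** *I* is repeatedly smoothed
   with a separable 5-tap generating kernel
   *w* = [¼−a/2, ¼, a, ¼, ¼−a/2] (default *a* = 0.4) and decimated by two,
   giving the Gaussian chain g₀…g_L. Detail bands are
   b_k = g_k − EXPAND(g_{k+1}); the pyramid (b₀…b_{L−1}, g_L) is exactly
   invertible.
2. **CLAHE on the detail bands.** Each signed band is mapped to [0, 1] by its
   own span and equalized with contrast-limited adaptive histogram
   equalization: per-tile histograms are clipped at
   `clip_limit · n/L` counts with the excess redistributed uniformly, and
   per-pixel output bilinearly interpolates the four surrounding tile
   mappings. A light Gaussian blur (σ = 0.5) restrains amplified noise.
3. **Morphology on the low-pass residual.** With a flat rectangular
   structuring element SE, top-hat TH = I − (I ∘ SE) lifts bright details and
   bottom-hat BH = (I • SE) − I extracts dark ones; the residual is replaced
   by C = I + TH − BH.
4. **Reconstruction** through the inverse pyramid recursion.
5. **Global gain.** The reconstructed image, mapped onto [−1, 1], is remapped
   through the odd sigmoid-difference curve
   f(z) = a·[sigm(c(z−b)) − sigm(−c(z+b))] with
   a = 1/(sigm(c(1−b)) − sigm(−c(1+b))), which fixes f(0)=0 and f(±1)=±1
   (defaults b = 0.35, c = 20).

Quality is quantified by three metrics: the contrast criterion
Cc = mean(f′²) − mean(f′)² (population variance of intensities), the contrast
improvement index CII = C_processed / C_original where C is the image-mean of
the per-pixel local contrast (X_max − X_min)/(X_max + X_min) over 5×5
windows, and a reference-based SNR in dB. By construction CII of an
unprocessed image is exactly 1.

## Worked example

Generate a synthetic phantom (a half-elliptical "breast" with smooth
background, fibroglandular texture, three ~5 %-contrast masses and twelve
microcalcifications), enhance it, and measure the improvement:

```console
$ mammopyr phantom --seed 7 --out phantom.png
wrote phantom.png
$ mammopyr enhance phantom.png enhanced.png --report report.json
wrote enhanced.png  Cc=0.0451 CII=1.8751
$ mammopyr metrics enhanced.png phantom.png
contrast=0.0451 cii=1.8749 snr=6.2739
```

The enhanced image has 1.88× the mean local contrast of the original
(CII = 1.875 > 1 means the 5×5-window contrast rose by that factor on
average) and a global contrast criterion Cc of 0.045; the modest SNR reflects
that enhancement deliberately changes the image away from the low-contrast
original. The tiny difference between the two CII printouts is 8-bit
quantization of the intermediate PNG.

The same pipeline is available as a library:

```python
import numpy as np
from mammopyr import EnhanceConfig, PhantomSpec, enhance, generate, cii

img, truth = generate(PhantomSpec(seed=7))
out = np.clip(enhance(img, EnhanceConfig(levels=3)), 0, 1)
print(cii(out, img))          # > 1: contrast improved
```

Other subcommands: `mammopyr equalize` (HE / AHE / CLAHE baselines),
`mammopyr morph` (single morphology operators), `mammopyr metrics`,
`mammopyr phantom`. Pipeline parameters can be given as a YAML/JSON config
file (`--config`); unknown keys are rejected by name.

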