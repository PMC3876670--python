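# Methods

## Model and assumptions

`mammopyr` enhances a single-channel grayscale image by decomposing it into
frequency bands and applying a different enhancement to each kind of band:
adaptive histogram equalization where the detail (high-frequency) information
lives, and grayscale morphology on the smooth low-pass residual that carries
the large-scale contrast. The premise is that diagnostically relevant
mammographic features occupy different scales — microcalcifications are
high-frequency, fibroglandular texture mid-frequency, masses and overall
glandular contrast low-frequency — so a single global operator cannot serve
all of them.

All images are handled internally as 2-D float64 arrays. Integer images are
normalized to [0, 1] on load as value/(2^depth − 1); all intermediate results
are unclipped floats, and clipping plus re-quantization happen only when a
file is written. The pipeline is fully deterministic: identical input and
configuration produce bit-identical output.

### Pyramid

The Laplacian Gaussian pyramid uses the one-parameter separable 5-tap
generating kernel w = [¼−a/2, ¼, a, ¼, ¼−a/2]. The default a = 0.4 is the
closest-to-Gaussian member of the family; the kernel is symmetric and sums to
one by construction. Reduction filters with w along each axis (symmetric,
edge-repeating border reflection) and keeps every second sample starting at
index 0, so an axis of length n becomes ⌈n/2⌉ and odd sizes are supported
throughout. Expansion targets an explicit shape (2n or 2n−1 per axis) and is
the zero-insertion adjoint: each output phase mixes the neighboring source
samples with doubled kernel weights, and both phases have unit weight sum, so
constant images expand to the same constant. Because each detail band is
defined as b_k = g_k − EXPAND(g_{k+1}) and reconstruction re-adds exactly the
same EXPAND output, the transform is exactly invertible for *any* expansion
operator; the measured round-trip error is at the level of one ulp
(~1e-16), far below the 1e-6 documented contract. Expansion by interpolation
would work equally well for invertibility; kernel-based expansion was fixed
because it keeps decomposition and reconstruction filters identical by
construction.

Default depth is 3 levels (configurable 1–8, capped by image size): at
mammographic resolution this separates punctate detail, mid-scale texture,
and a residual coarse enough for morphological enhancement to act on whole
masses.

### CLAHE on detail bands

Histograms of float images are formed by uniform binning of the declared
value range into L bins (half-open bins, last bin closed). Plain HE remaps
level r_k to s_k = (L−1)·Σ_{j≤k} p(r_j). CLAHE computes this mapping per
tile after clipping each tile histogram at a ceiling of clip_limit·n/L
counts; the clipped excess is redistributed uniformly over **all** bins, and
because redistribution can push bins back over the ceiling the
clip-and-spread step is iterated until the residual excess is below one count
(at most 5 passes). The total count is conserved exactly. Per-pixel output
bilinearly interpolates the four surrounding tile mappings, with clamping to
the nearest tile at the borders. This construction makes the degeneracy
ladder exact: with a 1×1 tile grid and an effectively infinite clip limit,
CLAHE equals plain HE pixelwise.

Defaults: 8×8 tiles, clip_limit 2.0, 256 bins — the community-standard CLAHE
operating point. Inside the pipeline the tile grid is automatically capped so
each tile keeps at least 2 pixels per axis on small pyramid levels.

Signed detail bands are equalized by affinely mapping the band onto [0, 1] by
its own min/max, applying CLAHE, smoothing with a Gaussian of σ = 0.5 to
restrain the noise that equalization amplifies, and mapping back to the
original span; a constant (zero-span) band passes through unchanged. The
order (CLAHE, then smoothing) is fixed: smoothing first would blur exactly
the detail the equalization is meant to lift.

### Morphology on the residual

Erosion/dilation with a flat rectangular structuring element are
sliding-window minimum/maximum with reflective borders; opening and closing
are the usual compositions. The residual is replaced by
C = I + TH − BH (equivalently 3I − opening − closing), which adds bright
details smaller than the SE and subtracts dark ones. The default SE is a
15×15 flat square: at the coarsest level of a 3-level pyramid a mass tens of
pixels wide at full resolution is only a few pixels wide, so the SE must
comfortably exceed that scale to lift whole structures rather than just their
edges. The SE is capped (keeping odd sizes) when the residual is smaller than
the SE. C can exceed the nominal intensity range; it is intentionally left
unclipped until file output so reconstruction arithmetic stays exact.

By default morphology is applied to the residual only; `morph_levels` can
extend it to the coarsest detail bands as well.

### Global gain

The gain curve f(z) = a[sigm(c(z−b)) − sigm(−c(z+b))], with the normalizer
a = 1/(sigm(c(1−b)) − sigm(−c(1+b))) recomputed from b and c, is an odd,
strictly increasing S-curve with fixed points f(0)=0 and f(±1)=±1. Those
fixed points dictate the working domain: the reconstructed image is affinely
mapped from its own [min, max] span onto [−1, 1] and back, which preserves
the span endpoints and passes constants through unchanged. Defaults
b = 0.35, c = 20 give a visibly steeper mid-tone slope without saturating
the S-curve.

One numerical subtlety: for large c (e.g. 50) the sampled curve saturates at
±1 near the endpoints in float64 — the tail differences are ~e^(−45),
below double-precision resolution — so strict monotonicity of *sampled*
values cannot hold there for any faithful evaluation. The analytic
derivative f′(z) = a·c[σ′(c(z−b)) + σ′(−c(z+b))], evaluated as
σ′(x) = σ(x)σ(−x), remains strictly positive in float, and that is what the
tests certify alongside non-decreasing samples.

### Metrics

* Cc: population variance of intensities, evaluated two-pass so a constant
  image yields exactly 0. Shift-invariant; scales as α² under I → αI.
* Local contrast: per-pixel (max−min)/(max+min) over an odd window (default
  5×5, reflective borders); windows with max+min = 0 contribute 0, which only
  occurs for all-zero neighborhoods where contrast is genuinely nil. CII is
  the ratio of the image-mean local contrast of processed to original;
  self-comparison is exactly 1.
* SNR: 10·log10(Σref² / Σ(enh−ref)²) dB with the original as reference.
  Identical images are reported as an infinite-SNR outcome (serialized as a
  null value plus a flag), not an error.
* The two-region contrast (m_f − m_b)/(m_f + m_b) is provided separately for
  mask-based comparisons, and drives the phantom mass-contrast measurement
  (mass mask as foreground, a surrounding annulus inside the breast as
  background, with a 2-pixel guard ring).

## The synthetic phantom

The generator emulates the statistical structure of a mammogram, not its
physics: a half-elliptical breast support (chest wall at the left edge) over
a dark exterior, a smooth intensity fall-off from chest wall to skin line,
band-limited texture (Gaussian-filtered white noise, σ = 4 px) standing in
for fibroglandular tissue, soft-edged discs at a few percent contrast for
masses, 3×3 punctate stamps for microcalcifications, and white Gaussian
detector noise added last. All randomness flows through numpy's PCG64
generator with an explicit seed, so phantoms are bit-reproducible across
platforms.

Defaults (chosen once as the test conditions): 256×512 pixels — large enough
for 3 pyramid levels with 8×8 CLAHE tiles on every band, small enough that a
ten-seed study runs in seconds; interior background 0.35 with a 10 %
gradient; texture strength 0.03; three masses of radius 10–18 px at 5 %
contrast (low-contrast but not subthreshold); twelve calcifications of
amplitude 0.25; noise σ = 0.01. The exterior darkfield sits at 0.08, well
above the noise σ, mirroring real digitizations where the detector offset
dominates the noise floor; an exterior near zero would make the ratio metric
(max−min)/(max+min) saturate on pure noise and swamp every other
contribution to mean local contrast.

What passing phantom tests shows: the pipeline raises mean local contrast,
global variance contrast, and mask-measured mass contrast on images with
mammogram-like scale structure. What it does not show: performance on real
anatomy (overlapping ducts, vessels, pectoral muscle, scatter), detector
artifacts, or any diagnostic claim.

## Design choices and limitations

* Gain is applied globally after reconstruction, never per band; the stage
  order is fixed.
* The library never resizes silently; images are processed at native size.
* HE and AHE baselines fall out of the CLAHE machinery (AHE = CLAHE with an
  effectively infinite clip limit) and are exposed via `mammopyr equalize`.
* Quantization on write is round-half-up, fixed to avoid platform-dependent
  banker's rounding.
* Known limitations: flat (unweighted) structuring elements only; no
  color or multi-frame support; DICOM is read-only and optional; the
  enhancement is tuned for display, so the dB-SNR against the original is
  expected to be modest — it measures departure from the input, not quality.
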