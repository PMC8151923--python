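# Methods

## Scope and model

`medfuse` fuses pairs of co-registered 2-D medical images by merging their
multiscale, multidirectional sub-band decompositions. The method assumes the
inputs are spatially registered, on a common intensity scale ([0, 1]
internally; 8-bit files are divided by 255 on read), and that salience can
be judged locally: the low-frequency approximation by the temporal dynamics
of a pulse coupled neural network (PCNN), the high-frequency detail by a
focus measure (WSEML). The method contains no randomness: identical inputs
and configuration give bit-identical output.

## Non-subsampled contourlet transform

**Pyramid.** Scale separation uses an à-trous (zero-inserted upsampling)
non-subsampled pyramid built from the CDF 9/7 biorthogonal low-pass pair
(analysis `h0`, 9 taps; synthesis `g0`, 7 taps; both normalized to DC
gain 1, coefficients from PyWavelets' `bior4.4`). The high-pass analysis
filter is `h1 = δ − h0*g0` with synthesis `g1 = δ`, so perfect
reconstruction is structural — `H0·G0 + H1·G1 ≡ 1` as polynomials, at every
à-trous dilation — rather than a numerical property of tuned coefficients.
Level *l* filters with kernels dilated by `2^(l−1)`; nothing is subsampled,
so all sub-bands keep the input shape.

**Directional stage.** Each band-pass level is split by a non-subsampled
directional filter bank. The first tree stage uses a zero-phase fan filter
obtained by the McClellan transform `x → (cos ω_col − cos ω_row)/2` of the
7-tap maxflat halfband prototype `[−1, 0, 9, 16, 9, 0, −1]/32`
(`P(x) = (2 + 3x − x³)/4`, so `P(1)=1`, `P(−1)=0`, `P(0)=½`); the second
stage uses the same fan upsampled on the quincunx lattice, giving the
standard four directional wedges per level. Every node's second channel is
the structural complement `band − fan*band`, so synthesis is the plain
channel sum and reconstruction is exact at any tree depth. Stages beyond the
second reuse the quincunx fan dilated à trous; this keeps exact
reconstruction for 8/16 directions but simplifies the wedge geometry there
(the default configuration, 4 directions per level, does not use those
stages).

**Boundaries.** All filtering mirrors at the borders (whole-sample
symmetric), which avoids edge ringing on medical images; since the 1-D 9/7
filters are odd-length symmetric, two-stage filtering composes exactly under
this extension and reconstruction error stays at machine precision. A
periodic mode exists and makes the transform exactly shift-equivariant; it
is used by the shift-invariance tests.

**Ordering convention.** Pyramids store levels coarse → fine;
`dirs_per_level` follows the same order; within a level, channels are in
filter-tree order (channel 0 = all-low fan path). "4 directions per level"
is interpreted as 4 directional sub-bands (tree depth 2) at each of the 4
pyramid levels.

## PCNN low-frequency rule

The network equations and defaults (α_L = 0.06931, α_θ = 0.2, β = 3,
V_L = 1, V_θ = 20, N = 200, one neuron per pixel) are given in the README.
Choices where the formulation leaves freedom:

* **Initial conditions** `L = U = θ = Y = T = 0`: every neuron with positive
  stimulus fires at n = 1 (the pulse test is the strict `U > θ`, so a zero
  stimulus never fires). This matches common PCNN-fusion practice.
* **Stimulus normalization.** The two low-frequency bands are rescaled to
  [0, 1] by their *joint* min/max before driving the network, so firing
  counts are comparable across modalities; `normalize="none"` feeds raw
  (nonnegative) bands.
* **Linking kernel** `[[0.7071, 1, 0.7071], [1, 0, 1], [0.7071, 1, 0.7071]]`
  — inverse Euclidean distance with zero centre.
* **Linking-window borders** mirror, so border neurons are coupled exactly
  like interior ones and a spatially constant stimulus stays perfectly
  symmetric (every neuron fires identically).
* **Tie rule**: `T_A ≥ T_B` selects source A.

## WSEML + guided-filter high-frequency rule

The eight-neighbourhood modified Laplacian sums the absolute horizontal and
vertical second differences plus both diagonal second differences weighted
by `diag_weight = 1/√2` (inverse diagonal distance; exposed as a parameter
since conventions differ). WSEML convolves this activity with the 3×3 kernel
`[[1,2,1],[2,4,2],[1,2,1]]/16` (sums to 1), mirror borders. Activities are
computed on the raw signed coefficients; absolute values appear only inside
the Laplacian terms.

The binary argmax maps (ties → A) are refined with a guided filter
(r = 3, ε = 1) guided by the corresponding sub-band. Numerical choices:

* Window statistics use truncated (shrinking) windows at the borders, the
  convention of the original guided-filter reference code; constants are
  preserved everywhere and `r = 0` makes the filter the exact identity,
  which collapses the rule to hard WSEML-max selection.
* Degenerate windows (zero variance with ε = 0) take the limit a = 0,
  b = mean(p).
* ε acts on the scale of the binary maps, so with ε = 1 the refined maps are
  strongly smoothed; outputs may leave [0, 1] slightly and are clipped
  before normalization so the final weights are convex.
* Where both refined maps vanish (total < 1e-12) the weights fall back to
  ½/½.

## Color extension

BT.601 luma `Y = 0.299R + 0.587G + 0.114B` with analog chroma
`U = 0.492(B−Y)`, `V = 0.877(R−Y)` (exactly invertible; achromatic inputs
give exactly U = V = 0). Only Y is fused; U and V pass through unchanged, so
the fusion cannot distort color — any gamut clipping happens only at the
final YUV→RGB conversion. Metrics on color fusions are computed on
luminance.

## Quality metrics

* **API / SD / EN** on the conventional 0–255 scale: mean, population
  standard deviation, and Shannon entropy (base 2) of the 256-bin histogram
  of the round-half-up 8-bit quantization (0·log 0 = 0).
* **Q_W** (weighted fusion quality index): universal image quality index
  over 8×8 sliding windows (step 1), mixed per window with saliency
  λ = var(A)/(var(A)+var(B)) and aggregated with importance
  c = max(var A, var B). Windows where both signals are degenerate score 0
  and carry zero importance.
* **VIFF** (visual information fidelity for fusion): 4 dyadic scales
  (Gaussian blur + 2× decimation between scales; Gaussian local moments with
  window `2^(5−scale)+1`), Gaussian-scale-mixture information terms
  `VID = log2(1 + g²σ_s²/(σ_v²+σ_n²))`, `VIND = log2(1 + σ_s²/σ_n²)` with
  visual-noise variance σ_n² = 2 on the 0–255 scale; per pixel the source
  with larger VIND is selected; the scale score is ΣVID/ΣVIND and scales are
  combined with geometric weights 8:4:2:1 (finest heaviest, normalized).
  Published VIFF variants differ in weights and selection details; this one
  is validated behaviorally (identity ⇒ 1 within 1e-6, strictly lower under
  blurring) rather than against any specific tabulated values.

## Synthetic phantoms

The generators emulate the *statistical contrast between modalities*, not
imaging physics: the CT-like image has a bright elliptical rim
(ring − interior mean contrast ≥ 0.4 by construction) with a near-uniform
interior; the MRI-like image shares the geometry with a dark rim and a
textured interior (band-limited noise, σ = 1.2 px, amplitude 0.12, plus
smooth blobs), so detail activity concentrates in the MRI and the strong
edge in the CT; the functional image has smooth in-gamut chroma blobs
(mean chroma gradient < 0.02 by construction) and moderate luminance
confined to the head. One seeded `numpy.random.default_rng` drives all
randomness; masks for ring/interior/background (and an eroded
`interior_core` clear of rim bleed) are returned for ground-truth checks.

What passing on phantoms does *not* show: real CT/MRI noise statistics,
bias fields, partial-volume effects, registration error, or pathology
appearance. Results on clinical atlas images will differ in absolute metric
values; the phantom suite establishes correctness of the machinery and the
qualitative behaviour (fusion raises SD/EN above the weaker source,
preserves chroma exactly, is deterministic).

## Problem sizes

Tests run phantoms at 32–128 px and the transform at 64 px with up to the
full 4×[4,4,4,4] configuration; the packaged acceptance script fuses
128×128 phantoms at the full default configuration (a 256×256 fusion takes
a few seconds). Brute-force oracle comparisons (nested-loop PCNN, per-window
guided filter) use 8×8–16×16 inputs, which is ample to pin every code path
integer- or 1e-10-exactly.

## Known limitations

* 2-D single-channel fusion only; no registration, no 3-D volumes.
* NSDFB wedge geometry is simplified beyond 4 directions per level (exact
  reconstruction is unaffected).
* The guided filter is the gray-guide variant (no 3-channel covariance).
* VIFF follows one published formulation; absolute values are not
  comparable across VIFF implementations with different scale weights.
* PCNN firing counts depend on the joint normalization choice; strongly
  skewed intensity distributions may favour the brighter modality.
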