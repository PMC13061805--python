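# Methods

## The problem

A Papanicolaou-stained cytology specimen carries four optically
relevant dyes — Eosin Y (EY), hematoxylin (H), Light Green SF (LG) and
Orange G (OG) — while a brightfield RGB image provides only three
channels.  Under the Beer–Lambert law the optical density (OD,
decadic absorbance) of a pixel is linear in the dye amounts:

    Y = A X,    Y ∈ R^{3×n},  A ∈ R^{3×4},  X ∈ R^{4×n},  X ≥ 0

where the columns of the stain matrix `A` are the per-dye RGB
absorption coefficient vectors (normalized to unit element sum so each
dye contributes on a comparable scale) and the rows of `X` are the
per-dye abundance maps.  With four unknowns per pixel and three
equations the system is underdetermined; `papunmix` makes it solvable
with three priors:

1. **Nonnegativity** — dyes absorb, they do not emit;
2. **Weighted nucleus sparsity** — hematoxylin binds to nuclei, so its
   abundance should be (exactly) zero over most of the image.  An
   iteratively reweighted l1 penalty `λ ‖w ⊙ x_H‖₁` with
   `w = exp(−x_H)` (clipped abundances, so `w ∈ (0, 1]`) pushes small H
   values to zero while leaving strongly stained nuclei almost
   unpenalized;
3. **Piecewise smoothness** — an anisotropic vector total-variation
   penalty `λ_TV ‖H X‖₁,₁` over horizontal and vertical neighbor
   differences (periodic boundaries) encourages spatial coherence.

The estimate solves

    min_X  ½‖AX − Y‖_F² + λ‖W ⊙ X‖₁,₁ + λ_TV‖HX‖₁,₁ + ι₊(X)

where `W` carries the weights on the H row only and `ι₊` is the
indicator of the nonnegative orthant.

## OD conversion

`y_i = log10(I_0,i / l_i)` with `I_0` the incident light measured on
bare glass.  Absorbance is taken positive for absorbing pixels (the
convention of the multiband formulation `α = log10(I_I / I_T)`);
pixels brighter than the incident estimate are clipped to OD 0, and
transmitted intensities are floored at `I_0·10^(−OD_max)` (default
`OD_max = 3`) so zero-valued pixels stay finite.  RGB spectral
sensitivities are ignored, i.e. each channel is treated as a single
effective wavelength.  The glass mask for the automatic `I_0` estimate
is: pixels whose *minimum* channel exceeds the 99th percentile of the
per-pixel minimum channel (the minimum avoids picking up saturated
single channels inside stained regions); `I_0` is the per-channel mean
over the mask, estimated per image.  ROI and explicit modes are
available when the field of view contains no glass.

## ADMM solver

Three auxiliary blocks with a common penalty `μ` and scaled duals:
`V1 = X` (weighted l1), `V2 = [H_h X; H_v X]` (TV), `V3 = X`
(nonnegativity).  The X-update solves the normal equations

    (AᵀA ⊗ I_n + μ(2 I + H_hᵀH_h + H_vᵀH_v)) X = RHS.

Because the difference operators are periodic they are circulant and
diagonal in the 2-D Fourier basis; `AᵀA` couples only the four dye
channels and is diagonalized once by a symmetric eigendecomposition.
The update therefore reduces to scalar divisions per dye-eigenchannel
and frequency and is exact (verified against a dense direct solve to
1e-14 on small rasters).  The V-updates are soft thresholds (levels
`(λ/μ)·W` and `λ_TV/μ`) and a projection onto the orthant.

Choices that the formulation leaves open, decided here:

* **Weight cadence** — weights are re-derived from the current clipped
  `x_H` once per ADMM iteration, starting from `w⁰ = 1`.  An outer
  loop of full ADMM solves per reweighting would also be defensible;
  the per-iteration variant converges in practice and keeps the
  iteration count bounded by a single `max_iter`.
* **Penalty** — `μ = 0.05`, constant (no adaptive scheme), exposed in
  `SolverConfig`.  Small `μ` favors the data term early, which matters
  for the nearly flat directions discussed below.
* **Stopping** — relative change `‖X⁺−X‖_F/‖X‖_F < tol` (default
  1e-5) with a `max_iter` cap of 1000.
* **TV counting** — `tv_value` uses the operator convention
  `‖H_hX‖₁,₁ + ‖H_vX‖₁,₁`, which counts each periodic neighbor pair
  exactly once per direction, so the penalty in the objective and the
  reported TV agree by construction.
* **Output** — the returned abundances are the projection of the final
  iterate onto the orthant, so nonnegativity is exact, and the
  reported `final_weights` are recomputed from the returned map
  (self-consistent by construction).

Defaults `λ = 2e-6`, `λ_TV = 1e-3` assume abundances of order one on
the "total OD per pixel" scale implied by a unit-column-sum stain
matrix; both are per-run tunables.

Baselines: color deconvolution `X = A⁺Y` via the Moore–Penrose
pseudoinverse (optionally clipped at zero), and the multispectral path
`X = E⁺Y_ms` for M-band cubes with M > 4, which serves as the
ground-truth route and is deliberately *not* clipped.

## Identifiability and what the solver can promise

With a 3×4 full-rank stain matrix the data term is flat along the
one-dimensional null space of `A`.  Writing `ν` for the null vector
(its components sum to zero because the columns of `A` sum to one),
the set of exact nonnegative solutions at a pixel is the segment
`{x* + tν ≥ 0}`.  The composition at a pixel is uniquely determined by
nonnegativity alone exactly when its *zero* dyes include `ν`
components of both signs, blocking the segment on both sides.  For
the bundled stain matrix `ν` has signs (−, +, −, +) over
(EY, H, LG, OG), so among compositions with at most three active dyes
the single ambiguous case is EY+LG with H and OG both absent.  Where
nonnegativity does not pin the pixel, the regularizers select within
the segment — the nucleus-sparsity weight pins `x_H = 0` in cytoplasm
whenever `ν_H ≠ 0`, which is the mechanism that makes the four-dye
problem practically solvable.

## Evaluation and calibration

* SRE (dB) `= 10 log10(‖X_GT‖_F² / ‖X_GT − X̂‖_F²)`; an exact
  reconstruction returns `+inf` (documented sentinel, not an error).
* RMSE `= √(‖X_GT − X̂‖_F² / n)` with `n` the total element count.
* Single-stain abundance: with one dye present, `s_j = (aᵀy_j)/(aᵀa)`
  per pixel; the MS/RGB calibration coefficient is the least-squares
  scale `p = (s_rgb·s_ms)/(s_rgb·s_rgb)`.  Published calibration and
  reference values are specimen-dependent and are not constants of
  this package.
* Reference values for display normalization are per-dye percentiles
  (default 99, linear-interpolation convention) of the abundance map;
  normalized maps are clipped to [0, 1] (the unclipped map remains
  available via `clip=False`).

## Synthetic phantoms

The generator emulates the three priors rather than the appearance of
real smears: non-overlapping elliptical "cells" with smooth
low-frequency cytoplasmic dye fields, disk nuclei carrying H only
(optionally with a ≤ 2 % H bleed into cytoplasm), zero background.
Cytoplasmic dye sets are drawn from the identifiable combinations
described above ({EY, OG}, {LG, OG}, or a single dye) so that a
noiseless scene is recoverable in principle.  Rendering composes
`I = I_0 · 10^(−AX)` with additive Gaussian noise in the intensity
(sensor) domain — noise enters at the detector, not in OD — followed
by clipping and quantization to 8 or 16 bits.  Default peak abundances
are (1.2, 2.0, 1.0, 0.8) for (EY, H, LG, OG): order-one values that
keep the darkest nuclei well above the OD ceiling of a 16-bit render.
Everything is driven by one integer seed; the same configuration
reproduces bit-identical scenes.

The bundled stain matrices are synthetic.  They reproduce the
qualitative structure of measured Papanicolaou coefficients — H
strongest in red OD, heavy EY/OG overlap, a distinct LG column — with
unit column sums; the 14-band spectral variant spans 440–720 nm.  (A
14-band grid cannot simultaneously have 20 nm steps and those
endpoints; the band count is the binding constraint, giving ~21.5 nm
spacing.)  Passing tests on these phantoms demonstrates correctness of
the optimization and the pipeline, not performance on real specimens:
real data add chromatic aberration, focus variation, nonlinear
LG response, scanner color processing, and stain co-localization
patterns the generator does not model.

## Spectral rendering

Multi-band cubes are rendered to sRGB for display through CIE XYZ
under illuminant D65 (the transmissive-microscopy convention): per
pixel, transmittance is weighted by the D65 spectrum and the CIE 1931
2° observer at the cube's band centers, converted with the standard
sRGB primaries matrix, white-point normalized so unit transmittance
maps exactly to full scale, then gamma encoded.  The color-matching
functions are evaluated from the published multi-lobe Gaussian fits
(Wyman, Sloan & Shirley 2013, ≈1 % of the tabulated observer); D65 is
interpolated from the standard 10 nm table.  This is a display path,
not a colorimetric calibration.

## Mucin classification

Cytoplasmic mucin patches (5×5 pixels) are averaged per dye and
converted to relative abundances `x̄_i / Σx̄`, which are invariant to
mucin thickness and concentration.  Group differences use the
Mann–Whitney U test: for pooled sizes ≤ 12 the two-sided p-value comes
from full enumeration of all C(m+n, m) group assignments with mid-rank
ties (p = P(|U − mn/2| ≥ |u_obs − mn/2|)); larger samples use the
tie- and continuity-corrected normal approximation.  Classification
uses two-class Fisher LDA with equal priors (weights
`∝ Σ_pooled⁻¹(μ_LEGH − μ_EC)`, bias at the midpoint of projected
class means, tiny ridge for near-singular covariance); a patch is
called LEGH when the discriminant is ≥ 0, and LEGH is the positive
class for precision/recall/F1.  The default feature set is the
relative abundances of EY and OG — the dyes whose balance separates
the pinkish acidic mucin of normal endocervical (EC) cells from the
yellowish gastric-type mucin of LEGH cells.  The synthetic feature
generator draws the two populations from Dirichlet distributions over
the four dyes that differ in their EY and OG concentrations; a
`separation` parameter interpolates between indistinguishable (0) and
the default shift (1).

## Problem sizes used by the validation suite

The test suite and acceptance checks run on 3×3 to 64×64 rasters: 50
random 3×4 instances for the NNLS-equivalence check (restricted to
pixels whose NNLS minimizer is unique and well-conditioned — see the
identifiability discussion), 8×8 rasters for the dense-vs-FFT solve
comparison, one 64×64 noiseless phantom for the recovery check, and
twenty 64×64 phantoms with 1 % sensor noise for the
regularization-benefit comparison against the clipped pseudoinverse
and the fixed-weight l1 ablation.

## Known limitations

* Linear Beer–Lambert mixing throughout; real LG response is known to
  deviate from linearity at high abundance.
* The five-dye case (Bismarck brown Y) is out of scope; the weight
  machinery addresses the H row by name, so other dye orderings work,
  but exactly one hematoxylin-like dye is assumed.
* Per-image automatic incident-light estimation assumes some glass is
  visible; fields fully covered by specimen need ROI or explicit mode.
* The reweighted penalty makes the overall problem nonconvex in the
  joint (weights, abundances) sense; the solver treats it as a
  heuristic fixed-point iteration and is deterministic, but no global
  optimality is claimed.
* Whole-slide formats, ICC color management and scanner-specific
  rendering are out of scope.
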