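# papunmix

Training-free **Papanicolaou stain unmixing** for RGB brightfield
images: estimate the per-pixel abundances of four dyes — Eosin Y (EY),
hematoxylin (H), Light Green SF (LG) and Orange G (OG) — from three
color channels.

## Who this is for

Cytopathology image analysts who want *physical* stain quantities
(dye amounts under the Beer–Lambert law) instead of psychophysical
color features, without training data: e.g. to quantify the EY/OG
balance of cytoplasmic mucin that separates normal endocervical (EC)
cells from lobular endocervical glandular hyperplasia (LEGH) cells.

## The model

In optical-density space `Y = A X` with a measured 3×4 stain matrix
`A` (unit column sums) and nonnegative abundances `X`.  The system is
underdetermined (four dyes, three channels), so `X` is estimated by

    min_X  ½‖AX − Y‖_F² + λ‖w ⊙ x_H‖₁ + λ_TV TV(X)   s.t.  X ≥ 0

with **weighted nucleus sparsity** — iteratively reweighted l1 on the
hematoxylin row, `w = exp(−x_H) ∈ (0, 1]`, which zeroes H outside
nuclei while preserving it inside — and anisotropic vector **total
variation** over neighbor pixels (periodic boundaries).  The problem
is solved by ADMM whose linear step is FFT-diagonalized, with
per-pixel nonnegative least squares and the Moore–Penrose color
deconvolution `X = A⁺Y` as baselines.  See `docs/methods.md` for the
full account.

The package also covers: stain-matrix measurement from single-stain
images, multispectral (M-band) pseudoinverse unmixing as a
ground-truth path, MS↔RGB abundance calibration, SRE/RMSE evaluation,
D65 spectral-cube→sRGB rendering, a seeded synthetic phantom
generator, and patch-level mucin classification
(Mann–Whitney U, two-class LDA).

## Worked example

Generate a 64×64 synthetic scene with 1 % sensor noise, unmix it, and
score the result against the known ground truth:

```sh
papunmix phantom --size 64 --cells 6 --seed 1 --noise-sd 655 --out-dir demo/phantom
papunmix unmix --image demo/phantom/noisy.tiff \
               --stainmat demo/phantom/stain_matrix.csv \
               --baseline cd --out-dir demo/unmix
papunmix eval  --pred demo/unmix/abundance.tiff \
               --truth demo/phantom/truth.tiff --per-dye --out demo/report.json
```

which prints (abridged from `demo/report.json`):

```
{"sre": 15.03, "rmse": 0.0442}
per dye:  EY 11.59 dB   H 24.15 dB   LG 20.99 dB   OG 11.47 dB
```

SRE (signal-to-reconstruction error, higher is better) is
`10·log10(‖X_GT‖²/‖X_GT − X̂‖²)`; RMSE is the root-mean-square
abundance error.  On the same scene the clipped pseudoinverse baseline
(`demo/unmix/baseline_cd.tiff`) reaches 11.20 dB / 0.0687 — the
regularization buys ~4 dB here.  Hematoxylin is recovered best because
the nucleus-sparsity prior matches its spatial support; EY and OG are
hardest because their absorption vectors overlap most.

The same operations are available as a library:

```python
from papunmix import PhantomConfig, make_phantom, rgb_to_od, unmix_admm, SolverConfig

ph = make_phantom(PhantomConfig(seed=1, noise_sd=655.0))
od = rgb_to_od(ph.noisy_rgb, ph.noisy_rgb.incident_light)
result = unmix_admm(od, ph.stain_matrix, SolverConfig())
abundances = result.abundance      # rows: EY, H, LG, OG
```

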