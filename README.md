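# sncontour

Shape-number contour-length estimation for single-biopolymer images.

## The problem

The contour length `l_c` of a DNA strand (or any biopolymer) can be read
from an AFM scan by thinning the imaged strand to a single-pixel-wide
backbone and summing its pixel connections. The classical Freeman
estimate, `L_F = r (n_e + √2 n_o)` — `r` the pixel resolution in
nm/pixel, `n_e`/`n_o` the counts of direct/diagonal chain-code steps —
overestimates smooth curves by 2–4 %, which is far too coarse when one
DNA base pair spans 0.34 nm.

`sncontour` implements a shape-aware estimator. Every interior
connection of the backbone sits inside a 4-pixel segment described by
three consecutive Freeman codes; there are exactly 64 such single-width
segments, falling into 12 shape classes `k_1 … k_12` under rotation,
mirroring, and traversal reversal. Each class gets a multiplicative
length correction calibrated against simulated worm-like chains of
known length:

    L_S = r ( Σ_j n_kj · k_j · l_kj + l_H + l_T ),   k_j(r) = m_j r + b_j

with `l_kj ∈ {1, √2}` the class's center-connection length and
`l_H, l_T` the raw head/tail connections. On held-out simulated corpora
this reduces the averaged relative error from ≈3 % (Freeman) to below
0.1 % — on the order of a single base pair.

The package covers the whole workflow: image preprocessing (threshold,
island filtering, thinning, debranching), chain coding, shape
classification, least-squares coefficient calibration, a seeded 2D
worm-like-chain simulator (persistence length 50 nm by default), and
error benchmarking against the Freeman, Kulpa, corner, and
factor-corrected (`L_DNA`) baselines. The core estimator is a
scikit-learn style regressor (`ShapeLengthModel.fit/predict`) and
composes with sklearn tooling.

## Worked example

Simulate one DNA-like strand of known length 680 nm at 6.4 nm/pixel,
then estimate its length from the digitized skeleton alone:

```sh
$ sncontour simulate --lc 680 --resolution 6.4 --n 1 --seed 7 --out-dir demo
$ sncontour estimate --path-csv demo/sample_00000.csv --resolution 6.4 --estimator shape
estimator,r_nm_per_px,n_pixels,n_e,n_o,k1,...,k12,head,tail,estimate_nm
shape,6.4,91,47,43,14,8,10,9,0,22,19,1,1,1,3,0,5,3,672.1793494505306
$ sncontour estimate --path-csv demo/sample_00000.csv --resolution 6.4 --estimator freeman
freeman,6.4,...,689.9915723650759
```

The backbone has 91 pixels (47 direct + 43 diagonal connections); the
columns `k1 … k12` are the shape-class tallies of its 88 interior
4-pixel segments. The shape estimate (672.2 nm, using the bundled
resolution-dependent coefficients) misses the true 680 nm by 1.2 % on
this *single* molecule — single-molecule scatter is a few nm — while the
Freeman sum lands 10 nm high on average; averaged over a corpus the
shape estimator is unbiased to ≲0.1 % where Freeman stays ≈3 % high.

Library use mirrors the CLI:

```python
import numpy as np
from sncontour import (ShapeLengthModel, REFERENCE_COEFFICIENT_MODEL,
                       draw_sample)

sample = draw_sample(l_c=680, r=6.4, rng=np.random.default_rng(7))
model = ShapeLengthModel(
    resolution=6.4,
    coefficients=REFERENCE_COEFFICIENT_MODEL.coefficients_at(6.4))
print(model.predict([sample.chain_code])[0])
```

Calibrating your own coefficients (e.g. for a different persistence
length) is one command:

```sh
sncontour calibrate --lc-grid 340:1020:34 --r-grid 5.1:7.8:0.1 \
    --n-per-case 200 --seed 0 --out coeffs.json
sncontour estimate --image strand.tif --resolution 6.0 --coeff-model coeffs.json
```

`sncontour enumerate-shapes` prints the full 64-segment taxonomy with
class labels for visual audit.

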