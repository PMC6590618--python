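# Methods

## Problem and model

A biopolymer strand imaged by AFM is reduced to a *single-width
backbone*: an ordered run of 8-connected pixels in which every pixel
touches only its path predecessor and successor. The backbone is encoded
as an 8-connect Freeman chain code `C = c_1 … c_n` (code 0 = +x,
counterclockwise), so even codes are unit steps and odd codes are √2
steps, in pixel units. The classical estimate of the contour length is
the Freeman sum `L_F = r (n_e + √2 n_o)` at pixel resolution `r`
(nm/pixel); it is biased by several percent because digital steps do not
follow the local curve geometry.

The shape estimator refines this by looking at the *4-pixel
neighborhood* of every interior connection. Each rolling window of three
consecutive codes `(c_{i-1}, c_i, c_{i+1})` is mapped to a shape number

    s_1 = (c_{i-1} − c_{i+1}) mod 8
    s_2 = (c_i − c_{i-1}) mod 8
    s_3 = (c_{i+1} − c_i) mod 8

and canonicalized (complement all digits by `(8 − d) mod 8` when
`s_1 > 4`, then order `s_2 ≤ s_3`). Brute-force enumeration over all
8³ code triples shows exactly 64 geometrically distinct single-width
4-pixel segments, partitioned by (canonical ID, parity of `c_i`) into 12
classes `k_1 … k_12`; the partition coincides with the orbits under 90°
rotations, mirrors, and traversal reversal (asserted by an independent
orbit oracle in the tests). The length model weights each class:

    L_S = r ( Σ_j n_kj · k_j · l_kj + l_H + l_T )

with `l_kj ∈ {1, √2}` the center-connection length of the class and
`l_H, l_T` the raw head/tail connection lengths, which carry no
coefficient; whatever systematic end effect exists is absorbed by the
calibration of the interior coefficients.

## Calibration

Stacking the model over m chains of known length gives the linear
system `r N D K + B = L` (N the m×12 count matrix, D =
diag(l_k1…l_k12), B the r-scaled head+tail lengths). K is solved by
least squares via orthogonal decomposition (`scipy.linalg.lstsq`), never
normal equations. Shape classes never observed in the training corpus
are pinned to `k_j = 1` (Freeman weighting) with a warning, so the
estimator degrades gracefully. Per-coefficient standard errors come from
the usual OLS covariance. Solving K at several resolutions and fitting
one ordinary least-squares line per class gives the resolution model
`k_j(r) = m_j r + b_j`, valid over the calibrated range r = 5.1–7.8
nm/pixel; evaluation outside it warns. The package ships a reference
line model for dsDNA-like contours as its default, and any user
calibration can replace it via JSON.

Calibration is performed per resolution, pooling training corpora across
the full grid of 21 contour lengths (340–1020 nm in 34 nm steps). A
single length would make the solve nearly circular (it could simply fit
the corpus mean); pooling lengths forces the coefficients to explain the
length dependence through the shape counts.

## Synthetic corpus

No calibrated ground-truth images exist at sub-nanometer accuracy, so
coefficients are calibrated on simulated strands. The generator is a
discrete 2D worm-like chain: headings increment by i.i.d. zero-mean
Gaussians of variance `ds / l_p` per step `ds` (default 1 nm), giving an
in-plane tangent correlation `⟨cos Δθ⟩ = exp(−Δs / (2 l_p))` — the
planar restriction of a chain with persistence length `l_p` (default
50 nm, dsDNA). Tests verify the tangent correlation and the closed-form
end-to-end distance `⟨R²⟩ = 4 l_p l_c [1 − (2 l_p/l_c)(1 −
e^{−l_c/(2 l_p)})]` by Monte Carlo. Self-intersecting realizations are
rejected and redrawn, because a crossed strand cannot be skeletonized
into a simple path; this mildly favors open conformations at the longest
lengths (~37% of raw draws are rejected at l_c = 1020 nm) and is shared
identically by calibration and evaluation.

Rasterization is occupancy-based: the polyline is resampled every r/10
nm, shifted by a uniform random sub-pixel phase, marked on a pixel grid,
and then thinned and debranched by the same preprocessing an imaged
strand receives. A rasterization is rejected (and the contour redrawn)
when the skeleton is a closed loop, violates single-width after pruning,
retains any skeleton pixel farther than 2 px from the extracted
backbone (a self-contact shortcut would otherwise amputate part of the
strand), or loses more than 2 px of extent at either end.

What the generator does *not* emulate: AFM height fields, tip-shape
convolution beyond the implicit widening that thinning removes,
measurement noise correlated along the scan axis, surface-adsorption
kinetics (the chain is an equilibrium 2D ensemble), and multi-molecule
scenes. Passing benchmarks therefore demonstrate the estimator's
behavior on ideal single-strand skeletons of known length, not
end-to-end accuracy on raw instrument data.

## Preprocessing of real images

`binarize_and_clean` thresholds (fixed fraction of the intensity range,
or Otsu when unspecified), removes connected components below
`min_island` pixels, and keeps the largest component.
`thin_and_debranch` applies iterative two-subiteration morphological
thinning (`skimage.morphology.thin`), then prunes side branches by
keeping the path between the farthest pair of skeleton endpoints
(breadth-first hop metric; ties broken toward the lexicographically
smallest endpoint, so output is deterministic), and finally removes
redundant corner pixels so the result satisfies every single-width
invariant or raises. Closed loops are rejected rather than cut at an
arbitrary point. Images are converted to Cartesian (x, y) with y up, so
code 2 is literally "up".

## Standard benchmark protocol and observed behavior

The packaged benchmark (`calibrate_and_evaluate`, also run by
`scripts/acceptance.py`) calibrates K at r ∈ {5.1, 6.4, 7.7} nm/pixel on
2000 training samples per (l_c, r) case over the 21-length grid, and
evaluates 4000 disjoint held-out samples at each reference cell
l_c ∈ {340, 680, 1020} nm, reporting relative (%), absolute (nm), and
per-sample standard deviation (nm) for L_S, the per-resolution
factor-corrected baseline L_DNA (C_f = ⟨l_c⟩/⟨L_F⟩ on the training
pool), and L_F. Problem sizes were chosen to keep the Monte-Carlo
standard error of each cell mean (≈0.01–0.03 % relative) well below the
quantities of interest at desk scale.

Under this protocol the Freeman baseline overestimates by ≈3.4 % at
r = 5.1 and ≈2.4 % at r = 7.7 with per-sample standard deviations of
≈5–12 nm, and the calibrated shape estimator reduces the averaged
relative error by roughly two orders of magnitude, to ≲0.1 %. The
residual is systematic, not noise: it is largest at the shortest length
(l_c = 340 nm) at every resolution, because small absolute
(length-independent) digitization end effects cannot be absorbed by
per-count coefficients and weigh most on short chains.

Coefficient convergence is limited by the rarest classes: the tight
double-turn shapes occur only ~0.02–0.1 times per chain at these
resolutions, so tens of thousands of chains still leave ~1–2 % sampling
error on their coefficients, while the common classes stabilize to a
few tenths of a percent. The convergence diagnostic
(`convergence_curve`) reports the maximum relative coefficient change
between growing sample prefixes.

## Numerical choices and edge cases

- Eight's complement of digit 0 is 0 (`(8 − 0) mod 8`), which the
  602 → 206 canonicalization requires.
- `s_1 = 4` never occurs on valid single-width segments (asserted by
  brute force), so the `s_1 > 4` complement rule has no boundary case.
- Code triples that cannot arise from a single-width backbone raise
  immediately (with window position) rather than classifying silently;
  they signal malformed input.
- Chains with fewer than 3 codes carry no interior segment; their tally
  is all zeros and the length estimate reduces to the head/tail terms.
- All randomness flows from one master seed through named
  `numpy.random.SeedSequence` substreams keyed by (role, case), so any
  subset of cases reproduces bit-for-bit regardless of traversal order.
- Least-squares fits use `lstsq`; rank deficiency over the observed
  columns raises with the deficient columns listed.

## Known limitations

- The simulation recipe (occupancy rasterization + thinning) is a
  design choice; digitization bias levels shift by a few tenths of a
  percent under plausible alternative recipes, and the calibrated
  coefficients are only valid for skeletons produced by a matching
  pipeline.
- Closed (circular) molecules and multi-strand scenes are out of scope.
- The corner-count baseline L_C defines a corner as any pair of adjacent
  unequal codes; the historical definition varies between sources, so
  L_C is shipped as a documented-assumption baseline only.
- Coefficients are calibrated for l_p = 50 nm; stiffer or softer
  polymers require re-calibration (one `calibrate` CLI run).
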