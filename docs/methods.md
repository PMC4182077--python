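# Methods

## Model and assumptions

The pipeline treats sharpening as a bounded, edge-restricted contrast
expansion. Three assumptions drive the design:

- The four global statistics (Min, Mid, Max, Avg) summarise the intensity
  distribution well enough that a GM(1,1) forecast of a "fifth statistic"
  measures how much headroom the image has; the gap Δ = |x⁰(5) − Avg| is a
  safe global cap on per-pixel change. GM(1,1) assumes the accumulated
  sequence is approximately exponential; with n = 4 samples the fit is a
  two-parameter least-squares problem over three equations.
- Edges are local first-difference events: a pixel is "around an edge" when
  it differs from its west or north neighbor by at least θ_eth. Isolated
  outliers also trip this test, so an edge flag is trusted only when at
  least θ_Lpf of the pixel's 8 neighbors are flagged too.
- The useful additive for an edge pixel shrinks with its existing local
  contrast: δ_x = s·Δ·min(x, LocalMean)/max(x, LocalMean), applied away
  from the local mean. Pixels already far from their neighborhood mean get
  small boosts; near-flat edge pixels get up to s·Δ.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| θ_eth | intensity (0–255) | 14 | discontinuity threshold; 8–18 is the useful band (8 for low-contrast medical images, 18 for busy textures) |
| θ_Lpf | neighbor count (1–8) | 3 (HVD), 2 (Canny) | HVD responses are nominally two pixels wide, Canny's one; the default adapts to the detector |
| s | dimensionless [0, 1] | 1.0 | scales δ_x; s = 0 is the identity |
| mid_mode | — | range-middle | "middle intensity" read as (Min+Max)/2; `median` selects the sample median instead (even counts: mean of the central pair) |
| gm_order | — | text | sequence order (Min, Mid, Max, Avg); `sorted` gives (Min, Mid, Avg, Max) |
| canny_sigma | pixels | 1.0 | Gaussian width of the Canny plugin; hysteresis thresholds are the plugin defaults |
| delta_override | intensity | off | bypasses the GM(1,1) pass for controlled experiments |

Both `mid_mode` and `gm_order` exist because "middle intensity" and the
exact sample ordering admit two natural readings; neither is guessed
silently, and Δ is sensitive to the choice. Avg enters the sequence as the
exact real-valued mean, untruncated.

## Numerical choices

- **a → 0 limit.** The white response divides by *a*; for |a| < 1e−12 the
  analytic limit x¹(k+1) = x⁰(1) + b·k is used, so constant sequences
  forecast their constant exactly.
- **Degenerate fit.** If |(n−1)F − C²| < 1e−12·max(1, F) the normal
  equations are singular (all-zero images); `compute_delta` catches this
  and returns Δ = 0 with a logged warning rather than crashing.
- **Rounding.** All arithmetic is double precision; Δ and δ_x are never
  rounded. A single half-away-from-zero rounding is applied to the final
  pixel value, then clamping to [0, 255] — in that order, so the output
  keeps the 8-bit integer contract without double-rounding bias.
- **Ties.** x = LocalMean falls to the additive ("otherwise") branch:
  δ_x = s·Δ is added. This is the literal reading of the piecewise rule and
  is deliberately kept although it means maximal boost at zero local
  contrast; it is the limit of the stated adaptation direction.
- **Borders.** Row 0 / column 0 pixels lack a north / west neighbor; a
  missing neighbor never triggers detection. The low-pass filter counts
  only existing neighbors and does not rescale its threshold, which biases
  against edges on the image border. LocalMean averages only existing
  pixels (9 interior, 6 edge, 4 corner). No padding anywhere.
- **Double-buffering.** x and LocalMean are always read from the unmodified
  input, so the result is independent of traversal order and the pipeline
  is fully deterministic.
- **One-pass filtering.** The low-pass filter reads the pre-filter map
  only; it never cascades. A consequence worth knowing: a literal
  west/north differentiator flags only the high side of an ideal step, a
  one-pixel-wide line whose interior pixels have just two flagged
  neighbors — θ_Lpf = 3 erases it. Real images produce thicker, more
  connected responses; on ideal synthetic steps use θ_Lpf = 2 or disable
  the filter when the step itself is the object of study.

## Synthetic fixtures: what they emulate and what they do not

The generator produces the structures the method targets: piecewise
constant steps (vstep/hstep), linear ramps, flat fields, checkerboards
(dense block boundaries), smooth low-gradient fields (per-pixel gradients
below any sensible θ_eth), and salt-and-pepper outliers on a flat base.
Outliers are placed by seeded rejection sampling at pairwise Chebyshev
distance ≥ 3: each outlier's detector response is an L-shaped three-pixel
cluster (the outlier plus its east and south neighbors), and that spacing
keeps clusters of distinct outliers out of each other's 8-neighborhoods,
which is exactly the condition under which a θ_Lpf = 3 filter removes
every flag. Plain non-adjacency of the outliers themselves is not enough —
at Chebyshev distance 2 the response clusters touch and flags survive.

Fixtures are deterministic in (spec, seed) and all randomness lives in the
generator, never in the pipeline. They do not emulate sensor noise,
texture, blur, gradual shading of real scenes, or the statistics of the
classic external test images; passing on fixtures demonstrates the
contracts (identity at s = 0, non-edge preservation, bounded change,
outlier suppression, PSNR ordering in s), not field performance on any
particular photograph. Published per-image PSNR figures for the standard
external test set depend on the exact image files and on the mid/order
policies, so they serve only as an optional external validation surface,
not as package tests.

## Problem sizes

The test suite exercises exhaustive per-pixel oracles on images up to 8×8
and property checks on 16×16–64×64 fixtures; the reproduction script uses
256×256 fixtures for Δ and the PSNR grid and a 128×128 field for the
salt-and-pepper counts. These sizes already contain every structural case
the method distinguishes (interior/edge/corner pixels, cluster
interactions, saturation), so larger images change nothing but runtime.

## Known limitations

- The literal one-sided differentiator halves the paper-style "two-pixel"
  edge width on ideal steps (see above); the discrepancy is documented,
  not resolved.
- Δ is a global cap derived from four numbers; images whose histogram is
  bimodal with a far-off mean can receive a generous cap, and s is the
  only guard.
- Only 8-bit grayscale is supported (PGM maxval ≤ 255, 8-bit PNG); deeper
  or color inputs are rejected or luma-converted on read (Rec. 601,
  half-away-from-zero rounding).
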