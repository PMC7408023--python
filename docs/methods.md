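# Methods

## The measurement model

A tablet of initial diameter 11 mm sits on a compliant silicone tongue
that is compressed against an acrylic palate once every 2 s while
simulated salivary fluid flows over the surface at 1.5 mL/min. An
overhead camera records at 30 fps. The quantity analysed is the
tablet's projected (top-down) area *A(t)* in mm², measured once per
compression cycle, and the operational disintegration time *T_d* is the
instant *A(t)* returns to its baseline value after the swelling peak.

### Compression-cycle timing

One cycle is partitioned as stationary pause → compression stroke →
hold → decompression stroke. With the default geometry (2000 ms period,
680 ms pause, 11 mm displacement at 18 mm/s) each stroke lasts
11/18 × 1000 ≈ 611.1 ms, so the phase table is 0–680 ms pause, 680–1291 ms
compression, 1291–1389 ms hold, 1389–2000 ms decompression. This
ordering is the only one that places the per-cycle measurement frame
(offset 1340 ms) *between* the compression and decompression strokes,
which is the protocol's stated extraction point: the tablet is pressed
flat and fully visible there. The ~98 ms hold absorbs the slack between
the pause plus two strokes and the period. Phase boundaries are held as
exact rationals of the inputs internally; only displayed values are
rounded. Frame indices are `floor(t·fps/1000)` with a 1 ns guard against
float representation error at exact frame boundaries.

### Segmentation

The tablet carries a red dye, so detection works on the red-dominance
transform `D = R − max(G, B)` (clipped at 0), which separates the tablet
(large red excess) from both the pink tongue and the palate and is
insensitive to global illumination changes. The threshold on `D` is
either a fixed configurable value or, by default, an automatic Otsu
threshold with a bimodality guard: if the separation between the above-
and below-threshold class means is under `min_contrast` (default 40
dominance units) the frame is declared tablet-free, so a uniform
background never yields a spurious half-frame mask. The binary mask is
morphologically closed (disk radius 2), hole-filled, and reduced to its
connected components of at least `min_component_px` pixels (default 9,
which suppresses single-pixel noise while keeping sub-millimetre
fragments at 10 px/mm).

Detached fragments contribute to the measured area by default
(`fragment_mode="all"`), because washed-away particles are part of the
visible disintegrate; a `"largest"` mode restricts measurement to the
main body. Area calibration is a single px/mm scale: `area_mm² =
pixels / scale²`.

### Endpoint rule and phases

The baseline *A₀* is the area at the **first measurement frame**
(1.34 s); no earlier measurable frame exists in the protocol, so it
stands in for the area at t = 0. The endpoint is the earliest time after
the global area maximum at which the linearly interpolated profile
crosses *A₀* from above. Linear interpolation between the 2-s samples
defines the sub-sample precision of the reported time. Degenerate and
edge cases:

* a profile that never exceeds its baseline (no measurable swelling)
  ends at the first subsequent sample at or below *A₀*;
* a record that ends above baseline is **censored**; censoring is
  reported, never imputed, and aggregation refuses censored values so
  the caller must handle them explicitly;
* anomalous replicates are retained — no outlier rejection is applied by
  default, so one slow replicate legitimately lifts its group mean.

Phases are anchored on the detected landmarks: swelling `[t₀, t_peak]`,
initial wash-away `(t_peak, T_d]`, final wash-away `(T_d, t_end]`. The
final window covers the residual thin film, where small detached areas
make edge detection erratic; it is flagged low-confidence and an
optional 3-point moving-median smoother (default **off**) is available
for display. The endpoint itself is always computed on unsmoothed data.

### Compendial verdicts

The EuPh criterion (complete disintegration within 180 s) and the USP
ODT criterion (30 s or less) are single-time-point rules: an item passes
iff its time ≤ limit, with equality passing, applied identically to both
compendia. Verdicts can be applied to replicate means (how the bundled
study table is summarised) or per replicate (the default for new data,
since compendia judge individual units). Apparatus metadata
(31 cycles/min, 54 mm stroke, 900 mL bath, 37 °C, discs) is carried for
provenance only; no basket-rack hydrodynamics are simulated.

## The synthetic generator

The generator emulates what the overhead camera sees, with known ground
truth, so each pipeline stage is testable without the physical device.
The noiseless trajectory is piecewise linear through the nodes

```
(0, A0) → (lag, A0) → (t_peak, s·A0) → (T_d, A0) → (t_end, f·A0)
```

Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `A0_mm2` | π·5.5² ≈ 95.0 mm² | footprint of the 11-mm tablet |
| `lag_s` | 1.34 s | wetting lag before swelling; equals the first measurement instant so the sampled baseline equals A₀ exactly |
| `swell_ratio` s | 4.0 | peak/initial area; volume conservation for an 11 × 4 mm tablet flattening to a ~1 mm film under compression quadruples the footprint |
| `t_peak_s` | 0.25·T_d | time of peak area |
| `t_end_s` | 1.2·T_d | record length |
| `residual_fraction` f | 0.2 | thin-film area fraction at record end |
| `per_cycle_noise_cv` | 0.03 | multiplicative lognormal measurement noise per cycle (areas are positive; per-cycle independence assumed) |
| `replicate_cv` | 0.09 | lognormal between-replicate CV on T_d (median-preserving), matching the ~10 s SDs observed at T_d ≈ 112 s |

Linear segments keep every endpoint analytically checkable; an
exponential-decay tail (same endpoint, convex film decay) sits behind
the `tail="exponential"` flag. Note that with the default shape the
pre- and post-endpoint slopes coincide ((s−1)/(0.75·T_d) =
(1−f)/(0.2·T_d) for s = 4, f = 0.2), so noiseless sampled profiles have
no kink at T_d and the interpolated endpoint is exact to machine
precision; for other shapes it is exact to within one 2-s sampling
interval.

The swell ratio deserves a note: it is a free parameter (published
profiles show the shape only qualitatively). Besides the
volume-conservation argument, the recovery precision of the endpoint is
governed by the ratio of the post-peak slope (s−1)·A₀/(T_d−t_peak) to
the per-cycle noise sd (≈ cv·A₀). At s = 4 the slope is ~3.4 mm²/s
against ~2.9 mm² noise, giving per-replicate endpoint errors of ~1 s;
at s = 1.5 the noise would dominate the slope and first-passage
detection would bias endpoints several seconds early. The default
therefore reflects both the physical argument and the precision the
instrument concept claims.

The wetting-lag node exists for a precise reason: the analysis defines
its baseline as the *first sampled* area. Without a lag the trajectory
is already rising at 1.34 s, the sampled baseline exceeds A₀, and every
detected endpoint would be early by lag·(T_d−t_peak)/t_peak (≈ 4 s with
the default shape) — an artefact of the generator, not of the analysis.
A short delay while fluid first penetrates the matrix is also the
physically expected behaviour.

Rendering draws the tablet as a filled disc (radius chosen so the drawn
pixel count tracks the noisy sampled area to within rasterisation
error, i.e. bounded by the perimeter) on a tongue-coloured background
with Gaussian pixel noise (sd 3). After T_d, 30 % of the remaining area
is rendered as scattered ~0.3-mm speckle to exercise the segmentation
path that the erratic thin-film phase exercises in real footage.
Replicate generation scales `t_peak` and `t_end` proportionally with
the drawn T_d and derives all child seeds deterministically from the
master seed.

### What the generator does *not* emulate

Uneven illumination and shadows, the tongue/palate texture, specular
reflection from the wetted film, partial occlusion by the plate edge,
non-circular tablet outlines, bottom-up erosion visible only side-on,
and any fluid- or pressure-physics of swelling. Passing tests therefore
demonstrate the correctness of the measurement chain and statistics
under the stated image model, not robustness to every optical artefact
of real footage; the fixed-threshold fallback and the largest-component
mode are the provided handles for harder footage.

## Numerical choices and problem sizes

* Endpoint interpolation is closed-form on the bracketing samples; an
  independent Brent root-finder over the same polyline is used as the
  test oracle. Ties at the peak resolve to the earliest maximum; a
  sample exactly equal to baseline is itself the endpoint.
* Sample SD uses the n−1 denominator and reports 0 for n = 1 (flagged).
* Percent changes are reported to one decimal.
* Verification runs use scaled problem sizes chosen to exercise every
  code path comfortably on a single CPU: recovery experiments render
  one frame per cycle (the measurement frame — the other 59 frames of
  each cycle carry no additional information for the analysis) at
  10 px/mm with 6 replicates per grade; segmentation accuracy uses 50
  randomised scenes with T_d between 14 and 30 s; the endpoint oracle
  uses 100 noiseless profiles.

## Known limitations

* The endpoint rule measures *projected-area return*, not complete
  disintegration; residual material persists past T_d by construction.
* Censored records carry no partial information into the group mean;
  with heavy censoring the summary reflects only the uncensored subset.
* Calibration assumes a fixed, distortion-free px/mm scale across the
  field of view.
* Video container decoding is out of scope; frame sequences (PNG/TIFF)
  are the supported input, which also keeps results codec-independent.
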