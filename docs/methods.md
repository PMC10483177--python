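# Methods

## Scope and data model

chromaplot treats one purification run as a `Chromatogram`: one or more
detector traces (`Curve`: elution volume in ml, signal in mAU, units taken
from the file), fraction-collector start marks, and injection/logbook
events. Volumes are a continuous axis; time-based exports are accepted
unchanged, the axis label simply follows the file's unit row. Duplicate
volume samples are kept with a warning (plotting tolerates them; the
baseline fit does not need strict monotonicity). Non-UV traces
(conductivity, pH) are parsed as generic curves with no special semantics;
peak detection and deconvolution are out of scope.

Fraction marks give only where each fraction *starts*. Intervals are formed
by tiling: fraction *i* spans from its own start to the next start, and the
final fraction ends at the maximum volume of the primary UV curve (the
280 nm trace when present) — the farthest a filled area can visually
extend. The tiling is exact: interval widths sum to the covered span with
no gaps or overlaps, which is what makes per-fraction areas additive.

## File dialects

Unicorn-style exports are paired-column tables: every series owns an
adjacent (volume, value) column pair, row 1 names the series, row 2 gives
units, and columns are ragged (trailing empty cells end a series; an empty
cell *inside* a series is ambiguous and rejected). Header conventions vary
across instrument-software versions, so tolerance is data, not code: a
`DialectDescriptor` (encoding × delimiter × decimal mark, 20 valid
combinations) that can be detected from the bytes — BOM or decode attempt
for the encoding, header-row frequency for the delimiter, numeric-cell
sampling for the decimal mark — or passed explicitly. Column pairs are
classified by unit-row tokens (`fraction`, `injection`, `logbook`,
case-insensitive substring); an unrecognized pair with non-numeric values
is kept as logbook-like events with a warning, so no named column is ever
silently dropped. Multi-run exports (`Chrom.1`, `Chrom.2`, …) parse the
first run and warn about the rest.

Numbers are written with `repr` (shortest exact float representation), so
every write → parse round trip is field-wise identity, not merely close.
The generic template for non-Äkta instruments is a deliberately minimal
second layout: tab-separated, one shared volume column, one column per
curve, optional trailing (volume, label) fraction pair.

## Baseline: asymmetric least squares

The baseline is fitted with the Whittaker smoother under asymmetric
weights. Given signal y, the baseline z minimizes

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^2 z_i)^2

with w_i = p where y_i > z_i and 1 - p otherwise, iterated from w = 1
until the relative change of z falls below `tol` (default 1e-6) or
`max_iter` (default 20) rounds. The normal equations are pentadiagonal and
solved sparsely; the fit is deterministic. ALS is the standard
chromatography choice because, with small p, points above the current
baseline (peaks) barely pull it up while everything below anchors it.
Whole-curve fitting is the only mode; region-restricted fits, rolling-ball/
SNIP/polynomial alternatives and automatic lambda selection are out of
scope.

Parameters:

- `p_asymmetry` (default 0.01, dimensionless in (0,1)): how strongly the
  fit ignores points above the baseline. The equilibrium places z roughly
  one noise-sd below the drift at p = 0.01 (~18% of noise samples end up
  below z); at p = 0.001 z hugs the lower envelope (≤5% below). This
  p-dependence is inherent to ALS, not an implementation artifact — the
  dense brute-force oracle shows the same values.
- `lambda_smooth` (default `(n/20)^4`): second differences are taken on
  the sample *index* (keeping the system pentadiagonal and insensitive to
  slightly uneven vendor grids), so the stiffness that corresponds to one
  physical smoothing scale grows with the fourth power of the sampling
  density. A fixed default would be wrong at some resolution: 1e6 is right
  for a ~600-point export but lets the baseline bulge under a peak sampled
  at 0.002 ml (where the peak spans ~1400 samples) and absorb most of its
  area. `(n/20)^4` pins the effective smoothing scale at ~5% of the run —
  exactly 1e6 at n ≈ 632 — and recovers linear drift to <0.8 mAU median
  while leaving peak areas intact at any tested resolution. Pass
  `lambda_smooth` explicitly to override.

Known limitations: a stiff baseline rings upward between broad overlapping
peaks (sigma ≳ 0.6 ml at default sampling), and the asymmetric equilibrium
sits systematically ~1–1.5 noise-sd below the true drift; both effects are
bounded by the drift-recovery and area-recovery numbers the acceptance
script measures.

## Normalization, restriction, areas, zoom

"Normalized" display defaults to `shift_min_zero` (subtract the minimum):
it keeps mAU readable on the axis. `minmax_01` is offered for overlaying
channels of very different magnitude and errors on constant curves. Each
curve is normalized independently; both methods are idempotent and
preserve x and the argmax.

Between samples the trace is treated as piecewise linear. Restricting to a
volume range keeps the interior samples and inserts exactly interpolated
boundary points at the requested volumes, so filled areas start and stop
where asked. Areas are trapezoidal (chosen over Simpson because vendor
grids are not guaranteed uniform), in ml·mAU, computed on the restricted
segment minus the baseline (interpolated onto the same grid) when one is
given; they can be negative where signal dips below baseline, and they are
additive over adjacent intervals to rounding error. Zooming clips curves,
baselines, intervals (partially visible ones truncated, invisible ones
dropped) and the highlight range to the window; because clipping only adds
on-segment interpolated points, any in-window area is unchanged by zoom.

## Rendering

The renderer is a decision tree of independent layers drawn in fixed
order: optional fills under the curves, the curves (260 nm red, 280 nm
blue, 230 nm green, explicit overrides first, deterministic fallbacks
otherwise), optional dashed baselines in the curve color (transformed with
the same normalization as their curve so they overlay the plotted trace),
selected-fraction fills (purple, alpha 0.4) and the volume-range fill
(gold, alpha 0.3) — overlaps stay visible by ordinary alpha compositing —
then the fraction strip, axis labels and window. Highlights attach to the
primary curve. Every artist carries a `gid` tag, so the decision tree is
testable by inventory rather than pixels; rendering is deterministic to
the byte at fixed dpi.

The fraction strip places a tick at each visible interval start with the
label beneath the axis, alternating between two rows whenever neighboring
starts are closer than 4% of the window width — preventing the label
overlaps that would otherwise need manual cleanup. Both channels share one
y-axis; per-curve secondary axes are out of scope. Exports: PDF/EPS vector
(PDF metadata omits the creation date so repeated exports are
byte-identical), TIFF/PNG raster at `round(size × dpi)` pixels (default
300 dpi), written via a temporary file and atomic rename so failures leave
no partial output. Default axis labels are "Elution volume (ml)" / "mAU".

## Style vs. selection persistence

`PlotStyle` (colors, fills, flags, labels, normalization) is what one
saves and reapplies across many similar runs; `Selection` (fraction
labels, volume range, zoom) refers to one specific file. The split is
enforced: style configs are flat YAML restricted to the PlotStyle fields,
unknown keys are an error listing them, and any selection-like key
(`fractions`, `volume_range`, `zoom`, …) is refused with an explanation.

## Synthetic runs and what passing tests show

The generator emulates a size-exclusion run: per channel,
`y(x) = drift(x) + Σ scale·peak_k(x) + N(0, noise_sd²)` from one seeded
RNG stream. Defaults model a 24 ml column sampled every 0.002 ml with one
main peak at 14 ml (height 120 mAU, sd 0.35 ml), linear drift
2 + 0.15·x mAU, noise 0.5 mAU, a 0.55-scaled 260 nm channel and 24 × 0.5 ml
fractions from 8 ml — sizes and noise typical of an analytical SEC
purification. True per-peak areas are `height·sigma·√(2π)·scale`.

It does *not* emulate peak tailing or fronting, detector saturation,
conductivity gradients, mid-run injections, or correlated noise; passing
the recovery tests therefore shows the pipeline's arithmetic and the
baseline's behavior under Gaussian assumptions, not robustness to every
real-world pathology. Test and acceptance problem sizes (hundreds of
samples for oracle comparisons, the 12001-sample default run for
end-to-end recovery, 100 fixture/dialect round-trips) were chosen as the
smallest that exercise each property convincingly.

## Numerical choices and edge cases

- Baseline fitting requires ≥3 points (second differences); curves require
  ≥2 finite, nondecreasing x.
- Convergence is declared on relative L2 change of z < 1e-6; the
  `converged` flag and iteration count are reported, never hidden.
- A fraction scheme's final interval ends at the primary curve's last
  sample; `x_end` at or before the last start is a boundary error rather
  than a zero-width interval.
- minmax normalization of a constant curve, ranges/zooms that select no
  data, and writing a chromatogram with zero curves are explicit errors.
- Ties in the strip-label collision rule and color fallbacks are
  deterministic (file order).
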