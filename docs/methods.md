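# Methods

## The RT ↔ iRT mapping problem

Retention times drift between runs, instruments and laboratories, while a
peptide's *relative* elution position is far more stable. The iRT scale
makes that relative position explicit: it is a dimensionless axis anchored
so that one reference peptide sits at 0 and another at 100. Converting
between a run's RT axis and the iRT axis requires a mapping, and for
segmented (multi-step) gradients that mapping is visibly nonlinear. The
package models it as a piecewise-linear curve estimated locally and
robustly, so that a small fraction of wrong anchor identifications
(false discoveries among the matched peptides, expected around 1 % at the
usual q-value threshold) cannot corrupt the fit.

## Segmented Theil–Sen regression

Given *n* anchor points, sorted by the independent coordinate (RT when
building a library, iRT when analyzing DIA data):

1. **Binning.** Each bin holds `bin_size = max(round(n/40), 20)` points
   (round half up). Bins start every `floor(bin_size/2)` indices — i.e.
   they overlap by half — and the last bin is right-aligned so it ends at
   index *n*. At *n* = 400 this gives 39 bins of 20 points. Equal *count*,
   not equal width: bin boundaries adapt to anchor density.
2. **Per-bin robust fit.** Theil–Sen: the slope is the median of all
   pairwise slopes (pairs with identical *x* excluded), the intercept the
   median of the per-point residual intercepts. The estimator tolerates up
   to ~29 % gross outliers per bin. Implementation:
   `scipy.stats.theilslopes(method="joint")`, which computes exactly this
   definition; the test suite checks it against an exhaustive pairwise
   enumeration oracle.
3. **Knots.** Each bin contributes the knot (median *x* of the bin, fitted
   value there). Knots sharing an *x* are merged by averaging *y*, keeping
   knot *x* strictly increasing. No monotonicity constraint is imposed on
   knot *y*.
4. **Prediction.** Linear interpolation between knots, linear
   extrapolation with the first/last segment slope outside them.
5. **Fallback.** With fewer than `min_anchors` anchors (defaults: 200 for
   spectral library generation, 50 for targeted DIA analysis) or fewer
   points than one bin, a single global Theil–Sen line is used.

**Accuracy structure.** On noise-free data the fit is exact (to floating
point) wherever a bin lies entirely within one linear segment of the true
mapping. Across a slope change ("kink") the error is bounded by the
interpolation ceiling Δslope × (knot spacing)/4 plus the bias of the one
bin that straddles the kink; with the default binning the knot spacing
approaches (x-range)/80 for large *n*, so this error is localized to a
narrow neighborhood of each kink. The tests assert both facts separately
rather than a single global bound, and the RT→iRT→RT round-trip identity
is asserted to 1e−6 on affine anchor sets, where it holds exactly; across
kinks the forward and backward binnings differ slightly and the round-trip
error is of the same order as the interpolation error.

**Inversion.** A fitted piecewise-linear model with strictly monotone knot
*y* values can be inverted exactly by swapping knot coordinates
(`invert()`). Models fitted on heavily noise-contaminated iRTs need not be
monotone; workflows that need both directions (precision evaluation) fit
both from the same anchors instead.

## The iRT scale and the extended calibration set

The scale is defined by an exact two-point linear map: slope
100/(rt_l − rt_b), sending the iRT = 0 peptide's mean RT to 0 and the
iRT = 100 peptide's to 100. Only those two peptides define the scale; a
least-squares fit over a full kit with known iRTs is available
(`kit_calibration`) when those values are supplied.

The extended set is built from ≥3 replicate runs: precursors observed in
*every* run are kept; mean and SD of apex RT use the sample SD (ddof = 1,
the convention for triplicates); the [min, max] range of mean RT is cut
into 20 equal-width bins (last bin closed on the right); per bin the 80 %
of precursors with the lowest SD are retained, with floor rounding and a
minimum of one per non-empty bin. Kit peptides are exempt from the filter
(retention by exemption, not re-insertion). Precursor identity is the
modified sequence plus charge, encoded `sequence/charge`; kit membership is
matched on the sequence part. No outlier rule beyond the SD filter is
applied.

## Dynamic extraction windows

Window estimation reuses the anchor set, sorted by iRT, with a different
binning: bin size `max(2, round(n/log2(n)))`, sliding by one index
(n − s + 1 bins), requiring at least 30 anchors. Per bin: *x* = mean iRT,
*w* = median peak width (an opaque positive duration supplied by the data
producer; the generator emits full width at half maximum), *q* = 75th
percentile of |measured RT − predicted RT| with linear interpolation
between order statistics, *y* = (*w* + *q*)/2. Residuals enter as absolute
values: windows are symmetric, and a signed percentile could be negative.
The reference points feed the same segmented regression with bin size
`max(2, round(m/10))`, and the emitted full window width is 2× its
prediction, centered on the predicted RT. In the zero-residual,
constant-width limit the window equals the peak width exactly
(2 × (w+0)/2 = w).

With fewer than 30 anchors a fixed full width applies; the default is 5 %
of the observed RT span (no established default exists for this fallback;
5 % of a 2 h gradient ≈ 6 min is a deliberately conservative first-pass
width, and the value is configurable).

## Spectral library rules

Fragments outside 300–1800 m/z (bounds inclusive — the exclusions are
strictly-below/strictly-above) or covering fewer than 3 residues are
removed; neutral-loss fragments pass on the same terms. At most the 6 most
intense fragments are kept, ties broken by lower m/z for determinism;
precursors with fewer than 3 surviving fragments are dropped. Per run, RTs
convert to iRT through the segmented regression against the anchor
database; the library iRT is the median across runs, which makes assembly
invariant to run order. Fragment intensities come from a single source
spectrum — the run with the best (lowest) PSM score, or the median-RT run
(lower middle for even counts) when scores are absent — rather than an
averaged consensus, a documented and testable policy. m/z arithmetic
(validation and precursor m/z) uses standard monoisotopic residue masses
via pyteomics and applies to unmodified sequences; modifications are
carried opaquely in the identifier and do not enter mass arithmetic.

## Synthetic runs: what they emulate, and what they do not

`generate_run` draws true iRTs uniformly over the warp domain (default
[−25, 125], admitting eluters outside the two scale anchors), maps them
through a piecewise-linear gradient warp, and adds Gaussian apex noise
(default SD 0.05 min, a realistic apex-determination error), lognormal
peak widths (default median 0.5 min, σ = 0.25 log-units; no published
width distribution exists, so a right-skewed positive law was chosen), and
a 1 % fraction of outliers placed uniformly over the RT span, mirroring
the expected false-discovery rate among anchors. Two warp presets ship: a
curved `segmented_2h` profile shaped like a multi-step solvent gradient
(shallow early ramp, steep middle, flat finish over ~2 h) and a straight
`linear_2h`. All randomness flows through one `numpy` seed;
identical seeds give bit-identical runs.

`inject_irt_noise` perturbs only the iRT column of a calibration set or
library with N(0, sd) noise, the design used to study how precision loss
degrades targeted analysis. `irt_noise_sweep` runs the full chain — fit
both mapping directions and the window model against the noisy library,
score against ground truth — across SDs {0, 1, 2, 4, 8, 16} with paired
seeds. Because the window's residual term grows proportionally with the
injected noise while the peak-width term stays constant, the median window
width responds linearly in the noise SD; the suite asserts R² ≥ 0.95.

What the harness does **not** emulate: MS2 spectra, chimeric interference,
FDR-controlled scoring, or identification counts. Identification loss is
proxied by *coverage* — the fraction of true apexes falling inside their
extraction windows — which captures the geometric effect of window
placement but has no calibrated quantitative relationship to search-engine
identification rates on real data. Passing tests therefore demonstrate the
correctness and precision behavior of the normalization machinery, not
end-to-end identification performance.

## Precision metrics

`evaluate_precision` reports, over non-outlier precursors: the median
absolute difference between library iRT and the model-converted apex RT;
the median full window width at the library iRTs; and coverage
(|apex − predicted RT| ≤ window/2). Problem sizes used in the test suite
and experiments (n = 1000–2000 per run, 10–20 seeds per battery) were
chosen so that binomial/chi-square concentration makes the asserted
properties stable across seeds.

## Numerical choices

* Rounding of bin sizes (n/40, n/log2(n), m/10): round half up, floored at
  the rule's minimum (20, 2, 2 respectively).
* Percentiles: linear interpolation between order statistics
  (`numpy.percentile` default), oracle-tested against a sort-based
  implementation.
* Degenerate inputs: fewer than 2 points or constant *x* raise a
  `DegenerateInputError` naming the condition; too few points for a bin
  plan raise `TooFewAnchorsError`, which fitting code catches to engage
  fallbacks.
* Keep-fraction rounding: floor, minimum 1 per non-empty bin.
* Serialization: models round-trip through JSON bit-exactly for finite
  doubles; tables are TSV with '.' radix only (',' decimals are rejected
  with an explicit message).

## Known limitations

* No monotonicity constraint on the fitted mapping: with extreme iRT noise
  the knots may be locally non-monotone, which is faithful to the binned
  estimator but precludes exact inversion (fit both directions instead).
* The two-anchor scale map ignores the other kit peptides' published iRTs
  unless supplied explicitly.
* Fragment mass arithmetic covers unmodified sequences and b/y series
  only.
* The fixed-window fallback width is a heuristic default, not an estimate.
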