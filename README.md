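# irtnorm

High-precision indexed retention time (iRT) normalization for targeted
analysis of data-independent acquisition (DIA) proteomics.

In peptide-centric DIA analysis, a spectral library tells the software
*what* to look for (fragment ions and their relative intensities) and
*when* to look for it (a normalized retention time, iRT). The narrower the
retention-time extraction window around the predicted elution, the less
interference and the better the identification — but only if the RT ↔ iRT
mapping is precise. A single linear fit through a handful of reference
peptides is not precise enough for segmented gradients or long runs.
`irtnorm` implements the high-precision alternative:

* **Segmented Theil–Sen regression.** Anchor peptides (peptides with both a
  measured apex RT and a known iRT) are sorted along the independent
  coordinate and split into overlapping equal-count bins — each bin holds
  max(*n*/40, 20) points and bins overlap by half. Per bin a robust
  Theil–Sen line (median of all pairwise slopes) is fitted; the bin's knot
  is (median *x*, fitted *y*). Knots are connected piecewise-linearly and
  extrapolated linearly at the edges. Below a minimum anchor count
  (200 for library generation, 50 for DIA analysis) a single global
  Theil–Sen line is used instead.
* **Extended anchor-set calibration.** From replicate runs of a complex
  digest, precursors seen in every replicate are averaged, binned into 20
  equal-width RT bins, and the 80 % with the lowest replicate SD per bin
  are kept (the calibration-kit peptides are always kept). iRT values are
  assigned by the exact two-anchor map that sends the iRT = 0 peptide's RT
  to 0 and the iRT = 100 peptide's RT to 100.
* **Dynamic extraction windows.** Anchors are grouped into bins of
  *n*/log₂(*n*) points sliding by one index; each bin contributes a
  reference point *y* = (*w* + *q*)/2, where *w* is the median
  chromatographic peak width and *q* the 75th percentile of the absolute RT
  prediction residuals. A segmented regression over these reference points
  (bin size *m*/10) predicts the half-window; the emitted full width is
  twice the prediction. With fewer than 30 anchors a fixed width applies.
* **Spectral library construction.** Fragment ions outside 300–1800 m/z or
  covering fewer than three residues are discarded; at most the six most
  intense fragments are kept and precursors with fewer than three are
  dropped; the library iRT is the median across runs after per-run
  segmented regression.
* **Simulation harness.** Synthetic runs with a known piecewise-linear
  gradient warp, Gaussian apex noise, lognormal peak widths and ~1 %
  misplaced outlier anchors, plus Gaussian iRT-noise injection into
  libraries — the machinery for controlled precision experiments.

The estimators (`SegmentedTheilSenRegressor`, `ExtractionWindowEstimator`)
follow scikit-learn conventions (`fit`/`predict`, `get_params`, fitted
attributes with trailing underscores) and compose with sklearn tooling.

## Worked example

Simulate a 2 000-precursor run on the curved segmented-gradient preset, fit
both directions of the RT ↔ iRT mapping, fit the dynamic window model, and
score everything against the ground truth:

```bash
irtnorm simulate --n 2000 --warp segmented_2h --seed 1 --out run.tsv
irtnorm model  --run run.tsv --mode irt_to_rt --out irt2rt.json
irtnorm model  --run run.tsv --mode rt_to_irt --out rt2irt.json
irtnorm window --run run.tsv --model irt2rt.json --out window.json
irtnorm evaluate --run run.tsv --model rt2irt.json --window window.json
```

prints

```json
{
 "median_abs_delta_irt": 0.04936457450696885,
 "median_window_width_min": 0.5623959793989004,
 "coverage": 0.9853683148335015,
 "n_evaluated": 1982
}
```

With 0.05 min of apex noise on a ~120 min gradient, the median absolute
iRT error is ≈ 0.05 iRT units, the median dynamic extraction window is
≈ 0.56 min (peak width ≈ 0.5 min plus a small residual term), and 98.5 %
of the non-outlier true apexes fall inside their windows. The same
workflow is available programmatically:

```python
from irtnorm import generate_run, analyze_run, evaluate_precision

run = generate_run(2000, seed=1)
rt_to_irt, irt_to_rt, windows = analyze_run(run)
report = evaluate_precision(run, irt_to_rt, windows, inverse_model=rt_to_irt)
print(report.to_dict())
```

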