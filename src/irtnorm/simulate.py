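"""Synthetic chromatographic runs with known ground truth.

The harness emulates the conditions of a precision study on retention-time
normalization without requiring raw mass-spectrometry data:

* a :class:`GradientWarp` is the ground-truth piecewise-linear iRT -> RT
  mapping of a run (a segmented-gradient preset that bends the mapping, and
  a linear preset);
* :func:`generate_run` draws precursors uniformly over the iRT domain,
  applies the warp, Gaussian apex-RT noise, lognormal chromatographic peak
  widths, and a fraction of uniformly misplaced outliers (emulating the
  ~1% false discoveries expected among anchor identifications);
* :func:`inject_irt_noise` perturbs library/calibration iRT values with
  Gaussian noise of a chosen SD, the design used to probe how extraction
  windows and identification degrade as iRT precision is lost;
* :func:`evaluate_precision` scores a fitted model and window estimator
  against the ground truth: median absolute delta-iRT, median window width,
  and the fraction of true apexes falling inside their windows.

All randomness flows through a single integer seed; identical seeds give
bit-identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationSet
from .library import SpectralLibrary
from .regression import SegmentedTheilSenRegressor
from .windowing import ExtractionWindowEstimator

__all__ = [
    "GradientWarp",
    "SEGMENTED_WARP",
    "LINEAR_WARP",
    "WARP_PRESETS",
    "SyntheticRun",
    "PrecisionReport",
    "generate_run",
    "inject_irt_noise",
    "analyze_run",
    "irt_noise_sweep",
    "evaluate_precision",
]

#: Default iRT sampling domain: includes eluters beyond the 0/100 anchors.
DEFAULT_IRT_DOMAIN = (-25.0, 125.0)

#: Default lognormal peak-width parameters (median 0.5 min full width).
DEFAULT_WIDTH_PARAMS = (math.log(0.5), 0.25)

DEFAULT_RT_NOISE_SD = 0.05  # minutes, apex determination error
DEFAULT_OUTLIER_FRACTION = 0.01  # ~1% false-discovery anchors


@dataclass(frozen=True)
class GradientWarp:
    """Ground-truth piecewise-linear iRT -> RT mapping of a run.

    ``breakpoints`` is an ordered sequence of (iRT, RT-minutes) control
    points, strictly increasing in both coordinates.
    """

    name: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = np.asarray(self.breakpoints, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("warp needs >= 2 (iRT, RT) breakpoints")
        if not np.isfinite(pts).all():
            raise ValueError("warp breakpoints must be finite")
        if not (np.all(np.diff(pts[:, 0]) > 0) and np.all(np.diff(pts[:, 1]) > 0)):
            raise ValueError("warp breakpoints must strictly increase in "
                             "both iRT and RT")

    @property
    def irt_domain(self) -> tuple[float, float]:
        return self.breakpoints[0][0], self.breakpoints[-1][0]

    @property
    def rt_span(self) -> tuple[float, float]:
        return self.breakpoints[0][1], self.breakpoints[-1][1]

    def __call__(self, irt):
        pts = np.asarray(self.breakpoints, dtype=float)
        return np.interp(np.asarray(irt, dtype=float), pts[:, 0], pts[:, 1])


#: Nonlinear preset shaped like a multi-step organic-solvent gradient
#: (shallow early ramp, steep middle, flat finish) over a ~2 h run.
SEGMENTED_WARP = GradientWarp("segmented_2h", (
    (-25.0, 1.0),
    (0.0, 5.0),
    (10.3, 7.0),
    (24.1, 16.0),
    (82.8, 110.0),
    (125.0, 126.0),
))

#: Linear 2 h gradient preset.
LINEAR_WARP = GradientWarp("linear_2h", (
    (-25.0, 0.0),
    (125.0, 120.0),
))

WARP_PRESETS = {w.name: w for w in (SEGMENTED_WARP, LINEAR_WARP)}


@dataclass
class SyntheticRun:
    """A generated run: ground-truth warp plus per-precursor observations.

    ``observations`` columns: ``precursor_id``, ``true_irt``, ``rt_apex``
    (minutes), ``peak_width`` (minutes, full width), ``is_outlier``.
    """

    warp: GradientWarp
    observations: pd.DataFrame
    rt_noise_sd: float
    outlier_fraction: float
    seed: int
    width_params: tuple[float, float] = DEFAULT_WIDTH_PARAMS

    def __len__(self) -> int:
        return len(self.observations)

    def anchors(self, library_irt: pd.Series | None = None) -> pd.DataFrame:
        """Anchor table (x=iRT from the library, y=apex RT) for model fitting.

        ``library_irt`` maps precursor_id -> library iRT; defaults to the
        ground-truth iRT (a perfect library).
        """
        obs = self.observations
        irt = (obs["true_irt"] if library_irt is None
               else obs["precursor_id"].map(library_irt))
        return pd.DataFrame({
            "precursor_id": obs["precursor_id"].to_numpy(),
            "x": irt.to_numpy(dtype=float),
            "y": obs["rt_apex"].to_numpy(dtype=float),
        })

    def config(self) -> dict:
        return {
            "warp": self.warp.name,
            "breakpoints": [list(bp) for bp in self.warp.breakpoints],
            "n": len(self),
            "rt_noise_sd": self.rt_noise_sd,
            "outlier_fraction": self.outlier_fraction,
            "width_params": list(self.width_params),
            "seed": self.seed,
        }


@dataclass
class PrecisionReport:
    """Precision metrics of a fitted model on a ground-truth run."""

    median_abs_delta_irt: float
    median_window_width: float  # minutes
    coverage: float  # fraction of true apexes inside their windows
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "median_abs_delta_irt": self.median_abs_delta_irt,
            "median_window_width_min": self.median_window_width,
            "coverage": self.coverage,
            "n_evaluated": self.n_evaluated,
        }


def generate_run(n: int, warp: GradientWarp = SEGMENTED_WARP,
                 rt_noise_sd: float = DEFAULT_RT_NOISE_SD,
                 width_params: tuple[float, float] = DEFAULT_WIDTH_PARAMS,
                 outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
                 seed: int = 0) -> SyntheticRun:
    """Generate a synthetic run of ``n`` precursors with known ground truth.

    Non-outlier apexes are ``warp(true_irt) + N(0, rt_noise_sd)``; outliers
    (fraction ``outlier_fraction``, flagged in the output) are placed
    uniformly over the run's RT span.  Peak widths are lognormal with the
    given (mu, sigma) of log-minutes.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= outlier_fraction < 1:
        raise ValueError(f"outlier_fraction must be in [0, 1), got "
                         f"{outlier_fraction}")
    if rt_noise_sd < 0:
        raise ValueError(f"rt_noise_sd must be >= 0, got {rt_noise_sd}")
    rng = np.random.default_rng(seed)
    lo, hi = warp.irt_domain
    true_irt = np.sort(rng.uniform(lo, hi, size=n))
    rt_true = warp(true_irt)
    rt_apex = rt_true + rng.normal(0.0, rt_noise_sd, size=n)
    is_outlier = rng.random(n) < outlier_fraction
    rt_lo, rt_hi = warp.rt_span
    rt_apex[is_outlier] = rng.uniform(rt_lo, rt_hi, size=int(is_outlier.sum()))
    mu, sigma = width_params
    peak_width = rng.lognormal(mu, sigma, size=n)
    obs = pd.DataFrame({
        "precursor_id": [f"PEP{i:06d}/2" for i in range(n)],
        "true_irt": true_irt,
        "rt_apex": rt_apex,
        "peak_width": peak_width,
        "is_outlier": is_outlier,
    })
    return SyntheticRun(warp=warp, observations=obs, rt_noise_sd=rt_noise_sd,
                        outlier_fraction=outlier_fraction, seed=seed,
                        width_params=width_params)


def inject_irt_noise(library_or_set, sd: float, seed: int = 0):
    """Add Gaussian noise (SD ``sd``) to every iRT of a library or anchor set.

    Only the iRT values change; all other fields are untouched.  ``sd = 0``
    returns an identical copy.  Accepts a :class:`CalibrationSet`, a
    :class:`SpectralLibrary`, or a DataFrame with an ``irt`` column.
    """
    if sd < 0:
        raise ValueError(f"noise SD must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    if isinstance(library_or_set, CalibrationSet):
        entries = library_or_set.entries.copy()
        entries["irt"] = entries["irt"].to_numpy(dtype=float) + (
            rng.normal(0.0, sd, size=len(entries)) if sd > 0 else 0.0)
        return CalibrationSet(entries=entries,
                              provenance={**library_or_set.provenance,
                                          "irt_noise_sd": sd, "noise_seed": seed})
    if isinstance(library_or_set, SpectralLibrary):
        noise = (rng.normal(0.0, sd, size=len(library_or_set))
                 if sd > 0 else np.zeros(len(library_or_set)))
        entries = [replace_entry_irt(e, e.irt + dz)
                   for e, dz in zip(library_or_set.entries, noise)]
        return SpectralLibrary(entries=entries,
                               meta={**library_or_set.meta,
                                     "irt_noise_sd": sd, "noise_seed": seed})
    if isinstance(library_or_set, pd.DataFrame):
        if "irt" not in library_or_set.columns:
            raise ValueError("DataFrame input needs an 'irt' column")
        out = library_or_set.copy()
        out["irt"] = out["irt"].to_numpy(dtype=float) + (
            rng.normal(0.0, sd, size=len(out)) if sd > 0 else 0.0)
        return out
    raise TypeError(f"unsupported input type {type(library_or_set).__name__}")


def replace_entry_irt(entry, irt: float):
    """Copy a library entry with a new iRT (fragments shared, not copied)."""
    from .library import LibraryEntry
    return LibraryEntry(
        precursor_id=entry.precursor_id,
        modified_sequence=entry.modified_sequence,
        sequence=entry.sequence,
        charge=entry.charge,
        precursor_mz=entry.precursor_mz,
        irt=float(irt),
        fragments=entry.fragments,
        protein_id=entry.protein_id,
    )


def analyze_run(run: SyntheticRun, library_irt: pd.Series | None = None,
                min_anchors: int = 50,
                ) -> tuple[SegmentedTheilSenRegressor,
                           SegmentedTheilSenRegressor,
                           ExtractionWindowEstimator]:
    """Fit the targeted-analysis models for a run against a library.

    Mirrors the DIA workflow: the run's identifications are matched to the
    library iRTs (ground truth by default), a segmented regression is
    fitted in both directions, and the extraction-window model is fitted on
    the iRT->RT residuals and peak widths.  Returns
    ``(rt_to_irt, irt_to_rt, window_model)``.
    """
    anchors = run.anchors(library_irt)
    irt = anchors["x"].to_numpy(dtype=float)
    rt = anchors["y"].to_numpy(dtype=float)
    irt_to_rt = SegmentedTheilSenRegressor(
        mode="irt_to_rt", min_anchors=min_anchors).fit(irt, rt)
    rt_to_irt = SegmentedTheilSenRegressor(
        mode="rt_to_irt", min_anchors=min_anchors).fit(rt, irt)
    wobs = pd.DataFrame({
        "precursor_id": anchors["precursor_id"],
        "irt": irt,
        "rt_measured": rt,
        "rt_predicted": np.asarray(irt_to_rt.predict(irt)),
        "peak_width": run.observations["peak_width"].to_numpy(dtype=float),
    })
    window_model = ExtractionWindowEstimator().fit(wobs)
    return rt_to_irt, irt_to_rt, window_model


def irt_noise_sweep(sds=(0.0, 1.0, 2.0, 4.0, 8.0, 16.0), n: int = 2000,
                    warp: GradientWarp = SEGMENTED_WARP, seed: int = 0,
                    rt_noise_sd: float = DEFAULT_RT_NOISE_SD) -> pd.DataFrame:
    """Degrade library iRT precision and measure the window response.

    For each noise SD, the same synthetic run (paired seed) is analyzed
    against a library whose iRTs carry Gaussian noise of that SD, and the
    precision metrics are recorded.  Returns one row per SD with columns
    ``irt_noise_sd``, ``median_window_width``, ``median_abs_delta_irt``,
    ``coverage`` and ``n_evaluated``.
    """
    run = generate_run(n=n, warp=warp, rt_noise_sd=rt_noise_sd, seed=seed)
    truth = run.observations.set_index("precursor_id")["true_irt"]
    rows = []
    for sd in sds:
        noisy = inject_irt_noise(truth.rename("irt").reset_index(), sd=sd,
                                 seed=seed + 1)
        lib_irt = noisy.set_index("precursor_id")["irt"]
        rt_to_irt, irt_to_rt, wmodel = analyze_run(run, lib_irt)
        rep = evaluate_precision(run, irt_to_rt, wmodel, library_irt=lib_irt,
                                 inverse_model=rt_to_irt)
        rows.append({"irt_noise_sd": float(sd), **rep.to_dict()})
    out = pd.DataFrame(rows).rename(columns={
        "median_window_width_min": "median_window_width"})
    return out


def evaluate_precision(run: SyntheticRun, model: SegmentedTheilSenRegressor,
                       windows: ExtractionWindowEstimator,
                       library_irt: pd.Series | None = None,
                       inverse_model: SegmentedTheilSenRegressor | None = None,
                       ) -> PrecisionReport:
    """Score a fitted RT <-> iRT model and window estimator on a run.

    ``model`` may be fitted in either direction; the opposite direction is
    derived by swapping knot coordinates (requires a monotone fit) unless
    ``inverse_model`` supplies it explicitly — with heavy iRT noise the
    fitted knots need not be monotone, and callers should then fit both
    directions from the same anchors.  Metrics are computed over
    non-outlier precursors only:

    * ``median_abs_delta_irt``: median |library iRT - model-converted apex RT|;
    * ``median_window_width``: median full window width at the library iRT;
    * ``coverage``: fraction of apexes with |rt_apex - predicted RT| <=
      window/2, where predicted RT maps the library iRT through the model.

    ``library_irt`` (precursor_id -> iRT) defaults to the ground truth, and
    is how noise-injected libraries enter the evaluation.
    """
    obs = run.observations
    if obs.empty:
        raise ValueError("cannot evaluate an empty run")
    other = model.invert() if inverse_model is None else inverse_model
    if inverse_model is not None and inverse_model.mode == model.mode:
        raise ValueError("inverse_model must map in the opposite direction")
    if model.mode == "rt_to_irt":
        rt_to_irt, irt_to_rt = model, other
    else:
        rt_to_irt, irt_to_rt = other, model
    good = ~obs["is_outlier"].to_numpy(dtype=bool)
    lib_irt = (obs["true_irt"] if library_irt is None
               else obs["precursor_id"].map(library_irt)).to_numpy(dtype=float)[good]
    rt_apex = obs["rt_apex"].to_numpy(dtype=float)[good]

    delta_irt = np.abs(np.asarray(rt_to_irt.predict(rt_apex)) - lib_irt)
    widths = np.asarray(windows.predict(lib_irt), dtype=float)
    rt_pred = np.asarray(irt_to_rt.predict(lib_irt))
    covered = np.abs(rt_apex - rt_pred) <= widths / 2.0
    return PrecisionReport(
        median_abs_delta_irt=float(np.median(delta_irt)),
        median_window_width=float(np.median(widths)),
        coverage=float(covered.mean()),
        n_evaluated=int(good.sum()),
    )
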