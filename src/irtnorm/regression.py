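"""Robust segmented (piecewise-linear) retention-time regression.

The RT <-> iRT mapping of a chromatographic run is rarely a single straight
line: segmented gradients, column aging and dead-volume effects all bend it.
The mapping is therefore estimated locally: anchor peptides (peptides with
both a measured apex RT and a known iRT) are sorted along the independent
coordinate, split into overlapping equal-count bins, a robust Theil-Sen line
is fitted per bin, and the per-bin reference points (median x, fitted y) are
connected into a piecewise-linear model with linear extrapolation beyond the
outermost knots.  When too few anchors are available the model falls back to
a single global Theil-Sen line.

:class:`SegmentedTheilSenRegressor` packages this as a scikit-learn style
estimator; :func:`fit_theil_sen`, :func:`plan_bins`,
:func:`build_segmented_model` and :func:`predict` are thin functional
wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DegenerateInputError",
    "TooFewAnchorsError",
    "LinearFit",
    "BinningPlan",
    "fit_theil_sen",
    "plan_bins",
    "SegmentedTheilSenRegressor",
    "build_segmented_model",
    "predict",
    "MIN_ANCHORS_LIBRARY",
    "MIN_ANCHORS_DIA",
]

#: Minimum anchor counts below which a global linear fallback is used.
MIN_ANCHORS_LIBRARY = 200  # spectral library generation
MIN_ANCHORS_DIA = 50  # targeted analysis of DIA data


class DegenerateInputError(ValueError):
    """Raised when a regression input admits no line (n < 2 or constant x)."""


class TooFewAnchorsError(ValueError):
    """Raised when a binning plan cannot be built; caller should fall back."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class LinearFit:
    """A fitted line ``y = slope * x + intercept``."""

    slope: float
    intercept: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class BinningPlan:
    """Equal-count, half-overlapping bins over sorted anchor indices.

    ``bin_size`` points per bin, bins starting every ``stride`` indices with
    the final bin right-aligned so that the last index is always covered.
    """

    bin_size: int
    stride: int
    bin_index_ranges: tuple[tuple[int, int], ...]

    @property
    def n_bins(self) -> int:
        return len(self.bin_index_ranges)


def fit_theil_sen(x, y) -> LinearFit:
    """Fit a Theil-Sen line: median pairwise slope, median residual intercept.

    The slope is the median of all pairwise slopes ``(y_j - y_i)/(x_j - x_i)``
    over pairs with distinct x; the intercept is the median of the per-point
    residuals ``y_i - slope * x_i``.  Breakdown point ~29%.

    Raises
    ------
    DegenerateInputError
        If fewer than two points are given, or all x coincide.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"x and y lengths differ: {x.size} != {y.size}")
    if x.size < 2:
        raise DegenerateInputError(
            f"Theil-Sen regression needs at least 2 points, got {x.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.all(x == x[0]):
        raise DegenerateInputError(
            "Theil-Sen regression undefined: all x values identical"
        )
    res = stats.theilslopes(y, x, method="joint")
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept))


def plan_bins(n: int, bin_size: int | None = None) -> BinningPlan:
    """Plan equal-count half-overlapping bins over ``n`` sorted points.

    The default bin size is ``max(round(n/40), 20)`` points (round half up);
    bins start every ``floor(bin_size/2)`` indices and the final bin is
    right-aligned to end at ``n``, so every index is covered.  At ``n = 400``
    this yields 39 bins of 20 points.

    Parameters
    ----------
    n : total number of sorted anchor points.
    bin_size : override the default points-per-bin rule (used by the
        extraction-window model, which feeds ``m/10``-sized bins).

    Raises
    ------
    TooFewAnchorsError
        If ``n < bin_size``; the caller should use a global linear fallback.
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if bin_size is None:
        bin_size = max(_round_half_up(n / 40), 20)
    if bin_size < 2:
        raise ValueError(f"bin_size must be >= 2, got {bin_size}")
    if n < bin_size:
        raise TooFewAnchorsError(
            f"{n} points cannot fill a bin of {bin_size}; fallback required"
        )
    stride = bin_size // 2
    starts = list(range(0, n - bin_size, stride))
    starts.append(n - bin_size)  # right-align the final bin
    ranges = tuple((s, s + bin_size) for s in starts)
    return BinningPlan(bin_size=bin_size, stride=stride, bin_index_ranges=ranges)


class SegmentedTheilSenRegressor(RegressorMixin, BaseEstimator):
    """Piecewise-linear RT <-> iRT regression from binned Theil-Sen fits.

    Anchors are sorted by x and split into overlapping equal-count bins
    (see :func:`plan_bins`).  Per bin, a Theil-Sen line gives one knot:
    x_ref = median x of the bin, y_ref = the line evaluated at x_ref.
    Prediction linearly interpolates between knots and extrapolates with
    the first/last segment slope beyond them.  With fewer than
    ``min_anchors`` anchors (or too few to fill one bin) a single global
    Theil-Sen line is used instead.

    Parameters
    ----------
    mode : {'rt_to_irt', 'irt_to_rt'}
        Semantic direction of the mapping; recorded in serialized models.
    min_anchors : int, default 50
        Minimum anchor count for the segmented fit (50 for targeted DIA
        analysis, 200 for spectral library generation).
    bin_size : int or None
        Override the default ``max(round(n/40), 20)`` points-per-bin rule.

    Attributes
    ----------
    knots_ : ndarray of shape (k, 2) or None
        Strictly-increasing-x reference points; None when the fallback is used.
    fallback_ : LinearFit or None
        Global Theil-Sen line, set when knot construction was not possible.
    n_anchors_ : int
        Number of anchors seen during fit.
    bin_plan_ : BinningPlan or None
        The binning actually applied (None for the fallback path).
    """

    _MODES = ("rt_to_irt", "irt_to_rt")

    def __init__(self, mode: str = "rt_to_irt", min_anchors: int = MIN_ANCHORS_DIA,
                 bin_size: int | None = None):
        self.mode = mode
        self.min_anchors = min_anchors
        self.bin_size = bin_size

    def _validate_xy(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError(f"X must have a single feature, got {x.shape[1]}")
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError(f"X and y lengths differ: {x.size} != {y.size}")
        return x, y

    def fit(self, X, y):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        x, y = self._validate_xy(X, y)
        if x.size < 2 or np.all(x == x[0]):
            raise DegenerateInputError(
                "segmented regression needs >= 2 anchors with distinct x"
            )
        self.n_anchors_ = int(x.size)
        self.knots_ = None
        self.fallback_ = None
        self.bin_plan_ = None
        if x.size >= self.min_anchors:
            try:
                self._fit_segmented(x, y)
            except TooFewAnchorsError:
                pass
        if self.knots_ is None:
            self.fallback_ = fit_theil_sen(x, y)
        return self

    def _fit_segmented(self, x, y):
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        plan = plan_bins(xs.size, bin_size=self.bin_size)
        xr, yr = [], []
        for lo, hi in plan.bin_index_ranges:
            line = fit_theil_sen(xs[lo:hi], ys[lo:hi])
            x_ref = float(np.median(xs[lo:hi]))
            xr.append(x_ref)
            yr.append(line.slope * x_ref + line.intercept)
        xr = np.asarray(xr)
        yr = np.asarray(yr)
        # collapse knots sharing an x_ref (tied medians) to their mean y_ref
        ux, inverse = np.unique(xr, return_inverse=True)
        uy = np.zeros_like(ux)
        counts = np.bincount(inverse)
        np.add.at(uy, inverse, yr)
        uy /= counts
        if ux.size < 2:
            raise TooFewAnchorsError("fewer than 2 distinct knots; fallback required")
        self.knots_ = np.column_stack([ux, uy])
        self.bin_plan_ = plan

    def predict(self, X):
        check_is_fitted(self, "n_anchors_")
        x = np.asarray(X, dtype=float)
        scalar = x.ndim == 0
        if x.ndim == 2:
            x = x[:, 0]
        x = np.atleast_1d(x).astype(float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite prediction input")
        if self.fallback_ is not None:
            out = self.fallback_(x)
        else:
            kx, ky = self.knots_[:, 0], self.knots_[:, 1]
            out = np.interp(x, kx, ky)
            lo_slope = (ky[1] - ky[0]) / (kx[1] - kx[0])
            hi_slope = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2])
            below = x < kx[0]
            above = x > kx[-1]
            out[below] = ky[0] + lo_slope * (x[below] - kx[0])
            out[above] = ky[-1] + hi_slope * (x[above] - kx[-1])
        return float(out[0]) if scalar else out

    def invert(self) -> "SegmentedTheilSenRegressor":
        """Return the inverse mapping (knot coordinates swapped).

        Valid only when the fitted mapping is strictly monotone in y
        (knot y strictly increasing or decreasing; nonzero fallback slope).
        """
        check_is_fitted(self, "n_anchors_")
        other_mode = "irt_to_rt" if self.mode == "rt_to_irt" else "rt_to_irt"
        inv = SegmentedTheilSenRegressor(
            mode=other_mode, min_anchors=self.min_anchors, bin_size=self.bin_size
        )
        inv.n_anchors_ = self.n_anchors_
        inv.bin_plan_ = None
        if self.fallback_ is not None:
            if self.fallback_.slope == 0:
                raise DegenerateInputError("cannot invert a zero-slope line")
            inv.knots_ = None
            inv.fallback_ = LinearFit(
                slope=1.0 / self.fallback_.slope,
                intercept=-self.fallback_.intercept / self.fallback_.slope,
            )
            return inv
        ky = self.knots_[:, 1]
        dy = np.diff(ky)
        if np.all(dy > 0):
            flipped = self.knots_[:, ::-1]
        elif np.all(dy < 0):
            flipped = self.knots_[::-1, ::-1]
        else:
            raise DegenerateInputError(
                "cannot invert: knot y values are not strictly monotone"
            )
        inv.knots_ = np.ascontiguousarray(flipped)
        inv.fallback_ = None
        return inv

    def to_dict(self) -> dict:
        """JSON-serializable representation; see :func:`irtnorm.io.save_model`."""
        check_is_fitted(self, "n_anchors_")
        return {
            "mode": self.mode,
            "knots": [] if self.knots_ is None else self.knots_.tolist(),
            "fallback": None if self.fallback_ is None else {
                "slope": self.fallback_.slope,
                "intercept": self.fallback_.intercept,
            },
            "meta": {"n_anchors": self.n_anchors_},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentedTheilSenRegressor":
        est = cls(mode=d["mode"])
        knots = np.asarray(d.get("knots") or [], dtype=float)
        est.knots_ = knots.reshape(-1, 2) if knots.size else None
        fb = d.get("fallback")
        est.fallback_ = None if fb is None else LinearFit(fb["slope"], fb["intercept"])
        if est.knots_ is None and est.fallback_ is None:
            raise ValueError("model has neither knots nor fallback")
        est.n_anchors_ = int(d.get("meta", {}).get("n_anchors", 0))
        est.bin_plan_ = None
        return est


def build_segmented_model(x, y, mode: str = "rt_to_irt",
                          min_anchors: int = MIN_ANCHORS_DIA,
                          bin_size: int | None = None) -> SegmentedTheilSenRegressor:
    """Fit and return a :class:`SegmentedTheilSenRegressor` on anchor arrays."""
    return SegmentedTheilSenRegressor(
        mode=mode, min_anchors=min_anchors, bin_size=bin_size
    ).fit(x, y)


def predict(model: SegmentedTheilSenRegressor, x):
    """Evaluate a fitted segmented model at ``x`` (scalar or array)."""
    return model.predict(x)
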